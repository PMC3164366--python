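"""Readers and writers: TSV for tables, JSON for structured results.

Readers validate and reject malformed input (naming offending lines) rather
than coercing it.  Writers embed the run configuration so every artifact
records how it was produced; two runs with identical configuration and seed
produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core import ComparisonResult, StepRecord
from .crossspecies import DirectionalSignature, HomologMap
from .errors import ContractError, FormatError
from .preprocess import CONTROL, TREATMENT, ExpressionMatrix, FoldChangeTable, RankedGeneList

__all__ = [
    "RunConfig",
    "read_design",
    "read_probe_map",
    "read_expression_matrix",
    "write_fold_change_table",
    "read_fold_change_table",
    "write_ranked_list",
    "read_ranked_list",
    "write_comparison_result",
    "read_comparison_result",
    "write_signature",
    "read_signature",
    "read_homolog_map",
    "dump_json",
]


@dataclass(frozen=True)
class RunConfig:
    """Parameters echoed into every output artifact."""

    step: int = 100
    alpha: float = 0.05
    percentile: float = 0.25
    fold_change_mode: str = "log_diff"
    direction: str = "both"
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        return cls(**{k: d[k] for k in d if k in {f.name for f in dataclasses.fields(cls)}})


def dump_json(obj, path: str | Path) -> None:
    """Canonical JSON serialization: sorted keys, fixed layout, full float
    precision (repr round-trip), trailing newline."""
    text = json.dumps(obj, sort_keys=True, indent=2)
    Path(path).write_text(text + "\n")


def read_design(path: str | Path) -> dict[str, str]:
    """Two-column TSV sample -> condition ('treatment' or 'control')."""
    design: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 tab-separated columns")
        sample, cond = parts
        if cond not in (TREATMENT, CONTROL):
            raise FormatError(
                f"{path}: line {lineno}: condition must be '{TREATMENT}' or "
                f"'{CONTROL}', got {cond!r}"
            )
        if sample in design:
            raise FormatError(f"{path}: line {lineno}: duplicate sample {sample!r}")
        design[sample] = cond
    if not design:
        raise FormatError(f"{path}: empty design")
    return design


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV probeset id -> gene symbol."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 tab-separated columns")
        probe, gene = parts
        if probe in mapping:
            raise FormatError(f"{path}: line {lineno}: duplicate probeset {probe!r}")
        mapping[probe] = gene
    return mapping


def read_expression_matrix(
    path: str | Path,
    design: Mapping[str, str] | str | Path,
    probe_map: Mapping[str, str] | str | Path | None = None,
) -> ExpressionMatrix:
    """Tab-delimited matrix: header of sample names, first column probeset id.

    ``design`` maps every used sample to its condition; samples named in the
    design but absent from the header are an error, as are duplicate
    probeset ids and rows with missing or non-numeric scores (reported with
    their line numbers).  Probesets not covered by ``probe_map`` (when
    given) keep their own id as gene symbol.
    """
    if not isinstance(design, Mapping):
        design = read_design(design)
    if probe_map is not None and not isinstance(probe_map, Mapping):
        probe_map = read_probe_map(probe_map)

    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    samples = header[1:]
    unknown = [s for s in design if s not in samples]
    if unknown:
        raise FormatError(f"{path}: design references samples absent from header: {unknown}")
    used = [s for s in samples if s in design]
    if not used:
        raise FormatError(f"{path}: no sample in the header appears in the design")
    col_idx = [samples.index(s) + 1 for s in used]
    labels = [design[s] for s in used]
    if TREATMENT not in labels or CONTROL not in labels:
        raise FormatError(f"{path}: design must assign both treatment and control columns")

    probeset_ids: list[str] = []
    rows: list[list[float]] = []
    seen: dict[str, int] = {}
    bad_lines: list[int] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise FormatError(
                f"{path}: line {lineno}: expected {len(header)} columns, got {len(parts)}"
            )
        pid = parts[0]
        if pid in seen:
            raise FormatError(
                f"{path}: line {lineno}: duplicate probeset id {pid!r} "
                f"(first seen on line {seen[pid]})"
            )
        seen[pid] = lineno
        try:
            values = [float(parts[i]) for i in col_idx]
        except ValueError:
            bad_lines.append(lineno)
            continue
        if not all(np.isfinite(values)):
            bad_lines.append(lineno)
            continue
        probeset_ids.append(pid)
        rows.append(values)
    if bad_lines:
        raise FormatError(
            f"{path}: rows with missing or non-numeric scores on lines {bad_lines}"
        )
    if not rows:
        raise FormatError(f"{path}: no data rows")
    gene_symbols = [
        (probe_map.get(p, p) if probe_map is not None else p) for p in probeset_ids
    ]
    return ExpressionMatrix(
        probeset_ids=probeset_ids,
        gene_symbols=gene_symbols,
        scores=np.array(rows, dtype=float),
        condition_labels=labels,
    )


def write_fold_change_table(fc: FoldChangeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_symbol\tfold_change\n")
        for g, v in zip(fc.genes, fc.fold_change):
            fh.write(f"{g}\t{float(v)!r}\n")


def read_fold_change_table(path: str | Path) -> FoldChangeTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_symbol": str},
                     float_precision="round_trip")
    if list(df.columns) != ["gene_symbol", "fold_change"]:
        raise FormatError(f"{path}: expected columns gene_symbol, fold_change")
    if df["fold_change"].isna().any():
        bad = df.index[df["fold_change"].isna()].tolist()
        raise FormatError(f"{path}: non-numeric fold changes at data rows {bad}")
    return FoldChangeTable(
        genes=df["gene_symbol"].to_numpy(dtype=object),
        fold_change=df["fold_change"].to_numpy(dtype=float),
    )


def write_ranked_list(rlist: RankedGeneList, path: str | Path) -> None:
    """TSV (rank, gene_symbol, fold_change) with direction and universe size
    in comment headers so the list round-trips."""
    sign = 1.0 if rlist.direction == "up" else -1.0
    with open(path, "w") as fh:
        fh.write(f"# direction: {rlist.direction}\n")
        fh.write(f"# universe_size: {rlist.universe_size}\n")
        fh.write("rank\tgene_symbol\tfold_change\n")
        for i, (g, mag) in enumerate(zip(rlist.genes, rlist.magnitudes), start=1):
            fh.write(f"{i}\t{g}\t{float(sign * mag)!r}\n")


def read_ranked_list(path: str | Path) -> RankedGeneList:
    direction = None
    universe = None
    data_lines: list[tuple[int, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("# direction:"):
            direction = line.split(":", 1)[1].strip()
        elif line.startswith("# universe_size:"):
            universe = int(line.split(":", 1)[1].strip())
        elif line.startswith("#") or not line.strip():
            continue
        else:
            data_lines.append((lineno, line))
    if direction not in ("up", "down") or universe is None:
        raise FormatError(f"{path}: missing '# direction:' or '# universe_size:' header")
    if not data_lines or data_lines[0][1].split("\t")[0] != "rank":
        raise FormatError(f"{path}: missing column header line")
    genes: list[str] = []
    mags: list[float] = []
    for lineno, line in data_lines[1:]:
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}: line {lineno}: expected 3 columns")
        try:
            fc = float(parts[2])
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: non-numeric fold change") from None
        genes.append(parts[1])
        mags.append(abs(fc))
    return RankedGeneList(
        direction=direction, genes=genes, magnitudes=np.array(mags), universe_size=universe
    )


def _result_to_dict(result: ComparisonResult) -> dict:
    return {
        "direction": result.direction,
        "universe_size": result.universe_size,
        "step": result.step,
        "alpha": result.alpha,
        "verdict": result.verdict,
        "selected_depth": result.selected_depth,
        "overlap_size": result.overlap_size,
        "common_genes": list(result.common_genes),
        "trace": [
            {
                "m": rec.m,
                "k": rec.k,
                "overlap_p": rec.overlap_p,
                "increment_p": rec.increment_p,
                "significant": rec.significant,
            }
            for rec in result.trace
        ],
    }


def write_comparison_result(
    result: ComparisonResult, path: str | Path, config: RunConfig | None = None
) -> None:
    payload = _result_to_dict(result)
    payload["config"] = (config or RunConfig(step=result.step, alpha=result.alpha)).to_dict()
    dump_json(payload, path)


def read_comparison_result(path: str | Path) -> ComparisonResult:
    d = json.loads(Path(path).read_text())
    try:
        return ComparisonResult(
            direction=d["direction"],
            universe_size=d["universe_size"],
            step=d["step"],
            alpha=d["alpha"],
            selected_depth=d["selected_depth"],
            common_genes=list(d["common_genes"]),
            trace=[
                StepRecord(
                    m=r["m"], k=r["k"], overlap_p=r["overlap_p"],
                    increment_p=r["increment_p"], significant=r["significant"],
                )
                for r in d["trace"]
            ],
            verdict=d["verdict"],
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing field {exc}") from None


def write_signature(sig: DirectionalSignature, path: str | Path) -> None:
    dump_json(
        {
            "species": sig.species,
            "up_genes": sorted(sig.up_genes),
            "down_genes": sorted(sig.down_genes),
        },
        path,
    )


def read_signature(path: str | Path) -> DirectionalSignature:
    d = json.loads(Path(path).read_text())
    try:
        return DirectionalSignature(
            species=d["species"], up_genes=set(d["up_genes"]), down_genes=set(d["down_genes"])
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing field {exc}") from None


def read_homolog_map(path: str | Path) -> HomologMap:
    """Two-column TSV (gene_a, gene_b); an optional third column is a
    HomoloGene-style group id, in which case pairs are the within-group
    cross product of A and B genes."""
    two_col: list[tuple[str, str]] = []
    three_col: list[tuple[str, str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) == 2:
            two_col.append((parts[0], parts[1]))
        elif len(parts) == 3:
            three_col.append((parts[0], parts[1], parts[2]))
        else:
            raise FormatError(f"{path}: line {lineno}: expected 2 or 3 columns")
    if two_col and three_col:
        raise FormatError(f"{path}: mixed 2- and 3-column rows")
    if three_col:
        return HomologMap.from_groups(three_col)
    return HomologMap(pairs=sorted(set(two_col)))
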