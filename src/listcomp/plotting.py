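"""Step-trace scatter: fraction shared (k/m) vs fraction selected (m/N).

Significant steps are drawn in red, non-significant in blue — the standard
way to eyeball how deep the marching comparison got before a criterion
failed.  Requires matplotlib (optional dependency)."""

from __future__ import annotations

from pathlib import Path

from .core import ComparisonResult

__all__ = ["plot_trace"]


def plot_trace(result: ComparisonResult, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = result.universe_size
    ms = [rec.m / n for rec in result.trace]
    ks = [rec.k / rec.m for rec in result.trace]
    sig = [rec.significant for rec in result.trace]
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter([m for m, s in zip(ms, sig) if s], [k for k, s in zip(ks, sig) if s],
               c="red", s=18, label="significant")
    ax.scatter([m for m, s in zip(ms, sig) if not s], [k for k, s in zip(ks, sig) if not s],
               c="blue", s=18, label="chance")
    ax.plot([0, 1], [0, 1], ls=":", c="grey", lw=1)
    ax.set_xlabel("fraction of genes selected (m/N)")
    ax.set_ylabel("fraction of genes in common (k/m)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    ax.set_title(f"{result.direction}: {result.verdict}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
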