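import numpy as np
import pytest

from listcomp import ExpressionMatrix, FoldChangeTable


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """Four probesets, 3+3 replicates, constant within replicate groups."""
    scores = np.array([
        [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
        [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
        [3.0, 3.0, 3.0, 3.0, 3.0, 3.0],
        [4.0, 4.0, 4.0, 4.0, 4.0, 4.0],
    ])
    return ExpressionMatrix(
        probeset_ids=["p1", "p2", "p3", "p4"],
        gene_symbols=["A", "B", "C", "D"],
        scores=scores,
        condition_labels=["treatment"] * 3 + ["control"] * 3,
    )


@pytest.fixture
def simple_fc() -> FoldChangeTable:
    return FoldChangeTable(
        genes=np.array(["A", "B", "C", "D"], dtype=object),
        fold_change=np.array([3.0, -2.0, 1.0, 0.0]),
    )
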