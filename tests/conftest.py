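import numpy as np
import pytest

from placentome import (
    ComparisonSpec,
    ExpressionMatrix,
    GeneAnnotation,
    ImprintStatus,
)


@pytest.fixture
def comparison():
    return ComparisonSpec("ivf_g1g2", "control")


@pytest.fixture
def small_matrix():
    """4 transcripts x 3 conditions with known log2 values."""
    values = np.array(
        [
            [5.0, 5.0, 7.0],   # 4-fold up in g1g2
            [8.0, 6.5, 6.8],   # down in both
            [6.0, 6.0, 6.0],   # flat
            [7.0, 7.4, 5.9],   # mild up / down
        ]
    )
    return ExpressionMatrix(
        ["t1", "t2", "t3", "t4"], ["control", "ivf_m16", "ivf_g1g2"], values
    )


@pytest.fixture
def small_annotations():
    return [
        GeneAnnotation("t1", "GeneA", "X", 1000),
        GeneAnnotation("t2", "GeneB", "7", 2000, ImprintStatus.PATERNAL),
        GeneAnnotation("t3", "GeneB", "7", 2000, ImprintStatus.PATERNAL),
        GeneAnnotation("t4", "GeneC", "2", 3000),
    ]


def make_records(ratios, comparison=None, classify=True, prefix="tx"):
    """Build (optionally classified) fold-change records from raw log2 ratios."""
    from placentome import FoldChangeRecord, classify_fold_change

    comparison = comparison or ComparisonSpec("ivf_g1g2", "control")
    records = [
        FoldChangeRecord(f"{prefix}{i}", comparison, float(r))
        for i, r in enumerate(ratios)
    ]
    return classify_fold_change(records) if classify else records
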