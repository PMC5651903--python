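import numpy as np
import pandas as pd
import pytest

from perksig.io import ExpressionStudy, GeneLociTable, GenomicIntervalSet, SurvivalTable


@pytest.fixture
def tiny_study():
    """3 genes x 5 samples with tumor/normal labels; linear scale."""
    values = pd.DataFrame(
        {
            "t1": [3.0, 1.0, 10.0],
            "t2": [7.0, 3.0, 12.0],
            "t3": [15.0, 1.0, 9.0],
            "n1": [1.0, 1.0, 11.0],
            "n2": [3.0, 3.0, 10.0],
        },
        index=["gA", "gB", "gC"],
    )
    groups = pd.Series(
        ["tumor", "tumor", "tumor", "normal", "normal"], index=values.columns
    )
    return ExpressionStudy(values=values, sample_group=groups)


@pytest.fixture
def toy_survival():
    """Two groups of two subjects each, all events: A at {1,2}, B at {3,4}."""
    return SurvivalTable(
        pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1", "b2"],
                "time": [1.0, 2.0, 3.0, 4.0],
                "event": [1, 1, 1, 1],
            }
        )
    )


@pytest.fixture
def toy_loci():
    return GeneLociTable(
        pd.DataFrame(
            {
                "gene": ["gL", "gR"],
                "chrom": ["chr1", "chr1"],
                "tss": [100, 1000],
                "strand": ["+", "-"],
            }
        )
    )


def make_intervals(rows, fmt="bed"):
    """rows: (chrom, start, end, name) or + (score, strand, ...)."""
    recs = []
    for r in rows:
        rec = {
            "chrom": r[0],
            "start": r[1],
            "end": r[2],
            "name": r[3] if len(r) > 3 else "p",
            "score": "0",
            "strand": ".",
        }
        if len(r) > 4:
            rec["summit"] = r[4]
        recs.append(rec)
    return GenomicIntervalSet(pd.DataFrame(recs), source_format=fmt)


def random_survival(rng, n_min=10, n_max=80):
    n = int(rng.integers(n_min, n_max))
    t = rng.exponential(50.0, n).round(3) + 0.001
    e = rng.integers(0, 2, n)
    if e.sum() == 0:
        e[0] = 1
    ids = [f"s{j:03d}" for j in range(n)]
    return (
        SurvivalTable(pd.DataFrame({"sample_id": ids, "time": t, "event": e})),
        np.asarray(ids),
        t,
        e,
    )
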