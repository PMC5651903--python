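"""Derive a cancer-specific signature from a pathway gene list, score samples
by mean signature expression, and bin samples into strata.

The derivation mirrors a volcano-plot filter: per-gene tumor-vs-normal
difference of mean log2(x + c) expression plus an equal-variance two-sided
Student t-test, then a twofold (log2 fold change >= 1) and Bonferroni
(p <= alpha / n_tests) cut.  Sample scores are the mean of log2(x + c) over
the signature genes; strata are rank-based top/bottom tertiles, top half, or
top/bottom 33% with the middle third unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionStudy

log = logging.getLogger(__name__)

__all__ = [
    "DifferentialTable",
    "GeneSignature",
    "ScoreTable",
    "StrataAssignment",
    "differential_expression",
    "derive_signature",
    "score_samples",
    "bin_by_score",
    "nested_bins",
    "read_scores",
    "write_scores",
    "read_strata",
    "write_strata",
]


@dataclass
class DifferentialTable:
    """Per-gene tumor-vs-normal differential statistics.

    Columns: mean_tumor, mean_normal (mean log2(x+c) per group), log2fc
    (their difference), t, p, constant (True where the gene was flat across
    every sample of both groups and t/p were defined as 0/1).
    """

    table: pd.DataFrame
    pseudocount: float = 1.0

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneSignature:
    """A derived gene list together with the thresholds that produced it."""

    genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class ScoreTable:
    """Per-sample signature score (mean log2(x+c) over signature genes)."""

    scores: pd.Series

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate sample ids in score table")
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            bad = self.scores.index[~np.isfinite(self.scores)].tolist()
            raise ValueError(f"non-finite scores for samples {bad[:10]}")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class StrataAssignment:
    """Sample -> stratum label; ``scheme`` records the binning rule used.

    Tertile scheme labels every sample high/mid/low; the half scheme labels
    high/low; the p33 scheme labels only the top and bottom thirds and leaves
    the middle third out of ``labels`` entirely.
    """

    labels: pd.Series
    scheme: str

    def samples_in(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


def differential_expression(
    study: ExpressionStudy,
    tumor_label: str = "tumor",
    normal_label: str = "normal",
    pseudocount: float = 1.0,
    welch: bool = False,
) -> DifferentialTable:
    """Per-gene difference of mean log2(x+c) with a two-sided Student t-test.

    Equal-variance (pooled) t by default; ``welch=True`` switches to the
    unequal-variance form.  Genes constant across all samples of both groups
    get t = 0, p = 1 and are flagged in the ``constant`` column.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    tumor = study.samples_in_group(tumor_label)
    normal = study.samples_in_group(normal_label)
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(tumor)} {tumor_label!r} "
            f"and {len(normal)} {normal_label!r}"
        )
    lt = np.log2(study.values[tumor].to_numpy(dtype=float) + pseudocount)
    ln = np.log2(study.values[normal].to_numpy(dtype=float) + pseudocount)
    mean_t = lt.mean(axis=1)
    mean_n = ln.mean(axis=1)
    log2fc = mean_t - mean_n
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(lt, ln, axis=1, equal_var=not welch)
    # Flat genes: zero pooled variance. Equal means -> no evidence (t=0, p=1);
    # unequal means with zero variance -> infinitely strong evidence.
    flat = (lt.std(axis=1) == 0) & (ln.std(axis=1) == 0)
    constant = flat & (log2fc == 0)
    t = np.where(constant, 0.0, t)
    p = np.where(constant, 1.0, p)
    degenerate = flat & (log2fc != 0)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.sign(log2fc) * np.inf, t)
    p = np.where(degenerate, 0.0, p)
    if constant.any():
        log.warning("%d genes constant across both groups (t=0, p=1)", constant.sum())
    table = pd.DataFrame(
        {
            "mean_tumor": mean_t,
            "mean_normal": mean_n,
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "constant": constant,
        },
        index=study.values.index,
    )
    return DifferentialTable(table=table, pseudocount=pseudocount)


def derive_signature(
    diff: DifferentialTable,
    fc_threshold_log2: float = 1.0,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> GeneSignature:
    """Genes over-expressed at least ``2**fc_threshold_log2``-fold and
    significant after Bonferroni correction (p <= alpha / n_tests)."""
    if fc_threshold_log2 <= 0 and not np.isinf(fc_threshold_log2):
        raise ValueError("fc_threshold_log2 must be positive")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if len(diff) == 0:
        log.warning("empty differential table; returning empty signature")
        members: list[str] = []
        n_tests = n_tests or 0
    else:
        if n_tests is None:
            n_tests = len(diff)
        cutoff = alpha / n_tests
        t = diff.table
        members = list(t.index[(t["log2fc"] >= fc_threshold_log2) & (t["p"] <= cutoff)])
    return GeneSignature(
        genes=members,
        provenance={
            "fc_threshold_log2": fc_threshold_log2,
            "alpha": alpha,
            "n_tests": n_tests,
            "pseudocount": diff.pseudocount,
        },
    )


def score_samples(
    study: ExpressionStudy,
    signature: GeneSignature,
    pseudocount: float = 1.0,
    strict: bool = True,
) -> ScoreTable:
    """Per-sample mean of log2(x + c) over the signature genes."""
    if len(signature) == 0:
        raise ValueError("cannot score with an empty signature")
    present = [g for g in signature.genes if g in study.values.index]
    missing = sorted(set(signature.genes) - set(present))
    if missing:
        if strict:
            raise ValueError(f"signature genes missing from study: {missing[:10]}")
        log.warning("dropping %d signature genes missing from study", len(missing))
    if not present:
        raise ValueError("no signature genes present in the study")
    sub = np.log2(study.values.loc[present].to_numpy(dtype=float) + pseudocount)
    return ScoreTable(pd.Series(sub.mean(axis=0), index=study.values.columns, name="score"))


def _ranked_ids(scores: ScoreTable) -> list[str]:
    # Descending score; ties broken by ascending sample id for reproducibility.
    df = pd.DataFrame({"score": scores.scores})
    df["sample_id"] = df.index.astype(str)
    df = df.sort_values(["score", "sample_id"], ascending=[False, True], kind="mergesort")
    return list(df.index)


def bin_by_score(scores: ScoreTable, scheme: str = "tertile") -> StrataAssignment:
    """Rank samples by score (descending) and assign strata.

    tertile: high = top floor(N/3), low = bottom floor(N/3), rest mid.
    half:    high = top floor(N/2), low = the rest.
    p33:     as tertile but the middle third is left unassigned.
    """
    n = len(scores)
    if scheme in ("tertile", "p33") and n < 3:
        raise ValueError(f"scheme {scheme!r} needs >=3 samples, got {n}")
    if scheme == "half" and n < 2:
        raise ValueError("scheme 'half' needs >=2 samples")
    order = _ranked_ids(scores)
    if scheme == "half":
        k = n // 2
        labels = pd.Series("low", index=pd.Index(order))
        labels.iloc[:k] = "high"
    elif scheme in ("tertile", "p33"):
        k = n // 3
        labels = pd.Series("mid", index=pd.Index(order))
        labels.iloc[:k] = "high"
        labels.iloc[n - k :] = "low"
        if scheme == "p33":
            labels = labels[labels != "mid"]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return StrataAssignment(labels=labels.rename("stratum"), scheme=scheme)


def nested_bins(
    scores_outer: ScoreTable,
    scores_inner: ScoreTable,
    scheme: str = "p33",
) -> StrataAssignment:
    """Two-level stratification: outer top/bottom 33% bins, then the same
    binning on the inner score *within* each outer bin, yielding four cells
    labeled outer_inner (high_high, high_low, low_high, low_low)."""
    if set(scores_outer.scores.index) != set(scores_inner.scores.index):
        raise ValueError("outer and inner score tables must cover the same samples")
    outer = bin_by_score(scores_outer, scheme=scheme)
    pieces = []
    for outer_label in ("high", "low"):
        members = outer.samples_in(outer_label)
        inner_scores = ScoreTable(scores_inner.scores.loc[members])
        inner = bin_by_score(inner_scores, scheme=scheme)
        pieces.append(inner.labels.map(lambda s, o=outer_label: f"{o}_{s}"))
    labels = pd.concat(pieces)
    return StrataAssignment(labels=labels.rename("stratum"), scheme=f"nested_{scheme}")


def write_scores(scores: ScoreTable, path) -> None:
    pd.DataFrame(
        {"sample_id": scores.scores.index, "score": scores.scores.values}
    ).to_csv(path, sep="\t", index=False)


def read_scores(path) -> ScoreTable:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "score"}.issubset(df.columns):
        raise ValueError("score file needs columns sample_id, score")
    return ScoreTable(pd.Series(df["score"].values, index=df["sample_id"].astype(str).values, name="score"))


def write_strata(strata: StrataAssignment, path) -> None:
    pd.DataFrame(
        {
            "sample_id": strata.labels.index,
            "stratum": strata.labels.values,
            "scheme": strata.scheme,
        }
    ).to_csv(path, sep="\t", index=False)


def read_strata(path) -> StrataAssignment:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "stratum"}.issubset(df.columns):
        raise ValueError("strata file needs columns sample_id, stratum")
    scheme = str(df["scheme"].iloc[0]) if "scheme" in df.columns and len(df) else "unknown"
    labels = pd.Series(
        df["stratum"].astype(str).values, index=df["sample_id"].astype(str).values, name="stratum"
    )
    return StrataAssignment(labels=labels, scheme=scheme)
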