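"""Synthetic study generators with planted ground truth.

Each generator emulates the statistical structure one analysis stage
assumes, at the study design sizes of the real cohorts, so every stage of
the pipeline can be validated by parameter recovery without any external
download:

* ``S-CSPS`` — a pathway-sized tumor-vs-normal expression matrix (388 genes,
  1093 tumors, 112 normals) with 23 genes shifted +2 on log2 scale in
  tumors, the target of the signature-derivation filter.
* ``M1`` — a survival cohort of 547 subjects whose event hazard increases
  with a standard-normal score: exponential event times at 0.0076/month in
  the bottom score tertile, scaled by sqrt(1.8) in the middle and by 1.8 in
  the top tertile (a true top-vs-bottom hazard ratio of 1.8), with
  administrative censoring at 120 months.
* ``G1`` — a two-group expression study (5000 genes, 273 + 273 samples) with
  one of 50 hundred-gene sets ("EMT") shifted +1 log2 in the high group, the
  target of the GSEA stage.
* ``C1`` — a synthetic 100 Mb chromosome with 20,000 genes, TF peaks at 14
  of 23 designated signature genes plus ~20% of background genes, and
  H3K27ac peaks directly overlapping the TF peak at exactly 12 of the 14.
* ``SPIKE`` — a five-point spike-in standard curve (1000, 333, 111, 37, 12
  cells) with multiplicative log-normal luminescence noise.

Every generator is a pure function of its config, seed included.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionStudy,
    GeneLociTable,
    GeneSetCollection,
    GenomicIntervalSet,
    SurvivalTable,
    write_expression,
    write_gmt,
    write_intervals,
    write_loci,
    write_sample_groups,
    write_survival,
)
from .signature import ScoreTable

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionScenario",
    "SurvivalScenario",
    "GseaScenario",
    "ChipScenario",
    "SpikeScenario",
    "gen_expression_study",
    "gen_survival_cohort",
    "gen_gsea_study",
    "gen_chip_study",
    "gen_spikein",
    "SCENARIOS",
    "simulate_to_dir",
]

# PlantedTruth is a plain JSON-serializable dict; keys are documented in each
# generator's docstring so truth.json sidecars are self-describing.
PlantedTruth = dict


def _check_positive(**counts) -> None:
    for name, value in counts.items():
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class ExpressionScenario:
    """Tumor-vs-normal design with planted over-expressed genes (S-CSPS)."""

    n_genes: int = 388
    n_tumors: int = 1093
    n_normals: int = 112
    n_planted: int = 23
    shift_log2: float = 2.0
    baseline_low: float = 3.0
    baseline_high: float = 8.0
    noise_sd: float = 1.0
    seed: int = 0


@dataclass(frozen=True)
class SurvivalScenario:
    """Score-dependent proportional-hazards cohort (M1)."""

    n_subjects: int = 547
    base_rate: float = 0.0076  # events per month in the bottom tertile
    hazard_ratio: float = 1.8  # top vs bottom tertile
    horizon_months: float = 120.0
    seed: int = 0


@dataclass(frozen=True)
class GseaScenario:
    """Two-group study with one planted enriched gene set (G1)."""

    n_genes: int = 5000
    n_sets: int = 50
    set_size: int = 100
    n_high: int = 273
    n_low: int = 273
    shift_log2: float = 1.0
    planted_set: str = "EMT"
    baseline_low: float = 3.0
    baseline_high: float = 8.0
    noise_sd: float = 1.0
    seed: int = 0


@dataclass(frozen=True)
class ChipScenario:
    """Peak sets with a planted bound-gene fraction (C1)."""

    chrom: str = "chrS"
    chrom_length: int = 100_000_000
    n_genes: int = 20_000
    n_signature: int = 23
    n_bound_signature: int = 14
    n_acetyl_overlap: int = 12
    peak_width: int = 400
    max_offset: int = 500  # peak center within +/- this of the TSS
    background_rate: float = 0.2
    background_acetyl_rate: float = 0.8
    seed: int = 0


@dataclass(frozen=True)
class SpikeScenario:
    """Spike-in standard curve with multiplicative log-normal noise."""

    counts: tuple[int, ...] = (1000, 333, 111, 37, 12)
    intercept: float = 500.0
    slope: float = 150.0
    sigma: float = 0.05
    seed: int = 0


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def gen_expression_study(cfg: ExpressionScenario) -> tuple[ExpressionStudy, PlantedTruth]:
    """Generate a tumor/normal matrix with planted over-expressed genes.

    Per gene, a baseline log2 level mu ~ Uniform(baseline_low, baseline_high);
    per sample a log2 value z ~ Normal(mu, noise_sd); planted genes receive
    +shift_log2 in tumor samples only.  Emitted linear value: max(0, 2^z - 1).

    Truth keys: ``planted_genes``, ``shift_log2``.
    """
    _check_positive(n_genes=cfg.n_genes, n_tumors=cfg.n_tumors, n_normals=cfg.n_normals)
    if cfg.n_planted > cfg.n_genes:
        raise ValueError(
            f"cannot plant {cfg.n_planted} genes in a universe of {cfg.n_genes}"
        )
    rng = np.random.default_rng(cfg.seed)
    genes = _ids("g", cfg.n_genes)
    tumors = _ids("t", cfg.n_tumors)
    normals = _ids("n", cfg.n_normals)
    mu = rng.uniform(cfg.baseline_low, cfg.baseline_high, cfg.n_genes)
    z = rng.normal(mu[:, None], cfg.noise_sd, (cfg.n_genes, cfg.n_tumors + cfg.n_normals))
    planted_idx = np.sort(rng.choice(cfg.n_genes, cfg.n_planted, replace=False))
    z[np.ix_(planted_idx, np.arange(cfg.n_tumors))] += cfg.shift_log2
    values = np.maximum(0.0, np.exp2(z) - 1.0)
    df = pd.DataFrame(values, index=genes, columns=tumors + normals)
    groups = pd.Series(
        ["tumor"] * cfg.n_tumors + ["normal"] * cfg.n_normals,
        index=tumors + normals,
        name="group",
    )
    truth = {
        "planted_genes": [genes[i] for i in planted_idx],
        "shift_log2": cfg.shift_log2,
    }
    return ExpressionStudy(values=df, sample_group=groups), truth


def gen_survival_cohort(
    cfg: SurvivalScenario,
) -> tuple[SurvivalTable, ScoreTable, PlantedTruth]:
    """Generate a cohort whose hazard follows the score tertile.

    Scores are standard normal; event times are exponential with rate
    base_rate (bottom tertile), base_rate*sqrt(HR) (middle), base_rate*HR
    (top), administratively censored at the horizon.

    Truth keys: ``hazard_ratio``, ``rates`` (per tertile), ``tertile`` (per
    subject), ``horizon_months``.
    """
    _check_positive(n_subjects=cfg.n_subjects, base_rate=cfg.base_rate)
    if cfg.hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    rng = np.random.default_rng(cfg.seed)
    ids = _ids("s", cfg.n_subjects)
    scores = rng.normal(0.0, 1.0, cfg.n_subjects)
    order = np.argsort(-scores, kind="stable")  # descending; continuous, no ties
    k = cfg.n_subjects // 3
    tertile = np.full(cfg.n_subjects, "mid", dtype=object)
    tertile[order[:k]] = "top"
    tertile[order[cfg.n_subjects - k :]] = "bottom"
    rates = {
        "bottom": cfg.base_rate,
        "mid": cfg.base_rate * np.sqrt(cfg.hazard_ratio),
        "top": cfg.base_rate * cfg.hazard_ratio,
    }
    lam = np.array([rates[t] for t in tertile])
    raw_times = rng.exponential(1.0 / lam)
    event = (raw_times <= cfg.horizon_months).astype(int)
    times = np.minimum(raw_times, cfg.horizon_months)
    table = SurvivalTable(pd.DataFrame({"sample_id": ids, "time": times, "event": event}))
    score_table = ScoreTable(pd.Series(scores, index=ids, name="score"))
    truth = {
        "hazard_ratio": cfg.hazard_ratio,
        "rates": rates,
        "tertile": dict(zip(ids, tertile)),
        "horizon_months": cfg.horizon_months,
    }
    return table, score_table, truth


def gen_gsea_study(
    cfg: GseaScenario,
) -> tuple[ExpressionStudy, GeneSetCollection, PlantedTruth]:
    """Generate a two-group study plus a gene-set collection with one planted
    enriched set.

    The gene universe is partitioned into n_sets disjoint sets of set_size
    genes; the planted set's genes are shifted +shift_log2 on log2 scale in
    the high group.  Truth keys: ``planted_set``, ``planted_genes``,
    ``shift_log2``.
    """
    _check_positive(n_genes=cfg.n_genes, n_sets=cfg.n_sets, set_size=cfg.set_size)
    if cfg.n_sets * cfg.set_size > cfg.n_genes:
        raise ValueError("gene sets exceed the gene universe")
    rng = np.random.default_rng(cfg.seed)
    genes = _ids("g", cfg.n_genes)
    high = _ids("h", cfg.n_high)
    low = _ids("l", cfg.n_low)
    assignment = rng.permutation(cfg.n_genes)
    sets: dict[str, set[str]] = {}
    planted_genes: list[str] = []
    for i in range(cfg.n_sets):
        name = cfg.planted_set if i == 0 else f"SET_{i + 1:02d}"
        member_idx = assignment[i * cfg.set_size : (i + 1) * cfg.set_size]
        members = [genes[j] for j in member_idx]
        sets[name] = set(members)
        if i == 0:
            planted_genes = sorted(members)
    mu = rng.uniform(cfg.baseline_low, cfg.baseline_high, cfg.n_genes)
    z = rng.normal(mu[:, None], cfg.noise_sd, (cfg.n_genes, cfg.n_high + cfg.n_low))
    if cfg.shift_log2 != 0:
        planted_idx = assignment[: cfg.set_size]
        z[np.ix_(planted_idx, np.arange(cfg.n_high))] += cfg.shift_log2
    values = np.maximum(0.0, np.exp2(z) - 1.0)
    df = pd.DataFrame(values, index=genes, columns=high + low)
    groups = pd.Series(
        ["high"] * cfg.n_high + ["low"] * cfg.n_low, index=high + low, name="group"
    )
    truth = {
        "planted_set": cfg.planted_set if cfg.shift_log2 != 0 else None,
        "planted_genes": planted_genes if cfg.shift_log2 != 0 else [],
        "shift_log2": cfg.shift_log2,
    }
    study = ExpressionStudy(values=df, sample_group=groups)
    return study, GeneSetCollection(sets=sets), truth


def _narrowpeak_frame(chrom: str, starts, ends, names, summits) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "name": names,
            "score": "0",
            "strand": ".",
            "signal_value": "0",
            "p_value": "-1",
            "q_value": "-1",
            "summit": summits,
        }
    )


def gen_chip_study(
    cfg: ChipScenario,
) -> tuple[GenomicIntervalSet, GenomicIntervalSet, GeneLociTable, PlantedTruth]:
    """Generate TF and H3K27ac peak sets plus a gene-locus table.

    TSSs are uniform on one synthetic chromosome.  The designated signature
    genes are drawn from loci isolated by more than 2 kb on both sides, so a
    peak centered within max_offset of such a TSS is guaranteed to annotate
    to that gene (and acetyl peaks near background genes cannot brush the
    signature peaks).  TF peaks are planted at n_bound_signature of the
    signature genes and at a Bernoulli(background_rate) subset of background
    genes; H3K27ac peaks directly overlap the TF peak at exactly
    n_acetyl_overlap of the bound signature genes.

    Truth keys: ``signature_genes``, ``bound_signature_genes``,
    ``acetyl_overlap_count``, ``background_bound_genes``, ``background_rate``.
    """
    _check_positive(n_genes=cfg.n_genes, chrom_length=cfg.chrom_length)
    if not (
        cfg.n_acetyl_overlap <= cfg.n_bound_signature <= cfg.n_signature <= cfg.n_genes
    ):
        raise ValueError("need n_acetyl_overlap <= n_bound_signature <= n_signature <= n_genes")
    rng = np.random.default_rng(cfg.seed)
    # Unique uniform TSS positions, away from the chromosome ends so no peak
    # needs clipping.
    margin = cfg.peak_width + cfg.max_offset + 10
    tss = np.array([], dtype=np.int64)
    while len(tss) < cfg.n_genes:
        cand = rng.integers(margin, cfg.chrom_length - margin, cfg.n_genes - len(tss))
        tss = np.unique(np.concatenate([tss, cand]))
    tss = np.sort(tss[: cfg.n_genes])
    genes = _ids("gene", cfg.n_genes)
    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    loci = GeneLociTable(
        pd.DataFrame({"gene": genes, "chrom": cfg.chrom, "tss": tss, "strand": strands})
    )
    # Signature genes must be isolated enough that a +/-max_offset peak is
    # closest to them and clear of any background-gene peak.
    gaps_prev = np.diff(tss, prepend=-10**12)
    gaps_next = np.diff(tss, append=10**13)
    min_gap = 4 * cfg.max_offset  # 2 kb at defaults
    isolated = np.flatnonzero((gaps_prev > min_gap) & (gaps_next > min_gap))
    if len(isolated) < cfg.n_signature:
        raise ValueError("chromosome too crowded to place isolated signature genes")
    sig_idx = np.sort(rng.choice(isolated, cfg.n_signature, replace=False))
    signature_genes = [genes[i] for i in sig_idx]
    bound_pos = np.sort(rng.choice(cfg.n_signature, cfg.n_bound_signature, replace=False))
    bound_idx = sig_idx[bound_pos]
    half = cfg.peak_width // 2

    tf_starts, tf_ends, tf_names = [], [], []
    sig_peak_rows = []  # row index in the TF set for each bound signature gene
    for j, gi in enumerate(bound_idx):
        offset = int(rng.integers(-cfg.max_offset, cfg.max_offset + 1))
        center = int(tss[gi]) + offset
        sig_peak_rows.append(len(tf_starts))
        tf_starts.append(center - half)
        tf_ends.append(center + half)
        tf_names.append(f"tf_sig_{j + 1:02d}")
    background_idx = np.setdiff1d(np.arange(cfg.n_genes), sig_idx)
    bg_mask = rng.random(len(background_idx)) < cfg.background_rate
    bg_bound_idx = background_idx[bg_mask]
    bg_peak_rows = []
    for j, gi in enumerate(bg_bound_idx):
        offset = int(rng.integers(-cfg.max_offset, cfg.max_offset + 1))
        center = int(tss[gi]) + offset
        bg_peak_rows.append(len(tf_starts))
        tf_starts.append(center - half)
        tf_ends.append(center + half)
        tf_names.append(f"tf_bg_{j + 1:05d}")
    tf = GenomicIntervalSet(
        _narrowpeak_frame(cfg.chrom, tf_starts, tf_ends, tf_names, half),
        source_format="narrowpeak",
    )

    # H3K27ac: directly overlap the TF peak at exactly n_acetyl_overlap of the
    # bound signature genes; the remaining bound signature peaks get no acetyl
    # anywhere near them (guaranteed by signature-gene isolation).
    overlap_pos = np.sort(
        rng.choice(cfg.n_bound_signature, cfg.n_acetyl_overlap, replace=False)
    )
    ac_starts, ac_ends, ac_names = [], [], []
    for j in overlap_pos:
        row = sig_peak_rows[j]
        shift = int(rng.integers(-half // 2, half // 2 + 1))
        ac_starts.append(tf_starts[row] + shift)
        ac_ends.append(tf_ends[row] + shift)
        ac_names.append(f"ac_sig_{j + 1:02d}")
    ac_mask = rng.random(len(bg_peak_rows)) < cfg.background_acetyl_rate
    for j, row in enumerate(bg_peak_rows):
        if ac_mask[j]:
            shift = int(rng.integers(-half // 2, half // 2 + 1))
            ac_starts.append(tf_starts[row] + shift)
            ac_ends.append(tf_ends[row] + shift)
            ac_names.append(f"ac_bg_{j + 1:05d}")
    acetyl = GenomicIntervalSet(
        pd.DataFrame(
            {
                "chrom": cfg.chrom,
                "start": ac_starts,
                "end": ac_ends,
                "name": ac_names,
                "score": "0",
                "strand": ".",
            }
        ),
        source_format="bed",
    )
    truth = {
        "signature_genes": signature_genes,
        "bound_signature_genes": [genes[i] for i in bound_idx],
        "acetyl_overlap_count": int(cfg.n_acetyl_overlap),
        "background_bound_genes": [genes[i] for i in bg_bound_idx],
        "background_rate": cfg.background_rate,
    }
    return tf, acetyl, loci, truth


def gen_spikein(cfg: SpikeScenario) -> tuple[np.ndarray, np.ndarray, PlantedTruth]:
    """Generate a spike-in standard curve.

    Luminescence = (intercept + slope * count) * exp(Normal(0, sigma)).
    Truth keys: ``intercept``, ``slope``, ``sigma``.
    """
    if cfg.slope <= 0:
        raise ValueError("slope must be positive")
    if cfg.sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    counts = np.asarray(cfg.counts, dtype=float)
    noise = np.exp(rng.normal(0.0, cfg.sigma, len(counts))) if cfg.sigma > 0 else 1.0
    lum = (cfg.intercept + cfg.slope * counts) * noise
    truth = {"intercept": cfg.intercept, "slope": cfg.slope, "sigma": cfg.sigma}
    return counts, lum, truth


SCENARIOS = {
    "S-CSPS": ExpressionScenario,
    "M1": SurvivalScenario,
    "G1": GseaScenario,
    "C1": ChipScenario,
    "SPIKE": SpikeScenario,
}


def simulate_to_dir(scenario: str, seed: int, out_dir, **overrides) -> Path:
    """Generate a scenario and write its files plus a truth.json sidecar."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {list(SCENARIOS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SCENARIOS[scenario](seed=seed, **overrides)
    if scenario == "S-CSPS":
        study, truth = gen_expression_study(cfg)
        write_expression(study, out / "expression.tsv")
        write_sample_groups(study.sample_group, out / "groups.tsv")
    elif scenario == "M1":
        table, scores, truth = gen_survival_cohort(cfg)
        write_survival(table, out / "survival.tsv")
        scores.scores.rename_axis("sample_id").reset_index().to_csv(
            out / "scores.tsv", sep="\t", index=False
        )
    elif scenario == "G1":
        study, collection, truth = gen_gsea_study(cfg)
        write_expression(study, out / "expression.tsv")
        write_sample_groups(study.sample_group, out / "groups.tsv")
        write_gmt(collection, out / "sets.gmt")
    elif scenario == "C1":
        tf, acetyl, loci, truth = gen_chip_study(cfg)
        write_intervals(tf, out / "tf_peaks.narrowPeak")
        write_intervals(acetyl, out / "h3k27ac_peaks.bed")
        write_loci(loci, out / "loci.tsv")
        write_gmt(
            GeneSetCollection(sets={"signature": set(truth["signature_genes"])}),
            out / "signature.gmt",
        )
    elif scenario == "SPIKE":
        counts, lum, truth = gen_spikein(cfg)
        pd.DataFrame({"count": counts, "luminescence": lum}).to_csv(
            out / "spikein.tsv", sep="\t", index=False
        )
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {"scenario": scenario, "config": dataclasses.asdict(cfg), "truth": truth},
            fh,
            indent=2,
        )
    return out
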