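"""Peak-to-gene annotation, bound-gene calling, binomial binding enrichment,
and co-localization of two peak sets.

Each peak is assigned the gene whose TSS is nearest its anchor (the summit
when present, otherwise the interval midpoint) on the same chromosome; the
fraction of signature genes that carry a peak is compared against the
background bound fraction with an exact one-sided binomial test.  Overlap
between two interval sets uses half-open semantics (>= 1 shared base).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneLociTable, GenomicIntervalSet
from .signature import GeneSignature

log = logging.getLogger(__name__)

__all__ = [
    "PeakAnnotation",
    "BindingEnrichment",
    "OverlapSummary",
    "annotate_peaks",
    "bound_genes",
    "binding_enrichment",
    "colocalization",
]


@dataclass
class PeakAnnotation:
    """Per-peak closest gene and signed anchor-to-TSS distance.

    Peaks on chromosomes without any gene have gene NaN and are flagged in
    ``unannotated``.
    """

    table: pd.DataFrame  # peak, chrom, anchor, gene, distance, unannotated

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class BindingEnrichment:
    k: int           # bound signature genes
    n: int           # signature size
    p0: float        # background bound fraction
    p: float         # one-sided binomial tail P(X >= k)


@dataclass
class OverlapSummary:
    considered: int
    overlapping: int

    @property
    def fraction(self) -> float:
        return self.overlapping / self.considered


def annotate_peaks(
    peaks: GenomicIntervalSet, loci: GeneLociTable, anchor: str = "summit_else_center"
) -> PeakAnnotation:
    """Assign each peak the gene with minimal |anchor - TSS| on its
    chromosome; ties go to the gene with the lower TSS coordinate."""
    if len(loci) == 0:
        raise ValueError("empty gene loci table")
    if anchor == "summit_else_center":
        anchors = peaks.anchors()
    elif anchor == "center":
        anchors = peaks.starts + (peaks.ends - peaks.starts) // 2
    else:
        raise ValueError(f"unknown anchor rule {anchor!r}")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in loci.data.groupby("chrom"):
        # sort by (tss, gene) so equal TSSs keep a deterministic winner
        sub = sub.sort_values(["tss", "gene"], kind="mergesort")
        by_chrom[chrom] = (sub["tss"].to_numpy(), sub["gene"].to_numpy())
    genes_out = np.full(len(peaks), None, dtype=object)
    dist_out = np.zeros(len(peaks), dtype=np.int64)
    unannotated = np.zeros(len(peaks), dtype=bool)
    chroms = peaks.chroms
    for i in range(len(peaks)):
        entry = by_chrom.get(chroms[i])
        if entry is None:
            unannotated[i] = True
            continue
        tss, gene_names = entry
        a = int(anchors[i])
        j = int(np.searchsorted(tss, a))
        best_j = None
        best_d = None
        for cand in (j - 1, j):
            if 0 <= cand < len(tss):
                d = abs(a - int(tss[cand]))
                # strict < keeps the lower-TSS gene on an exact distance tie
                if best_d is None or d < best_d:
                    best_d = d
                    best_j = cand
        genes_out[i] = gene_names[best_j]
        dist_out[i] = a - int(tss[best_j])
    if unannotated.any():
        log.warning("%d peaks on chromosomes without genes", int(unannotated.sum()))
    table = pd.DataFrame(
        {
            "peak": peaks.records["name"].to_numpy(),
            "chrom": chroms,
            "anchor": anchors,
            "gene": genes_out,
            "distance": dist_out,
            "unannotated": unannotated,
        }
    )
    return PeakAnnotation(table=table)


def bound_genes(annotation: PeakAnnotation, max_distance: float | None = None) -> set[str]:
    """Genes that are the closest gene of at least one peak, optionally
    requiring |distance| <= max_distance."""
    t = annotation.table
    keep = ~t["unannotated"]
    if max_distance is not None:
        keep &= t["distance"].abs() <= max_distance
    return set(t.loc[keep, "gene"])


def binding_enrichment(
    signature: GeneSignature | set,
    bound: set,
    universe: GeneLociTable,
    p0: float | None = None,
) -> BindingEnrichment:
    """Exact one-sided binomial test of signature binding enrichment.

    k = |signature & bound|, n = |signature|; by default p0 is the bound
    fraction among non-signature universe genes; p = P(X >= k | n, p0).
    """
    sig = set(signature.genes) if isinstance(signature, GeneSignature) else set(signature)
    universe_genes = set(universe.gene_ids)
    stray = sig - universe_genes
    if stray:
        raise ValueError(f"signature genes outside the universe: {sorted(stray)[:10]}")
    k = len(sig & bound)
    n = len(sig)
    if p0 is None:
        background = universe_genes - sig
        if not background:
            raise ValueError("no background genes left after excluding the signature")
        p0 = len(bound & background) / len(background)
    if not (0.0 < p0 < 1.0):
        raise ValueError(
            f"degenerate background rate p0={p0}; supply a p0 strictly inside (0,1) "
            "or a universe with both bound and unbound background genes"
        )
    p = float(stats.binom.sf(k - 1, n, p0))
    return BindingEnrichment(k=k, n=n, p0=float(p0), p=p)


def colocalization(
    peaks_at_genes: GenomicIntervalSet, second_mark: GenomicIntervalSet
) -> OverlapSummary:
    """Fraction of peaks sharing >= 1 base (half-open) with the second mark."""
    if len(peaks_at_genes) == 0:
        raise ValueError("empty peak set")
    count = 0
    second_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in second_mark.records.groupby("chrom"):
        order = np.argsort(sub["start"].to_numpy(), kind="mergesort")
        starts = sub["start"].to_numpy()[order]
        ends = sub["end"].to_numpy()[order]
        # prefix max of ends lets one binary search answer "any interval
        # starting before my end that also ends after my start"
        second_by_chrom[chrom] = (starts, np.maximum.accumulate(ends))
    chroms = peaks_at_genes.chroms
    starts = peaks_at_genes.starts
    ends = peaks_at_genes.ends
    for i in range(len(peaks_at_genes)):
        entry = second_by_chrom.get(chroms[i])
        if entry is None:
            continue
        s2, emax = entry
        j = int(np.searchsorted(s2, ends[i], side="left"))  # intervals with start < end_i
        if j > 0 and emax[j - 1] > starts[i]:
            count += 1
    return OverlapSummary(considered=len(peaks_at_genes), overlapping=count)
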