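"""Genotype comparisons of poly(A) usage.

For genes with more than one merged PAC, the dominant PAC (most reads,
summed over a genotype's replicates) is compared between genotypes; a
"shift" is a change of dominant-PAC identity.  Within all of a gene's
PACs, the most common PAS — the single nucleotide with the most reads —
is compared between genotypes as a signed distance in gene orientation
(negative = upstream/5').  Distances are binned ±10 / ±100 / ±1000 / >1000
and histogrammed in a ±40 nt window.  Enrichment of events across target
sets uses Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact


@dataclass
class GenePacSummary:
    gene_id: str
    strand: str
    n_pacs: int
    pac_reads: dict  # genotype -> list of per-PAC read totals (PAC order fixed)
    top_pas: dict  # genotype -> (genomic position, reads) or None if tied
    pac_ids: list = None  # labels aligned with pac_reads entries


@dataclass
class ShiftResult:
    gene_id: str
    dominant: dict  # genotype -> PAC index (or None)
    shifted: bool | None
    excluded_reason: str | None = None


@dataclass
class DistanceResult:
    gene_id: str
    distance: int  # signed, gene orientation: negative = upstream (5')
    bin: str | None = None


def summarize_gene_pacs(gene_id, pacs, pas_count, genotype_map) -> GenePacSummary:
    """Per-genotype PAC read totals and most-common PAS for one gene.

    ``pacs`` are the gene's merged PACs; reads are genuine PAS counts
    summed over each genotype's replicates.  The most common PAS is the
    single position within all of the gene's PACs with the most reads; an
    exact tie leaves it undeterminable (None).
    """
    genotypes = sorted(set(genotype_map.values()))
    strand = pacs[0].strand
    pac_reads = {gt: [0] * len(pacs) for gt in genotypes}
    pos_reads = {gt: {} for gt in genotypes}
    for sample, gt in genotype_map.items():
        for k, pac in enumerate(pacs):
            pos, cnt = pas_count.track("genuine", sample, pac.contig, pac.strand)
            sel = (pos >= pac.start) & (pos < pac.end)
            pac_reads[gt][k] += int(cnt[sel].sum())
            for p, c in zip(pos[sel], cnt[sel]):
                pos_reads[gt][int(p)] = pos_reads[gt].get(int(p), 0) + int(c)
    top_pas = {}
    for gt in genotypes:
        if not pos_reads[gt]:
            top_pas[gt] = None
            continue
        best = max(pos_reads[gt].values())
        winners = [p for p, c in pos_reads[gt].items() if c == best]
        top_pas[gt] = (winners[0], best) if len(winners) == 1 else None
    return GenePacSummary(
        gene_id=gene_id,
        strand=strand,
        n_pacs=len(pacs),
        pac_reads=pac_reads,
        top_pas=top_pas,
        pac_ids=list(range(len(pacs))),
    )


def dominant_pac_shift(summary: GenePacSummary, genotypes=None) -> ShiftResult:
    """Dominant-PAC identity comparison for a multi-PAC gene.

    Single-PAC genes and read-count ties are excluded with a reason rather
    than tie-broken.
    """
    if genotypes is None:
        genotypes = sorted(summary.pac_reads)
    if summary.n_pacs <= 1:
        return ShiftResult(summary.gene_id, {}, None, excluded_reason="single-PAC")
    dominant = {}
    for gt in genotypes:
        reads = summary.pac_reads[gt]
        best = max(reads)
        winners = [k for k, r in enumerate(reads) if r == best]
        if len(winners) != 1 or best == 0:
            return ShiftResult(summary.gene_id, {}, None, excluded_reason="tie")
        dominant[gt] = winners[0]
    a, b = genotypes[:2]
    return ShiftResult(summary.gene_id, dominant, shifted=dominant[a] != dominant[b])


def most_common_pas_distance(summary: GenePacSummary, reference_gt, other_gt) -> DistanceResult | None:
    """Signed distance between most-common PASs, other minus reference.

    Computed in gene orientation (sign flipped on minus-strand genes);
    returns None when either genotype's most-common PAS is undeterminable.
    """
    ref = summary.top_pas.get(reference_gt)
    oth = summary.top_pas.get(other_gt)
    if ref is None or oth is None:
        return None
    d = oth[0] - ref[0]
    if summary.strand == "-":
        d = -d
    return DistanceResult(gene_id=summary.gene_id, distance=int(d))


_BIN_EDGES = (10, 100, 1000)


def bin_label(d: int) -> str:
    mag = abs(d)
    for edge in _BIN_EDGES:
        if mag <= edge:
            sign = "-" if d < 0 else "+"
            return f"{sign}{edge}" if d != 0 else f"+{edge}"
    return ">1000" if d > 0 else "<-1000"


def bin_distances(results) -> tuple:
    """Signed bin counts plus the per-nucleotide histogram in ±40 nt.

    Bins (|d|<=10, 10<|d|<=100, 100<|d|<=1000, |d|>1000, each signed;
    d = 0 counted in the +10 bin) partition the input: counts sum to the
    number of distance results.
    """
    counts: dict = {}
    hist = {d: 0 for d in range(-40, 41)}
    for r in results:
        r.bin = bin_label(r.distance)
        counts[r.bin] = counts.get(r.bin, 0) + 1
        if -40 <= r.distance <= 40:
            hist[r.distance] += 1
    order = ["<-1000", "-1000", "-100", "-10", "+10", "+100", "+1000", ">1000"]
    table = pd.Series({k: counts.get(k, 0) for k in order}, name="n_genes")
    return table, pd.Series(hist, name="n_genes")


def fisher_enrichment(table) -> dict:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    ``table`` is [[a, b], [c, d]], e.g. rows = in/out of a target set,
    columns = event (shifted dominant PAC) yes/no.  The odds ratio uses a
    0.5 (Haldane) correction when any cell is zero; an empty margin leaves
    both statistics undefined (NaN).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return {"odds_ratio": float("nan"), "p": float("nan"), "defined": False}
    _, p = fisher_exact(t.astype(int), alternative="two-sided")
    if (t == 0).any():
        t = t + 0.5
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return {"odds_ratio": float(odds), "p": float(p), "defined": True}
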