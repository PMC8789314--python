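"""Poly(A)-site cluster (PAC) calling by subtractive kernel density.

Per sample, PAS-read 3'-end counts are smoothed with a Gaussian kernel and
the equally smoothed gene-body-read background (scaled to matching read
mass) is subtracted; maximal runs of positive signal, trimmed to the span
of supporting PAS reads, become clusters.  Cluster-level artifact removal
drops any cluster with more misprime-filtered than genuine signal;
replicate consensus keeps clusters overlapping calls in at least two of
three replicates of *both* genotypes; survivors are merged (bedtools-merge
semantics) and organelle/rDNA contigs excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d


@dataclass
class DensityTrack:
    contig: str
    strand: str
    grid_start: int  # genomic coordinate of signal[0]
    signal: np.ndarray  # subtracted density
    foreground: np.ndarray
    background: np.ndarray


@dataclass
class PAC:
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    sample: str | None = None
    support: int = 0  # genuine PAS reads in the interval
    filtered_support: int = 0  # misprime-filtered reads in the interval
    gene_id: str | None = None
    sample_support: dict = field(default_factory=dict)

    def overlaps(self, other) -> bool:
        return (
            self.contig == other.contig
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


def subtractive_kde(
    fg_pos,
    fg_counts,
    bg_pos,
    bg_counts,
    contig: str,
    strand: str,
    bandwidth: float = 15.0,
    background_scale: float | None = None,
    pad: int | None = None,
) -> DensityTrack:
    """Subtracted Gaussian density of PAS ends over gene-body-end background.

    Both tracks are rendered on the same nucleotide grid; densities are
    kernel sums (they integrate to read counts), and the background is
    scaled by ``background_scale`` — defaulting to the foreground/background
    read-count ratio so the subtraction is scale-free.
    """
    fg_pos = np.asarray(fg_pos, dtype=int)
    fg_counts = np.asarray(fg_counts, dtype=float)
    bg_pos = np.asarray(bg_pos, dtype=int)
    bg_counts = np.asarray(bg_counts, dtype=float)
    if fg_pos.size == 0:
        return DensityTrack(contig, strand, 0, np.zeros(0), np.zeros(0), np.zeros(0))
    if pad is None:
        pad = int(np.ceil(4 * bandwidth))
    all_pos = np.r_[fg_pos, bg_pos] if bg_pos.size else fg_pos
    lo = int(all_pos.min()) - pad
    hi = int(all_pos.max()) + pad + 1
    n = hi - lo
    fg = np.zeros(n)
    np.add.at(fg, fg_pos - lo, fg_counts)
    bg = np.zeros(n)
    if bg_pos.size:
        np.add.at(bg, bg_pos - lo, bg_counts)
    fg_d = gaussian_filter1d(fg, sigma=bandwidth, mode="constant")
    bg_d = gaussian_filter1d(bg, sigma=bandwidth, mode="constant")
    if background_scale is None:
        bg_total = bg_counts.sum() if bg_pos.size else 0.0
        background_scale = (fg_counts.sum() / bg_total) if bg_total > 0 else 0.0
    signal = fg_d - background_scale * bg_d
    return DensityTrack(contig, strand, lo, signal, fg_d, bg_d)


def call_clusters(track: DensityTrack, fg_pos, fg_counts, min_reads: int = 2, sample=None):
    """Maximal positive-signal runs, trimmed to supporting PAS reads.

    A run with fewer than ``min_reads`` genuine reads (or with no PAS read
    at all) is discarded.
    """
    fg_pos = np.asarray(fg_pos, dtype=int)
    fg_counts = np.asarray(fg_counts, dtype=float)
    if track.signal.size == 0:
        return []
    pos_mask = track.signal > 0
    # run boundaries
    edges = np.flatnonzero(np.diff(np.r_[0, pos_mask.view(np.int8), 0]))
    clusters = []
    for i in range(0, len(edges), 2):
        run_lo = track.grid_start + edges[i]
        run_hi = track.grid_start + edges[i + 1]  # half-open
        in_run = (fg_pos >= run_lo) & (fg_pos < run_hi)
        if not in_run.any():
            continue
        reads = fg_counts[in_run].sum()
        if reads < min_reads:
            continue
        p = fg_pos[in_run]
        clusters.append(
            PAC(
                contig=track.contig,
                start=int(p.min()),
                end=int(p.max()) + 1,
                strand=track.strand,
                sample=sample,
                support=int(reads),
            )
        )
    return clusters


def call_sample_pacs(
    pas_count,
    sample: str,
    bandwidth: float = 15.0,
    min_reads: int = 2,
    background_scale: float | None = None,
    apply_fp_filter: bool = True,
):
    """Per-sample PAC calling over all contig/strand tracks of a PasCount."""
    gen = pas_count.genuine
    keys = (
        gen.loc[gen["sample"] == sample, ["contig", "strand"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    out = []
    for contig, strand in keys:
        fg_pos, fg_counts = pas_count.track("genuine", sample, contig, strand)
        bg_pos, bg_counts = pas_count.track("background", sample, contig, strand)
        track = subtractive_kde(
            fg_pos, fg_counts, bg_pos, bg_counts, contig, strand,
            bandwidth=bandwidth, background_scale=background_scale,
        )
        pacs = call_clusters(track, fg_pos, fg_counts, min_reads=min_reads, sample=sample)
        fl_pos, fl_counts = pas_count.track("filtered", sample, contig, strand)
        for pac in pacs:
            sel = (fl_pos >= pac.start) & (fl_pos < pac.end)
            pac.filtered_support = int(fl_counts[sel].sum())
        if apply_fp_filter:
            pacs = [p for p in pacs if cluster_fp_filter(p)]
        out.extend(pacs)
    return out


def cluster_fp_filter(pac: PAC) -> bool:
    """Keep a cluster unless it has more filtered (misprimed) than genuine
    signal; equality keeps the cluster."""
    return not pac.filtered_support > pac.support


def replicate_consensus_and_merge(pacs_by_sample: dict, genotype_map: dict, pas_count=None):
    """Replicate-consensus filtering across genotypes, then interval merge.

    A per-sample cluster is retained iff clusters overlapping it (>= 1 bp,
    its own replicate counted) exist in at least two replicates of *each*
    genotype.  Retained clusters are coalesced with bedtools-merge
    semantics (touching or overlapping intervals union).  Per-sample
    support is re-aggregated onto the merged intervals from ``pas_count``
    when given, else by summing retained cluster supports.
    """
    genotypes = sorted(set(genotype_map.values()))
    reps_per_gt: dict = {}
    for s, gt in genotype_map.items():
        reps_per_gt[gt] = reps_per_gt.get(gt, 0) + 1
    for gt, n in reps_per_gt.items():
        if n < 2:
            raise ValueError(f"genotype {gt!r} has {n} replicate(s); need >= 2")

    all_pacs = [p for pacs in pacs_by_sample.values() for p in pacs]

    def supported(pac):
        for gt in genotypes:
            n_reps = 0
            for s, pacs in pacs_by_sample.items():
                if genotype_map[s] != gt:
                    continue
                if any(pac.overlaps(q) for q in pacs):
                    n_reps += 1
            if n_reps < 2:
                return False
        return True

    retained = [p for p in all_pacs if supported(p)]
    merged = merge_intervals(retained)
    for m in merged:
        m.sample_support = {}
        for s in pacs_by_sample:
            if pas_count is not None:
                pos, cnt = pas_count.track("genuine", s, m.contig, m.strand)
                sel = (pos >= m.start) & (pos < m.end)
                m.sample_support[s] = int(cnt[sel].sum())
            else:
                m.sample_support[s] = sum(
                    p.support for p in pacs_by_sample[s] if p.overlaps(m)
                )
        m.support = sum(m.sample_support.values())
    return merged


def merge_intervals(pacs):
    """Union of overlapping/touching clusters per (contig, strand)."""
    out = []
    by_key: dict = {}
    for p in pacs:
        by_key.setdefault((p.contig, p.strand), []).append(p)
    for (contig, strand), group in sorted(by_key.items()):
        group = sorted(group, key=lambda p: (p.start, p.end))
        cur_start, cur_end = group[0].start, group[0].end
        for p in group[1:]:
            if p.start <= cur_end:  # touching intervals coalesce
                cur_end = max(cur_end, p.end)
            else:
                out.append(PAC(contig, cur_start, cur_end, strand))
                cur_start, cur_end = p.start, p.end
        out.append(PAC(contig, cur_start, cur_end, strand))
    return out


def exclude_contigs(pacs, excluded_contigs=(), excluded_intervals=()):
    """Drop clusters on excluded contigs or overlapping excluded loci.

    Returns (kept, n_dropped)."""
    excluded_contigs = set(excluded_contigs)
    kept = []
    dropped = 0
    for p in pacs:
        if p.contig in excluded_contigs:
            dropped += 1
            continue
        hit = any(
            p.contig == c and p.start < e and s < p.end for c, s, e in excluded_intervals
        )
        if hit:
            dropped += 1
            continue
        kept.append(p)
    return kept, dropped


def assign_pacs_to_genes(pacs, genes, extension: int = 200):
    """Assign each merged PAC to a gene by strand-matched overlap.

    Gene spans are extended ``extension`` nt past their annotated 3' end
    (PASs commonly fall downstream of annotation); a PAC overlapping
    several genes goes to the one whose annotated 3' end is nearest.
    Returns (gene_id -> list of PACs, unassigned list); assigned PACs get
    their ``gene_id`` set.
    """
    ext_genes = []
    for g in genes:
        if g.strand == "+":
            ext_genes.append((g.contig, g.start, g.end + extension, g))
        else:
            ext_genes.append((g.contig, max(0, g.start - extension), g.end, g))

    gene_map: dict = {}
    unassigned = []
    for p in pacs:
        cands = [
            g
            for contig, s, e, g in ext_genes
            if contig == p.contig and g.strand == p.strand and p.start < e and s < p.end
        ]
        if not cands:
            unassigned.append(p)
            continue
        if len(cands) > 1:
            mid = (p.start + p.end) / 2
            cands.sort(key=lambda g: abs(g.three_prime_end() - mid))
        g = cands[0]
        p.gene_id = g.gene_id
        gene_map.setdefault(g.gene_id, []).append(p)
    return gene_map, unassigned


def pacs_to_bed(pacs, path):
    with open(path, "w") as fh:
        for p in sorted(pacs, key=lambda q: (q.contig, q.start)):
            name = p.gene_id or "."
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\t{name}\t{p.support}\t{p.strand}\n")
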