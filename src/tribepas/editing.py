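"""Differential A-to-G editing-site calling from aligned RNA-seq.

The workflow mirrors HyperTRIBE target calling: count bases per genomic
position in transcript orientation, keep every position with a mismatch in
any fusion sample as a candidate, test each candidate for a difference in
editing proportion between fusion and free-ADAR control replicates with a
beta-binomial regression (common dispersion across sites), adjust p-values
by Benjamini-Hochberg, then filter to A-to-G, non-SNP sites.  A second
entry point compares two mutant backgrounds with scaled ADAR abundance as a
covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .stats import (
    bh_adjust,
    betabinom_lrt,
    betabinom_lrt_batch,
    estimate_common_rho_batch,
    pooled_log2fc,
)

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class DesignMatrix:
    """Two-group design with an optional per-sample covariate.

    ``group_of`` maps sample id -> group label; ``comparison`` names the
    (reference, alternative) groups — e.g. ("control", "fusion") or
    ("single", "triple").  The covariate (per-sample ADAR transgene
    abundance) is z-scored across the samples entering the comparison.
    """

    group_of: dict
    comparison: tuple
    covariate: dict | None = None

    def __post_init__(self):
        ref, alt = self.comparison
        sizes = {ref: 0, alt: 0}
        for g in self.group_of.values():
            if g in sizes:
                sizes[g] += 1
        for g, n in sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} has {n} sample(s); need >= 2")

    def samples(self) -> list:
        ref, alt = self.comparison
        return [s for s, g in self.group_of.items() if g in (ref, alt)]

    def indicator(self, samples) -> np.ndarray:
        """1 for the alternative group, 0 for the reference group."""
        return np.array(
            [1.0 if self.group_of[s] == self.comparison[1] else 0.0 for s in samples]
        )

    def scaled_covariate(self, samples):
        """Z-scored covariate over ``samples``; None if absent or constant."""
        if self.covariate is None:
            return None
        x = np.array([float(self.covariate[s]) for s in samples])
        sd = x.std(ddof=0)
        if sd == 0:
            warnings.warn("covariate is constant across samples; dropping it")
            return None
        return (x - x.mean()) / sd


@dataclass
class BaseCountMatrix:
    """Per-position base counts in transcript orientation.

    ``positions`` has columns contig, pos (0-based), strand, ref (sense
    base).  ``counts[sample]`` is an (n_positions, 4) array of A/C/G/T
    counts, already complemented for minus-strand genes so that column
    order always refers to the transcript sense strand.
    """

    positions: pd.DataFrame
    counts: dict
    samples: list = field(default_factory=list)

    def __post_init__(self):
        if not self.samples:
            self.samples = list(self.counts)

    def __len__(self) -> int:
        return len(self.positions)

    def coverage(self, sample) -> np.ndarray:
        return self.counts[sample].sum(axis=1)

    def subset(self, mask) -> "BaseCountMatrix":
        idx = np.asarray(mask)
        return BaseCountMatrix(
            positions=self.positions.loc[idx].reset_index(drop=True)
            if idx.dtype == bool
            else self.positions.iloc[idx].reset_index(drop=True),
            counts={s: c[idx] for s, c in self.counts.items()},
            samples=list(self.samples),
        )


def _gene_trees(genes):
    trees: dict = {}
    for g in genes:
        trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end, g)
    return trees


def pileup_counts(
    bam_paths: dict,
    fasta_path,
    genes,
    fusion_samples,
    min_base_quality: int = 20,
    min_coverage: int = 10,
) -> BaseCountMatrix:
    """Strand-aware per-position base counts over annotated genes.

    Positions overlapped by genes on both strands are dropped (editing
    orientation would be ambiguous); positions whose coverage is below
    ``min_coverage`` in every fusion sample are dropped.  Counts and the
    reference base are reported in transcript orientation: for minus-strand
    genes a reference-strand T with C mismatches becomes A with G support.
    """
    import pyfaidx

    fasta = pyfaidx.Fasta(str(fasta_path))
    trees = _gene_trees(genes)
    samples = list(bam_paths)
    bams = {s: pysam.AlignmentFile(str(p)) for s, p in bam_paths.items()}
    for s, bam in bams.items():
        if not bam.has_index():
            raise ValueError(f"BAM for sample {s} is not indexed")
        missing = {g.contig for g in genes} - set(bam.references)
        if missing:
            raise ValueError(f"contigs {sorted(missing)} absent from BAM of {s}")

    pos_rows = []
    count_blocks: dict = {s: [] for s in samples}
    for contig, tree in trees.items():
        ref_seq = str(fasta[contig][:]).upper()
        for iv in sorted(tree):
            gene = iv.data
            # strand-ambiguous span check
            span_hits = tree.overlap(gene.start, gene.end)
            both = {h.data.strand for h in span_hits}
            L = gene.end - gene.start
            ambiguous = np.zeros(L, dtype=bool)
            if len(both) > 1:
                for h in span_hits:
                    if h.data is gene or h.data.strand == gene.strand:
                        continue
                    lo = max(gene.start, h.begin) - gene.start
                    hi = min(gene.end, h.end) - gene.start
                    ambiguous[lo:hi] = True

            block = {}
            for s in samples:
                cc = bams[s].count_coverage(
                    contig, gene.start, gene.end, quality_threshold=min_base_quality
                )
                arr = np.array(cc, dtype=np.int64).T  # (L, 4) in A,C,G,T
                if gene.strand == "-":
                    arr = arr[:, ::-1]  # complement: A<->T, C<->G
                block[s] = arr
            fus_cov = np.max(
                [block[s].sum(axis=1) for s in fusion_samples if s in block], axis=0
            )
            keep = (fus_cov >= min_coverage) & ~ambiguous
            if not keep.any():
                continue
            offs = np.nonzero(keep)[0]
            refs = [ref_seq[gene.start + o] for o in offs]
            if gene.strand == "-":
                refs = [_COMP.get(b, "N") for b in refs]
            for o, rb in zip(offs, refs):
                pos_rows.append((contig, gene.start + int(o), gene.strand, rb))
            for s in samples:
                count_blocks[s].append(block[s][keep])

    for bam in bams.values():
        bam.close()
    if pos_rows:
        positions = pd.DataFrame(pos_rows, columns=["contig", "pos", "strand", "ref"])
        counts = {s: np.vstack(blocks) for s, blocks in count_blocks.items()}
    else:
        positions = pd.DataFrame(columns=["contig", "pos", "strand", "ref"])
        counts = {s: np.zeros((0, 4), dtype=np.int64) for s in samples}
    return BaseCountMatrix(positions=positions, counts=counts, samples=samples)


def detect_candidate_positions(bcm: BaseCountMatrix, fusion_samples) -> BaseCountMatrix:
    """Every position with >=1 non-reference base in >=1 fusion sample.

    No significance filtering happens here — all mismatch positions are
    passed to the differential test.
    """
    ref_idx = np.array([_BASES.index(b) if b in _BASES else -1 for b in bcm.positions["ref"]])
    mism = np.zeros(len(bcm), dtype=bool)
    for s in fusion_samples:
        arr = bcm.counts[s]
        nonref = arr.sum(axis=1) - np.where(
            ref_idx >= 0, arr[np.arange(len(arr)), np.clip(ref_idx, 0, 3)], 0
        )
        mism |= nonref > 0
    mism &= ref_idx >= 0
    return bcm.subset(mism)


def _alt_base_index(bcm, fusion_samples):
    """Most supported non-reference base per position, pooled over fusion samples."""
    pooled = sum(bcm.counts[s] for s in fusion_samples)
    ref_idx = np.array([_BASES.index(b) for b in bcm.positions["ref"]])
    masked = pooled.copy().astype(float)
    masked[np.arange(len(masked)), ref_idx] = -1
    return ref_idx, masked.argmax(axis=1)


def test_differential_editing(alt, coverage, group, covariate=None, rho=None):
    """Replicate-aware two-group test at one site.

    ``alt``/``coverage`` are per-sample alt (G) and alt+ref (G+A) counts;
    ``group`` the 0/1 design indicator.  Returns dict with ``p`` and the
    pooled-proportion ``log2fc`` (one pseudocount on alt and ref totals of
    each group).  A group with zero total coverage raises ValueError (the
    caller skips and logs such sites).
    """
    alt = np.asarray(alt, float)
    coverage = np.asarray(coverage, float)
    group = np.asarray(group, float)
    for gval in (0.0, 1.0):
        if coverage[group == gval].sum() == 0:
            raise ValueError("a group has zero total coverage at this site")
    res = betabinom_lrt(alt, coverage, group, covariate=covariate, rho=rho)
    g1 = group == 1.0
    g0 = ~g1
    res["log2fc"] = pooled_log2fc(
        alt[g1].sum(), (coverage - alt)[g1].sum(), alt[g0].sum(), (coverage - alt)[g0].sum()
    )
    res["prop_alt"] = float(alt[g1].sum() / coverage[g1].sum())
    res["prop_ref_group"] = float(alt[g0].sum() / coverage[g0].sum())
    return res


def run_differential_editing(
    bcm: BaseCountMatrix, design: DesignMatrix, rho=None, use_covariate=False
) -> pd.DataFrame:
    """Test every position of ``bcm`` for differential editing.

    Estimates a common beta-binomial dispersion across sites (unless
    ``rho`` is given), LRTs each site, and BH-adjusts across all tested
    sites.  Returns one row per tested site with per-group pooled
    proportions, log2FC, p_raw and p_adj; skipped sites (a group entirely
    uncovered) are excluded and counted in ``df.attrs['n_skipped']``.
    """
    samples = [s for s in design.samples() if s in bcm.counts]
    grp = design.indicator(samples)
    cov = design.scaled_covariate(samples) if use_covariate else None

    ref_idx, alt_idx = _alt_base_index(
        bcm, [s for s, gv in zip(samples, grp) if gv == 1.0]
    )
    n = len(bcm)
    alt_mat = np.stack(
        [bcm.counts[s][np.arange(n), alt_idx] for s in samples], axis=1
    ).astype(float)
    ref_mat = np.stack(
        [bcm.counts[s][np.arange(n), ref_idx] for s in samples], axis=1
    ).astype(float)
    tot = alt_mat + ref_mat

    g1 = grp == 1.0
    g0 = ~g1
    testable = (tot[:, g1].sum(axis=1) > 0) & (tot[:, g0].sum(axis=1) > 0)
    n_skipped = int((~testable).sum())
    alt_t, tot_t = alt_mat[testable], tot[testable]

    if rho is None:
        rho = estimate_common_rho_batch(alt_t, tot_t, grp, covariate=cov)

    df = bcm.positions.loc[testable].reset_index(drop=True).copy()
    if len(df):
        res = betabinom_lrt_batch(alt_t, tot_t, grp, covariate=cov, rho=rho)
        a1, r1 = alt_t[:, g1].sum(1), (tot_t - alt_t)[:, g1].sum(1)
        a0, r0 = alt_t[:, g0].sum(1), (tot_t - alt_t)[:, g0].sum(1)
        df["alt"] = [_BASES[i] for i in alt_idx[testable]]
        with np.errstate(invalid="ignore", divide="ignore"):
            df["prop_alt_group"] = a1 / np.maximum(a1 + r1, 1)
            df["prop_ref_group"] = a0 / np.maximum(a0 + r0, 1)
        df["log2fc"] = np.log2(((a1 + 1) / (a1 + r1 + 2)) / ((a0 + 1) / (a0 + r0 + 2)))
        df["p_raw"] = res["p"]
        for j, s in enumerate(samples):
            df[f"alt_{s}"] = alt_t[:, j].astype(int)
            df[f"cov_{s}"] = tot_t[:, j].astype(int)
        df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
        df["is_AtoG"] = (df["ref"] == "A") & (df["alt"] == "G")
    df.attrs["n_skipped"] = n_skipped
    df.attrs["rho"] = float(rho)
    df.attrs["samples"] = samples
    df.attrs["groups"] = design.comparison
    return df


def classify_and_filter_sites(
    sites: pd.DataFrame,
    control_samples,
    snp_mask=None,
    control_alt_max: float = 0.35,
    global_alt_min: float = 0.8,
    p_adj_max: float = 0.01,
    log2fc_min: float = 1.0,
    require_significant: bool = True,
) -> pd.DataFrame:
    """A-to-G / SNP / significance filtering of tested sites.

    Drops non-A-to-G sites and positions in the user SNP mask, then
    heuristic SNPs: pooled alt proportion >= ``control_alt_max`` in the
    control samples, or alt proportion >= ``global_alt_min`` in every
    sample.  Flags ``significant_vs_control`` (p_adj < 0.01 and
    log2FC > 1 by default) and, when ``require_significant``, returns only
    significant sites.
    """
    if sites.empty:
        return sites.copy()
    df = sites.copy()
    keep = df["is_AtoG"].to_numpy(copy=True)

    if snp_mask:
        masked = {(c, p) for c, p in snp_mask}
        keep &= ~df.apply(lambda r: (r["contig"], r["pos"]) in masked, axis=1).to_numpy()

    alt_cols = [f"alt_{s}" for s in control_samples]
    cov_cols = [f"cov_{s}" for s in control_samples]
    ctrl_alt = df[alt_cols].sum(axis=1).to_numpy(dtype=float)
    ctrl_cov = df[cov_cols].sum(axis=1).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ctrl_prop = np.where(ctrl_cov > 0, ctrl_alt / np.maximum(ctrl_cov, 1), 0.0)
    snp_ctrl = ctrl_prop >= control_alt_max

    all_alt = df[[c for c in df.columns if c.startswith("alt_")]].to_numpy(float)
    all_cov = df[[c for c in df.columns if c.startswith("cov_")]].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(all_cov > 0, all_alt / np.maximum(all_cov, 1), 1.0)
    snp_global = (props >= global_alt_min).all(axis=1)

    df["is_SNP"] = snp_ctrl | snp_global
    keep &= ~df["is_SNP"].to_numpy()
    df["significant_vs_control"] = (df["p_adj"] < p_adj_max) & (df["log2fc"] > log2fc_min)
    out = df.loc[keep].reset_index(drop=True)
    if require_significant:
        out = out.loc[out["significant_vs_control"]].reset_index(drop=True)
    return out


def compare_backgrounds(
    bcm: BaseCountMatrix,
    design: DesignMatrix,
    control_significant,
    rho=None,
    p_adj_max: float = 0.1,
    abs_log2fc_min: float = 0.25,
) -> pd.DataFrame:
    """Differential editing between triple and single mutant backgrounds.

    Same test family as the fusion-vs-control comparison, with the
    z-scored ADAR abundance as an extra covariate.  ``control_significant``
    is the set of (contig, pos) keys that are significant against the
    free-ADAR control in at least one of the two backgrounds; only such
    positions can be reported, at p_adj < 0.1 and |log2FC| > 0.25.
    """
    df = run_differential_editing(bcm, design, rho=rho, use_covariate=True)
    if df.empty:
        df["reported"] = pd.Series(dtype=bool)
        return df
    ctrl = {(c, p) for c, p in control_significant}
    in_ctrl = df.apply(lambda r: (r["contig"], r["pos"]) in ctrl, axis=1)
    df["significant_background_diff"] = (df["p_adj"] < p_adj_max) & (
        df["log2fc"].abs() > abs_log2fc_min
    )
    df["reported"] = df["significant_background_diff"] & in_ctrl
    return df


def sites_to_target_genes(sites: pd.DataFrame, genes) -> pd.DataFrame:
    """Aggregate significant sites to target genes.

    A gene is a target iff at least one site lies within its annotated
    span.  Sites outside every gene are collected under gene_id
    ``"intergenic"`` rather than dropped.
    """
    trees = _gene_trees(genes)
    rows: dict = {}
    for r in sites.itertuples():
        hits = trees.get(r.contig, IntervalTree()).overlap(r.pos, r.pos + 1)
        hits = [h.data for h in hits if h.data.strand == r.strand]
        if not hits:
            rows.setdefault("intergenic", []).append((r.contig, r.pos))
        for g in hits:
            rows.setdefault(g.gene_id, []).append((r.contig, r.pos))
    return pd.DataFrame(
        [{"gene_id": gid, "n_sites": len(ss), "sites": ss} for gid, ss in sorted(rows.items())]
    )
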