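"""Simulators for HyperTRIBE-style RNA editing experiments.

Two levels are provided:

* :func:`simulate_editing_experiment` writes per-sample coordinate-sorted,
  indexed BAMs with A-to-G edits (transcript orientation) at chosen sites,
  replicate overdispersion, SNPs and uniform sequencing error — the full
  input of the pileup-based caller.
* :func:`simulate_site_counts` draws per-site, per-sample (alt, coverage)
  count pairs directly from the same beta-binomial replicate model, for
  calibration and power studies at scale.

Replicate overdispersion follows a beta-binomial: the per-sample editing
proportion is drawn from a Beta with mean equal to the group proportion and
intra-class correlation ``rho``, then reads covering the site are edited
independently at that realised proportion.  The truth table records both the
group-level and the realised per-sample proportions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .genome import ToyGenome


@dataclass
class Sample:
    sample_id: str
    group: str
    replicate: int
    adar_abundance: float = 1.0

    def __post_init__(self):
        if not np.isfinite(self.adar_abundance) or self.adar_abundance < 0:
            raise ValueError("adar_abundance must be finite and non-negative")


@dataclass
class SampleSheet:
    samples: list
    seed: int = 0

    def __post_init__(self):
        counts = self.group_sizes()
        for g, n in counts.items():
            if n < 2:
                raise ValueError(f"group {g!r} has {n} replicate(s); need >= 2")

    def group_sizes(self) -> dict:
        out: dict = {}
        for s in self.samples:
            out[s.group] = out.get(s.group, 0) + 1
        return out

    def groups(self) -> list:
        seen = []
        for s in self.samples:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def sample_ids(self) -> list:
        return [s.sample_id for s in self.samples]

    def by_group(self, group: str) -> list:
        return [s for s in self.samples if s.group == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "group": s.group,
                    "replicate": s.replicate,
                    "adar_abundance": s.adar_abundance,
                }
                for s in self.samples
            ]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, seed: int = 0) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t")
        samples = [
            Sample(
                sample_id=str(r.sample_id),
                group=str(r.group),
                replicate=int(r.replicate),
                adar_abundance=float(r.adar_abundance),
            )
            for r in df.itertuples()
        ]
        return cls(samples=samples, seed=seed)


def make_sample_sheet(groups, n_replicates=5, adar_abundance=None, seed=0) -> SampleSheet:
    """Sample sheet with ``n_replicates`` per group.

    ``adar_abundance`` may be a mapping group -> (mean, sd) for lognormal-ish
    per-line transgene expression, or None for unit abundance everywhere.
    """
    rng = np.random.default_rng(seed)
    samples = []
    for g in groups:
        for r in range(1, n_replicates + 1):
            if adar_abundance is None:
                ab = 1.0
            else:
                mean, sd = adar_abundance[g]
                ab = float(max(0.05, rng.normal(mean, sd)))
            samples.append(Sample(f"{g}_rep{r}", g, r, ab))
    return SampleSheet(samples=samples, seed=seed)


@dataclass
class EditingTruth:
    """A simulated site: an editing site, or a SNP shared by all groups."""

    contig: str
    pos: int  # 0-based genomic
    strand: str
    proportion_by_group: dict = field(default_factory=dict)
    rho: float = 0.02
    kind: str = "edit"  # edit | snp_hom | snp_het

    def __post_init__(self):
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        for p in self.proportion_by_group.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must be in [0, 1]")


def choose_editing_sites(
    genome: ToyGenome,
    n_sites: int,
    proportion_by_group,
    seed: int,
    rho: float = 0.02,
    n_snp_hom: int = 0,
    n_snp_het: int = 0,
) -> list:
    """Pick ``n_sites`` positions whose sense base is A, plus optional SNPs.

    ``proportion_by_group`` is either a dict (same proportions at every
    site) or a callable rng -> dict drawing per-site proportions.
    """
    rng = np.random.default_rng(seed)
    nuclear = [g for g in genome.gene_models if g.contig not in genome.decoy_contigs]
    candidates = []
    for g in nuclear:
        seq = genome.gene_sequence(g)
        for t, base in enumerate(seq):
            if base == "A" and 5 < t < len(seq) - 5:
                pos = g.start + t if g.strand == "+" else g.end - 1 - t
                candidates.append((g.contig, pos, g.strand))
    total = n_sites + n_snp_hom + n_snp_het
    if total > len(candidates):
        raise ValueError("not enough A positions in the toy genome")
    idx = rng.choice(len(candidates), size=total, replace=False)
    truths = []
    for j, i in enumerate(idx):
        contig, pos, strand = candidates[i]
        if j < n_sites:
            props = proportion_by_group(rng) if callable(proportion_by_group) else dict(proportion_by_group)
            truths.append(EditingTruth(contig, pos, strand, props, rho=rho, kind="edit"))
        elif j < n_sites + n_snp_hom:
            truths.append(EditingTruth(contig, pos, strand, {}, rho=0.0, kind="snp_hom"))
        else:
            truths.append(EditingTruth(contig, pos, strand, {}, rho=0.0, kind="snp_het"))
    return truths


def _bam_header(genome: ToyGenome) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.contigs.items()],
    }


def simulate_editing_experiment(
    genome: ToyGenome,
    truths,
    sheet: SampleSheet,
    out_dir,
    coverage_mean: float = 50.0,
    error_rate: float = 0.001,
    read_length: int = 80,
    covariate_coupling: bool = False,
    base_quality: int = 37,
):
    """Write per-sample BAMs with edits at the truth sites.

    Returns (bam_paths: dict sample_id -> path, truth table DataFrame).
    The truth table has one row per (site, sample) with the realised
    editing proportion actually used for that library.

    With ``covariate_coupling`` the per-sample mean proportion is scaled
    linearly by the sample's ADAR abundance relative to the sheet mean
    (clipped to [0, 1]) — emulating editing efficiency tracking transgene
    expression.
    """
    if coverage_mean <= 0:
        raise ValueError("coverage_mean must be > 0")
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    for t in truths:
        if t.kind == "edit" and genome.sense_base(t.contig, t.pos, t.strand) != "A":
            raise ValueError(
                f"truth site {t.contig}:{t.pos} reference base is not A in "
                "transcript orientation"
            )

    os.makedirs(out_dir, exist_ok=True)
    header = _bam_header(genome)
    mean_ab = float(np.mean([s.adar_abundance for s in sheet.samples])) or 1.0
    contig_arrays = {
        name: np.frombuffer(seq.encode(), dtype="S1") for name, seq in genome.contigs.items()
    }

    # pre-index truths per gene
    truth_by_contig: dict = {}
    for t in truths:
        truth_by_contig.setdefault(t.contig, []).append(t)

    ss = np.random.SeedSequence(sheet.seed)
    children = ss.spawn(len(sheet.samples))
    bam_paths = {}
    records = []
    for s_i, sample in enumerate(sheet.samples):
        rng = np.random.default_rng(children[s_i])
        # realised per-sample proportion for every truth site
        realised = {}
        for t in truths:
            if t.kind == "snp_hom":
                realised[(t.contig, t.pos)] = 1.0
                p_mean = 1.0
            elif t.kind == "snp_het":
                realised[(t.contig, t.pos)] = 0.5
                p_mean = 0.5
            else:
                p_mean = t.proportion_by_group.get(sample.group, 0.0)
                if covariate_coupling:
                    p_mean = float(np.clip(p_mean * sample.adar_abundance / mean_ab, 0.0, 1.0))
                if t.rho > 0 and 0.0 < p_mean < 1.0:
                    conc = 1.0 / t.rho - 1.0
                    realised[(t.contig, t.pos)] = float(
                        rng.beta(p_mean * conc, (1.0 - p_mean) * conc)
                    )
                else:
                    realised[(t.contig, t.pos)] = p_mean
            records.append(
                {
                    "contig": t.contig,
                    "pos": t.pos,
                    "strand": t.strand,
                    "kind": t.kind,
                    "sample_id": sample.sample_id,
                    "group": sample.group,
                    "proportion_group": p_mean,
                    "proportion_realised": realised[(t.contig, t.pos)],
                }
            )

        path = os.path.join(out_dir, f"{sample.sample_id}.bam")
        unsorted = path + ".unsorted"
        tid_of = {name: i for i, name in enumerate(genome.contigs)}
        with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
            rid = 0
            for gene in genome.gene_models:
                glen = gene.length
                n_reads = rng.poisson(coverage_mean * glen / read_length)
                if n_reads == 0:
                    continue
                starts = rng.integers(
                    gene.start, max(gene.start + 1, gene.end - read_length), n_reads
                )
                gene_truths = [
                    t
                    for t in truth_by_contig.get(gene.contig, [])
                    if gene.start <= t.pos < gene.end
                ]
                carr = contig_arrays[gene.contig]
                for st in starts:
                    st = int(st)
                    seq = carr[st : st + read_length].astype("U1")
                    # edits / SNP alleles (plus-strand alt base)
                    for t in gene_truths:
                        off = t.pos - st
                        if 0 <= off < len(seq) and rng.random() < realised[(t.contig, t.pos)]:
                            ref_plus = genome.contigs[t.contig][t.pos]
                            seq[off] = "G" if ref_plus == "A" else "C"
                    # uniform sequencing error
                    if error_rate > 0:
                        n_err = rng.binomial(len(seq), error_rate)
                        for off in rng.integers(0, len(seq), n_err):
                            cur = seq[off]
                            choices = [b for b in "ACGT" if b != cur]
                            seq[off] = choices[int(rng.integers(0, 3))]
                    a = pysam.AlignedSegment()
                    a.query_name = f"{sample.sample_id}:{gene.gene_id}:{rid}"
                    rid += 1
                    a.query_sequence = "".join(seq)
                    a.reference_id = tid_of[gene.contig]
                    a.reference_start = st
                    a.cigartuples = [(0, len(seq))]
                    a.mapping_quality = 60
                    a.flag = 16 if gene.strand == "-" else 0
                    a.query_qualities = pysam.qualitystring_to_array(
                        chr(base_quality + 33) * len(seq)
                    )
                    bam.write(a)
        pysam.sort("-o", path, unsorted)
        os.remove(unsorted)
        pysam.index(path)
        bam_paths[sample.sample_id] = path

    truth_df = pd.DataFrame(records)
    return bam_paths, truth_df


def simulate_site_counts(
    seed: int,
    n_sites: int,
    prop_a,
    prop_b,
    rho: float = 0.02,
    n_rep: tuple = (5, 5),
    coverage_mean: float = 100.0,
    coverage_range: tuple | None = None,
    abundance_a=None,
    abundance_b=None,
    coupling: bool = False,
):
    """Draw (alt, coverage) count matrices for two groups of replicates.

    ``prop_a``/``prop_b`` are scalars or length-``n_sites`` arrays of group
    editing proportions (group a first).  Coverage is Poisson with mean
    ``coverage_mean`` unless ``coverage_range=(lo, hi)`` draws uniform
    integers instead.  With ``coupling``, per-sample mean proportions scale
    linearly with the sample's abundance relative to the overall mean.

    Returns a dict with ``alt`` and ``cov`` (n_sites x m arrays), ``group``
    (length-m 0/1 vector), ``abundance`` and ``realised`` per-sample
    proportions.
    """
    rng = np.random.default_rng(seed)
    ma, mb = n_rep
    m = ma + mb
    group = np.r_[np.zeros(ma), np.ones(mb)]
    prop_a = np.broadcast_to(np.asarray(prop_a, dtype=float), (n_sites,))
    prop_b = np.broadcast_to(np.asarray(prop_b, dtype=float), (n_sites,))
    p_site = np.column_stack([np.tile(prop_a, (ma, 1)).T, np.tile(prop_b, (mb, 1)).T])

    if abundance_a is not None or abundance_b is not None:
        ab = np.r_[np.asarray(abundance_a, dtype=float), np.asarray(abundance_b, dtype=float)]
    else:
        ab = np.ones(m)
    if coupling:
        p_site = np.clip(p_site * (ab / ab.mean())[None, :], 0.0, 1.0)

    if coverage_range is not None:
        cov = rng.integers(coverage_range[0], coverage_range[1] + 1, size=(n_sites, m))
    else:
        cov = rng.poisson(coverage_mean, size=(n_sites, m))

    if rho > 0:
        conc = 1.0 / rho - 1.0
        inner = np.clip(p_site, 1e-12, 1 - 1e-12)
        realised = rng.beta(inner * conc, (1.0 - inner) * conc)
        realised = np.where((p_site == 0) | (p_site == 1), p_site, realised)
    else:
        realised = p_site
    alt = rng.binomial(cov, realised)
    return {
        "alt": alt,
        "cov": cov,
        "group": group,
        "abundance": ab,
        "realised": realised,
        "p_site": p_site,
    }
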