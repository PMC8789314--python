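"""Toy genome and annotation generator.

Builds a small multi-contig genome with non-overlapping gene models on both
strands, per-gene true poly(A) sites (PASs) with per-genotype usage weights,
purine-rich internal-priming decoy stretches inside gene bodies, and
organelle/rDNA analogue contigs, so that every downstream filtering rule has
something real to act on.  All outputs are deterministic functions of the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PURINES = frozenset("AG")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A gene as a plain genomic interval (0-based, half-open)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    # genotype -> list of (genomic PAS position, usage weight); weights sum to 1
    true_pas: dict = field(default_factory=dict)
    # genomic positions immediately upstream (gene orientation) of a
    # purine-rich stretch; oligo-dT mispriming lands here
    internal_prime_decoys: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    def three_prime_end(self) -> int:
        """Genomic coordinate of the annotated 3' end (last transcribed base)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class ToyGenome:
    contigs: dict  # name -> uppercase ACGT string
    gene_models: list
    decoy_contigs: set  # organelle / rDNA analogues

    def validate(self) -> None:
        for name, seq in self.contigs.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name} has non-ACGT characters")
        for g in self.gene_models:
            if g.contig not in self.contigs:
                raise ValueError(f"gene {g.gene_id} on unknown contig {g.contig}")
            if not (0 <= g.start < g.end <= len(self.contigs[g.contig])):
                raise ValueError(f"gene {g.gene_id} outside contig bounds")
        if not self.decoy_contigs <= set(self.contigs):
            raise ValueError("decoy_contigs must be a subset of contig names")

    def gene_sequence(self, gene: GeneModel) -> str:
        """Gene sequence in transcript (sense) orientation."""
        seq = self.contigs[gene.contig][gene.start : gene.end]
        return seq if gene.strand == "+" else revcomp(seq)

    def sense_base(self, contig: str, pos: int, strand: str) -> str:
        base = self.contigs[contig][pos]
        return base if strand == "+" else base.translate(COMPLEMENT)

    def downstream_window(self, contig: str, pos: int, strand: str, size: int = 15) -> str:
        """Sense-strand window immediately downstream of ``pos`` (exclusive)."""
        seq = self.contigs[contig]
        if strand == "+":
            return seq[pos + 1 : pos + 1 + size]
        return revcomp(seq[max(0, pos - size) : pos])

    # ---------------------------------------------------------------- output
    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.contigs:
                fh.write(f">{name}\n")
                seq = self.contigs[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.gene_models:
                fh.write(
                    f"{g.contig}\ttribepas\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for g in self.gene_models:
                fh.write(
                    f"{g.contig}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
                )


def purine_fraction(window: str) -> float:
    if not window:
        return 0.0
    return sum(1 for b in window if b in PURINES) / len(window)


def _random_seq(rng, n: int) -> np.ndarray:
    return rng.integers(0, 4, n)


_BASES = np.array(list("ACGT"))


def _decoy_motif(rng) -> str:
    """15-nt stretch, >=80% purine, starting with a long A run (>=10).

    The leading A run is what an oligo-dT primer can anneal to; the purine
    content is what the downstream mispriming filter keys on.
    """
    n_a = int(rng.integers(10, 13))
    rest = "".join(rng.choice(list("AGAG") + ["C", "T"], size=15 - n_a).tolist())
    motif = "A" * n_a + rest
    # enforce the >=80% purine construction guarantee exactly
    while purine_fraction(motif) < 0.8:
        idx = next(i for i, b in enumerate(motif) if b not in PURINES)
        motif = motif[:idx] + "G" + motif[idx + 1 :]
    return motif


def build_toy_genome(
    seed: int,
    n_genes: int = 50,
    gene_length_range: tuple = (800, 1500),
    decoy_density: float = 0.5,
    intergenic: int = 300,
    pas_per_gene: tuple = (1, 3),
    pas_region: int = 300,
    pas_min_separation: int = 150,
    dominant_shift_fraction: float = 0.1,
    genotypes: tuple = ("wt", "mut"),
    n_nuclear_contigs: int = 2,
) -> ToyGenome:
    """Build a deterministic toy genome with annotation and PAS truth.

    Parameters
    ----------
    decoy_density : probability that a gene carries one internal-priming
        decoy stretch in its body.
    pas_per_gene : inclusive range of true PAS count per gene; PASs sit in
        the last ``pas_region`` nt of the gene, separated by at least
        ``pas_min_separation`` nt.
    dominant_shift_fraction : fraction of multi-PAS genes whose dominant
        PAS usage switches between the two genotypes (ground truth for
        shift-detection tests).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = gene_length_range
    if lo < 2 * pas_region:
        lo = max(lo, 2 * pas_region)
        hi = max(hi, lo + 1)
    rng = np.random.default_rng(seed)

    genes_per_contig = [len(a) for a in np.array_split(np.arange(n_genes), n_nuclear_contigs)]
    contigs: dict = {}
    genes: list = []
    gi = 0
    for ci, n_on_contig in enumerate(genes_per_contig, start=1):
        name = f"chr{ci}"
        parts = []
        pos = 0
        for _ in range(n_on_contig):
            gap = int(rng.integers(intergenic // 2, intergenic + 1))
            parts.append(_random_seq(rng, gap))
            pos += gap
            glen = int(rng.integers(lo, hi + 1))
            gseq = _random_seq(rng, glen)
            parts.append(gseq)
            strand = "+" if rng.random() < 0.5 else "-"
            gi += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{gi:04d}",
                    contig=name,
                    start=pos,
                    end=pos + glen,
                    strand=strand,
                )
            )
            pos += glen
        parts.append(_random_seq(rng, intergenic))
        contigs[name] = "".join(_BASES[np.concatenate(parts)])

    # organelle / rDNA analogue contigs (decoys for contig exclusion);
    # each carries one gene so reads can actually land there
    decoy_names = set()
    for name in ("organelle_1", "rdna_1"):
        glen = int(rng.integers(lo, hi + 1))
        seq = "".join(_BASES[_random_seq(rng, glen + 2 * intergenic)])
        contigs[name] = seq
        decoy_names.add(name)
        gi += 1
        genes.append(
            GeneModel(
                gene_id=f"gene{gi:04d}",
                contig=name,
                start=intergenic,
                end=intergenic + glen,
                strand="+",
            )
        )

    genome = ToyGenome(contigs=contigs, gene_models=genes, decoy_contigs=decoy_names)
    _place_pas_truth(
        genome,
        rng,
        pas_per_gene=pas_per_gene,
        pas_region=pas_region,
        pas_min_separation=pas_min_separation,
        dominant_shift_fraction=dominant_shift_fraction,
        genotypes=genotypes,
    )
    _place_decoys(genome, rng, decoy_density=decoy_density)
    genome.validate()
    return genome


def _place_pas_truth(
    genome, rng, pas_per_gene, pas_region, pas_min_separation, dominant_shift_fraction, genotypes
):
    """Assign true PASs and per-genotype usage weights to every gene."""
    for gene in genome.gene_models:
        max_n = max(1, min(pas_per_gene[1], pas_region // pas_min_separation))
        n_pas = int(rng.integers(pas_per_gene[0], max_n + 1))
        # transcript coordinates measured from the 3' end, spread apart
        offsets = [30 + i * pas_min_separation + int(rng.integers(0, 40)) for i in range(n_pas)]
        positions = []
        for off in offsets:
            if gene.strand == "+":
                positions.append(gene.end - 1 - off)
            else:
                positions.append(gene.start + off)
        # dominant PAS gets the bulk of usage
        w = rng.dirichlet(np.ones(n_pas))
        order = np.argsort(w)[::-1]
        base_w = np.zeros(n_pas)
        base_w[order[0]] = 0.7
        if n_pas > 1:
            base_w[order[1:]] = 0.3 * w[order[1:]] / w[order[1:]].sum()
        else:
            base_w[order[0]] = 1.0
        for pos in positions:
            _write_pas_downstream_element(genome, gene, pos, rng)
        shifted = n_pas > 1 and rng.random() < dominant_shift_fraction
        for gt_i, gt in enumerate(genotypes):
            weights = base_w.copy()
            if shifted and gt_i == 1:
                # swap the two most-used PASs in the second genotype
                a, b = order[0], order[1]
                weights[a], weights[b] = weights[b], weights[a]
            gene.true_pas[gt] = list(zip(positions, weights.tolist()))


def _write_pas_downstream_element(genome, gene, pos, rng):
    """Pyrimidine-containing context downstream of a true PAS.

    Plant poly(A) sites carry U-rich downstream elements; writing spaced
    pyrimidines into the 15 nt downstream of each true PAS emulates that
    and guarantees (by recount) that no window near the site reaches the
    80%-purine mispriming threshold — that failure mode is exercised
    deliberately by the decoy stretches instead.
    """
    offsets = (1, 3, 6, 9, 12, 15)  # sense-strand offsets from the PAS
    seq = genome.contigs[gene.contig]
    chars = list(seq)
    for off in offsets:
        py = "T" if rng.random() < 0.7 else "C"
        if gene.strand == "+":
            i = pos + off
            if i < len(chars):
                chars[i] = py
        else:
            i = pos - off
            if i >= 0:
                chars[i] = "A" if py == "T" else "G"  # plus-strand complement
    genome.contigs[gene.contig] = "".join(chars)


def _place_decoys(genome, rng, decoy_density):
    """Write purine-rich stretches into gene bodies and record positions.

    The decoy position is the last transcribed base before the stretch, i.e.
    where a misprimed read's 3' end will land; the 15-nt window immediately
    downstream of it (gene orientation) is the inserted motif.
    """
    for gene in genome.gene_models:
        if rng.random() >= decoy_density:
            continue
        # keep decoys in the gene body, clear of the PAS region
        body_len = gene.length - 400
        if body_len < 120:
            continue
        t = int(rng.integers(60, body_len))  # transcript coordinate of decoy
        motif = _decoy_motif(rng)
        seq = genome.contigs[gene.contig]
        if gene.strand == "+":
            pos = gene.start + t
            genome.contigs[gene.contig] = seq[: pos + 1] + motif + seq[pos + 16 :]
        else:
            pos = gene.end - 1 - t
            ins = revcomp(motif)
            genome.contigs[gene.contig] = seq[: pos - 15] + ins + seq[pos:]
        gene.internal_prime_decoys.append(pos)
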