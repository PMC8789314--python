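"""Smart-seq2 poly(A)-read simulator.

Generates, per sample, paired alignments where a subset of fragments
carries an untemplated oligo-A tail at a true PAS (with positional jitter),
a subset ends at internal-priming decoy positions (genomically templated
A-rich 3' ends), and the rest are tail-less gene-body fragments.

The BAM stores the *aligned, tail-trimmed* span of the 3'-end mate; the raw
(untrimmed, as-sequenced) sequence and qualities are kept in the ``OS`` and
``OQ`` tags so the tail detector operates on pre-alignment sequence, as it
would on real FASTQs.  Mates are emitted as proper pairs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .editing import SampleSheet, _bam_header
from .genome import ToyGenome, revcomp

TAIL_FLOOR = 9  # detector's minimum untemplated-A run


@dataclass
class SmartSeqConfig:
    reads_per_gene: tuple = (50, 200)  # uniform range per gene per sample
    read_length: int = 80
    fragment_length: int = 300
    tail_nb_size: float = 4.0  # shifted negative binomial above the floor
    tail_nb_p: float = 0.3
    tail_nona_rate: float = 0.02  # internal non-A contamination in tails
    pas_jitter_sd: float = 5.0
    misprime_fraction: float = 0.1
    body_fraction: float = 0.3
    base_quality: int = 37
    fiveprime_t_fraction: float = 0.3  # tails sequenced as leading Ts

    def __post_init__(self):
        fracs = (self.misprime_fraction, self.body_fraction)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("fractions must lie in [0,1] and sum to <= 1")


def _tail_length(rng, cfg) -> int:
    return TAIL_FLOOR + int(rng.negative_binomial(cfg.tail_nb_size, cfg.tail_nb_p))


def _make_tail(rng, cfg) -> str:
    """Oligo-A tail, length >= 9, with internal non-A at most 6% of the span.

    Non-A bases are restricted to internal positions (never the terminal
    base, never the first base) and capped so every simulated tail remains a
    valid longest-suffix call for the detector.
    """
    n = _tail_length(rng, cfg)
    tail = ["A"] * n
    max_mm = int(0.06 * n)
    if max_mm > 0 and n > 2:
        n_mm = min(rng.binomial(n, cfg.tail_nona_rate), max_mm)
        if n_mm > 0:
            pos = rng.choice(np.arange(1, n - 1), size=n_mm, replace=False)
            for p in pos:
                tail[int(p)] = "CGT"[int(rng.integers(0, 3))]
    return "".join(tail)


def simulate_smartseq_experiment(
    genome: ToyGenome,
    sheet: SampleSheet,
    out_dir,
    config: SmartSeqConfig | None = None,
    genotype_of_group=None,
):
    """Write per-sample BAMs plus a per-read truth table.

    ``genotype_of_group`` maps sample-sheet group labels onto the genotype
    keys of ``GeneModel.true_pas`` (identity by default).

    Returns (bam_paths, truth DataFrame).  Truth columns: read id, sample,
    gene, class (tailed|misprime|body), true 3'-end genomic position, and
    the sampled tail length (0 for tail-less classes).
    """
    cfg = config or SmartSeqConfig()
    os.makedirs(out_dir, exist_ok=True)
    header = _bam_header(genome)
    tid_of = {name: i for i, name in enumerate(genome.contigs)}
    ss = np.random.SeedSequence(sheet.seed)
    children = ss.spawn(len(sheet.samples))
    bam_paths = {}
    records = []

    for s_i, sample in enumerate(sheet.samples):
        rng = np.random.default_rng(children[s_i])
        genotype = sample.group if genotype_of_group is None else genotype_of_group[sample.group]
        path = os.path.join(out_dir, f"{sample.sample_id}.bam")
        unsorted = path + ".unsorted"
        with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
            rid = 0
            for gene in genome.gene_models:
                if genotype not in gene.true_pas:
                    raise ValueError(
                        f"gene {gene.gene_id} has no true PAS for genotype {genotype!r}"
                    )
                n_total = int(rng.integers(cfg.reads_per_gene[0], cfg.reads_per_gene[1] + 1))
                p_mis = cfg.misprime_fraction if gene.internal_prime_decoys else 0.0
                p_body = cfg.body_fraction
                p_tail = max(0.0, 1.0 - p_mis - p_body)
                n_tail, n_mis, n_body = rng.multinomial(n_total, [p_tail, p_mis, p_body])

                pas_pos = [p for p, _ in gene.true_pas[genotype]]
                pas_w = np.array([w for _, w in gene.true_pas[genotype]])
                pas_w = pas_w / pas_w.sum()

                for _ in range(n_tail):
                    k = int(rng.choice(len(pas_pos), p=pas_w))
                    jit = int(np.rint(rng.normal(0.0, cfg.pas_jitter_sd)))
                    end = pas_pos[k] + (jit if gene.strand == "+" else -jit)
                    end = _clamp_end(gene, end)
                    tail = _make_tail(rng, cfg)
                    rid += 1
                    _emit_pair(
                        bam, genome, tid_of, gene, end, tail, cfg, rng,
                        f"{sample.sample_id}:{gene.gene_id}:t{rid}",
                    )
                    records.append(
                        _rec(sample, gene, f"{sample.sample_id}:{gene.gene_id}:t{rid}",
                             "tailed", end, len(tail))
                    )
                for _ in range(n_mis):
                    end = int(rng.choice(gene.internal_prime_decoys))
                    # templated A-run downstream of the decoy position
                    ds = genome.downstream_window(gene.contig, end, gene.strand, 15)
                    run = 0
                    for b in ds:
                        if b != "A":
                            break
                        run += 1
                    rid += 1
                    _emit_pair(
                        bam, genome, tid_of, gene, end, None, cfg, rng,
                        f"{sample.sample_id}:{gene.gene_id}:m{rid}", templated_run=run,
                    )
                    records.append(
                        _rec(sample, gene, f"{sample.sample_id}:{gene.gene_id}:m{rid}",
                             "misprime", end, 0)
                    )
                for _ in range(n_body):
                    t = int(rng.integers(cfg.read_length, max(cfg.read_length + 1, gene.length - 20)))
                    end = gene.start + t if gene.strand == "+" else gene.end - 1 - t
                    end = _clamp_end(gene, end)
                    rid += 1
                    _emit_pair(
                        bam, genome, tid_of, gene, end, "", cfg, rng,
                        f"{sample.sample_id}:{gene.gene_id}:b{rid}",
                    )
                    records.append(
                        _rec(sample, gene, f"{sample.sample_id}:{gene.gene_id}:b{rid}",
                             "body", end, 0)
                    )
        pysam.sort("-o", path, unsorted)
        os.remove(unsorted)
        pysam.index(path)
        bam_paths[sample.sample_id] = path

    return bam_paths, pd.DataFrame(records)


def _rec(sample, gene, read_id, klass, end, tail_len):
    return {
        "read_id": read_id,
        "sample_id": sample.sample_id,
        "group": sample.group,
        "gene_id": gene.gene_id,
        "contig": gene.contig,
        "strand": gene.strand,
        "class": klass,
        "true_end": end,
        "tail_length": tail_len,
    }


def _clamp_end(gene, end):
    # keep >20 alignable nt on the 5' side of the read in gene orientation
    if gene.strand == "+":
        return int(np.clip(end, gene.start + 25, gene.end - 1))
    return int(np.clip(end, gene.start, gene.end - 26))


def _aligned_span(gene, end, read_len):
    """Genomic [start, stop) of a read whose 3' end (gene orientation) is ``end``."""
    if gene.strand == "+":
        start = max(gene.start, end - read_len + 1)
        return start, end + 1
    stop = min(gene.end, end + read_len)
    return end, stop


def _emit_pair(bam, genome, tid_of, gene, end, tail, cfg, rng, name, templated_run=0):
    """Write the 3'-end mate (with OS/OQ raw-read tags) and its 5' mate.

    ``tail`` is the untemplated tail string ("" for body reads); ``None``
    marks a misprimed read whose apparent tail is the genomically templated
    A-run of length ``templated_run`` downstream of ``end``.
    """
    aln_start, aln_stop = _aligned_span(gene, end, cfg.read_length)
    plus_seq = genome.contigs[gene.contig][aln_start:aln_stop]
    sense_seq = plus_seq if gene.strand == "+" else revcomp(plus_seq)

    if tail is None:
        apparent = genome.downstream_window(gene.contig, end, gene.strand, 15)[:templated_run]
        raw = sense_seq + apparent
    else:
        raw = sense_seq + tail
    qual = chr(cfg.base_quality + 33) * len(raw)
    if tail != "" and rng.random() < cfg.fiveprime_t_fraction:
        raw = revcomp(raw)  # sequenced from the other end: leading Ts
        qual = qual[::-1]

    a = pysam.AlignedSegment()
    a.query_name = name
    a.query_sequence = plus_seq
    a.reference_id = tid_of[gene.contig]
    a.reference_start = aln_start
    a.cigartuples = [(0, len(plus_seq))]
    a.mapping_quality = 60
    a.is_paired = True
    a.is_read1 = True
    a.is_proper_pair = True
    a.is_reverse = gene.strand == "-"
    a.mate_is_reverse = not a.is_reverse
    a.query_qualities = pysam.qualitystring_to_array(chr(cfg.base_quality + 33) * len(plus_seq))
    a.set_tag("OS", raw)
    a.set_tag("OQ", qual)

    # 5' mate: upstream end of the fragment, opposite orientation
    if gene.strand == "+":
        m_start = max(gene.start, end - cfg.fragment_length + 1)
        m_stop = min(m_start + cfg.read_length, gene.end)
    else:
        m_stop = min(gene.end, end + cfg.fragment_length)
        m_start = max(m_stop - cfg.read_length, gene.start)
    m_seq = genome.contigs[gene.contig][m_start:m_stop]
    b = pysam.AlignedSegment()
    b.query_name = name
    b.query_sequence = m_seq
    b.reference_id = tid_of[gene.contig]
    b.reference_start = m_start
    b.cigartuples = [(0, len(m_seq))]
    b.mapping_quality = 60
    b.is_paired = True
    b.is_read2 = True
    b.is_proper_pair = True
    b.is_reverse = not (gene.strand == "-")
    b.query_qualities = pysam.qualitystring_to_array(chr(cfg.base_quality + 33) * len(m_seq))

    a.next_reference_id = b.reference_id
    a.next_reference_start = b.reference_start
    b.next_reference_id = a.reference_id
    b.next_reference_start = a.reference_start
    bam.write(a)
    bam.write(b)
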