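"""Untemplated poly(A)-tail detection and poly(A)-site (PAS) counting.

A Smart-seq2 read that ran through the poly(A) tail carries a terminal
oligo-A (or, sequenced from the other end, leading oligo-T) run that is not
genomically templated.  This module finds such tails (longest valid
terminal run of length >= 9 with at most 6% non-A, never ending in a
mismatch), applies the post-trimming length/quality filters, locates each
read's PAS as its 3'-most aligned base in gene orientation, filters
oligo-dT mispriming artifacts by the downstream purine content of the
genome, and accumulates per-position per-sample PAS count tracks (genuine
and misprime-filtered kept separately).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .simulate.genome import purine_fraction

TAIL_MIN_LEN = 9
TAIL_MAX_MISMATCH_RATE = 0.06
MIN_TRIMMED_LENGTH = 20  # strict: keep iff length > 20
MIN_TRIMMED_MEANQ = 25.0  # strict: keep iff mean Phred > 25
PURINE_WINDOW = 15
PURINE_MIN_FRACTION = 0.8
PURINE_MIN_WINDOW = 8  # shorter truncated windows are classified genuine


@dataclass
class TailCall:
    read_id: str
    end: str  # "3A" or "5T"
    tail_length: int
    mismatches_in_tail: int
    trimmed_sequence: str
    trimmed_qualities: list
    pass_filters: bool = False

    @property
    def trimmed_length(self) -> int:
        return len(self.trimmed_sequence)

    @property
    def trimmed_mean_quality(self) -> float:
        if not self.trimmed_qualities:
            return float("nan")
        return float(np.mean(self.trimmed_qualities))


def _longest_valid_run(bases, quals, char):
    """Longest valid suffix run of ``char`` scanning from the read end.

    ``bases`` must be ordered so that index 0 is the terminal base.  A
    suffix of length L is valid iff L >= 9 and its mismatch count is at
    most 6% of L; the terminal base itself must match ``char`` — the tail
    terminates the read and may not end in a mismatch.  Returns
    (length, mismatches) of the longest valid suffix, or None.
    """
    if not bases or bases[0] != char:  # tail may not end in a mismatch
        return None
    best = None
    mm = 0
    for L in range(1, len(bases) + 1):
        if bases[L - 1] != char:
            mm += 1
        if L >= TAIL_MIN_LEN and mm <= TAIL_MAX_MISMATCH_RATE * L:
            best = (L, mm)
    return best


def trim_polya_tail(sequence: str, qualities=None, read_id: str = "") -> TailCall | None:
    """Detect and trim a terminal untemplated oligo-A (3') or oligo-T (5') run.

    Returns a :class:`TailCall` with the trimmed read, or None when no
    valid tail exists (a normal outcome for gene-body reads).  When both
    ends carry a valid run the longer one wins (ties prefer the 3' A
    tail).  5'T calls are reverse-complemented downstream before use.
    """
    seq = sequence.upper()
    n = len(seq)
    if qualities is None:
        quals = [40] * n
    elif isinstance(qualities, str):
        quals = [ord(c) - 33 for c in qualities]
    else:
        quals = list(qualities)

    run3 = _longest_valid_run(seq[::-1], quals[::-1], "A") if n else None
    run5 = _longest_valid_run(seq, quals, "T") if n else None
    if run3 is None and run5 is None:
        return None
    if run5 is None or (run3 is not None and run3[0] >= run5[0]):
        L, mm = run3
        trimmed = seq[: n - L]
        tq = quals[: n - L]
        end = "3A"
    else:
        L, mm = run5
        trimmed = seq[L:]
        tq = quals[L:]
        end = "5T"
    return TailCall(
        read_id=read_id,
        end=end,
        tail_length=L,
        mismatches_in_tail=mm,
        trimmed_sequence=trimmed,
        trimmed_qualities=tq,
    )


def filter_trimmed_read(call: TailCall) -> bool:
    """Keep iff trimmed length > 20 and trimmed mean Phred > 25 (strict).

    Reads without quality information are discarded with a warning by the
    caller; a kept read also retains its mate pair downstream.
    """
    if not call.trimmed_qualities:
        return False
    ok = call.trimmed_length > MIN_TRIMMED_LENGTH and call.trimmed_mean_quality > MIN_TRIMMED_MEANQ
    call.pass_filters = ok
    return ok


def locate_pas(read: pysam.AlignedSegment, gene_strand: str, max_terminal_mismatches: int = 2):
    """Genomic PAS of an aligned, trimmed read: 3'-most aligned base in gene
    orientation.  Soft-clipped or mismatched terminal bases (up to
    ``max_terminal_mismatches``, already excluded from the aligned span)
    do not shift the call.  Returns None for unaligned reads.
    """
    if read.is_unmapped:
        return None
    if gene_strand == "+":
        return read.reference_end - 1
    return read.reference_start


def mispriming_read_filter(genome, contig: str, pas: int, gene_strand: str) -> str:
    """Classify a PAS as ``"genuine"`` or ``"misprimed"``.

    Misprimed iff the 15-nt window immediately downstream of the PAS in
    gene orientation (sense positions pas+1 .. pas+15) is at least 80%
    purine (A/G) — a likely oligo-dT mispriming substrate.  Truncated
    windows shorter than 8 bases are classified genuine.
    """
    window = genome.downstream_window(contig, pas, gene_strand, PURINE_WINDOW)
    if len(window) < PURINE_MIN_WINDOW:
        return "genuine"
    return "misprimed" if purine_fraction(window) >= PURINE_MIN_FRACTION else "genuine"


@dataclass
class PasCount:
    """Per-position per-sample 3'-end counts.

    ``genuine`` and ``filtered`` (misprime-removed) are long-form frames
    with columns contig, strand, pos, sample, count; ``background`` holds
    gene-body-read 3' ends for subtractive KDE.
    """

    genuine: pd.DataFrame
    filtered: pd.DataFrame
    background: pd.DataFrame
    summary: pd.DataFrame  # per-sample read accounting

    @staticmethod
    def _frame(counter) -> pd.DataFrame:
        rows = [
            {"contig": c, "strand": st, "pos": p, "sample": s, "count": n}
            for (c, st, p, s), n in sorted(counter.items())
        ]
        return pd.DataFrame(rows, columns=["contig", "strand", "pos", "sample", "count"])

    def track(self, which: str, sample: str, contig: str, strand: str):
        df = getattr(self, which)
        if df.empty:
            return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
        sel = df[(df["sample"] == sample) & (df["contig"] == contig) & (df["strand"] == strand)]
        return sel["pos"].to_numpy(), sel["count"].to_numpy()


def extract_polya(
    bam_paths: dict,
    genome,
    genes,
    max_terminal_mismatches: int = 2,
) -> PasCount:
    """Run the full read-level pipeline over per-sample BAMs.

    Reads are assigned to genes by position (intervaltree); the raw
    as-sequenced read is taken from the ``OS``/``OQ`` tags when present
    (the simulator records it there), otherwise from the alignment record.
    Tail-less reads contribute their 3' ends to the background track.
    """
    trees: dict = {}
    for g in genes:
        trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end, g)

    counts: dict = {}
    filtered: dict = {}
    background: dict = {}
    summaries = []
    for sample, path in bam_paths.items():
        n_in = n_tailed = n_kept = n_misprimed = n_unassigned = 0
        with pysam.AlignmentFile(str(path)) as bam:
            for read in bam.fetch():
                if read.is_secondary or read.is_supplementary or read.is_read2:
                    continue
                n_in += 1
                hits = trees.get(read.reference_name, IntervalTree()).overlap(
                    read.reference_start, read.reference_end
                )
                if not hits:
                    n_unassigned += 1
                    continue
                gene = max(
                    hits,
                    key=lambda h: min(h.end, read.reference_end) - max(h.begin, read.reference_start),
                ).data
                if read.has_tag("OS"):
                    raw = read.get_tag("OS")
                    rq = read.get_tag("OQ") if read.has_tag("OQ") else None
                else:
                    raw = read.query_sequence
                    rq = read.query_qualities
                if rq is None:
                    warnings.warn(f"read {read.query_name} has no qualities; discarded")
                    continue
                call = trim_polya_tail(raw, rq, read_id=read.query_name)
                key_base = (read.reference_name, gene.strand)
                pas = locate_pas(read, gene.strand, max_terminal_mismatches)
                if pas is None:
                    continue
                if call is None:
                    background[key_base + (pas, sample)] = (
                        background.get(key_base + (pas, sample), 0) + 1
                    )
                    continue
                n_tailed += 1
                if not filter_trimmed_read(call):
                    continue
                n_kept += 1
                verdict = mispriming_read_filter(genome, read.reference_name, pas, gene.strand)
                if verdict == "misprimed":
                    n_misprimed += 1
                    filtered[key_base + (pas, sample)] = (
                        filtered.get(key_base + (pas, sample), 0) + 1
                    )
                else:
                    counts[key_base + (pas, sample)] = (
                        counts.get(key_base + (pas, sample), 0) + 1
                    )
        summaries.append(
            {
                "sample": sample,
                "reads_in": n_in,
                "tailed": n_tailed,
                "kept": n_kept,
                "misprimed": n_misprimed,
                "unassigned": n_unassigned,
            }
        )

    def reorder(d):
        return {(c, st, p, s): n for (c, st, p, s), n in d.items()}

    return PasCount(
        genuine=PasCount._frame(reorder(counts)),
        filtered=PasCount._frame(reorder(filtered)),
        background=PasCount._frame(reorder(background)),
        summary=pd.DataFrame(summaries),
    )
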