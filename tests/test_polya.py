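"""Tail trimming, read filtering, PAS location and mispriming filtering."""

import numpy as np
import pytest

from tribepas import polya
from tribepas.simulate import build_toy_genome, make_sample_sheet
from tribepas.simulate.genome import GeneModel, ToyGenome


def brute_force_trim(seq):
    """Independent oracle: scan every terminal window of both read ends.

    A 3' suffix (or 5' prefix of Ts) of length L is a valid tail iff
    L >= 9, its non-A (non-T) count is <= 0.06*L and the read's terminal
    base matches.  Longest valid span wins; ties prefer the 3'A call.
    Returns (end, length) or None.
    """
    n = len(seq)
    best3 = None
    if n and seq[-1] == "A":
        for L in range(9, n + 1):
            window = seq[n - L :]
            if window.count("A") >= L - 0.06 * L:
                best3 = L
    best5 = None
    if n and seq[0] == "T":
        for L in range(9, n + 1):
            window = seq[:L]
            if window.count("T") >= L - 0.06 * L:
                best5 = L
    if best3 is None and best5 is None:
        return None
    if best5 is None or (best3 is not None and best3 >= best5):
        return ("3A", best3)
    return ("5T", best5)


def test_trim_agrees_with_brute_force_on_random_reads(rng):
    bases = np.array(list("ACGT"))
    tails = 0
    for i in range(2000):
        n = int(rng.integers(1, 60))
        seq = "".join(rng.choice(bases, n, p=[0.4, 0.1, 0.1, 0.4]))
        style = i % 4
        if style == 1:  # append a (possibly contaminated) 3' A run
            run = "".join(rng.choice(bases, int(rng.integers(5, 25)), p=[0.92, 0.03, 0.03, 0.02]))
            seq = seq + run
        elif style == 2:  # prepend a 5' T run
            run = "".join(rng.choice(bases, int(rng.integers(5, 25)), p=[0.02, 0.03, 0.03, 0.92]))
            seq = run + seq
        expected = brute_force_trim(seq)
        got = polya.trim_polya_tail(seq)
        if expected is None:
            assert got is None, seq
        else:
            assert got is not None, seq
            assert (got.end, got.tail_length) == expected, seq
            tails += 1
    assert tails > 100  # the base mix actually exercises the tail path


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=300, derandomize=True, deadline=None)
@given(
    body=st.text(alphabet="ACGT", min_size=0, max_size=50),
    tail=st.text(alphabet="AAAAAAAAAAAAACGT", min_size=0, max_size=30),
)
def test_trim_property_matches_brute_force(body, tail):
    """For arbitrary body+A-biased-tail reads the trimmer equals the oracle."""
    seq = body + tail
    expected = brute_force_trim(seq)
    got = polya.trim_polya_tail(seq)
    if expected is None:
        assert got is None
    else:
        assert (got.end, got.tail_length) == expected


@pytest.mark.parametrize(
    "seq,expect_len",
    [
        ("CGTCG" + "A" * 9, 9),  # exactly the floor
        ("CGTCG" + "A" * 8, None),  # below the floor
        ("CGTCG" + "A" * 10 + "G" + "A" * 6, 17),  # 1/17 = 5.9% <= 6%
        ("CGTCG" + "A" * 8 + "G", None),  # may not end in a mismatch
    ],
)
def test_trim_examples(seq, expect_len):
    call = polya.trim_polya_tail(seq)
    if expect_len is None:
        assert call is None
    else:
        assert call.tail_length == expect_len
        assert call.end == "3A"


def test_five_prime_t_tail_detected():
    call = polya.trim_polya_tail("T" * 12 + "GCGCGTACGTCGTACGTAGCTAGCTA")
    assert call is not None and call.end == "5T"
    assert call.tail_length == 12
    assert call.trimmed_sequence == "GCGCGTACGTCGTACGTAGCTAGCTA"


def test_reconstruction_of_trimmed_read():
    seq = "GCGTACGTACGTACGTACGTT" + "A" * 14
    call = polya.trim_polya_tail(seq)
    assert call.trimmed_sequence + "A" * call.tail_length == seq


@pytest.mark.parametrize(
    "length,meanq,keep",
    [(21, 30, True), (20, 40, False), (30, 25, False), (30, 26, True)],
)
def test_filter_strict_inequalities(length, meanq, keep):
    call = polya.TailCall(
        read_id="r", end="3A", tail_length=9, mismatches_in_tail=0,
        trimmed_sequence="G" * length, trimmed_qualities=[meanq] * length,
    )
    assert polya.filter_trimmed_read(call) is keep


def test_filter_discards_missing_qualities():
    call = polya.TailCall("r", "3A", 9, 0, "G" * 30, [])
    assert polya.filter_trimmed_read(call) is False


class TestLocatePas:
    def _read(self, start, length, reverse):
        import pysam

        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c", "LN": 10000}]}
        )
        a = pysam.AlignedSegment(header)
        a.query_name = "r"
        a.query_sequence = "A" * length
        a.reference_id = 0
        a.reference_start = start
        a.cigartuples = [(0, length)]
        a.flag = 16 if reverse else 0
        return a

    def test_plus_gene_end(self):
        read = self._read(970, 31, reverse=False)
        assert polya.locate_pas(read, "+") == 1000

    def test_minus_gene_uses_leftmost_base(self):
        read = self._read(1000, 31, reverse=True)
        assert polya.locate_pas(read, "-") == 1000


class TestMisprimingFilter:
    def _genome(self, window):
        # gene on +; PAS at position 19; window occupies 20..34
        seq = "C" * 20 + window + "C" * 20
        return ToyGenome({"c": seq}, [GeneModel("g", "c", 0, 50, "+")], set())

    def test_boundary_12_of_15_is_misprimed(self):
        g = self._genome("AG" * 6 + "CTT")  # 12 purines / 15
        assert polya.mispriming_read_filter(g, "c", 19, "+") == "misprimed"

    def test_11_of_15_is_genuine(self):
        g = self._genome("AG" * 5 + "ACTTT")  # 11 purines
        assert polya.mispriming_read_filter(g, "c", 19, "+") == "genuine"

    def test_all_purine_window_misprimed(self):
        g = self._genome("A" * 15)
        assert polya.mispriming_read_filter(g, "c", 19, "+") == "misprimed"

    def test_short_truncated_window_genuine(self):
        g = ToyGenome({"c": "C" * 20 + "AAAAA"}, [GeneModel("g", "c", 0, 25, "+")], set())
        # only 5 bases remain downstream of PAS 19+... position 24 leaves none
        assert polya.mispriming_read_filter(g, "c", 20, "+") == "genuine"

    def test_pure_function_of_genome_position_strand(self):
        g = self._genome("A" * 15)
        calls = {polya.mispriming_read_filter(g, "c", 19, "+") for _ in range(5)}
        assert calls == {"misprimed"}

    def test_minus_strand_window(self):
        # minus-strand gene: downstream of PAS 30 is plus-strand [15,30) revcomp'd
        seq = "C" * 15 + "T" * 15 + "C" * 20
        g = ToyGenome({"c": seq}, [GeneModel("g", "c", 10, 45, "-")], set())
        assert polya.mispriming_read_filter(g, "c", 30, "-") == "misprimed"


def test_extract_polya_conservation(toy_genome, tmp_path):
    """Located tailed reads split exactly into genuine + misprimed."""
    from tribepas.simulate import SmartSeqConfig, simulate_smartseq_experiment

    sheet = make_sample_sheet(["wt", "mut"], n_replicates=2, seed=21)
    bams, truth = simulate_smartseq_experiment(
        toy_genome, sheet, tmp_path, config=SmartSeqConfig(reads_per_gene=(20, 40))
    )
    pc = polya.extract_polya(bams, toy_genome, toy_genome.gene_models)
    for r in pc.summary.itertuples():
        genuine = pc.genuine.loc[pc.genuine["sample"] == r.sample, "count"].sum()
        filtered = pc.filtered.loc[pc.filtered["sample"] == r.sample, "count"].sum()
        assert genuine + filtered == r.kept
        assert r.misprimed == filtered
        # every simulated misprime read must be caught by the filter
        n_true_misprime = (
            (truth["sample_id"] == r.sample) & (truth["class"] == "misprime")
        ).sum()
        assert filtered >= n_true_misprime
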