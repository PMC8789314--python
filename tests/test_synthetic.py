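"""Tests of the synthetic-data generators and their construction guarantees."""

import numpy as np
import pytest

from tribepas.polya import trim_polya_tail
from tribepas.simulate import (
    SampleSheet,
    Sample,
    SmartSeqConfig,
    build_toy_genome,
    choose_editing_sites,
    evaluate_recovery,
    make_sample_sheet,
    simulate_editing_experiment,
    simulate_site_counts,
    simulate_smartseq_experiment,
)
from tribepas.simulate.genome import purine_fraction, revcomp


def test_empty_genome_rejected():
    with pytest.raises(ValueError):
        build_toy_genome(seed=1, n_genes=0)


def test_genome_outputs_byte_identical_across_runs(tmp_path):
    for run in ("a", "b"):
        g = build_toy_genome(seed=1, n_genes=50)
        g.write_fasta(tmp_path / f"{run}.fa")
        g.write_gff3(tmp_path / f"{run}.gff3")
        g.write_bed(tmp_path / f"{run}.bed")
    for ext in ("fa", "gff3", "bed"):
        assert (tmp_path / f"a.{ext}").read_bytes() == (tmp_path / f"b.{ext}").read_bytes()


def test_genome_structure(toy_genome):
    g = toy_genome
    strands = {x.strand for x in g.gene_models}
    assert strands == {"+", "-"}
    assert {"organelle_1", "rdna_1"} <= set(g.contigs)
    assert g.decoy_contigs == {"organelle_1", "rdna_1"}
    for gene in g.gene_models:
        assert 0 <= gene.start < gene.end <= len(g.contigs[gene.contig])
        for gt, pas in gene.true_pas.items():
            assert sum(w for _, w in pas) == pytest.approx(1.0)
            for p, _ in pas:
                assert gene.start <= p < gene.end


def test_decoy_windows_purine_rich_by_recount(toy_genome):
    """Recount purines in the written sequence downstream of every decoy."""
    n = 0
    for gene in toy_genome.gene_models:
        for pos in gene.internal_prime_decoys:
            window = toy_genome.downstream_window(gene.contig, pos, gene.strand, 15)
            assert len(window) == 15
            assert purine_fraction(window) >= 0.8
            n += 1
    assert n >= 3


def test_sample_sheet_requires_two_replicates():
    with pytest.raises(ValueError):
        SampleSheet(samples=[Sample("s1", "fusion", 1), Sample("s2", "control", 1)])


def test_truth_site_must_be_A(toy_genome, sheet_fc, tmp_path):
    from tribepas.simulate.editing import EditingTruth

    gene = toy_genome.gene_models[0]
    seq = toy_genome.gene_sequence(gene)
    t_not_a = next(i for i, b in enumerate(seq) if b != "A")
    pos = gene.start + t_not_a if gene.strand == "+" else gene.end - 1 - t_not_a
    bad = EditingTruth(gene.contig, pos, gene.strand, {"fusion": 0.3, "control": 0.0})
    with pytest.raises(ValueError, match="reference base is not A"):
        simulate_editing_experiment(toy_genome, [bad], sheet_fc, tmp_path)


def test_editing_bams_reproduce_proportions_and_snps(toy_genome, sheet_fc, tmp_path):
    """Pooled counts track the simulated proportions; SNPs are group-independent."""
    import pysam

    truths = choose_editing_sites(
        toy_genome, 4, {"fusion": 0.5, "control": 0.0}, seed=3, rho=0.0, n_snp_het=2
    )
    bams, truth = simulate_editing_experiment(
        toy_genome, truths, sheet_fc, tmp_path, coverage_mean=120, error_rate=0.0
    )
    control_ids = [s.sample_id for s in sheet_fc.by_group("control")]
    for t in truths:
        alt = {True: 0, False: 0}  # control or not
        cov = {True: 0, False: 0}
        for sid, path in bams.items():
            with pysam.AlignmentFile(path) as bam:
                cc = np.array(bam.count_coverage(t.contig, t.pos, t.pos + 1))[:, 0]
            ref_plus = toy_genome.contigs[t.contig][t.pos]
            alt_base = "G" if ref_plus == "A" else "C"
            is_ctrl = sid in control_ids
            alt[is_ctrl] += cc["ACGT".index(alt_base)]
            cov[is_ctrl] += cc.sum()
        if t.kind == "snp_het":
            for is_ctrl in (True, False):
                assert alt[is_ctrl] / cov[is_ctrl] == pytest.approx(0.5, abs=0.12)
        else:
            assert alt[False] / cov[False] == pytest.approx(0.5, abs=0.1)
            assert alt[True] == 0  # proportion 0, no sequencing error


def test_site_counts_binomial_bound():
    """rho=0, huge coverage: pooled proportion within the binomial bound."""
    d = simulate_site_counts(2, 5, 0.3, 0.3, rho=0.0, n_rep=(1, 1), coverage_mean=10000)
    pooled = d["alt"].sum(1) / d["cov"].sum(1)
    assert np.abs(pooled - 0.3).max() < 0.01


def test_zero_proportion_site_only_error_background():
    d = simulate_site_counts(3, 20, 0.0, 0.0, rho=0.02, n_rep=(5, 5), coverage_mean=200)
    assert d["alt"].sum() == 0


@pytest.fixture(scope="module")
def sim(toy_genome, tmp_path_factory):
    sheet = make_sample_sheet(["wt", "mut"], n_replicates=2, seed=11)
    cfg = SmartSeqConfig(reads_per_gene=(30, 60), pas_jitter_sd=5.0)
    out = tmp_path_factory.mktemp("smartseq")
    bams, truth = simulate_smartseq_experiment(toy_genome, sheet, out, config=cfg)
    return bams, truth


class TestSmartSeqSimulator:
    def test_class_conservation(self, sim):
        _, truth = sim
        counts = truth.groupby(["sample_id", "gene_id"]).size()
        assert (counts >= 30).all() and (counts <= 60).all()

    def test_all_tails_at_least_floor_and_detectable(self, sim, toy_genome):
        """Every simulated tail is >= 9 nt and a valid detector call."""
        _, truth = sim
        tailed = truth[truth["class"] == "tailed"]
        assert (tailed["tail_length"] >= 9).all()

    def test_tailed_ends_jitter_sd(self, toy_genome, tmp_path):
        """Empirical sd of read ends around the PAS is close to the set sd."""
        sheet = make_sample_sheet(["wt", "mut"], n_replicates=2, seed=4)
        cfg = SmartSeqConfig(
            reads_per_gene=(120, 140), pas_jitter_sd=5.0, misprime_fraction=0.0,
            body_fraction=0.0,
        )
        bams, truth = simulate_smartseq_experiment(toy_genome, sheet, tmp_path, config=cfg)
        devs = []
        by_gene = {g.gene_id: g for g in toy_genome.gene_models}
        for r in truth[truth["class"] == "tailed"].itertuples():
            gene = by_gene[r.gene_id]
            pas = min(
                (p for p, _ in gene.true_pas[r.group]), key=lambda p: abs(p - r.true_end)
            )
            devs.append(r.true_end - pas)
        devs = np.asarray(devs, dtype=float)
        assert len(devs) > 1000
        # clamping at gene edges never triggers for interior PASs; sd in [4, 6]
        assert 4.0 <= devs.std() <= 6.0

    def test_misprime_free_truth_ends_are_true_pas(self, toy_genome, tmp_path):
        sheet = make_sample_sheet(["wt", "mut"], n_replicates=2, seed=5)
        cfg = SmartSeqConfig(
            reads_per_gene=(10, 20), misprime_fraction=0.0, pas_jitter_sd=0.0
        )
        _, truth = simulate_smartseq_experiment(toy_genome, sheet, tmp_path, config=cfg)
        by_gene = {g.gene_id: g for g in toy_genome.gene_models}
        for r in truth[truth["class"] == "tailed"].itertuples():
            pas_set = {p for p, _ in by_gene[r.gene_id].true_pas[r.group]}
            assert r.true_end in pas_set

    def test_raw_reads_carry_valid_tails(self, sim):
        """OS-tag raw sequences of tailed reads pass the tail detector."""
        import pysam

        bams, truth = sim
        klass = dict(zip(truth["read_id"], truth["class"]))
        n_checked = 0
        path = next(iter(bams.values()))
        with pysam.AlignmentFile(path) as bam:
            for read in bam.fetch():
                if read.is_read2 or not read.has_tag("OS"):
                    continue
                if klass.get(read.query_name) != "tailed":
                    continue
                call = trim_polya_tail(read.get_tag("OS"), read.get_tag("OQ"))
                assert call is not None
                assert call.tail_length >= 9
                assert call.mismatches_in_tail / call.tail_length <= 0.06
                n_checked += 1
                if n_checked >= 200:
                    break
        assert n_checked >= 100


class TestEvaluateRecovery:
    def test_perfect_agreement(self):
        r = evaluate_recovery([1, 5, 9], [1, 5, 9], tolerance=0)
        assert r.precision == 1.0 and r.recall == 1.0

    def test_shift_beyond_tolerance(self):
        r = evaluate_recovery([11, 25], [5, 19], tolerance=5)
        assert r.recall == 0.0

    def test_hand_enumerated_mixed_case(self):
        # 3 true, 2 called, exactly 1 match -> precision 1/2, recall 1/3
        r = evaluate_recovery([100, 900], [98, 500, 700], tolerance=5)
        assert r.precision == pytest.approx(0.5)
        assert r.recall == pytest.approx(1 / 3)

    def test_empty_truth_undefined_recall(self):
        r = evaluate_recovery([1, 2], [], tolerance=1)
        assert r.recall is None
        assert r.precision == 0.0

    def test_matching_respects_contig_and_strand(self):
        called = [("chr1", "+", 100)]
        truth = [("chr1", "-", 100), ("chr2", "+", 100)]
        r = evaluate_recovery(called, truth, tolerance=10)
        assert r.n_matched == 0

    def test_categories(self):
        res = evaluate_recovery({"pas": [1]}, {"pas": [1], "decoy": [5]}, tolerance=0)
        assert res["pas"].recall == 1.0
        assert res["decoy"].recall == 0.0


def test_editing_bams_record_identical_across_runs(toy_genome, tmp_path):
    """Same seed => identical alignment records (the BAM container header
    embeds the sort command's temp path, so identity is at record level)."""
    import pysam

    def run(sub):
        sheet = make_sample_sheet(["fusion", "control"], n_replicates=2, seed=5)
        truths = choose_editing_sites(toy_genome, 5, {"fusion": 0.3, "control": 0.0}, seed=5)
        bams, _ = simulate_editing_experiment(
            toy_genome, truths, sheet, tmp_path / sub, coverage_mean=15
        )
        out = {}
        for k, p in bams.items():
            with pysam.AlignmentFile(p) as bam:
                out[k] = [
                    (r.query_name, r.reference_start, r.query_sequence, r.flag)
                    for r in bam.fetch()
                ]
        return out

    assert run("a") == run("b")


def test_revcomp_roundtrip():
    assert revcomp("ACGT") == "ACGT"
    assert revcomp(revcomp("GATTACA")) == "GATTACA"
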