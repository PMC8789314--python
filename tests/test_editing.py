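"""Tests of pileup, candidate detection, site filtering and gene aggregation."""

import numpy as np
import pandas as pd
import pytest

from tribepas import editing as ed
from tribepas.simulate.genome import GeneModel, ToyGenome, revcomp

from conftest import write_mini_bam


@pytest.fixture(scope="module")
def mini_setup(tmp_path_factory):
    """Two genes on opposite strands with hand-placed mismatch reads.

    geneP (+) spans [10, 60); reference base at pos 30 is A.
    geneM (-) spans [70, 120); reference (plus-strand) base at 90 is T,
    i.e. a sense-strand A for the minus-strand gene.
    """
    tmp = tmp_path_factory.mktemp("mini")
    seq = ["C"] * 140
    seq[30] = "A"
    seq[90] = "T"
    contig = "".join(seq)
    genome = ToyGenome(
        contigs={"c1": contig},
        gene_models=[
            GeneModel("geneP", "c1", 10, 60, "+"),
            GeneModel("geneM", "c1", 70, 120, "-"),
        ],
        decoy_contigs=set(),
    )
    fasta = tmp / "mini.fa"
    genome.write_fasta(fasta)

    def read_at(start, length=30, mutate=None):
        s = list(contig[start : start + length])
        if mutate is not None:
            off, base = mutate
            s[off - start] = base
        return "".join(s)

    # fusion: 7 ref + 3 G at pos 30 (plus gene); 3 C-reads at 90 (minus gene)
    fusion_reads = []
    for i in range(7):
        fusion_reads.append((f"fr{i}", "c1", 15, read_at(15), False))
    for i in range(3):
        fusion_reads.append((f"fg{i}", "c1", 15, read_at(15, mutate=(30, "G")), False))
    for i in range(3):
        fusion_reads.append((f"fc{i}", "c1", 75, read_at(75, mutate=(90, "C")), True))
    for i in range(9):
        fusion_reads.append((f"fm{i}", "c1", 75, read_at(75), True))
    # control: clean coverage at both, plus a control-only mismatch at pos 40
    control_reads = []
    for i in range(12):
        control_reads.append((f"cr{i}", "c1", 15, read_at(15), False))
        control_reads.append((f"cm{i}", "c1", 75, read_at(75), True))
    for i in range(4):
        control_reads.append((f"cx{i}", "c1", 15, read_at(15, mutate=(40, "T")), False))

    bams = {
        "fusion_rep1": write_mini_bam(tmp / "f1.bam", {"c1": 140}, fusion_reads),
        "fusion_rep2": write_mini_bam(tmp / "f2.bam", {"c1": 140}, fusion_reads),
        "control_rep1": write_mini_bam(tmp / "c1.bam", {"c1": 140}, control_reads),
        "control_rep2": write_mini_bam(tmp / "c2.bam", {"c1": 140}, control_reads),
    }
    return genome, fasta, bams


FUSION = ["fusion_rep1", "fusion_rep2"]
CONTROL = ["control_rep1", "control_rep2"]


def _pileup(mini_setup, **kw):
    genome, fasta, bams = mini_setup
    kw.setdefault("min_coverage", 5)
    return ed.pileup_counts(bams, fasta, genome.gene_models, FUSION, **kw)


def test_pileup_plus_strand_counts(mini_setup):
    bcm = _pileup(mini_setup)
    df = bcm.positions
    i = df.index[(df["pos"] == 30)][0]
    assert df.loc[i, "ref"] == "A" and df.loc[i, "strand"] == "+"
    assert bcm.counts["fusion_rep1"][i, 0] == 7  # A
    assert bcm.counts["fusion_rep1"][i, 2] == 3  # G


def test_pileup_minus_strand_reported_as_sense(mini_setup):
    """Reference-strand T with C mismatches becomes sense A with G support."""
    bcm = _pileup(mini_setup)
    df = bcm.positions
    i = df.index[(df["pos"] == 90)][0]
    assert df.loc[i, "ref"] == "A" and df.loc[i, "strand"] == "-"
    assert bcm.counts["fusion_rep1"][i, 2] == 3  # G (sense) == plus-strand C
    assert bcm.counts["fusion_rep1"][i, 0] == 9  # A (sense) == plus-strand T


def test_pileup_respects_fusion_coverage_floor(mini_setup):
    bcm = ed.pileup_counts(
        mini_setup[2], mini_setup[1], mini_setup[0].gene_models, FUSION, min_coverage=50
    )
    assert len(bcm) == 0


def test_candidates_require_fusion_mismatch(mini_setup):
    bcm = _pileup(mini_setup)
    cand = ed.detect_candidate_positions(bcm, FUSION)
    pos = set(cand.positions["pos"])
    assert 30 in pos and 90 in pos
    assert 40 not in pos  # mismatches only in control samples


def test_no_mismatch_no_candidates(mini_setup):
    bcm = _pileup(mini_setup)
    cand = ed.detect_candidate_positions(bcm, CONTROL[:1] + CONTROL[1:])
    # control libraries carry the pos-40 mismatch only
    assert set(cand.positions["pos"]) == {40}


def test_run_differential_editing_end_to_end(mini_setup):
    bcm = _pileup(mini_setup)
    cand = ed.detect_candidate_positions(bcm, FUSION)
    design = ed.DesignMatrix(
        group_of={s: ("fusion" if s in FUSION else "control") for s in FUSION + CONTROL},
        comparison=("control", "fusion"),
    )
    df = ed.run_differential_editing(cand, design, rho=0.02)
    assert set(df["pos"]) == {30, 90}
    assert ((df["p_raw"] >= 0) & (df["p_raw"] <= 1)).all()
    assert (df["p_adj"] >= df["p_raw"] - 1e-12).all()
    assert df["is_AtoG"].all()
    row30 = df.set_index("pos").loc[30]
    assert row30["prop_alt_group"] == pytest.approx(0.3)
    assert row30["log2fc"] > 1


def _site_row(ref, alt, fus_alt, fus_cov, ctl_alt, ctl_cov, p_adj=1e-4, log2fc=3.0):
    row = {
        "contig": "c1", "pos": 1, "strand": "+", "ref": ref, "alt": alt,
        "prop_alt_group": fus_alt / fus_cov, "prop_ref_group": ctl_alt / max(ctl_cov, 1),
        "log2fc": log2fc, "p_raw": p_adj, "p_adj": p_adj,
        "is_AtoG": ref == "A" and alt == "G",
    }
    for i, s in enumerate(FUSION):
        row[f"alt_{s}"], row[f"cov_{s}"] = fus_alt // 2, fus_cov // 2
    for s in CONTROL:
        row[f"alt_{s}"], row[f"cov_{s}"] = ctl_alt // 2, ctl_cov // 2
    return row


class TestClassifyAndFilter:
    def test_non_atog_dropped(self):
        sites = pd.DataFrame([_site_row("C", "T", 30, 100, 0, 100)])
        assert len(ed.classify_and_filter_sites(sites, CONTROL)) == 0

    def test_homozygous_pattern_dropped_as_snp(self):
        sites = pd.DataFrame([_site_row("A", "G", 99, 100, 99, 100)])
        out = ed.classify_and_filter_sites(sites, CONTROL, require_significant=False)
        assert len(out) == 0

    def test_control_proportion_snp_threshold(self):
        sites = pd.DataFrame([_site_row("A", "G", 50, 100, 40, 100)])
        assert len(ed.classify_and_filter_sites(sites, CONTROL)) == 0

    def test_clean_editing_site_retained(self):
        sites = pd.DataFrame([_site_row("A", "G", 30, 100, 0, 100)])
        out = ed.classify_and_filter_sites(sites, CONTROL)
        assert len(out) == 1
        assert out.iloc[0]["significant_vs_control"]

    def test_user_snp_mask(self):
        sites = pd.DataFrame([_site_row("A", "G", 30, 100, 0, 100)])
        out = ed.classify_and_filter_sites(sites, CONTROL, snp_mask={("c1", 1)})
        assert len(out) == 0


def test_design_matrix_covariate_scaling():
    d = ed.DesignMatrix(
        group_of={"a": "single", "b": "single", "c": "triple", "d": "triple"},
        comparison=("single", "triple"),
        covariate={"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0},
    )
    z = d.scaled_covariate(["a", "b", "c", "d"])
    assert z.mean() == pytest.approx(0.0)
    assert z.std(ddof=0) == pytest.approx(1.0)


def test_constant_covariate_dropped_with_warning():
    d = ed.DesignMatrix(
        group_of={"a": "single", "b": "single", "c": "triple", "d": "triple"},
        comparison=("single", "triple"),
        covariate={"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0},
    )
    with pytest.warns(UserWarning, match="constant"):
        assert d.scaled_covariate(["a", "b", "c", "d"]) is None


def test_compare_backgrounds_requires_control_significance(mini_setup):
    bcm = _pileup(mini_setup)
    cand = ed.detect_candidate_positions(bcm, FUSION)
    design = ed.DesignMatrix(
        group_of={s: ("triple" if s in FUSION else "single") for s in FUSION + CONTROL},
        comparison=("single", "triple"),
        covariate={s: float(i + 1) for i, s in enumerate(FUSION + CONTROL)},
    )
    all_sig = ed.compare_backgrounds(cand, design, {("c1", 30), ("c1", 90)}, rho=0.02)
    none_sig = ed.compare_backgrounds(cand, design, set(), rho=0.02)
    assert not none_sig["reported"].any()
    # reporting can only shrink when control support is removed
    assert all_sig["reported"].sum() >= none_sig["reported"].sum()


class TestSitesToTargetGenes:
    GENES = [
        GeneModel("gA", "c1", 0, 100, "+"),
        GeneModel("gB", "c1", 200, 300, "+"),
    ]

    def _sites(self, rows):
        return pd.DataFrame(rows, columns=["contig", "pos", "strand"])

    def test_multiple_sites_single_gene(self):
        df = ed.sites_to_target_genes(
            self._sites([("c1", 10, "+"), ("c1", 20, "+"), ("c1", 30, "+")]), self.GENES
        )
        assert df.set_index("gene_id").loc["gA", "n_sites"] == 3
        assert "gB" not in set(df["gene_id"])

    def test_empty_sites(self):
        df = ed.sites_to_target_genes(self._sites([]), self.GENES)
        assert len(df) == 0

    def test_adjacent_gene_resolution_and_intergenic(self):
        df = ed.sites_to_target_genes(
            self._sites([("c1", 250, "+"), ("c1", 150, "+")]), self.GENES
        ).set_index("gene_id")
        assert df.loc["gB", "n_sites"] == 1
        assert df.loc["intergenic", "n_sites"] == 1
        assert "gA" not in df.index


def test_strand_symmetry_of_pileup(tmp_path):
    """Counting on a reverse-complemented genome with flipped strands gives
    mirrored counts (sense-orientation invariance)."""
    n = 60
    seq = "".join(np.random.default_rng(3).choice(list("ACGT"), n))
    gene_fwd = GeneModel("g", "c", 5, 55, "+")
    gene_rev = GeneModel("g", "c", n - 55, n - 5, "-")
    gf = ToyGenome({"c": seq}, [gene_fwd], set())
    gr = ToyGenome({"c": revcomp(seq)}, [gene_rev], set())
    fa_f, fa_r = tmp_path / "f.fa", tmp_path / "r.fa"
    gf.write_fasta(fa_f)
    gr.write_fasta(fa_r)
    read = seq[10:40]
    bam_f = write_mini_bam(tmp_path / "f.bam", {"c": n}, [("r1", "c", 10, read, False)] * 1 + [(f"r{i}", "c", 10, read, False) for i in range(2, 12)])
    bam_r = write_mini_bam(
        tmp_path / "r.bam", {"c": n},
        [(f"r{i}", "c", n - 40, revcomp(read), True) for i in range(1, 12)],
    )
    bcm_f = ed.pileup_counts({"s": bam_f}, fa_f, [gene_fwd], ["s"], min_coverage=5)
    bcm_r = ed.pileup_counts({"s": bam_r}, fa_r, [gene_rev], ["s"], min_coverage=5)
    # same sense-space refs and counts, mirrored coordinates
    assert list(bcm_f.positions["ref"]) == list(bcm_r.positions["ref"][::-1])
    np.testing.assert_array_equal(bcm_f.counts["s"], bcm_r.counts["s"][::-1])
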