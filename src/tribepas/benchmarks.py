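"""Reproducible simulation studies of the pipeline's statistical behaviour.

Each function generates synthetic data with known ground truth, runs the
relevant pipeline stage, and reports summary metrics: oracle agreement for
the tail trimmer and mispriming filter, type-I error and power of the
differential-editing test, covariate adjustment behaviour, poly(A)-cluster
recovery, shift-detection accuracy and target-set invariants.  The same
routines back the acceptance script and the acceptance test suite.
"""

from __future__ import annotations

import tempfile

import numpy as np
from scipy.special import comb

from . import pac as pacmod
from . import polya, shifts, targets
from .simulate import (
    SmartSeqConfig,
    build_toy_genome,
    make_sample_sheet,
    simulate_site_counts,
    simulate_smartseq_experiment,
)
from .stats import bh_adjust, betabinom_lrt_batch, estimate_common_rho_batch


# --------------------------------------------------------------- tail trimmer
def brute_force_trim(seq: str):
    """Exhaustive scan over all terminal windows of both read ends.

    Independent oracle for the tail detector: a 3' suffix (5' prefix) of
    length L >= 9 is valid iff its non-A (non-T) count is <= 6% of L and
    the read terminus matches; the longest valid span wins, ties prefer
    the 3' A call.  Returns (end, length) or None.
    """
    n = len(seq)
    best3 = best5 = None
    if n and seq[-1] == "A":
        for L in range(9, n + 1):
            if seq[n - L :].count("A") >= L - 0.06 * L:
                best3 = L
    if n and seq[0] == "T":
        for L in range(9, n + 1):
            if seq[:L].count("T") >= L - 0.06 * L:
                best5 = L
    if best3 is None and best5 is None:
        return None
    if best5 is None or (best3 is not None and best3 >= best5):
        return ("3A", best3)
    return ("5T", best5)


def tail_trim_oracle_study(seed: int, n_reads: int = 10000) -> dict:
    """Fraction of random reads where the trimmer matches the brute force."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    n_agree = n_tailed = 0
    for i in range(n_reads):
        n = int(rng.integers(1, 70))
        seq = "".join(rng.choice(bases, n))
        style = i % 4
        if style == 1:
            run = "".join(
                rng.choice(bases, int(rng.integers(5, 30)), p=[0.92, 0.03, 0.03, 0.02])
            )
            seq = seq + run
        elif style == 2:
            run = "".join(
                rng.choice(bases, int(rng.integers(5, 30)), p=[0.02, 0.03, 0.03, 0.92])
            )
            seq = run + seq
        expected = brute_force_trim(seq)
        got = polya.trim_polya_tail(seq)
        if expected is None:
            n_agree += got is None
        else:
            n_tailed += 1
            n_agree += got is not None and (got.end, got.tail_length) == expected
    return {"agreement": n_agree / n_reads, "n_reads": n_reads, "n_tailed": n_tailed}


# --------------------------------------------------------- mispriming filter
def misprime_recount_study(seed: int, n_genes: int = 60) -> dict:
    """Classification vs direct purine-fraction recount at simulated PASs.

    Checks every true PAS and every decoy position of a toy genome, plus
    the exact 12/15 boundary (>= 80% purine is misprimed).
    """
    genome = build_toy_genome(seed=seed, n_genes=n_genes, decoy_density=0.8)
    n = n_agree = 0
    for gene in genome.gene_models:
        positions = [p for pas in gene.true_pas.values() for p, _ in pas]
        positions += list(gene.internal_prime_decoys)
        for pos in set(positions):
            window = genome.downstream_window(gene.contig, pos, gene.strand, 15)
            if len(window) < 8:
                expected = "genuine"
            else:
                frac = sum(1 for b in window if b in "AG") / len(window)
                expected = "misprimed" if frac >= 0.8 else "genuine"
            got = polya.mispriming_read_filter(genome, gene.contig, pos, gene.strand)
            n += 1
            n_agree += got == expected
    # inclusive boundary: exactly 12 purines of 15
    from .simulate.genome import GeneModel, ToyGenome

    boundary = ToyGenome(
        {"c": "C" * 20 + "AG" * 6 + "CTT" + "C" * 20},
        [GeneModel("g", "c", 0, 55, "+")],
        set(),
    )
    boundary_ok = polya.mispriming_read_filter(boundary, "c", 19, "+") == "misprimed"
    return {"agreement": n_agree / n, "n_positions": n, "boundary_12_of_15_misprimed": boundary_ok}


# ------------------------------------------------------- editing test studies
def null_calibration_study(
    seed: int,
    n_sites: int = 2000,
    proportion: float = 0.01,
    rho: float = 0.02,
    n_rep: tuple = (5, 5),
    coverage_mean: float = 100.0,
) -> dict:
    """Type-I error of the differential test on equal-proportion sites."""
    d = simulate_site_counts(
        seed, n_sites, proportion, proportion, rho=rho, n_rep=n_rep,
        coverage_mean=coverage_mean,
    )
    rho_hat = estimate_common_rho_batch(d["alt"], d["cov"], d["group"])
    res = betabinom_lrt_batch(d["alt"], d["cov"], d["group"], rho=rho_hat)
    p = res["p"]
    padj = bh_adjust(p)
    l2fc = _pooled_l2fc(d)
    return {
        "frac_p_lt_05": float((p < 0.05).mean()),
        "frac_p_lt_01": float((p < 0.01).mean()),
        "n_significant_calls": int(((padj < 0.01) & (l2fc > 1)).sum()),
        "rho_hat": float(rho_hat),
        "n_sites": n_sites,
    }


def _pooled_l2fc(d):
    g1 = d["group"] == 1
    g0 = ~g1
    a1, t1 = d["alt"][:, g1].sum(1), d["cov"][:, g1].sum(1)
    a0, t0 = d["alt"][:, g0].sum(1), d["cov"][:, g0].sum(1)
    return np.log2(((a1 + 1) / (t1 + 2)) / ((a0 + 1) / (t0 + 2)))


def power_study(
    seed: int,
    n_sites: int = 500,
    prop_range: tuple = (0.1, 0.5),
    control_prop: float = 0.003,
    rho: float = 0.02,
    coverage_range: tuple = (50, 150),
) -> dict:
    """Detection rate and proportion-estimate accuracy on true sites."""
    rng = np.random.default_rng(seed)
    ptrue = rng.uniform(*prop_range, n_sites)
    d = simulate_site_counts(
        seed + 1, n_sites, control_prop, ptrue, rho=rho, n_rep=(5, 5),
        coverage_range=coverage_range,
    )
    rho_hat = estimate_common_rho_batch(d["alt"], d["cov"], d["group"])
    res = betabinom_lrt_batch(d["alt"], d["cov"], d["group"], rho=rho_hat)
    padj = bh_adjust(res["p"])
    l2fc = _pooled_l2fc(d)
    detected = (padj < 0.01) & (l2fc > 1)
    g1 = d["group"] == 1
    pooled = d["alt"][:, g1].sum(1) / d["cov"][:, g1].sum(1)
    realised = (d["realised"][:, g1] * d["cov"][:, g1]).sum(1) / d["cov"][:, g1].sum(1)
    return {
        "detection_rate": float(detected.mean()),
        "frac_within_05_of_realised": float(
            (np.abs(pooled - realised)[detected] <= 0.05).mean()
        ),
        "frac_within_05_of_group_truth": float(
            (np.abs(pooled - ptrue)[detected] <= 0.05).mean()
        ),
        "n_sites": n_sites,
    }


def covariate_study(
    seed: int,
    n_sites: int = 2000,
    rho: float = 0.02,
    coverage_mean: float = 100.0,
) -> dict:
    """Effect of the scaled-abundance covariate on background comparisons.

    Editing tracks ADAR transgene abundance linearly; the two backgrounds
    differ in abundance but not in any true background effect.  With the
    z-scored covariate the test should stay quiet; withholding it turns
    the abundance difference into spurious background hits.

    The per-line abundances are fixed design constants (two-fold higher
    mean in the second background, ±30% line-to-line spread), emulating
    transgene expression differing systematically between backgrounds.
    """
    rng = np.random.default_rng(seed)
    ab_single = np.array([0.7, 0.85, 1.0, 1.15, 1.3])
    ab_triple = 2.0 * ab_single
    base = rng.uniform(0.05, 0.3, n_sites)
    d = simulate_site_counts(
        seed + 1, n_sites, base, base, rho=rho, n_rep=(5, 5),
        coverage_mean=coverage_mean, abundance_a=ab_single, abundance_b=ab_triple,
        coupling=True,
    )
    z = (d["abundance"] - d["abundance"].mean()) / d["abundance"].std()
    rho_with = estimate_common_rho_batch(d["alt"], d["cov"], d["group"], covariate=z)
    res_with = betabinom_lrt_batch(d["alt"], d["cov"], d["group"], covariate=z, rho=rho_with)
    rho_wo = estimate_common_rho_batch(d["alt"], d["cov"], d["group"])
    res_wo = betabinom_lrt_batch(d["alt"], d["cov"], d["group"], rho=rho_wo)
    return {
        "frac_padj_lt_01_with_covariate": float((bh_adjust(res_with["p"]) < 0.1).mean()),
        "frac_padj_lt_01_without_covariate": float((bh_adjust(res_wo["p"]) < 0.1).mean()),
        "n_sites": n_sites,
    }


# ------------------------------------------------------------- poly(A) studies
def run_polya_experiment(
    seed: int,
    n_genes: int = 200,
    reads_per_gene: tuple = (80, 330),
    pas_jitter_sd: float = 5.0,
    dominant_shift_fraction: float = 0.1,
    out_dir=None,
):
    """Full poly(A) pipeline on a simulated two-genotype experiment.

    3+3 replicates; ~50-200 tailed reads per gene per sample after the
    misprime/body fractions.  Returns a dict of intermediate objects for
    the recovery and shift studies.
    """
    genome = build_toy_genome(
        seed=seed, n_genes=n_genes, decoy_density=0.5,
        dominant_shift_fraction=dominant_shift_fraction,
    )
    sheet = make_sample_sheet(["wt", "mut"], n_replicates=3, seed=seed + 1)
    cfg = SmartSeqConfig(reads_per_gene=reads_per_gene, pas_jitter_sd=pas_jitter_sd)
    if out_dir is None:
        out_dir = tempfile.mkdtemp(prefix="tribepas_polya_")
    bams, truth = simulate_smartseq_experiment(genome, sheet, out_dir, config=cfg)
    pc = polya.extract_polya(bams, genome, genome.gene_models)
    genotype_map = {s.sample_id: s.group for s in sheet.samples}
    per_sample = {s: pacmod.call_sample_pacs(pc, s) for s in sheet.sample_ids()}
    merged = pacmod.replicate_consensus_and_merge(per_sample, genotype_map, pas_count=pc)
    merged, n_excluded = pacmod.exclude_contigs(merged, excluded_contigs=genome.decoy_contigs)
    gene_map, unassigned = pacmod.assign_pacs_to_genes(merged, genome.gene_models)
    return {
        "genome": genome,
        "sheet": sheet,
        "truth": truth,
        "pas_count": pc,
        "per_sample_pacs": per_sample,
        "merged": merged,
        "n_excluded": n_excluded,
        "gene_map": gene_map,
        "genotype_map": genotype_map,
    }


def _interval_distance(pos, pac):
    if pac.start <= pos < pac.end:
        return 0
    return min(abs(pos - pac.start), abs(pos - (pac.end - 1)))


def pac_recovery_study(exp, tolerance: int = 15, min_support: int = 20) -> dict:
    """True-PAC recovery, decoy-cluster removal and replicate support."""
    genome = exp["genome"]
    truth = exp["truth"]
    merged = exp["merged"]
    by_key: dict = {}
    for p in merged:
        by_key.setdefault((p.contig, p.strand), []).append(p)

    # reads per true PAS (nearest-PAS attribution; separations >> jitter)
    tailed = truth[truth["class"] == "tailed"]
    support: dict = {}
    for gene in genome.gene_models:
        pas_positions = sorted({p for pas in gene.true_pas.values() for p, _ in pas})
        sub = tailed[tailed["gene_id"] == gene.gene_id]
        for end in sub["true_end"]:
            nearest = min(pas_positions, key=lambda p: abs(p - end))
            support[(gene.contig, gene.strand, nearest)] = (
                support.get((gene.contig, gene.strand, nearest), 0) + 1
            )

    n_true = n_recovered = 0
    for gene in genome.gene_models:
        if gene.contig in genome.decoy_contigs:
            continue  # excluded by design; nothing to recover there
        for pos in sorted({p for pas in gene.true_pas.values() for p, _ in pas}):
            if support.get((gene.contig, gene.strand, pos), 0) < min_support:
                continue
            n_true += 1
            pacs = by_key.get((gene.contig, gene.strand), [])
            if any(_interval_distance(pos, p) <= tolerance for p in pacs):
                n_recovered += 1

    # decoy positions with simulated misprime reads must yield no cluster
    n_decoys = n_removed = 0
    misprimed = truth[truth["class"] == "misprime"]
    for gene in genome.gene_models:
        if gene.contig in genome.decoy_contigs:
            continue
        sub = set(misprimed.loc[misprimed["gene_id"] == gene.gene_id, "true_end"])
        for pos in gene.internal_prime_decoys:
            if pos not in sub:
                continue
            n_decoys += 1
            pacs = by_key.get((gene.contig, gene.strand), [])
            if not any(_interval_distance(pos, p) <= tolerance for p in pacs):
                n_removed += 1

    # every merged PAC re-checkably supported in >=2 replicates per genotype
    per_sample = exp["per_sample_pacs"]
    genotype_map = exp["genotype_map"]
    n_supported = 0
    for m in exp["merged"]:
        ok = True
        for gt in set(genotype_map.values()):
            reps = sum(
                1
                for s, pacs in per_sample.items()
                if genotype_map[s] == gt and any(m.overlaps(q) for q in pacs)
            )
            ok &= reps >= 2
        n_supported += ok
    return {
        "pas_recovery": n_recovered / n_true if n_true else float("nan"),
        "n_true_pas": n_true,
        "decoy_removal": n_removed / n_decoys if n_decoys else float("nan"),
        "n_decoys": n_decoys,
        "frac_merged_with_replicate_support": (
            n_supported / len(exp["merged"]) if exp["merged"] else float("nan")
        ),
        "n_merged_pacs": len(exp["merged"]),
    }


def hypergeom_fisher_two_sided(table):
    """Exhaustive two-sided Fisher p over the hypergeometric support."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    denom = comb(n, col1, exact=True)
    probs = {
        k: comb(row1, k, exact=True) * comb(n - row1, col1 - k, exact=True) / denom
        for k in range(kmin, kmax + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


def shift_study(exp) -> dict:
    """Shift-detection accuracy against the injected dominant-PAC switches."""
    genome = exp["genome"]
    gene_map = exp["gene_map"]
    pc = exp["pas_count"]
    genotype_map = exp["genotype_map"]

    truth_shifted = set()
    truth_multi = set()
    for gene in genome.gene_models:
        if gene.contig in genome.decoy_contigs:
            continue
        if len(gene.true_pas["wt"]) > 1:
            truth_multi.add(gene.gene_id)
            top_wt = max(gene.true_pas["wt"], key=lambda x: x[1])[0]
            top_mut = max(gene.true_pas["mut"], key=lambda x: x[1])[0]
            if top_wt != top_mut:
                truth_shifted.add(gene.gene_id)

    detected = set()
    distances = []
    distances_swapped = []
    n_determinable = 0
    for gid, pacs in sorted(gene_map.items()):
        summ = shifts.summarize_gene_pacs(gid, pacs, pc, genotype_map)
        res = shifts.dominant_pac_shift(summ, ["wt", "mut"])
        if res.shifted:
            detected.add(gid)
        d = shifts.most_common_pas_distance(summ, "wt", "mut")
        if d is not None:
            n_determinable += 1
            distances.append(d)
            distances_swapped.append(shifts.most_common_pas_distance(summ, "mut", "wt"))

    tp = len(detected & truth_shifted)
    precision = tp / len(detected) if detected else float("nan")
    recall = tp / len(truth_shifted) if truth_shifted else float("nan")

    table, _hist = shifts.bin_distances(distances)
    bins_partition_ok = int(table.sum()) == n_determinable
    antisymmetry_ok = all(
        a.distance == -b.distance for a, b in zip(distances, distances_swapped)
    )

    # Fisher on (in a target-like set) x (shifted dominant PAC)
    testable = sorted(truth_multi & set(gene_map))
    in_set = {g for i, g in enumerate(testable) if i % 2 == 0}
    a = sum(1 for g in testable if g in in_set and g in detected)
    b = sum(1 for g in testable if g in in_set and g not in detected)
    c = sum(1 for g in testable if g not in in_set and g in detected)
    d_ = sum(1 for g in testable if g not in in_set and g not in detected)
    fisher_p = shifts.fisher_enrichment([[a, b], [c, d_]])["p"]
    fisher_oracle = hypergeom_fisher_two_sided([[a, b], [c, d_]])
    return {
        "precision": precision,
        "recall": recall,
        "n_truth_shifted": len(truth_shifted),
        "n_detected": len(detected),
        "bins_partition_ok": bins_partition_ok,
        "antisymmetry_ok": antisymmetry_ok,
        "fisher_p": float(fisher_p),
        "fisher_abs_error_vs_enumeration": float(abs(fisher_p - fisher_oracle)),
    }


# ----------------------------------------------------------------- set algebra
def set_algebra_study(seed: int, trials: int = 100, universe_size: int = 300) -> dict:
    """Target-set invariants on randomized gene universes."""
    rng = np.random.default_rng(seed)
    universe = np.array([f"g{i}" for i in range(universe_size)])
    n_ok = 0
    for _ in range(trials):
        expressed = set(rng.choice(universe, rng.integers(1, universe_size), replace=False))
        pick = lambda: set(
            rng.choice(universe, rng.integers(0, universe_size // 2), replace=False)
        )
        coll = targets.build_target_sets(pick(), pick(), pick(), expressed)
        ok = (
            coll.stringent <= coll.permissive
            and (coll.permissive | coll.non_target) == coll.expressed
            and not (coll.permissive & coll.non_target)
        )
        n_ok += ok
    return {"frac_invariants_hold": n_ok / trials, "trials": trials}
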