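from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epimem.counts import simulate_methylomes
from epimem.dmr import call_dms, filter_sites, merge_dms
from epimem.genome import generate_genome
from epimem.integrate import (DEThresholds, OverlapResult, annotate_dmrs,
                              call_dmgs, de_test, intersect_dedmg,
                              overlap_test, shared_sets, tmm_factors)
from epimem.scenario import PlantedDMR
from epimem.truth import apply_treatment, simulate_truth

from conftest import make_small_scenario


def _gene(fid, chrom, start, end, strand):
    return {"feature_id": fid, "chrom": chrom, "start": start, "end": end,
            "strand": strand, "type": "gene"}


def _dmr(chrom, start, end, context="CHG", direction="hyper"):
    return {"chrom": chrom, "start": start, "end": end, "context": context,
            "direction": direction, "n_dms": 3, "level_ctrl": 0.3,
            "level_trt": 0.6, "diff": 0.3}


GENES = pd.DataFrame([
    _gene("gA", "chr1", 10_000, 12_000, "+"),
    _gene("gB", "chr1", 30_000, 32_000, "-"),
])


# ----------------------------------------------------------------------
# annotation


def test_promoter_upstream_of_plus_gene():
    ann = annotate_dmrs(pd.DataFrame([_dmr("chr1", 9_400, 9_601)]), GENES)
    row = ann.iloc[0]
    assert row["category"] == "promoter"
    assert row["gene"] == "gA"
    assert row["tss_distance"] == -500


def test_gene_body_minus_strand_distance_positive():
    ann = annotate_dmrs(pd.DataFrame([_dmr("chr1", 30_500, 30_701)]), GENES)
    row = ann.iloc[0]
    assert row["category"] == "gene body"
    assert row["gene"] == "gB"
    assert row["tss_distance"] > 0


def test_downstream_and_intergenic():
    ann = annotate_dmrs(pd.DataFrame([
        _dmr("chr1", 12_400, 12_601),   # 500 bp past gA TTS
        _dmr("chr1", 20_000, 20_201),   # between genes, > 2 kb from both
    ]), GENES)
    assert ann.iloc[0]["category"] == "downstream"
    assert ann.iloc[1]["category"] == "intergenic"
    assert ann.iloc[1]["tss_distance"] is not None


def test_tie_goes_to_lexicographically_smaller_gene():
    genes = pd.DataFrame([
        _gene("gB", "chr1", 10_000, 12_000, "+"),
        _gene("gA", "chr1", 13_000, 15_000, "+"),
    ])
    # midpoint 12500: 500 bp into gB's downstream zone and gA's promoter
    # promoter precedence wins -> gA; equal-rank ties use the id ordering
    ann = annotate_dmrs(pd.DataFrame([_dmr("chr1", 12_400, 12_601)]), genes)
    assert ann.iloc[0]["category"] == "promoter"
    assert ann.iloc[0]["gene"] == "gA"

    twins = pd.DataFrame([
        _gene("gB", "chr1", 13_000, 15_000, "+"),
        _gene("gA", "chr1", 13_000, 15_000, "+"),
    ])
    ann = annotate_dmrs(pd.DataFrame([_dmr("chr1", 12_400, 12_601)]), twins)
    assert ann.iloc[0]["gene"] == "gA"


def test_annotation_partition(small_genome):
    rng = np.random.default_rng(0)
    dmrs = pd.DataFrame([
        _dmr("chr1", int(s), int(s) + 200) for s in rng.integers(0, 59_000, 40)
    ]).sort_values("start").reset_index(drop=True)
    ann = annotate_dmrs(dmrs, small_genome.genes)
    assert len(ann) == len(dmrs)
    assert ann["category"].isin(["promoter", "gene body", "downstream",
                                 "intergenic"]).all()
    counts = ann["category"].value_counts()
    assert counts.sum() == len(dmrs)


def test_unstranded_gene_rejected():
    bad = GENES.copy()
    bad.loc[0, "strand"] = "."
    with pytest.raises(ValueError, match="stranded"):
        annotate_dmrs(pd.DataFrame([_dmr("chr1", 0, 200)]), bad)


# ----------------------------------------------------------------------
# DMG calling


def test_downstream_only_is_not_dmg():
    ann = annotate_dmrs(pd.DataFrame([_dmr("chr1", 12_400, 12_601)]), GENES)
    dmgs = call_dmgs(ann)
    assert dmgs["any"] == set()


def test_dmg_contexts_and_union():
    ann = annotate_dmrs(pd.DataFrame([
        _dmr("chr1", 9_400, 9_601, context="CHG"),
        _dmr("chr1", 10_500, 10_701, context="CHH"),
    ]), GENES)
    dmgs = call_dmgs(ann)
    assert dmgs["CHG"] == {"gA"}
    assert dmgs["CHH"] == {"gA"}
    assert dmgs["any"] == {"gA"}


def test_planted_dmg_recovery_jaccard():
    """Genes given planted body DMRs are recovered as DMGs (Jaccard >= 0.8)."""
    sc = make_small_scenario()
    g = generate_genome(sc)
    targets = g.genes.iloc[::2].head(8)  # every other gene, both chromosomes
    sc.planted_dmrs = [
        PlantedDMR(r["chrom"], int(r["start"]) + 100, int(r["start"]) + 700,
                   "CHG", 0.45)
        for _, r in targets.iterrows()
    ]
    sc.validate()
    truth = apply_treatment(simulate_truth(g, sc), sc)
    table = simulate_methylomes(truth, sc, groups=["eco1"])
    ctrl = table.samples_where(condition="18C")
    trt = table.samples_where(condition="28C")
    dms = call_dms(filter_sites(table, "CHG", ctrl, trt), fdr=0.003, B=1000,
                   seed=1)
    dmrs = merge_dms(dms)
    dmgs = call_dmgs(annotate_dmrs(dmrs, g.genes))["any"]
    planted = set(targets["feature_id"])
    jacc = len(dmgs & planted) / len(dmgs | planted)
    assert jacc >= 0.8


# ----------------------------------------------------------------------
# TMM


def _counts(matrix, samples):
    return pd.DataFrame(matrix, columns=samples,
                        index=[f"g{i}" for i in range(len(matrix))])


def test_tmm_identity():
    rng = np.random.default_rng(1)
    base = rng.poisson(100, size=500)
    counts = _counts(np.column_stack([base] * 4), list("abcd"))
    assert np.allclose(tmm_factors(counts), 1.0)


def test_tmm_absorbs_pure_depth_doubling():
    rng = np.random.default_rng(2)
    a = rng.poisson(100, size=800)
    counts = _counts(np.column_stack([a, 2 * a]), ["a", "b"])
    f = tmm_factors(counts)
    assert np.allclose(f["b"] / f["a"], 1.0, atol=1e-12)
    assert np.allclose(np.log(f).mean(), 0.0, atol=1e-12)


def test_tmm_gene_order_invariant(rng):
    counts = _counts(rng.poisson(80, size=(400, 3)), list("abc"))
    perm = rng.permutation(len(counts))
    assert np.allclose(tmm_factors(counts), tmm_factors(counts.iloc[perm]))


def test_tmm_rejects_empty_library():
    counts = _counts(np.array([[5, 0], [3, 0]]), ["a", "b"])
    with pytest.raises(ValueError, match="all-zero"):
        tmm_factors(counts)


# ----------------------------------------------------------------------
# DE testing


def _null_counts(G, n, seed, mu=150.0, disp=0.05):
    rng = np.random.default_rng(seed)
    r = 1 / disp
    counts = _counts(rng.negative_binomial(r, r / (r + mu), size=(G, 2 * n)),
                     [f"s{i}" for i in range(2 * n)])
    design = pd.DataFrame({"sample": counts.columns,
                           "condition": ["A"] * n + ["B"] * n})
    return counts, design


def test_de_type_one_error_near_nominal():
    G = 2000
    counts, design = _null_counts(G, 3, seed=5)
    res = de_test(counts, design)
    frac = (res["p"] <= 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / G)
    assert abs(frac - 0.05) < 3 * se


def test_de_identical_counts_not_deg():
    # identical libraries: a constant gene has exactly zero fold change
    counts, design = _null_counts(50, 3, seed=6)
    counts = _counts(np.column_stack([counts["s0"]] * 6), counts.columns)
    res = de_test(counts, design)
    assert (res["log2fc"] == 0.0).all()
    assert (res["p"] == 1.0).all()
    assert not res["deg"].any()

    # a constant gene inside varying libraries is still never a DEG
    counts2, _ = _null_counts(50, 3, seed=6)
    counts2.iloc[0] = 42
    res2 = de_test(counts2, design)
    assert abs(res2.iloc[0]["log2fc"]) < 0.05
    assert not res2.iloc[0]["deg"]


def test_de_recovers_planted_fold_changes():
    rng = np.random.default_rng(9)
    G, n = 1500, 3
    r = 1 / 0.05
    mu = np.full(G, 100.0)
    lfc = np.zeros(G)
    lfc[:200] = 2.0
    a = rng.negative_binomial(r, r / (r + mu[:, None]), size=(G, n))
    b = rng.negative_binomial(r, r / (r + (mu * 2.0**lfc)[:, None]), size=(G, n))
    counts = _counts(np.hstack([a, b]), [f"s{i}" for i in range(2 * n)])
    design = pd.DataFrame({"sample": counts.columns,
                           "condition": ["A"] * n + ["B"] * n})
    res = de_test(counts, design)
    recall = res["deg"].to_numpy()[:200].mean()
    assert recall >= 0.8
    assert res["log2fc"][:200].mean() == pytest.approx(2.0, abs=0.15)


def test_de_rejects_degenerate_design():
    counts, design = _null_counts(20, 2, seed=3)
    design["condition"] = "A"
    with pytest.raises(ValueError, match="2 conditions"):
        de_test(counts, design)


# ----------------------------------------------------------------------
# overlap statistics


def test_hypergeometric_matches_brute_force_sum():
    universe = {f"x{i}" for i in range(100)}
    a = {f"x{i}" for i in range(10)}
    b = {f"x{i}" for i in range(5, 15)}
    res = overlap_test(a, b, universe)
    assert res.overlap == 5
    assert res.representation_factor == pytest.approx(5.0)
    exact = sum(comb(10, k) * comb(90, 10 - k) for k in range(5, 11)) / comb(100, 10)
    assert res.p == pytest.approx(exact, rel=1e-12)


def test_overlap_boundary_cases():
    universe = {f"x{i}" for i in range(30)}
    a = {f"x{i}" for i in range(10)}
    b = {f"x{i}" for i in range(20, 30)}
    res = overlap_test(a, b, universe)
    assert res.overlap == 0 and res.representation_factor == 0.0
    assert res.p == pytest.approx(1.0)
    sat = overlap_test(universe, b, universe)
    assert sat.overlap == len(b)
    assert sat.representation_factor == pytest.approx(1.0)
    assert sat.p == pytest.approx(1.0)


def test_hypergeometric_equals_fisher_one_tail(rng):
    for _ in range(20):
        N = int(rng.integers(20, 200))
        nA = int(rng.integers(1, N))
        nB = int(rng.integers(1, N))
        O = int(rng.integers(max(0, nA + nB - N), min(nA, nB) + 1))
        p_hyp = stats.hypergeom.sf(O - 1, N, nA, nB)
        table = [[O, nA - O], [nB - O, N - nA - nB + O]]
        _, p_fisher = stats.fisher_exact(table, alternative="greater")
        assert p_hyp == pytest.approx(p_fisher, rel=1e-9)


def test_intersect_dedmg_definition():
    universe = {f"g{i}" for i in range(50)}
    dmgs = {"CHG": {"g1", "g2", "g3"}, "any": {"g1", "g2", "g3", "g4"}}
    degs = {"g2", "g4", "g9"}
    dedmg, res = intersect_dedmg(dmgs, degs, universe)
    assert dedmg == {"g2", "g4"}
    assert isinstance(res, OverlapResult)
    assert res.fraction_of_a == pytest.approx(2 / 4)


def test_shared_sets_patterns(rng):
    identical = {g: {"a", "b", "c"} for g in ("w", "x", "y", "z")}
    df = shared_sets(identical)
    assert len(df) == 1
    assert df.iloc[0]["n_groups"] == 4 and df.iloc[0]["count"] == 3

    disjoint = {"w": {"a"}, "x": {"b"}, "y": {"c"}}
    df = shared_sets(disjoint)
    assert (df["n_groups"] == 1).all()
    assert df["count"].sum() == 3

    sets = {g: set(rng.choice(50, rng.integers(5, 25), replace=False))
            for g in ("p", "q", "r")}
    df = shared_sets(sets)
    # brute-force cross-check of every pattern cell
    for _, row in df.iterrows():
        members = [g for g, flag in zip(sets, row["pattern"]) if flag == "1"]
        expected = 0
        for item in set().union(*sets.values()):
            if all((item in sets[g]) == (g in members) for g in sets):
                expected += 1
        assert row["count"] == expected
    assert df["count"].sum() == len(set().union(*sets.values()))
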