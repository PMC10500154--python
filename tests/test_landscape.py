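import dataclasses

import numpy as np
import pandas as pd
import pytest

from epimem.counts import simulate_methylomes
from epimem.expression import simulate_expression
from epimem.genome import generate_genome
from epimem.integrate import de_test
from epimem.landscape import (call_peaks, dmr_density, feature_density,
                              games_howell, methylation_regression,
                              pca_windows, proximity_categories,
                              proximity_effect, shared_peak_windows)
from epimem.methylome import window_profile
from epimem.scenario import PlantedDMR, ScenarioConfig, baseline_scenario
from epimem.truth import apply_treatment, simulate_truth


def _dmrs(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).assign(
        context="CHG", direction="hyper", n_dms=2, level_ctrl=0.3,
        level_trt=0.6, diff=0.3)


LENGTHS = {"chr1": 150_000, "chr2": 150_000}


# ----------------------------------------------------------------------
# density and peaks


def test_density_zero_and_conservation():
    dens = dmr_density(_dmrs([]), LENGTHS)
    assert (dens["count"] == 0).all()
    rows = [("chr1", 100, 300), ("chr1", 60_000, 60_100), ("chr2", 10, 50)]
    dens = dmr_density(_dmrs(rows), LENGTHS)
    assert dens["count"].sum() == 3


def test_density_window_boundary_goes_right():
    # midpoint exactly at 50_000 belongs to window 1 (half-open rule)
    dens = dmr_density(_dmrs([("chr1", 49_900, 50_101)]), LENGTHS)
    row = dens[(dens["chrom"] == "chr1") & (dens["window"] == 1)]
    assert row["count"].item() == 1


def test_peaks_floor_and_sharing():
    def dens_with(counts_by_window):
        dens = dmr_density(_dmrs([]), LENGTHS)
        for (c, w), k in counts_by_window.items():
            dens.loc[(dens["chrom"] == c) & (dens["window"] == w), "count"] = k
        return dens

    below = {"a": dens_with({("chr1", 0): 9}), "b": dens_with({("chr1", 0): 8})}
    assert shared_peak_windows(call_peaks(below, floor=10, quantile=None)) == []

    both = {"a": dens_with({("chr1", 0): 12, ("chr2", 1): 15}),
            "b": dens_with({("chr1", 0): 11})}
    shared = shared_peak_windows(call_peaks(both, floor=10, quantile=None))
    assert shared == [("chr1", 0)]  # chr2 peak missing in group b

    # adding a group can only shrink the shared set
    three = dict(both, c=dens_with({}))
    assert shared_peak_windows(call_peaks(three, floor=10, quantile=None)) == []


# ----------------------------------------------------------------------
# feature density


def test_feature_density_boundaries():
    feats = pd.DataFrame([
        {"feature_id": "r1", "chrom": "chr1", "start": 0, "end": 50_000,
         "strand": "+", "type": "dispersed_repeat"},
    ])
    dens = feature_density(feats, LENGTHS, window=50_000)
    w0 = dens[(dens["chrom"] == "chr1") & (dens["window"] == 0)].iloc[0]
    assert w0["dispersed_repeat"] == pytest.approx(1.0)
    assert w0["gene"] == 0.0


def test_feature_density_union_of_overlaps():
    feats = pd.DataFrame([
        {"feature_id": "r1", "chrom": "chr1", "start": 1000, "end": 3000,
         "strand": "+", "type": "dispersed_repeat"},
        {"feature_id": "r2", "chrom": "chr1", "start": 2000, "end": 4000,
         "strand": "+", "type": "dispersed_repeat"},
    ])
    dens = feature_density(feats, {"chr1": 50_000}, window=50_000)
    # brute-force base enumeration of the union
    covered = np.zeros(50_000, dtype=bool)
    covered[1000:3000] = True
    covered[2000:4000] = True
    assert dens.iloc[0]["dispersed_repeat"] == pytest.approx(covered.mean())


# ----------------------------------------------------------------------
# regression


def test_regression_exact_linear_response():
    rng = np.random.default_rng(0)
    dens = pd.DataFrame({
        "chrom": "chr1", "window": np.arange(40),
        "gene": rng.uniform(0, 0.4, 40),
        "dispersed_repeat": rng.uniform(0, 0.3, 40),
        "pseudogene": rng.uniform(0, 0.1, 40),
    })
    level = 0.5 - 0.4 * dens["gene"] + 0.8 * dens["dispersed_repeat"] \
        + 0.2 * dens["pseudogene"]
    prof = dens[["chrom", "window"]].assign(context="CHG", level=level)
    fit = methylation_regression(prof, dens)["CHG"]
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.coefficients["gene"] == pytest.approx(-0.4)
    assert fit.coefficients["dispersed_repeat"] == pytest.approx(0.8)

    noise = prof.assign(level=rng.normal(0.4, 0.05, 40))
    fit0 = methylation_regression(noise, dens)["CHG"]
    assert fit0.r_squared < 0.25


def test_regression_sign_recovery_over_replicates():
    """The default landscape yields negative gene and positive RE/pseudogene
    coefficients in >= 95% of replicate simulations."""
    success = 0
    reps = 20
    for rep in range(reps):
        sc = baseline_scenario(seed=300 + rep)
        g = generate_genome(sc)
        table = simulate_methylomes(simulate_truth(g, sc), sc,
                                    groups=["eco1"], conditions=["18C"])
        prof = window_profile(table)
        prof = prof[prof["chrom"] != "chrC"]
        lengths = {c: L for c, L in g.chrom_lengths.items() if c != "chrC"}
        fits = methylation_regression(prof, feature_density(g.features, lengths))
        good = all(
            f.coefficients["gene"] < 0
            and f.coefficients["dispersed_repeat"] > 0
            and f.coefficients["pseudogene"] > 0
            for f in fits.values()
        )
        success += good
    assert success >= 0.95 * reps


# ----------------------------------------------------------------------
# proximity categories


def test_proximity_overlap_and_edges():
    genes = pd.DataFrame([
        {"feature_id": "g1", "chrom": "c", "start": 10_000, "end": 12_000,
         "strand": "+", "type": "gene"},   # overlapped by RE
        {"feature_id": "g2", "chrom": "c", "start": 20_000, "end": 21_000,
         "strand": "+", "type": "gene"},   # exactly 2000 away
        {"feature_id": "g3", "chrom": "c", "start": 40_000, "end": 41_000,
         "strand": "+", "type": "gene"},   # 16 kb away -> no RE within 10 kb
    ])
    res = pd.DataFrame([
        {"feature_id": "r1", "chrom": "c", "start": 11_500, "end": 13_000,
         "strand": "+", "type": "dispersed_repeat"},
        {"feature_id": "r2", "chrom": "c", "start": 23_000, "end": 24_000,
         "strand": "+", "type": "dispersed_repeat"},
    ])
    cats = proximity_categories(genes, res)
    assert cats.loc["g1", "re_distance"] == 0
    assert cats.loc["g1", "category"] == "RE within 2 kb"
    assert cats.loc["g2", "re_distance"] == 2000
    assert cats.loc["g2", "category"] == "RE within 2 kb"  # closed right edge
    assert cats.loc["g3", "category"] == "no RE within 10 kb"


def test_proximity_matches_brute_force(small_genome):
    genes = small_genome.genes
    res = small_genome.features_of_type("dispersed_repeat")
    cats = proximity_categories(genes, res)
    for _, g in genes.iterrows():
        best = np.inf
        for _, r in res.iterrows():
            if r["chrom"] != g["chrom"]:
                continue
            gap = max(r["start"] - g["end"], g["start"] - r["end"], 0)
            best = min(best, gap)
        assert cats.loc[g["feature_id"], "re_distance"] == best


# ----------------------------------------------------------------------
# Games-Howell


def test_games_howell_identical_groups():
    x = np.r_[np.ones(20), 2 * np.ones(20)]
    out = games_howell({"a": x, "b": x.copy()})
    assert out.iloc[0]["p"] > 0.99


def test_games_howell_detects_shifted_group(rng):
    groups = {
        "a": rng.normal(0, 1, 50),
        "b": rng.normal(0, 1, 50),
        "c": rng.normal(5, 1, 50),
    }
    out = games_howell(groups).set_index(["group_a", "group_b"])
    assert out.loc[("a", "c"), "p"] < 1e-6
    assert out.loc[("b", "c"), "p"] < 1e-6
    assert out.loc[("a", "b"), "p"] > 0.05


def test_games_howell_agrees_with_independent_implementation(rng):
    pingouin = pytest.importorskip("pingouin")
    for trial in range(10):
        k = int(rng.integers(2, 5))
        data, labels = [], []
        for j in range(k):
            n = int(rng.integers(5, 30))
            data.append(rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n))
            labels += [f"G{j}"] * n
        df = pd.DataFrame({"y": np.concatenate(data), "grp": labels})
        ours = games_howell({f"G{j}": d for j, d in enumerate(data)})
        ref = pingouin.pairwise_gameshowell(data=df, dv="y", between="grp")
        ours = ours.set_index(["group_a", "group_b"])
        for _, row in ref.iterrows():
            mine = ours.loc[(row["A"], row["B"])]
            assert abs(abs(mine["t"]) - abs(row["T"])) < 1e-6
            assert abs(mine["df"] - row["df"]) < 1e-6
            assert abs(mine["p"] - row["pval"]) < 1e-4


def test_games_howell_degenerate_variances():
    out = games_howell({"a": np.ones(5), "b": np.ones(5)})
    assert out.iloc[0]["p"] == 1.0
    out2 = games_howell({"a": np.ones(5), "b": 2 * np.ones(5)})
    assert out2.iloc[0]["p"] == 0.0


# ----------------------------------------------------------------------
# proximity effect on expression


@pytest.fixture(scope="module")
def proximity_world():
    sc = ScenarioConfig(
        chrom_lengths={f"chr{i}": 300_000 for i in (1, 2, 3)} | {"chrC": 10_000},
        genes_per_chrom=50, res_per_chrom=12, pseudogenes_per_chrom=4,
        de_fraction=0.08, dedmg_coupling=1.0, seed=31,
    )
    g = generate_genome(sc)
    # plant DMRs into bodies of RE-adjacent genes so the methylation-coupled
    # responsive genes sit in the within-2kb category
    cats = proximity_categories(g.genes, g.features_of_type("dispersed_repeat"))
    near = cats[cats["category"] == "RE within 2 kb"].index[:10]
    genes = g.genes.set_index("feature_id")
    sc.planted_dmrs = [
        PlantedDMR(genes.loc[gid, "chrom"], int(genes.loc[gid, "start"]) + 100,
                   int(genes.loc[gid, "start"]) + 700, "CHG", 0.4)
        for gid in near
    ]
    sc.validate()
    return sc, g, cats


def _gene_stats(sc, g, repression, seed_offset=0):
    sc = dataclasses.replace(sc, repression_factor=repression,
                             seed=sc.seed + seed_offset)
    counts, _ = simulate_expression(g, sc)
    cols = [s for s in counts.columns if s.startswith("eco1_")]
    design = pd.DataFrame({"sample": cols,
                           "condition": [s.split("_")[1] for s in cols]})
    return de_test(counts[cols], design)


def test_no_proximity_effect_in_null_world(proximity_world):
    sc, g, cats = proximity_world
    sc0 = dataclasses.replace(sc, de_fraction=0.0, planted_dmrs=[])
    stats_ = _gene_stats(sc0, g, repression=1.0)
    out = proximity_effect(stats_, cats, value="mean_norm")
    assert (out["pairwise"]["p"] > 0.05).all()


def test_repression_detected_only_within_2kb(proximity_world):
    sc, g, cats = proximity_world
    stats_ = _gene_stats(sc, g, repression=0.5)
    out = proximity_effect(stats_, cats, value="mean_norm")
    pw = out["pairwise"].set_index(["group_a", "group_b"])
    near, far = "RE within 2 kb", "no RE within 10 kb"
    assert pw.loc[(near, far), "p"] < 0.05
    assert pw.loc[("RE 2-5 kb", far), "p"] > 0.05
    assert pw.loc[("RE 5-10 kb", far), "p"] > 0.05


def test_coupled_responsive_genes_raise_lfc_near_res(proximity_world):
    sc, g, cats = proximity_world
    stats_ = _gene_stats(sc, g, repression=0.5)
    out = proximity_effect(stats_, cats, value="abs_log2fc")
    summ = out["summary"].set_index("category")
    assert summ.loc["RE within 2 kb", "mean"] > summ.loc["no RE within 10 kb", "mean"]


# ----------------------------------------------------------------------
# PCA


def test_pca_duplicate_sample_and_variance():
    rng = np.random.default_rng(4)
    X = pd.DataFrame(rng.normal(size=(4, 30)),
                     index=["a", "b", "c", "a2"])
    X.iloc[3] = X.iloc[0]
    out = pca_windows(X)
    assert np.allclose(out["scores"].loc["a"], out["scores"].loc["a2"])
    assert out["variance_fraction"].sum() <= 1.0 + 1e-9
    with pytest.raises(ValueError):
        pca_windows(X.iloc[:1])


def test_pca_separates_conditions(small_scenario, small_truth):
    table = simulate_methylomes(small_truth, small_scenario)
    # warm columns differ from cold through the planted CHG intervals alone,
    # so use CHG window levels
    sc = dataclasses.replace(small_scenario,
                             global_shift={"CGN": 0.0, "CHG": 0.08, "CHH": 0.0})
    from epimem.truth import apply_treatment, simulate_truth
    from epimem.genome import generate_genome
    g = generate_genome(sc)
    truth = apply_treatment(simulate_truth(g, sc), sc)
    table = simulate_methylomes(truth, sc, groups=["eco1"])
    prof = window_profile(table, window=10_000, per_sample=True)
    sub = prof[(prof["context"] == "CHG") & (prof["chrom"] != "chrC")]
    mat = sub.pivot_table(index="sample", columns=["chrom", "window"],
                          values="level")
    out = pca_windows(mat)
    pc1 = out["scores"]["PC1"]
    warm = pc1.index.str.contains("_28C_")
    assert (pc1[warm].min() > pc1[~warm].max()) or (pc1[warm].max() < pc1[~warm].min())
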