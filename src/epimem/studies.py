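"""Packaged study-condition experiments.

Each function runs one self-contained simulation-plus-analysis under the
default study conditions (the scenario presets) and returns the quantities
of interest.  The numbered analysis scripts, the test suite, and the
acceptance script all call these, so the computations exist in exactly one
place.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import stable_stream
from .counts import simulate_methylomes
from .dmr import call_dms, filter_sites, merge_dms
from .genome import generate_genome
from .landscape import call_peaks, dmr_density, shared_peak_windows
from .methylome import MethylomeTable, estimate_nonconversion, weighted_level
from .scenario import CONTEXTS, baseline_scenario, peak_fixture_scenario, warm_shift_scenario
from .truth import apply_treatment, simulate_truth


def baseline_global_levels(seed: int = 1, group: str = "eco1") -> dict:
    """Genome-wide weighted methylation (percent) per context at 18C.

    Simulates the baseline scenario (~2.1 Mb genome, 30x coverage, three
    replicates of one group) and pools counts genome-wide, excluding the
    chloroplast control contig.
    """
    sc = baseline_scenario(seed=seed)
    genome = generate_genome(sc)
    truth = simulate_truth(genome, sc)
    table = simulate_methylomes(truth, sc, groups=[group],
                                conditions=[sc.conditions[0]])
    out = {
        ctx: 100.0 * weighted_level(table, context=ctx,
                                    exclude_chroms=[sc.chloroplast])
        for ctx in CONTEXTS
    }
    out["epsilon"] = estimate_nonconversion(table, sc.chloroplast)
    out["n_sites"] = len(truth.sites)
    return out


def warm_shift_deltas(seed: int = 2, group: str = "eco1") -> dict:
    """Warm-minus-cold genome-wide weighted level difference (points).

    Simulates paired 18C and 28C methylomes (three replicates each) from the
    global warm-shift scenario and reports the per-context pooled difference
    in percentage points.
    """
    sc = warm_shift_scenario(seed=seed)
    genome = generate_genome(sc)
    truth = apply_treatment(simulate_truth(genome, sc), sc)
    table = simulate_methylomes(truth, sc, groups=[group])
    cold = table.samples_where(condition=sc.conditions[0])
    warm = table.samples_where(condition=sc.conditions[1])
    out = {}
    for ctx in CONTEXTS:
        lo = weighted_level(table, context=ctx, samples=cold,
                            exclude_chroms=[sc.chloroplast])
        hi = weighted_level(table, context=ctx, samples=warm,
                            exclude_chroms=[sc.chloroplast])
        out[ctx] = 100.0 * (hi - lo)
    out["n_samples"] = len(cold) + len(warm)
    return out


def _flat_chg_table(rng, n_sites: int, n_per_group: int, base: float,
                    effect: float, frac_alt: float, coverage_mean: float,
                    coverage_shape: float = 10.0):
    """Synthetic CHG site panel: two groups, a fraction of sites shifted."""
    n_alt = int(round(frac_alt * n_sites))
    sites = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.arange(n_sites, dtype=np.int64) * 1000,
        "strand": "+",
        "tri": "CAG",
        "context": np.full(n_sites, 1, dtype=np.int8),  # CHG
        "truncated": False,
    })
    table = MethylomeTable(sites)
    alt = np.zeros(n_sites, dtype=bool)
    alt[:n_alt] = True
    r = coverage_shape
    for g, cond in ((0, "18C"), (1, "28C")):
        p = np.full(n_sites, base)
        if g == 1:
            p[alt] = base + effect
        for rep in range(n_per_group):
            cov = rng.negative_binomial(r, r / (r + coverage_mean), n_sites)
            mc = rng.binomial(cov, p)
            table.add_sample(f"s{g}_{rep}", mc, cov, group="sim",
                             condition=cond, replicate=rep + 1)
    return table, alt


def dms_fdr_calibration(seed: int = 0, n_sites: int = 20_000, n_reps: int = 20,
                        frac_alt: float = 0.05, effect: float = 0.3,
                        base: float = 0.3, coverage: float = 30.0,
                        fdr: float = 0.003, B: int = 1000,
                        min_pooled_cov: int = 30) -> dict:
    """Realized DMS false-discovery proportion in the mixed two-group panel.

    Per replicate: ``n_sites`` CHG sites, 3 vs 3 at ``coverage``x, 5% of
    sites shifted by ``effect``; sites filtered at pooled coverage >= 30,
    then the RMS permutation test with pooled-null empirical FDR at the
    nominal level.  Reports mean false-discovery proportion and power over
    ``n_reps`` seed replicates.
    """
    fdps, powers, calls_list = [], [], []
    for rep in range(n_reps):
        rng = stable_stream(seed, "fdr-calibration", rep)
        table, alt = _flat_chg_table(rng, n_sites, 3, base, effect,
                                     frac_alt, coverage)
        ctrl = table.samples_where(condition="18C")
        trt = table.samples_where(condition="28C")
        mat = filter_sites(table, "CHG", ctrl, trt,
                           min_pooled_cov=min_pooled_cov)
        dms = call_dms(mat, fdr=fdr, B=B, seed=int(rep) + seed * 1000)
        idx = dms["pos"].to_numpy() // 1000
        calls = len(dms)
        false = int((~alt[idx]).sum())
        fdps.append(false / calls if calls else 0.0)
        powers.append(alt[idx].sum() / max(alt.sum(), 1))
        calls_list.append(calls)
    return {
        "mean_fdp": float(np.mean(fdps)),
        "mean_power": float(np.mean(powers)),
        "mean_calls": float(np.mean(calls_list)),
        "fdps": fdps,
        "n_reps": n_reps,
        "n_sites": n_sites,
    }


def shared_peak_recovery(seed: int = 3, contexts=("CHG",), fdr: float = 0.003,
                         B: int = 1000, floor: int = 10) -> dict:
    """Four-group shared DMR-peak recovery on the planted-cluster fixture.

    Simulates the peak-fixture scenario (clustered CHG DMRs planted in eight
    designated 50-kb windows for every group plus scattered singles), calls
    DMSs/DMRs per group, and intersects floor-thresholded peak windows
    across all four groups.
    """
    sc = peak_fixture_scenario(seed=seed)
    genome = generate_genome(sc)
    truth = apply_treatment(simulate_truth(genome, sc), sc)
    table = simulate_methylomes(truth, sc)
    chrom_lengths = {c: L for c, L in genome.chrom_lengths.items()
                     if c != sc.chloroplast}
    density, dmrs_by_group = {}, {}
    for group in sc.groups:
        ctrl = table.samples_where(group=group, condition=sc.conditions[0])
        trt = table.samples_where(group=group, condition=sc.conditions[1])
        parts = []
        for ctx in contexts:
            mat = filter_sites(table, ctx, ctrl, trt)
            dms = call_dms(mat, fdr=fdr, B=B, seed=seed)
            parts.append(merge_dms(dms))
        dmrs = pd.concat(parts, ignore_index=True)
        dmrs_by_group[group] = dmrs
        density[group] = dmr_density(dmrs[dmrs["context"] == "CHG"],
                                     chrom_lengths)
    peaks = call_peaks(density, floor=floor, quantile=None)
    shared = shared_peak_windows(peaks)

    planted = [(d.chrom, d.start, d.end) for d in sc.planted_dmrs]
    recovered = 0
    for chrom, start, end in planted:
        hit = all(
            ((d["chrom"] == chrom) & (d["start"] < end) & (d["end"] > start)).any()
            for d in dmrs_by_group.values()
        )
        recovered += int(hit)
    return {
        "shared_windows": shared,
        "n_shared": len(shared),
        "expected_windows": sorted(map(tuple, sc.peak_fixture.windows)),
        "dmrs_per_group": {g: len(d) for g, d in dmrs_by_group.items()},
        "scattered_planted": len(planted),
        "scattered_recovered_all_groups": recovered,
    }
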