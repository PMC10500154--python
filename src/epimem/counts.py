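"""Bisulfite read-count simulation over a truth methylome.

Coverage per site is negative-binomial around the scenario mean (WGBS
coverage is over-dispersed); methylated counts are binomial with success
probability p*(1 - eps_under) + (1 - p)*eps, so unmethylated cytosines
(including the whole chloroplast) read as methylated at the non-conversion
rate eps.  Each sample's stream is derived by stable hashing of
(master seed, sample id), so replicates are independent but the whole
simulation is reproducible from the scenario alone.
"""

from __future__ import annotations

import numpy as np

from ._util import stable_stream
from .methylome import MethylomeTable
from .scenario import ScenarioConfig
from .truth import TruthMethylome


def simulate_counts(truth: TruthMethylome, scenario: ScenarioConfig,
                    sample_id: str, group: str = "", condition: str = "",
                    seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(mc, cov) arrays for one sample, aligned with ``truth.sites``."""
    scenario.validate()
    if condition == "":
        condition = scenario.conditions[0]
    rng = stable_stream(scenario.seed if seed is None else seed, "counts", sample_id)
    n = len(truth.sites)
    mu, r = scenario.coverage_mean, scenario.coverage_shape
    cov = rng.negative_binomial(r, r / (r + mu), size=n).astype(np.int32)
    p = truth.prob_for(group, condition)
    p_obs = p * (1.0 - scenario.epsilon_under) + (1.0 - p) * scenario.epsilon
    mc = rng.binomial(cov, p_obs).astype(np.int32)
    return mc, cov


def simulate_methylomes(truth: TruthMethylome, scenario: ScenarioConfig,
                        groups=None, conditions=None) -> MethylomeTable:
    """A full multi-sample table for the scenario design (or a subset of it)."""
    table = MethylomeTable(truth.sites)
    for sample_id, group, condition, rep in scenario.samples():
        if groups is not None and group not in groups:
            continue
        if conditions is not None and condition not in conditions:
            continue
        if condition not in truth.probs:
            raise ValueError(f"truth lacks condition {condition!r}; "
                             "run apply_treatment first")
        mc, cov = simulate_counts(truth, scenario, sample_id, group, condition)
        table.add_sample(sample_id, mc, cov, group=group, condition=condition,
                         replicate=rep)
    return table
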