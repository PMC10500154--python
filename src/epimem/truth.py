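"""Ground-truth methylation landscapes for the synthetic world.

Each cytosine's true methylation probability is

    p = base[context] * submult[trinucleotide] * shape(position) * renorm[context]

where ``shape`` is a piecewise-smooth multiplicative profile built from the
annotated features (smooth dips flanking TSS/TTS inside gene bodies, a
hypermethylation plateau across repetitive elements, edge peaks on
pseudogenes) and ``renorm`` rescales the shape field to site-weighted mean
one per context class, so that configured base levels are genome-wide
weighted methylation levels.  The chloroplast contig is exactly
unmethylated.  The warm treatment adds per-context global shifts plus any
planted DMR intervals, clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel, cytosine_sites
from .scenario import CONTEXTS, ScenarioConfig


@dataclass
class TruthMethylome:
    """Per-site true methylation probabilities per condition.

    ``sites`` is the cytosine table (chrom, pos, strand, tri, context,
    truncated); ``probs`` maps a condition label to an aligned probability
    array.  Groups are exchangeable unless ``group_effect_scale`` rescales a
    group's warm response.
    """

    sites: pd.DataFrame
    probs: dict[str, np.ndarray]
    chloroplast: str | None = None
    baseline_condition: str = "18C"
    group_effect_scale: dict[str, float] = field(default_factory=dict)

    def prob_for(self, group: str, condition: str) -> np.ndarray:
        p = self.probs[condition]
        scale = self.group_effect_scale.get(group, 1.0)
        if condition == self.baseline_condition or scale == 1.0:
            return p
        base = self.probs[self.baseline_condition]
        return np.clip(base + scale * (p - base), 0.0, 1.0)


def _ramp(x: np.ndarray, lo: float, hi: float, length: float) -> np.ndarray:
    """Half-cosine rise from lo (x=0) to hi (x>=length)."""
    t = np.clip(x / max(length, 1.0), 0.0, 1.0)
    return lo + (hi - lo) * 0.5 * (1.0 - np.cos(np.pi * t))


def _shape_field(genome: GenomeModel, sc: ScenarioConfig) -> dict[str, np.ndarray]:
    """Multiplicative shape profile per chromosome (position-indexed)."""
    fields = {c: np.ones(L) for c, L in genome.chrom_lengths.items()}
    for _, f in genome.features.iterrows():
        s, e, n = int(f["start"]), int(f["end"]), int(f["end"] - f["start"])
        x = np.arange(n, dtype=float)
        d_edge = np.minimum(x, n - 1 - x)  # distance to nearer feature edge
        if f["type"] == "gene":
            ramp = min(sc.gene_dip_ramp, n // 2) or 1
            prof = _ramp(d_edge, sc.gene_dip_mult, sc.gene_body_mult, ramp)
        elif f["type"] == "dispersed_repeat":
            prof = np.full(n, sc.re_plateau_mult)
        else:  # pseudogene: peaks at both edges, lower body
            ramp = min(sc.pseudogene_edge_len, n // 2) or 1
            prof = _ramp(d_edge, sc.pseudogene_edge_mult, sc.pseudogene_body_mult, ramp)
        fields[f["chrom"]][s:e] *= prof
    return fields


def simulate_truth(genome: GenomeModel, scenario: ScenarioConfig) -> TruthMethylome:
    """Baseline-condition truth probabilities for every cytosine."""
    sites = cytosine_sites(genome.sequences)
    fields = _shape_field(genome, scenario)

    pos = sites["pos"].to_numpy()
    ctx = sites["context"].to_numpy()
    mult = np.ones(len(sites))
    chrom_arr = sites["chrom"].to_numpy()
    for chrom in genome.sequences:
        m = chrom_arr == chrom
        mult[m] = fields[chrom][pos[m]]

    sub = np.ones(len(sites))
    tri = sites["tri"]
    for t, factor in scenario.subcontext_multipliers.items():
        sub[(tri == t).to_numpy()] = factor

    plastid = (
        np.zeros(len(sites), dtype=bool)
        if scenario.chloroplast is None
        else (chrom_arr == scenario.chloroplast)
    )
    renorm = np.ones(3)
    if scenario.normalize_shapes:
        for code in range(3):
            m = (ctx == code) & ~plastid
            if m.any():
                renorm[code] = 1.0 / mult[m].mean()

    base = np.array([scenario.base_levels[c] for c in CONTEXTS])
    p = base[ctx] * sub * mult * renorm[ctx]
    p[plastid] = 0.0
    np.clip(p, 0.0, 1.0, out=p)

    return TruthMethylome(
        sites=sites,
        probs={scenario.conditions[0]: p},
        chloroplast=scenario.chloroplast,
        baseline_condition=scenario.conditions[0],
        group_effect_scale=dict(scenario.group_effect_scale),
    )


def apply_treatment(truth: TruthMethylome, scenario: ScenarioConfig) -> TruthMethylome:
    """Add the warm-condition probabilities (global shifts + planted DMRs)."""
    cold = truth.probs[truth.baseline_condition]
    sites = truth.sites
    ctx = sites["context"].to_numpy()
    shift = np.array([scenario.global_shift.get(c, 0.0) for c in CONTEXTS])
    warm = cold + shift[ctx]

    chrom_arr = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    for dmr in scenario.all_planted():
        dmr.validate(scenario.chrom_lengths)
        code = CONTEXTS.index(dmr.context)
        m = (chrom_arr == dmr.chrom) & (pos >= dmr.start) & (pos < dmr.end) & (ctx == code)
        warm[m] += dmr.shift

    np.clip(warm, 0.0, 1.0, out=warm)
    if truth.chloroplast is not None:
        warm[chrom_arr == truth.chloroplast] = 0.0

    probs = dict(truth.probs)
    warm_label = scenario.conditions[1] if len(scenario.conditions) > 1 else "warm"
    probs[warm_label] = warm
    return TruthMethylome(
        sites=sites,
        probs=probs,
        chloroplast=truth.chloroplast,
        baseline_condition=truth.baseline_condition,
        group_effect_scale=truth.group_effect_scale,
    )
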