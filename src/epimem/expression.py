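"""Gene-expression count simulation with RE-proximity repression and
temperature-responsive genes coupled to planted methylation changes.

Per gene and sample, counts are negative-binomial.  Genes with a repetitive
element within 2 kb have their baseline mean multiplied by the repression
factor (transposon-proximity silencing).  A scenario-chosen fraction of
genes respond to the warm condition with a log2 fold change drawn from the
configured range; where the scenario plants DMRs inside gene promoters or
bodies, a coupling fraction of the responsive genes is drawn from those
planted genes first (the DEDMG coupling).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import stable_stream
from .genome import GenomeModel
from .scenario import ScenarioConfig

PROMOTER_LEN = 2000


def _nearest_re_distance(genes: pd.DataFrame, res: pd.DataFrame) -> np.ndarray:
    """Boundary-to-boundary distance from each gene to its closest RE (0 if
    overlapping, inf if the chromosome has none)."""
    out = np.full(len(genes), np.inf)
    for chrom, gsub in genes.groupby("chrom", observed=True):
        rsub = res[res["chrom"] == chrom]
        if len(rsub) == 0:
            continue
        rs = rsub["start"].to_numpy()
        re_ = rsub["end"].to_numpy()
        for i, (_, g) in enumerate(gsub.iterrows()):
            # signed gaps; overlap makes both negative -> clipped to 0
            gap = np.maximum(np.maximum(rs - g["end"], g["start"] - re_), 0)
            out[gsub.index[i]] = gap.min()
    return out


def planted_dmg_genes(genome: GenomeModel, scenario: ScenarioConfig,
                      promoter_len: int = PROMOTER_LEN) -> set[str]:
    """Genes whose promoter or body overlaps a planted DMR interval."""
    out = set()
    genes = genome.genes
    for dmr in scenario.all_planted():
        g = genes[genes["chrom"] == dmr.chrom]
        for _, row in g.iterrows():
            if row["strand"] == "+":
                lo, hi = row["start"] - promoter_len, row["end"]
            else:
                lo, hi = row["start"], row["end"] + promoter_len
            if dmr.start < hi and dmr.end > lo:
                out.add(row["feature_id"])
    return out


def simulate_expression(genome: GenomeModel, scenario: ScenarioConfig,
                        seed: int | None = None):
    """Expression counts (genes x samples) plus the gene-level truth table.

    Returns ``(counts, truth)``: a counts DataFrame indexed by gene id with
    one column per sample, and a truth DataFrame with each gene's baseline
    mean, RE-proximity flag, true log2 fold change (28C vs 18C) and DE /
    planted-DMG category.
    """
    scenario.validate()
    master = scenario.seed if seed is None else seed
    rng = stable_stream(master, "expression-design")
    genes = genome.genes
    n = len(genes)
    gene_ids = genes["feature_id"].to_numpy()

    dist = _nearest_re_distance(genes, genome.features_of_type("dispersed_repeat"))
    re_near = dist <= 2000

    base_mean = np.full(n, float(scenario.expr_mean))
    base_mean[re_near] *= scenario.repression_factor

    # choose responsive genes, preferring planted-DMG genes per the coupling
    n_de = int(round(scenario.de_fraction * n))
    is_de = np.zeros(n, dtype=bool)
    planted = planted_dmg_genes(genome, scenario)
    planted_idx = np.flatnonzero(np.isin(gene_ids, sorted(planted)))
    n_coupled = min(len(planted_idx), int(round(scenario.dedmg_coupling * n_de)))
    if n_coupled > 0:
        is_de[rng.choice(planted_idx, size=n_coupled, replace=False)] = True
    rest = np.flatnonzero(~is_de)
    extra = n_de - int(is_de.sum())
    if extra > 0:
        is_de[rng.choice(rest, size=extra, replace=False)] = True

    lfc = np.zeros(n)
    lo, hi = scenario.lfc_range
    magnitudes = rng.uniform(lo, hi, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    lfc[is_de] = (signs * magnitudes)[is_de]

    disp = scenario.expr_dispersion
    r = 1.0 / disp if disp > 0 else np.inf
    cols = {}
    for sample_id, group, condition, rep in scenario.samples():
        srng = stable_stream(master, "expression", sample_id)
        mu = base_mean * np.where(condition == scenario.conditions[1], 2.0 ** lfc, 1.0)
        if np.isfinite(r):
            cols[sample_id] = srng.negative_binomial(r, r / (r + mu)).astype(np.int64)
        else:
            cols[sample_id] = srng.poisson(mu).astype(np.int64)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene"))

    truth = pd.DataFrame({
        "gene": gene_ids,
        "baseline_mean": base_mean,
        "re_within_2kb": re_near,
        "re_distance": dist,
        "is_de": is_de,
        "true_log2fc": lfc,
        "planted_dmg": np.isin(gene_ids, sorted(planted)),
    }).set_index("gene")
    return counts, truth
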