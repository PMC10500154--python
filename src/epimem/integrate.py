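"""Methylome-transcriptome integration: DMR annotation, DMG calling, TMM
normalization, negative-binomial Wald differential expression, and
DMG x DEG overlap statistics.

The DE engine is a deliberately simple stand-in for commercial GLM
pipelines: TMM-scaled library sizes, per-gene method-of-moments NB
dispersion shrunk toward an abundance-matched trend, and a Wald test on the
condition log2 fold change.  Its contract is calibration (type-I error near
nominal, recovery of planted effects), not gene-list equality with any
particular tool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_PROMOTER = 2000

CATEGORY_ORDER = ("promoter", "gene body", "downstream", "intergenic")


# ----------------------------------------------------------------------
# DMR -> feature annotation


def annotate_dmrs(dmrs: pd.DataFrame, genes: pd.DataFrame,
                  promoter_len: int = DEFAULT_PROMOTER) -> pd.DataFrame:
    """Assign each DMR one category by midpoint precedence.

    Precedence per gene, strand-aware: promoter [TSS - promoter_len, TSS),
    gene body [TSS, TTS], downstream (TTS, TTS + promoter_len]; a DMR whose
    midpoint hits no gene's zones is intergenic.  The signed distance from
    the nearest TSS (negative upstream in the gene's 5'->3' orientation) is
    always reported.  Midpoint ties between genes go to the
    lexicographically smaller gene id.
    """
    if len(genes) and (genes["strand"].isin(["+", "-"]) == False).any():  # noqa: E712
        raise ValueError("all genes must be stranded +/-")
    gsub = genes.sort_values("feature_id").reset_index(drop=True)
    records = []
    for i, dmr in dmrs.reset_index(drop=True).iterrows():
        mid = (int(dmr["start"]) + int(dmr["end"]) - 1) // 2
        best = None  # (precedence rank, |distance|, gene_id, category, signed)
        nearest = None  # (|distance|, gene_id, signed distance)
        for _, g in gsub[gsub["chrom"] == dmr["chrom"]].iterrows():
            if g["strand"] == "+":
                tss, tts = g["start"], g["end"] - 1
                signed = mid - tss
                in_prom = tss - promoter_len <= mid < tss
                in_body = tss <= mid <= tts
                in_down = tts < mid <= tts + promoter_len
            else:
                tss, tts = g["end"] - 1, g["start"]
                signed = tss - mid
                in_prom = tss < mid <= tss + promoter_len
                in_body = tts <= mid <= tss
                in_down = tts - promoter_len <= mid < tts
            if nearest is None or (abs(signed), g["feature_id"]) < nearest[:2]:
                nearest = (abs(signed), g["feature_id"], signed)
            for rank, (flag, cat) in enumerate(
                [(in_prom, "promoter"), (in_body, "gene body"), (in_down, "downstream")]
            ):
                if flag:
                    cand = (rank, abs(signed), g["feature_id"], cat, signed)
                    if best is None or cand < best:
                        best = cand
                    break
        if best is not None:
            category, gene_id, signed = best[3], best[2], best[4]
        else:
            category, gene_id = "intergenic", None
            signed = nearest[2] if nearest is not None else np.nan
        records.append({
            "chrom": dmr["chrom"], "start": dmr["start"], "end": dmr["end"],
            "context": dmr.get("context", ""),
            "direction": dmr.get("direction", ""),
            "midpoint": mid, "category": category, "gene": gene_id,
            "tss_distance": signed,
        })
    return pd.DataFrame(records)


def call_dmgs(annotations: pd.DataFrame) -> dict[str, set]:
    """Differentially methylated genes per context plus the any-context union.

    A gene is a DMG for context c iff at least one context-c DMR is annotated
    to its promoter or gene body (downstream-only hits do not qualify).
    """
    hits = annotations[
        annotations["category"].isin(["promoter", "gene body"])
        & annotations["gene"].notna()
    ]
    out: dict[str, set] = {}
    for ctx, sub in hits.groupby("context", observed=True):
        out[str(ctx)] = set(sub["gene"])
    out["any"] = set(hits["gene"])
    return out


# ----------------------------------------------------------------------
# expression normalization and DE


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric-mean-normalized.

    Reference sample: upper quartile closest to the mean upper quartile.
    Per sample, M/A values over genes positive in both sample and reference
    are double-trimmed (30% of M tails, 5% of A tails) and the factor is the
    precision-weighted mean M, exponentiated.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    if (counts < 0).to_numpy().any():
        raise ValueError("counts must be nonnegative")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("sample with all-zero counts")
    uq = counts[counts > 0].quantile(0.75).fillna(0.0)
    ref = (uq - uq.mean()).abs().idxmin()

    log_factors = {}
    xr = counts[ref].to_numpy(dtype=float)
    for s in counts.columns:
        if s == ref:
            log_factors[s] = 0.0
            continue
        xs = counts[s].to_numpy(dtype=float)
        both = (xs > 0) & (xr > 0)
        fs, fr = xs[both] / lib[s], xr[both] / lib[ref]
        M = np.log2(fs / fr)
        A = 0.5 * np.log2(fs * fr)
        # asymptotic (delta-method) variance of M
        w = 1.0 / (
            (lib[s] - xs[both]) / (lib[s] * xs[both])
            + (lib[ref] - xr[both]) / (lib[ref] * xr[both])
        )
        keep = np.ones(len(M), dtype=bool)
        for vals, trim in ((M, trim_m), (A, trim_a)):
            lo, hi = np.quantile(vals, [trim, 1.0 - trim])
            keep &= (vals >= lo) & (vals <= hi)
        if keep.sum() == 0:
            log_factors[s] = 0.0
        else:
            log_factors[s] = float(np.average(M[keep], weights=w[keep]))
    lf = pd.Series(log_factors).reindex(counts.columns)
    lf -= lf.mean()  # geometric mean of factors = 1
    return np.exp2(lf)


@dataclass
class DEThresholds:
    """DEG-flag presets; the default mirrors the volcano-plot rule
    (raw p <= 0.05 and |fold change| >= 1.5)."""

    p: float = 0.05
    fc: float = 1.5
    use_adjusted: bool = False


def _trend_dispersion(mean_expr: np.ndarray, disp: np.ndarray, nbins: int = 20) -> np.ndarray:
    """Trimmed mean dispersion among similar-abundance genes."""
    order = np.argsort(mean_expr)
    bins = np.array_split(order, nbins)
    trend = np.empty_like(disp)
    for idx in bins:
        if len(idx) == 0:
            continue
        vals = np.sort(disp[idx])
        k = max(1, int(0.1 * len(vals)))
        trimmed = vals[k:-k] if len(vals) > 2 * k else vals
        trend[idx] = trimmed.mean()
    return trend


def de_test(counts: pd.DataFrame, design: pd.DataFrame, factors: pd.Series | None = None,
            thresholds: DEThresholds | None = None) -> pd.DataFrame:
    """Per-gene NB Wald test of the condition effect (second level vs first).

    ``design`` needs columns sample/condition (replicate optional).  Counts
    are scaled by TMM-adjusted library sizes; dispersion is method-of-moments
    per gene, floored at 1e-8 and shrunk 50/50 toward the trimmed trend of
    similar-abundance genes; the Wald statistic on log2FC is referred to a
    moderated t distribution (3x residual df; see docs/methods.md).
    """
    thresholds = thresholds or DEThresholds()
    design = design.set_index("sample") if "sample" in design.columns else design
    conds = pd.unique(design.loc[counts.columns, "condition"])
    if len(conds) != 2:
        raise ValueError(f"need exactly 2 conditions, got {list(conds)}")
    g1 = [s for s in counts.columns if design.loc[s, "condition"] == conds[0]]
    g2 = [s for s in counts.columns if design.loc[s, "condition"] == conds[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 replicates per condition")
    if factors is None:
        factors = tmm_factors(counts)

    eff_lib = counts.sum(axis=0).astype(float) * factors.reindex(counts.columns)
    scale = eff_lib / np.exp(np.log(eff_lib).mean())
    norm = counts / scale

    x1, x2 = norm[g1].to_numpy(), norm[g2].to_numpy()
    n1, n2 = x1.shape[1], x2.shape[1]
    mu1, mu2 = x1.mean(axis=1), x2.mean(axis=1)
    pseudo = 0.5
    log2fc = np.log2((mu2 + pseudo) / (mu1 + pseudo))

    # method-of-moments NB dispersion from within-condition residuals
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    v = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    mu = (n1 * mu1 + n2 * mu2) / (n1 + n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw_disp = (v - mu) / mu**2
    raw_disp = np.where(np.isfinite(raw_disp), raw_disp, 0.0)
    raw_disp = np.maximum(raw_disp, 1e-8)
    disp = 0.5 * raw_disp + 0.5 * _trend_dispersion(mu, raw_disp)

    # delta-method SE of log2(mu) under NB sampling
    se2 = ((1.0 / np.maximum(mu1, pseudo) + disp) / n1
           + (1.0 / np.maximum(mu2, pseudo) + disp) / n2) / np.log(2.0) ** 2
    wald = log2fc / np.sqrt(se2)
    # moderated reference: dispersion shrinkage borrows strength across genes,
    # so the Wald statistic has more effective df than the residual df; the
    # factor 3 calibrates the null rejection rate at the default 3v3 design
    df = 3 * (n1 + n2 - 2)
    pval = 2.0 * stats.t.sf(np.abs(wald), df)
    identical = (v == 0) & (mu1 == mu2)
    pval[identical] = 1.0
    padj = multipletests(pval, method="fdr_bh")[1]

    p_used = padj if thresholds.use_adjusted else pval
    deg = (p_used <= thresholds.p) & (np.exp2(np.abs(log2fc)) >= thresholds.fc)

    out = pd.DataFrame({
        "gene": counts.index,
        "mean_norm": mu,
        f"mean_{conds[0]}": mu1,
        f"mean_{conds[1]}": mu2,
        "log2fc": log2fc,
        "dispersion": disp,
        "wald": wald,
        "p": pval,
        "padj": padj,
        "deg": deg,
    }).set_index("gene")
    out.attrs.update({"conditions": list(conds), "thresholds": vars(thresholds)})
    return out


# ----------------------------------------------------------------------
# overlap statistics


@dataclass
class OverlapResult:
    """Hypergeometric over-representation of an intersection."""

    n_a: int
    n_b: int
    overlap: int
    universe: int
    p: float
    representation_factor: float

    @property
    def fraction_of_a(self) -> float:
        return self.overlap / self.n_a if self.n_a else 0.0


def overlap_test(set_a: set, set_b: set, universe: set) -> OverlapResult:
    """Upper-tail hypergeometric p for observing >= |A & B| overlaps."""
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    N, nA, nB = len(universe), len(set_a), len(set_b)
    O = len(set_a & set_b)
    p = float(stats.hypergeom.sf(O - 1, N, nA, nB)) if O > 0 else 1.0
    expected = nA * nB / N if N else 0.0
    rf = O / expected if expected > 0 else 0.0
    return OverlapResult(nA, nB, O, N, min(p, 1.0), rf)


def intersect_dedmg(dmg_sets: dict[str, set], deg_set: set,
                    universe: set) -> tuple[set, OverlapResult]:
    """DEDMGs = any-context DMGs that are also DEGs, with enrichment stats.

    The universe is the set of genes that passed DE testing; DMGs outside it
    (not expressed/tested) are dropped before testing.
    """
    dmg_any = set(dmg_sets.get("any", set().union(*dmg_sets.values()) if dmg_sets else set()))
    dmg_any &= universe
    deg = set(deg_set) & universe
    if len(universe) < max(len(dmg_any), len(deg)):
        raise ValueError("universe smaller than a tested set")
    res = overlap_test(dmg_any, deg, universe)
    return dmg_any & deg, res


def shared_sets(per_group: dict[str, set]) -> pd.DataFrame:
    """Venn-style membership-pattern counts for k group-specific sets.

    Returns one row per non-empty membership pattern; counts sum to the size
    of the union.
    """
    names = list(per_group)
    union = set().union(*per_group.values()) if per_group else set()
    patterns: dict[tuple, int] = {}
    for item in union:
        key = tuple(item in per_group[g] for g in names)
        patterns[key] = patterns.get(key, 0) + 1
    rows = []
    for key, count in sorted(patterns.items(), reverse=True):
        rows.append({
            "pattern": "".join("1" if k else "0" for k in key),
            "groups": "&".join(g for g, k in zip(names, key) if k),
            "n_groups": sum(key),
            "count": count,
        })
    df = pd.DataFrame(rows, columns=["pattern", "groups", "n_groups", "count"])
    df.attrs["group_order"] = names
    return df
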