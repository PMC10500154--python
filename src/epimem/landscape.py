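"""Window-level landscape analytics: DMR-density peaks and cross-group
sharing, methylation ~ feature-density regression, RE-proximity expression
effects (Games-Howell), and window PCA.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._util import covered_bp
from .scenario import DEFAULT_WINDOW

DEFAULT_PEAK_FLOOR = 10
DEFAULT_PEAK_QUANTILE = 0.99

PROXIMITY_EDGES = (2000, 5000, 10000)
PROXIMITY_LABELS = ("RE within 2 kb", "RE 2-5 kb", "RE 5-10 kb", "no RE within 10 kb")


# ----------------------------------------------------------------------
# DMR density and peaks


def dmr_density(dmrs: pd.DataFrame, chrom_lengths: dict[str, int],
                window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """DMR counts per (chromosome, window); a DMR belongs to the window
    containing its midpoint (half-open windows, boundary goes right)."""
    rows = []
    for chrom, length in chrom_lengths.items():
        nwin = max(1, -(-length // window))
        counts = np.zeros(nwin, dtype=int)
        sub = dmrs[dmrs["chrom"] == chrom] if len(dmrs) else dmrs
        if len(sub):
            mid = (sub["start"].to_numpy(dtype=np.int64)
                   + sub["end"].to_numpy(dtype=np.int64)) // 2
            np.add.at(counts, np.minimum(mid // window, nwin - 1), 1)
        for w in range(nwin):
            rows.append({"chrom": chrom, "window": w, "count": int(counts[w])})
    return pd.DataFrame(rows)


def call_peaks(density_by_group: dict[str, pd.DataFrame],
               floor: int = DEFAULT_PEAK_FLOOR,
               quantile: float | None = DEFAULT_PEAK_QUANTILE) -> pd.DataFrame:
    """Flag high-DMR-density windows per group and their all-group sharing.

    A window is a peak for a group iff its count >= max(floor, the group's
    empirical ``quantile`` of nonzero window counts).  ``quantile=None``
    (the scale-free fixture rule) applies the floor alone, as does having
    fewer than 10 nonzero windows.  Shared peaks are peaks in every group.
    """
    frames = []
    for group, dens in density_by_group.items():
        counts = dens["count"].to_numpy()
        nonzero = counts[counts > 0]
        if quantile is not None and len(nonzero) >= 10:
            thr = max(float(floor), float(np.quantile(nonzero, quantile)))
        else:
            thr = float(floor)
        df = dens.copy()
        df["group"] = group
        df["peak"] = df["count"] >= thr
        df.attrs["threshold"] = thr
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True)
    shared = (
        merged.groupby(["chrom", "window"], observed=True)["peak"]
        .agg(["all", "size"])
        .rename(columns={"all": "shared"})
    )
    ngroups = len(density_by_group)
    shared["shared"] &= shared["size"] == ngroups
    merged = merged.merge(shared["shared"], on=["chrom", "window"], how="left")
    return merged


def shared_peak_windows(peaks: pd.DataFrame) -> list[tuple[str, int]]:
    sub = peaks[peaks["shared"]]
    return sorted({(r["chrom"], int(r["window"])) for _, r in sub.iterrows()})


# ----------------------------------------------------------------------
# feature densities and regression


def feature_density(features: pd.DataFrame, chrom_lengths: dict[str, int],
                    window: int = DEFAULT_WINDOW,
                    types=("gene", "dispersed_repeat", "pseudogene")) -> pd.DataFrame:
    """Per-window fraction of bases covered by each feature type (union)."""
    rows = []
    for chrom, length in chrom_lengths.items():
        nwin = max(1, -(-length // window))
        sub = features[features["chrom"] == chrom]
        by_type = {
            t: sub[sub["type"] == t][["start", "end"]].to_numpy() for t in types
        }
        for w in range(nwin):
            ws, we = w * window, min((w + 1) * window, length)
            row = {"chrom": chrom, "window": w}
            for t in types:
                row[t] = covered_bp(by_type[t], ws, we) / window
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RegressionFit:
    """OLS fit of window methylation on feature densities."""

    context: str
    coefficients: dict[str, float]
    intercept: float
    r_squared: float
    n_windows: int
    condition_number: float
    collinear: bool


def methylation_regression(window_levels: pd.DataFrame, densities: pd.DataFrame,
                           predictors=("gene", "dispersed_repeat", "pseudogene"),
                           ) -> dict[str, RegressionFit]:
    """Per-context OLS: methylation ~ gene + RE + pseudogene density.

    Windows with undefined (NaN) methylation are dropped.  A condition
    number above 1e8 flags collinearity (the pseudo-inverse fit is still
    reported).
    """
    out = {}
    for context, sub in window_levels.groupby("context", observed=True):
        merged = sub.merge(densities, on=["chrom", "window"], how="inner").dropna(
            subset=["level"]
        )
        X = sm.add_constant(merged[list(predictors)].to_numpy())
        fit = sm.OLS(merged["level"].to_numpy(), X).fit()
        cond = float(np.linalg.cond(X))
        out[str(context)] = RegressionFit(
            context=str(context),
            coefficients=dict(zip(predictors, fit.params[1:])),
            intercept=float(fit.params[0]),
            r_squared=float(fit.rsquared),
            n_windows=len(merged),
            condition_number=cond,
            collinear=cond > 1e8,
        )
    return out


# ----------------------------------------------------------------------
# RE proximity


def proximity_categories(genes: pd.DataFrame, res: pd.DataFrame) -> pd.DataFrame:
    """Gene categories by boundary-to-boundary distance to the closest RE.

    Edges closed on the right: distance 0 (overlap) .. 2000 -> "RE within
    2 kb"; (2000, 5000] -> "RE 2-5 kb"; (5000, 10000] -> "RE 5-10 kb"; else
    no RE within 10 kb.
    """
    from .expression import _nearest_re_distance

    dist = _nearest_re_distance(genes.reset_index(drop=True), res)
    cat = np.full(len(dist), PROXIMITY_LABELS[3], dtype=object)
    cat[dist <= PROXIMITY_EDGES[2]] = PROXIMITY_LABELS[2]
    cat[dist <= PROXIMITY_EDGES[1]] = PROXIMITY_LABELS[1]
    cat[dist <= PROXIMITY_EDGES[0]] = PROXIMITY_LABELS[0]
    return pd.DataFrame({
        "gene": genes["feature_id"].to_numpy(),
        "re_distance": dist,
        "category": pd.Categorical(cat, categories=list(PROXIMITY_LABELS)),
    }).set_index("gene")


def games_howell(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Games-Howell pairwise comparisons for unequal-variance group means.

    For each pair: Welch t statistic, Welch-Satterthwaite df, and p from the
    studentized-range distribution with k groups at q = |t| * sqrt(2).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    for name in names:
        if len(groups[name]) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 observations")
    k = len(names)
    stats_ = {
        n: (np.mean(groups[n]), np.var(groups[n], ddof=1), len(groups[n]))
        for n in names
    }
    rows = []
    for a, b in combinations(names, 2):
        ma, va, na = stats_[a]
        mb, vb, nb = stats_[b]
        se2 = va / na + vb / nb
        if se2 == 0:
            t = 0.0 if ma == mb else np.inf
            df = na + nb - 2.0
            p = 1.0 if ma == mb else 0.0
        else:
            t = (ma - mb) / np.sqrt(se2)
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            q = abs(t) * np.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, k, df))
        rows.append({
            "group_a": a, "group_b": b, "mean_a": ma, "mean_b": mb,
            "diff": ma - mb, "t": t, "df": df, "p": min(max(p, 0.0), 1.0),
        })
    return pd.DataFrame(rows)


def proximity_effect(gene_stats: pd.DataFrame, categories: pd.DataFrame,
                     value: str = "mean_norm", min_genes: int = 3) -> dict:
    """Expression (or |log2FC|) by RE-proximity category with Games-Howell.

    ``value`` may be any numeric gene_stats column, or "abs_log2fc" for the
    magnitude of the temperature response.  Categories with fewer than
    ``min_genes`` genes are excluded (with a note in the result).
    """
    merged = categories.join(gene_stats, how="inner")
    if value == "abs_log2fc":
        merged["abs_log2fc"] = merged["log2fc"].abs()
    groups, excluded = {}, []
    for cat in PROXIMITY_LABELS:
        vals = merged.loc[merged["category"] == cat, value].dropna().to_numpy()
        if len(vals) >= min_genes:
            groups[cat] = vals
        else:
            excluded.append(cat)
    summary = pd.DataFrame([
        {"category": c, "n": len(v), "mean": float(np.mean(v)),
         "median": float(np.median(v))}
        for c, v in groups.items()
    ])
    table = games_howell(groups) if len(groups) >= 2 else pd.DataFrame()
    return {"value": value, "summary": summary, "pairwise": table,
            "excluded": excluded}


# ----------------------------------------------------------------------
# PCA


def pca_windows(level_matrix: pd.DataFrame, n_components: int = 5) -> dict:
    """Centered SVD of the samples x windows level matrix.

    Columns with any undefined level are dropped; returns per-sample scores
    and variance fractions.
    """
    if level_matrix.shape[0] < 2:
        raise ValueError("PCA needs >= 2 samples")
    X = level_matrix.dropna(axis=1).to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(s))
    scores = pd.DataFrame(
        U[:, :k] * s[:k],
        index=level_matrix.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    total = (s**2).sum()
    var_frac = (s[:k] ** 2 / total) if total > 0 else np.zeros(k)
    return {"scores": scores, "variance_fraction": var_frac}
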