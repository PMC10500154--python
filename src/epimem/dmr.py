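"""Differential-methylation engine: RMS heterogeneity statistic, parametric
permutation null, empirical-FDR thresholding, and DMS -> DMR assembly.

The site statistic is the root-mean-square deviation of per-unit
methylation frequencies from the pooled frequency,

    d = sqrt( (1/s) * sum_i (m_i/n_i - pbar)^2 ),   pbar = sum(m_i)/sum(n_i).

In the default two-group *contrast* mode the units are the two groups'
pooled counts (replicates of a condition summed), so d measures the
between-condition frequency gap; ``heterogeneity=True`` instead uses every
sample as its own unit and tests all-sample homogeneity.  The null
distribution is generated by a parametric bootstrap: B replicates draw
m_i* ~ Binomial(n_i, pbar) per unit and recompute d.  Differentially
methylated sites are thresholded by empirical FDR: for a candidate
threshold t, eFDR(t) = (mean per replicate of null exceedances of t,
pooled across sites) / (observed exceedances of t); the call threshold is
the smallest t with eFDR(t) <= the nominal level (default 0.003).  Called
sites within 250 bp with the same context and direction merge into DMRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import stable_stream
from .genome import CONTEXT_NAMES
from .methylome import MethylomeTable

_CHUNK_SITES = 4096  # fixed internal chunk => draws independent of caller batching
_CHUNK_B = 250
_EFDR_GRID = 2048  # threshold-grid resolution for pooled-null eFDR

DEFAULT_FDR = 0.003
DEFAULT_MIN_COV = 30
DEFAULT_PERMUTATIONS = 1000
DEFAULT_MERGE_GAP = 250


@dataclass
class SiteCountMatrix:
    """Candidate sites x samples count matrix for one context and contrast."""

    chrom: np.ndarray
    pos: np.ndarray
    strand: np.ndarray
    context: str
    m: np.ndarray  # (sites, samples) methylated counts
    n: np.ndarray  # (sites, samples) coverages
    sample_ids: list[str]
    group_of: np.ndarray  # 0 = control group, 1 = treatment group per sample

    def __post_init__(self):
        if self.m.shape != self.n.shape:
            raise ValueError("m and n must have identical shapes")
        if (self.m < 0).any() or (self.m > self.n).any():
            raise ValueError("need 0 <= m <= n")
        for g in (0, 1):
            if (self.group_of == g).sum() < 2:
                raise ValueError("need >= 2 samples per group")

    def __len__(self):
        return self.m.shape[0]


def filter_sites(table: MethylomeTable, context: str, control_samples,
                 treatment_samples, min_pooled_cov: int = DEFAULT_MIN_COV) -> SiteCountMatrix:
    """Candidate sites: requested context, pooled coverage >= the floor, and
    at least one read in every sample."""
    ids = list(control_samples) + list(treatment_samples)
    group_of = np.array([0] * len(control_samples) + [1] * len(treatment_samples))
    code = list(CONTEXT_NAMES).index(context)
    ctx_mask = table.sites["context"].to_numpy() == code
    n = np.column_stack([table.cov[s] for s in ids])
    m = np.column_stack([table.mc[s] for s in ids])
    keep = ctx_mask & (n.sum(axis=1) >= min_pooled_cov) & (n > 0).all(axis=1)
    return SiteCountMatrix(
        chrom=table.sites["chrom"].to_numpy()[keep],
        pos=table.sites["pos"].to_numpy()[keep],
        strand=table.sites["strand"].to_numpy()[keep],
        context=context,
        m=m[keep], n=n[keep],
        sample_ids=ids, group_of=group_of,
    )


# ----------------------------------------------------------------------
# statistic and null


def rms_statistic(m: np.ndarray, n: np.ndarray) -> np.ndarray:
    """RMS deviation of per-sample frequencies from the pooled frequency.

    Accepts (samples,) vectors for one site or (sites, samples) matrices.
    """
    m = np.atleast_2d(np.asarray(m, dtype=float))
    n = np.atleast_2d(np.asarray(n, dtype=float))
    if (n <= 0).any():
        raise ValueError("rms_statistic requires all coverages > 0; filter first")
    f = m / n
    pbar = m.sum(axis=-1) / n.sum(axis=-1)
    d = np.sqrt(((f - pbar[..., None]) ** 2).mean(axis=-1))
    return d if d.size > 1 else float(d[0])


def _null_d(rng, n: np.ndarray, pbar: np.ndarray, nb: int) -> np.ndarray:
    """(nb, sites) null statistics from the binomial bootstrap."""
    s, k = n.shape
    m_star = rng.binomial(n[None, :, :], pbar[None, :, None], size=(nb, s, k))
    f = m_star / n[None, :, :]
    pb = m_star.sum(axis=-1) / n.sum(axis=-1)[None, :]
    return np.sqrt(((f - pb[..., None]) ** 2).mean(axis=-1))


def permutation_null(m: np.ndarray, n: np.ndarray, B: int = DEFAULT_PERMUTATIONS,
                     seed: int = 0):
    """Null statistic sample and permutation p-value for a single site.

    Returns ``(null_d, p)`` with p = (1 + #{d* >= d}) / (B + 1).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    m = np.asarray(m, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    d = rms_statistic(m, n)
    pbar = np.array([m.sum() / n.sum()])
    rng = stable_stream(seed, "perm-single")
    null = _null_d(rng, n[None, :], pbar, B)[:, 0]
    p = (1 + int((null >= d).sum())) / (B + 1)
    return null, p


# ----------------------------------------------------------------------
# genome-wide calling


def call_dms(matrix: SiteCountMatrix, fdr: float = DEFAULT_FDR,
             B: int = DEFAULT_PERMUTATIONS, seed: int = 0,
             pooled_null: bool = True, heterogeneity: bool = False) -> pd.DataFrame:
    """Call differentially methylated sites by empirical-FDR thresholding.

    By default the RMS statistic contrasts the two groups' pooled counts;
    ``heterogeneity=True`` tests per-sample homogeneity instead.  Null
    statistics are pooled across sites within the context when forming the
    empirical FDR (``pooled_null=True``, the default); the alternative
    applies BH to per-site permutation p-values.  The returned frame carries
    diagnostics in ``.attrs`` (threshold, tested site count, nominal level).
    """
    S = len(matrix)
    empty = pd.DataFrame(columns=[
        "chrom", "pos", "strand", "context", "d", "p", "direction",
        "mc_ctrl", "cov_ctrl", "mc_trt", "cov_trt",
    ])
    empty.attrs.update({"threshold": np.inf, "n_tested": S, "fdr": fdr, "B": B})
    if S == 0:
        return empty

    if heterogeneity:
        m, n = matrix.m.astype(np.int64), matrix.n.astype(np.int64)
    else:
        ctrl_, trt_ = matrix.group_of == 0, matrix.group_of == 1
        m = np.column_stack([matrix.m[:, ctrl_].sum(axis=1),
                             matrix.m[:, trt_].sum(axis=1)]).astype(np.int64)
        n = np.column_stack([matrix.n[:, ctrl_].sum(axis=1),
                             matrix.n[:, trt_].sum(axis=1)]).astype(np.int64)
    d_obs = np.atleast_1d(rms_statistic(m, n))
    pbar = m.sum(axis=1) / n.sum(axis=1)

    d_sorted = np.sort(d_obs)

    # candidate thresholds: a fine grid over the observed range (d <= 0.5 by
    # construction of the statistic on two units; generally d <= 1)
    dmax = float(d_sorted[-1])
    edges = np.linspace(0.0, dmax + 1e-12, _EFDR_GRID + 1)
    width = edges[1] - edges[0] if dmax > 0 else 1.0

    # accumulate per-site #{d* >= d_site} and a pooled null histogram on the
    # threshold grid (exact exceedance counts at every grid edge)
    ge_count = np.zeros(S, dtype=np.int64)
    pooled_hist = np.zeros(_EFDR_GRID + 2, dtype=np.int64)
    for lo in range(0, S, _CHUNK_SITES):
        hi = min(lo + _CHUNK_SITES, S)
        rng = stable_stream(seed, "perm", lo)
        for b0 in range(0, B, _CHUNK_B):
            nb = min(_CHUNK_B, B - b0)
            null = _null_d(rng, n[lo:hi], pbar[lo:hi], nb)
            ge_count[lo:hi] += (null >= d_obs[None, lo:hi]).sum(axis=0)
            if pooled_null:
                idx = np.minimum((null.ravel() / width).astype(np.int64),
                                 _EFDR_GRID + 1)
                pooled_hist += np.bincount(idx, minlength=_EFDR_GRID + 2)

    p_perm = (1.0 + ge_count) / (B + 1.0)

    if pooled_null:
        # null values with bin index >= j are >= edges[j]; exact at edges
        suffix = np.cumsum(pooled_hist[::-1])[::-1]
        null_exceed = suffix[1:_EFDR_GRID + 1]  # exceedances of edges[1..]
        obs_exceed = S - np.searchsorted(d_sorted, edges[1:], side="left")
        with np.errstate(divide="ignore", invalid="ignore"):
            efdr = np.where(obs_exceed > 0,
                            (null_exceed / B) / np.maximum(obs_exceed, 1),
                            np.inf)
        ok = np.flatnonzero(efdr <= fdr)
        if len(ok) == 0:
            return empty
        thr = float(edges[1:][ok[0]])  # smallest grid threshold meeting eFDR
        called = d_obs >= thr
    else:
        from statsmodels.stats.multitest import multipletests
        reject = multipletests(p_perm, alpha=fdr, method="fdr_bh")[0]
        called = reject
        thr = d_obs[called].min() if called.any() else np.inf

    ctrl = matrix.group_of == 0
    trt = matrix.group_of == 1
    m_all, n_all = matrix.m.astype(np.int64), matrix.n.astype(np.int64)
    mc_c, cov_c = m_all[:, ctrl].sum(axis=1), n_all[:, ctrl].sum(axis=1)
    mc_t, cov_t = m_all[:, trt].sum(axis=1), n_all[:, trt].sum(axis=1)
    lvl_c, lvl_t = mc_c / cov_c, mc_t / cov_t
    direction = np.where(lvl_t > lvl_c, "hyper", np.where(lvl_t < lvl_c, "hypo", "none"))

    out = pd.DataFrame({
        "chrom": matrix.chrom[called],
        "pos": matrix.pos[called],
        "strand": matrix.strand[called],
        "context": matrix.context,
        "d": d_obs[called],
        "p": p_perm[called],
        "direction": direction[called],
        "mc_ctrl": mc_c[called], "cov_ctrl": cov_c[called],
        "mc_trt": mc_t[called], "cov_trt": cov_t[called],
    }).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    out.attrs.update({"threshold": float(thr) if np.isfinite(thr) else np.inf,
                      "n_tested": S, "fdr": fdr, "B": B})
    return out


# ----------------------------------------------------------------------
# DMS -> DMR assembly


def merge_dms(dms: pd.DataFrame, gap: int = DEFAULT_MERGE_GAP) -> pd.DataFrame:
    """Greedy left-to-right merge of same-context, same-direction DMSs.

    Consecutive member sites at most ``gap`` bp apart (inclusive) join one
    DMR; the DMR interval spans first to last member cytosine (half-open,
    so a single-site DMR has length 1).  Input must be position-sorted per
    chromosome.
    """
    cols = ["chrom", "start", "end", "context", "direction", "n_dms",
            "level_ctrl", "level_trt", "diff"]
    if len(dms) == 0:
        return pd.DataFrame(columns=cols)
    rows = []
    for (chrom, context), sub in dms.groupby(["chrom", "context"], observed=True, sort=False):
        pos = sub["pos"].to_numpy()
        if (np.diff(pos) < 0).any():
            raise ValueError(f"DMS input not position-sorted on {chrom}")
        direction = sub["direction"].to_numpy()
        new_run = np.r_[True, (np.diff(pos) > gap) | (direction[1:] != direction[:-1])]
        run_id = np.cumsum(new_run)
        for rid in np.unique(run_id):
            member = sub[run_id == rid]
            mc_c, cov_c = member["mc_ctrl"].sum(), member["cov_ctrl"].sum()
            mc_t, cov_t = member["mc_trt"].sum(), member["cov_trt"].sum()
            lc, lt = mc_c / cov_c, mc_t / cov_t
            rows.append({
                "chrom": chrom,
                "start": int(member["pos"].iloc[0]),
                "end": int(member["pos"].iloc[-1]) + 1,
                "context": context,
                "direction": member["direction"].iloc[0],
                "n_dms": len(member),
                "level_ctrl": lc, "level_trt": lt, "diff": lt - lc,
            })
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def dmr_summary(dmr_sets: dict) -> pd.DataFrame:
    """Hyper/hypo DMR counts per (comparison, context).

    ``dmr_sets`` maps a comparison label (e.g. an ecotype, or a control
    contrast) to its DMR frame.
    """
    rows = []
    for label, dmrs in dmr_sets.items():
        for context in CONTEXT_NAMES:
            sub = dmrs[dmrs["context"] == context] if len(dmrs) else dmrs
            rows.append({
                "comparison": label,
                "context": context,
                "hyper": int((sub["direction"] == "hyper").sum()) if len(sub) else 0,
                "hypo": int((sub["direction"] == "hypo").sum()) if len(sub) else 0,
                "total": len(sub),
            })
    return pd.DataFrame(rows)
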