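"""Methylome container and per-cytosine / regional methylation analytics.

Methylation levels throughout are *weighted*: pooled methylated reads over
pooled total reads (not means of per-site fractions), matching the
methylated-reads/total-reads definition used for whole-genome bisulfite
data.  Internal coordinates are 0-based half-open; on-disk formats are
converted at the IO layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import CONTEXT_NAMES
from ._util import revcomp

STATUS_UNMETHYLATED, STATUS_METHYLATED, STATUS_UNCOVERED = 0, 1, 2


@dataclass(frozen=True)
class CytosineSite:
    """One cytosine: position, strand, trinucleotide and context class."""

    chrom: str
    pos: int  # 0-based
    strand: str
    tri: str
    context: str
    truncated: bool = False


def classify_context(sequence: str, position: int, strand: str = "+",
                     chrom: str = "") -> CytosineSite:
    """Classify a single cytosine into CGN / CHG / CHH.

    The trinucleotide is read 5'->3' on the cytosine's own strand.  Precedence:
    a G immediately 3' of the C gives CGN; else a G two bases 3' gives CHG;
    else CHH.  Bases beyond the sequence end count as non-G and the site is
    flagged truncated.
    """
    L = len(sequence)
    if strand == "+":
        if position < 0 or position >= L or sequence[position] != "C":
            raise ValueError(f"no cytosine at +:{position}")
        b1 = sequence[position + 1] if position + 1 < L else "N"
        b2 = sequence[position + 2] if position + 2 < L else "N"
        truncated = position + 2 >= L
    elif strand == "-":
        if position < 0 or position >= L or sequence[position] != "G":
            raise ValueError(f"no cytosine at -:{position} (reference G expected)")
        b1 = revcomp(sequence[position - 1]) if position - 1 >= 0 else "N"
        b2 = revcomp(sequence[position - 2]) if position - 2 >= 0 else "N"
        truncated = position - 2 < 0
    else:
        raise ValueError(f"bad strand {strand!r}")
    context = "CGN" if b1 == "G" else ("CHG" if b2 == "G" else "CHH")
    return CytosineSite(chrom, position, strand, "C" + b1 + b2, context, truncated)


# ----------------------------------------------------------------------


class MethylomeTable:
    """Per-cytosine counts for a set of samples over one shared site table.

    ``sites`` holds (chrom, pos, strand, tri, context, truncated); per-sample
    methylated/total read counts live in aligned arrays.  Sample metadata
    (group, condition, replicate) drives the group contrasts downstream.
    """

    def __init__(self, sites: pd.DataFrame):
        self.sites = sites.reset_index(drop=True)
        self.mc: dict[str, np.ndarray] = {}
        self.cov: dict[str, np.ndarray] = {}
        self.meta: dict[str, dict] = {}
        self._chrom_index: dict[str, tuple[int, int]] | None = None

    # -- construction ---------------------------------------------------
    def add_sample(self, sample_id: str, mc: np.ndarray, cov: np.ndarray,
                   group: str = "", condition: str = "", replicate: int = 0) -> None:
        mc = np.asarray(mc)
        cov = np.asarray(cov)
        if len(mc) != len(self.sites) or len(cov) != len(self.sites):
            raise ValueError("count arrays must align with the site table")
        if (mc < 0).any() or (mc > cov).any():
            raise ValueError(f"sample {sample_id}: need 0 <= mc <= cov")
        self.mc[sample_id] = mc.astype(np.int32)
        self.cov[sample_id] = cov.astype(np.int32)
        self.meta[sample_id] = {
            "group": group, "condition": condition, "replicate": replicate,
        }

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mc)

    def samples_where(self, group=None, condition=None) -> list[str]:
        out = []
        for s, m in self.meta.items():
            if group is not None and m["group"] != group:
                continue
            if condition is not None and m["condition"] != condition:
                continue
            out.append(s)
        return out

    def design(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"sample": s, **m} for s, m in self.meta.items()]
        )

    # -- site selection -------------------------------------------------
    def _chrom_slices(self) -> dict[str, tuple[int, int]]:
        """Index ranges per chromosome (sites are position-sorted per chrom)."""
        if self._chrom_index is None:
            idx = {}
            chroms = self.sites["chrom"].to_numpy()
            bounds = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
            starts = np.r_[0, bounds]
            ends = np.r_[bounds, len(chroms)]
            for s, e in zip(starts, ends):
                idx[chroms[s]] = (int(s), int(e))
            self._chrom_index = idx
        return self._chrom_index

    def region_mask(self, regions) -> np.ndarray:
        """Boolean site mask for a list of (chrom, start, end) half-open regions."""
        mask = np.zeros(len(self.sites), dtype=bool)
        pos = self.sites["pos"].to_numpy()
        slices = self._chrom_slices()
        for chrom, start, end in regions:
            if chrom not in slices:
                continue
            lo, hi = slices[chrom]
            a = lo + np.searchsorted(pos[lo:hi], start, side="left")
            b = lo + np.searchsorted(pos[lo:hi], end, side="left")
            mask[a:b] = True
        return mask

    def pooled_counts(self, samples=None) -> tuple[np.ndarray, np.ndarray]:
        """Site-wise counts summed over the selected samples."""
        ids = samples if samples is not None else self.sample_ids
        if not ids:
            raise ValueError("no samples selected")
        mc = np.zeros(len(self.sites), dtype=np.int64)
        cov = np.zeros(len(self.sites), dtype=np.int64)
        for s in ids:
            mc += self.mc[s]
            cov += self.cov[s]
        return mc, cov


# ----------------------------------------------------------------------
# conversion control and site calling


def estimate_nonconversion(table: MethylomeTable, control_contig: str) -> float:
    """Bisulfite non-conversion rate from an unmethylated control contig.

    Pools methylated and total reads over every site of the control contig
    (all contexts, all samples): epsilon = sum(mc) / sum(cov).
    """
    chroms = table.sites["chrom"].to_numpy()
    mask = chroms == control_contig
    if not mask.any():
        raise ValueError(f"control contig {control_contig!r} absent from the table")
    mc, cov = table.pooled_counts()
    total = int(cov[mask].sum())
    if total == 0:
        raise ValueError(f"control contig {control_contig!r} has zero pooled coverage")
    return float(mc[mask].sum() / total)


def call_sites(table: MethylomeTable, epsilon: float, q: float = 0.01) -> dict[str, np.ndarray]:
    """Per-sample binomial methylation status calls.

    For each covered site, the one-sided binomial p-value P(X >= mc | cov,
    epsilon) is tested against the non-conversion background; BH correction
    across sites at level ``q`` yields methylated/unmethylated; sites with
    zero coverage are uncovered.
    """
    if not 0 <= epsilon < 1:
        raise ValueError("epsilon must be in [0, 1)")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    out = {}
    for s in table.sample_ids:
        mc, cov = table.mc[s], table.cov[s]
        status = np.full(len(mc), STATUS_UNCOVERED, dtype=np.int8)
        covered = cov > 0
        p = stats.binom.sf(mc[covered] - 1, cov[covered], epsilon)
        reject = multipletests(p, alpha=q, method="fdr_bh")[0] if covered.any() else np.array([], bool)
        st = np.where(reject & (mc[covered] > 0), STATUS_METHYLATED, STATUS_UNMETHYLATED)
        status[covered] = st
        out[s] = status
    return out


# ----------------------------------------------------------------------
# weighted levels and profiles


def weighted_level(table: MethylomeTable, context: str | None = None,
                   regions=None, samples=None, exclude_chroms=()) -> float:
    """Pooled methylated/total read fraction over selected sites and samples.

    Returns NaN (undefined) when the pooled coverage is zero.
    """
    mc, cov = table.pooled_counts(samples)
    mask = np.ones(len(table.sites), dtype=bool)
    if context is not None:
        code = list(CONTEXT_NAMES).index(context)
        mask &= table.sites["context"].to_numpy() == code
    if regions is not None:
        mask &= table.region_mask(regions)
    for chrom in exclude_chroms:
        mask &= table.sites["chrom"].to_numpy() != chrom
    total = cov[mask].sum()
    if total == 0:
        return float("nan")
    return float(mc[mask].sum() / total)


def window_profile(table: MethylomeTable, window: int = 50_000,
                   samples=None, per_sample: bool = False) -> pd.DataFrame:
    """Pooled weighted level per (chromosome, window, context).

    Windows are half-open [i*w, (i+1)*w) tiles; the last window of each
    chromosome is truncated.  Levels are NaN where pooled coverage is zero.
    """
    if window <= 0:
        raise ValueError("window size must be positive")
    sample_sets = (
        [(s, [s]) for s in (samples or table.sample_ids)]
        if per_sample
        else [(None, samples)]
    )
    sites = table.sites
    chrom_codes, chrom_names = pd.factorize(sites["chrom"].to_numpy())
    win = sites["pos"].to_numpy() // window
    ctx = sites["context"].to_numpy()
    nwin = int(win.max()) + 1 if len(win) else 0
    key = (chrom_codes * nwin + win) * 3 + ctx
    frames = []
    for label, ids in sample_sets:
        mc, cov = table.pooled_counts(ids)
        size = len(chrom_names) * nwin * 3
        mc_sum = np.bincount(key, weights=mc, minlength=size)
        cov_sum = np.bincount(key, weights=cov, minlength=size)
        present = np.flatnonzero(np.bincount(key, minlength=size))
        with np.errstate(invalid="ignore", divide="ignore"):
            level = mc_sum[present] / cov_sum[present]
        df = pd.DataFrame({
            "chrom": np.asarray(chrom_names)[present // (nwin * 3)],
            "window": (present // 3) % nwin,
            "context": CONTEXT_NAMES[present % 3],
            "mc": mc_sum[present].astype(np.int64),
            "cov": cov_sum[present].astype(np.int64),
            "level": level,
        })
        if per_sample:
            df.insert(0, "sample", label)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def metaplot(table: MethylomeTable, features: pd.DataFrame, body_bins: int = 20,
             flank: int = 2000, flank_bin: int = 100, samples=None) -> pd.DataFrame:
    """Average methylation profile across scaled feature bodies plus flanks.

    Bins 0..19 are the 5' flank (fixed ``flank_bin``-bp pieces), 20..39 the
    body (fractional 1/``body_bins`` pieces), 40..59 the 3' flank.  Features
    on the minus strand are orientation-flipped so bin 0 is always the distal
    5' end.  Bin values pool reads across all features.
    """
    if len(features) == 0:
        raise ValueError("empty feature set")
    if (features["strand"] == ".").any() or features["strand"].isna().any():
        raise ValueError("metaplot requires stranded features")
    nflank = flank // flank_bin
    nbins = 2 * nflank + body_bins
    mc, cov = table.pooled_counts(samples)
    pos = table.sites["pos"].to_numpy()
    ctx = table.sites["context"].to_numpy()
    slices = table._chrom_slices()
    mc_bins = np.zeros((nbins, 3))
    cov_bins = np.zeros((nbins, 3))
    for _, f in features.iterrows():
        if f["chrom"] not in slices:
            continue
        lo, hi = slices[f["chrom"]]
        s, e = int(f["start"]), int(f["end"])
        a = lo + np.searchsorted(pos[lo:hi], s - flank, side="left")
        b = lo + np.searchsorted(pos[lo:hi], e + flank, side="left")
        if a == b:
            continue
        p = pos[a:b]
        rel = np.empty(len(p), dtype=np.int64)
        up = p < s
        down = p >= e
        body = ~up & ~down
        rel[up] = (p[up] - (s - flank)) // flank_bin
        rel[body] = nflank + np.minimum(
            ((p[body] - s) * body_bins) // max(e - s, 1), body_bins - 1
        )
        rel[down] = nflank + body_bins + np.minimum(
            (p[down] - e) // flank_bin, nflank - 1
        )
        if f["strand"] == "-":
            rel = nbins - 1 - rel
        np.add.at(mc_bins, (rel, ctx[a:b]), mc[a:b])
        np.add.at(cov_bins, (rel, ctx[a:b]), cov[a:b])
    with np.errstate(invalid="ignore", divide="ignore"):
        level = mc_bins / cov_bins
    records = []
    for b in range(nbins):
        zone = "upstream" if b < nflank else ("body" if b < nflank + body_bins else "downstream")
        for c in range(3):
            records.append({
                "bin": b, "zone": zone, "context": CONTEXT_NAMES[c],
                "mc": int(mc_bins[b, c]), "cov": int(cov_bins[b, c]),
                "level": level[b, c],
            })
    return pd.DataFrame(records)


def subcontext_summary(table: MethylomeTable, samples=None,
                       per_chrom: bool = False) -> pd.DataFrame:
    """Pooled weighted level per trinucleotide subcontext.

    Truncated-trinucleotide sites (chromosome ends) are excluded.
    """
    if not table.sample_ids:
        raise ValueError("empty methylome table: no samples")
    mc, cov = table.pooled_counts(samples)
    sites = table.sites
    keep = ~sites["truncated"].to_numpy()
    df = pd.DataFrame({
        "tri": sites["tri"].to_numpy()[keep],
        "context": CONTEXT_NAMES[sites["context"].to_numpy()[keep]],
        "mc": mc[keep],
        "cov": cov[keep],
    })
    if per_chrom:
        df["chrom"] = sites["chrom"].to_numpy()[keep]
        grouped = df.groupby(["chrom", "context", "tri"], observed=True)[["mc", "cov"]].sum()
    else:
        grouped = df.groupby(["context", "tri"], observed=True)[["mc", "cov"]].sum()
    grouped = grouped.reset_index()
    with np.errstate(invalid="ignore", divide="ignore"):
        grouped["level"] = grouped["mc"] / grouped["cov"]
    return grouped
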