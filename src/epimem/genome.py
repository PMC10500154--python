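"""Synthetic genome generation: random sequences plus typed, placed features.

The genome stand-in has uniform base composition, non-overlapping features of
each type (gene, repetitive element, pseudogene) placed uniformly at random,
and one chloroplast contig that downstream stages treat as the unmethylated
bisulfite-conversion control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import stable_stream
from .scenario import ScenarioConfig

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C, _G = ord("C"), ord("G")

FEATURE_TYPES = ("gene", "dispersed_repeat", "pseudogene")


class FeaturePlacementError(RuntimeError):
    pass


@dataclass
class GenomeModel:
    """Chromosome sequences plus a typed feature table.

    ``features`` columns: feature_id, chrom, start, end (0-based half-open),
    strand, type (one of gene / dispersed_repeat / pseudogene).
    """

    sequences: dict[str, str]
    features: pd.DataFrame
    chloroplast: str | None = None

    def __post_init__(self):
        for _, f in self.features.iterrows():
            L = len(self.sequences.get(f["chrom"], ""))
            if f["chrom"] not in self.sequences or f["end"] > L or f["start"] < 0:
                raise ValueError(f"feature {f['feature_id']} outside sequence bounds")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def features_of_type(self, ftype: str) -> pd.DataFrame:
        return self.features[self.features["type"] == ftype].reset_index(drop=True)

    @property
    def genes(self) -> pd.DataFrame:
        return self.features_of_type("gene")


def _place_features(rng, length, n, len_range, occupied_starts, occupied_ends,
                    chrom_name, max_tries=200):
    """Place n non-overlapping intervals uniformly; returns (starts, ends) sorted."""
    starts, ends = list(occupied_starts), list(occupied_ends)
    out = []
    for _ in range(n):
        for attempt in range(max_tries):
            flen = int(rng.integers(len_range[0], len_range[1] + 1))
            if flen >= length:
                continue
            s = int(rng.integers(0, length - flen))
            e = s + flen
            if all(e <= os or s >= oe for os, oe in zip(starts, ends)):
                starts.append(s)
                ends.append(e)
                out.append((s, e))
                break
        else:
            raise FeaturePlacementError(
                f"could not place feature on crowded chromosome {chrom_name!r} "
                f"after {max_tries} tries"
            )
    out.sort()
    return out


def generate_genome(scenario: ScenarioConfig) -> GenomeModel:
    """Random genome with placed features; deterministic given the master seed."""
    scenario.validate()
    rng = stable_stream(scenario.seed, "genome")
    sequences: dict[str, str] = {}
    rows = []
    counters = dict.fromkeys(FEATURE_TYPES, 0)
    for chrom, length in scenario.chrom_lengths.items():
        seq = _BASES[rng.integers(0, 4, size=length)]
        sequences[chrom] = seq.tobytes().decode()
        if chrom == scenario.chloroplast:
            continue  # the control contig carries no annotated features
        specs = [
            ("gene", scenario.genes_per_chrom, scenario.gene_len),
            ("dispersed_repeat", scenario.res_per_chrom, scenario.re_len),
            ("pseudogene", scenario.pseudogenes_per_chrom, scenario.pseudogene_len),
        ]
        for ftype, n, len_range in specs:
            # same-type features never overlap; different types may
            placed = _place_features(rng, length, n, len_range, [], [], chrom)
            for s, e in placed:
                counters[ftype] += 1
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append(
                    (f"{ftype[:4]}_{counters[ftype]:05d}", chrom, s, e, strand, ftype)
                )
    features = pd.DataFrame(
        rows, columns=["feature_id", "chrom", "start", "end", "strand", "type"]
    )
    return GenomeModel(sequences=sequences, features=features,
                       chloroplast=scenario.chloroplast)


# ----------------------------------------------------------------------
# cytosine enumeration

CONTEXT_CODES = {"CGN": 0, "CHG": 1, "CHH": 2}
CONTEXT_NAMES = np.array(["CGN", "CHG", "CHH"])

_TRI_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b
_N = ord("N")


def _tri_strings(second: np.ndarray, third: np.ndarray) -> np.ndarray:
    """Trinucleotide strings 'C<second><third>' from byte arrays."""
    tri = np.empty((len(second), 3), dtype=np.uint8)
    tri[:, 0] = _C
    tri[:, 1] = second
    tri[:, 2] = third
    return tri.reshape(-1).view(f"S{3}").astype("U3")


def _chrom_sites(chrom: str, seq: str) -> pd.DataFrame:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    L = len(arr)
    frames = []

    # plus strand: cytosines read left to right
    pos = np.flatnonzero(arr == _C)
    if len(pos):
        nxt = np.where(pos + 1 < L, arr[np.minimum(pos + 1, L - 1)], _N)
        nxt2 = np.where(pos + 2 < L, arr[np.minimum(pos + 2, L - 1)], _N)
        ctx = np.where(nxt == _G, 0, np.where(nxt2 == _G, 1, 2)).astype(np.int8)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos.astype(np.int64), "strand": "+",
            "tri": _tri_strings(nxt, nxt2), "context": ctx,
            "truncated": pos + 2 >= L,
        }))

    # minus strand: guanines on the reference are cytosines on the reverse strand
    pos = np.flatnonzero(arr == _G)
    if len(pos):
        cnxt = _COMP[np.where(pos - 1 >= 0, arr[np.maximum(pos - 1, 0)], _N)]
        cnxt2 = _COMP[np.where(pos - 2 >= 0, arr[np.maximum(pos - 2, 0)], _N)]
        ctx = np.where(cnxt == _G, 0, np.where(cnxt2 == _G, 1, 2)).astype(np.int8)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos.astype(np.int64), "strand": "-",
            "tri": _tri_strings(cnxt, cnxt2), "context": ctx,
            "truncated": pos - 2 < 0,
        }))

    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "tri", "context", "truncated"])
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["pos", "strand"], kind="stable").reset_index(drop=True)


def cytosine_sites(sequences: dict[str, str]) -> pd.DataFrame:
    """Every cytosine on both strands, with trinucleotide and context class.

    Trinucleotides are read 5'->3' on the cytosine's own strand; positions are
    0-based reference coordinates.  Sites whose trinucleotide runs off the
    chromosome end are flagged ``truncated`` (missing bases are treated as
    non-G for context classification and written as N).
    """
    frames = [_chrom_sites(chrom, seq) for chrom, seq in sequences.items()]
    df = pd.concat(frames, ignore_index=True)
    df["tri"] = df["tri"].astype("category")
    df["strand"] = df["strand"].astype("category")
    df["chrom"] = pd.Categorical(df["chrom"], categories=list(sequences))
    return df
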