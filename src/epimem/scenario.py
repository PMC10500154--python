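"""Scenario configuration for the synthetic methylome/transcriptome world.

A :class:`ScenarioConfig` pins down everything the generator needs: genome
geometry, feature counts, per-context baseline methylation, feature-shape
parameters, the warm-treatment effect (global shifts plus planted DMRs and
the clustered peak fixture), sequencing depth and bisulfite non-conversion,
expression parameters, and the group design.  Every generator output is a
pure function of (scenario, master seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from ._util import stable_stream

CONTEXTS = ("CGN", "CHG", "CHH")

#: window size (bp) used for peak fixtures and landscape analyses
DEFAULT_WINDOW = 50_000


@dataclass
class PlantedDMR:
    """A truth interval receiving an extra methylation shift in the warm condition."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    context: str = "CHG"
    shift: float = 0.4

    def validate(self, chrom_lengths: dict[str, int]) -> None:
        if self.chrom not in chrom_lengths:
            raise ValueError(f"planted DMR on unknown chromosome {self.chrom!r}")
        if not (0 <= self.start < self.end <= chrom_lengths[self.chrom]):
            raise ValueError(
                f"planted DMR {self.chrom}:{self.start}-{self.end} outside chromosome bounds"
            )
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")


@dataclass
class PeakFixture:
    """Windows that receive clustered planted hyper-CHG DMRs in every group.

    Each designated 50-kb window gets ``clusters_per_window`` short intervals,
    spaced > merge distance apart, so DMR calling yields at least the
    peak-count floor of DMRs per window in each group.
    """

    windows: list[tuple[str, int]] = field(default_factory=list)
    clusters_per_window: int = 12
    cluster_len: int = 400
    cluster_spacing: int = 3500
    shift: float = 0.4
    context: str = "CHG"
    window_size: int = DEFAULT_WINDOW

    def validate(self, chrom_lengths: dict[str, int]) -> None:
        if len(set(map(tuple, self.windows))) != len(self.windows):
            raise ValueError("peak fixture windows must be distinct")
        for chrom, idx in self.windows:
            if chrom not in chrom_lengths:
                raise ValueError(f"fixture window on unknown chromosome {chrom!r}")
            if idx < 0 or idx * self.window_size >= chrom_lengths[chrom]:
                raise ValueError(f"fixture window {chrom}:{idx} beyond chromosome end")
        span = 2000 + self.clusters_per_window * self.cluster_spacing
        if span > self.window_size:
            raise ValueError("fixture clusters do not fit inside one window")

    def intervals(self) -> list[PlantedDMR]:
        """Expand the fixture into concrete planted intervals."""
        out = []
        for chrom, idx in self.windows:
            base = idx * self.window_size + 2000
            for k in range(self.clusters_per_window):
                s = base + k * self.cluster_spacing
                out.append(PlantedDMR(chrom, s, s + self.cluster_len, self.context, self.shift))
        return out


@dataclass
class ScenarioConfig:
    """Full parameterization of one synthetic study."""

    # genome geometry
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 300_000 for i in range(1, 8)} | {"chrC": 30_000}
    )
    chloroplast: str = "chrC"
    genes_per_chrom: int = 60
    res_per_chrom: int = 50
    pseudogenes_per_chrom: int = 15
    gene_len: tuple[int, int] = (800, 2000)
    re_len: tuple[int, int] = (300, 1500)
    pseudogene_len: tuple[int, int] = (600, 1200)

    # truth methylation landscape
    base_levels: dict[str, float] = field(
        default_factory=lambda: {"CGN": 0.55, "CHG": 0.32, "CHH": 0.06}
    )
    subcontext_multipliers: dict[str, float] = field(default_factory=lambda: {"CCG": 0.8})
    gene_body_mult: float = 0.6
    gene_dip_mult: float = 0.2
    gene_dip_ramp: int = 300
    re_plateau_mult: float = 1.6
    pseudogene_edge_mult: float = 1.5
    pseudogene_body_mult: float = 1.1
    pseudogene_edge_len: int = 150
    normalize_shapes: bool = True

    # warm-treatment effect
    global_shift: dict[str, float] = field(
        default_factory=lambda: {"CGN": 0.04, "CHG": 0.05, "CHH": 0.01}
    )
    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    peak_fixture: PeakFixture | None = None
    group_effect_scale: dict[str, float] = field(default_factory=dict)

    # sequencing
    coverage_mean: float = 30.0
    coverage_shape: float = 10.0  # NB shape; var = mu + mu^2/shape
    epsilon: float = 0.005  # non-conversion (false-methylation) rate
    epsilon_under: float = 0.0  # under-conversion of methylated cytosines

    # expression
    expr_mean: float = 150.0
    expr_dispersion: float = 0.05
    repression_factor: float = 0.5
    de_fraction: float = 0.2
    dedmg_coupling: float = 0.6
    lfc_range: tuple[float, float] = (1.0, 2.0)

    # design
    groups: tuple[str, ...] = ("eco1", "eco2", "eco3", "eco4")
    conditions: tuple[str, ...] = ("18C", "28C")
    replicates: int = 3

    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.chloroplast not in self.chrom_lengths:
            raise ValueError("chloroplast contig missing from chrom_lengths")
        for ctx in CONTEXTS:
            p = self.base_levels[ctx]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"base level for {ctx} outside [0,1]: {p}")
        for tri, m in self.subcontext_multipliers.items():
            if m < 0 or not tri.startswith("C") or len(tri) != 3:
                raise ValueError(f"bad subcontext multiplier {tri}={m}")
        for ctx, s in self.global_shift.items():
            if ctx not in CONTEXTS:
                raise ValueError(f"global shift for unknown context {ctx!r}")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per group x condition")
        if not 0.0 <= self.epsilon <= 0.05:
            raise ValueError("epsilon outside [0, 0.05]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        for dmr in self.planted_dmrs:
            dmr.validate(self.chrom_lengths)
        if self.peak_fixture is not None:
            self.peak_fixture.validate(self.chrom_lengths)

    # ------------------------------------------------------------------
    def all_planted(self) -> list[PlantedDMR]:
        """Scattered planted DMRs plus the expanded peak fixture."""
        out = list(self.planted_dmrs)
        if self.peak_fixture is not None:
            out += self.peak_fixture.intervals()
        return out

    def samples(self):
        """The full (sample_id, group, condition, replicate) design."""
        out = []
        for g in self.groups:
            for c in self.conditions:
                for r in range(1, self.replicates + 1):
                    out.append((f"{g}_{c}_r{r}", g, c, r))
        return out

    # ------------------------------------------------------------------
    def to_json(self, path=None) -> str:
        d = dataclasses.asdict(self)
        text = json.dumps(d, indent=2, default=list)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str) -> "ScenarioConfig":
        if "\n" not in source and not source.lstrip().startswith("{"):
            with open(source) as fh:
                source = fh.read()
        d = json.loads(source)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        if "planted_dmrs" in d:
            d["planted_dmrs"] = [PlantedDMR(**x) for x in d["planted_dmrs"]]
        if d.get("peak_fixture") is not None:
            pf = d["peak_fixture"]
            pf["windows"] = [tuple(w) for w in pf["windows"]]
            d["peak_fixture"] = PeakFixture(**pf)
        for key in ("gene_len", "re_len", "pseudogene_len", "lfc_range", "groups", "conditions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ----------------------------------------------------------------------
# preset scenarios


def baseline_scenario(seed: int = 0) -> ScenarioConfig:
    """The 18C-only world used for global-level recovery."""
    return ScenarioConfig(seed=seed)


def warm_shift_scenario(seed: int = 0) -> ScenarioConfig:
    """Global per-context warm hypermethylation only (no planted regions)."""
    return ScenarioConfig(seed=seed)


def default_peak_windows() -> list[tuple[str, int]]:
    # two windows on each of four autosomes, mirroring a shared-peak layout
    return [
        ("chr2", 1), ("chr2", 4),
        ("chr3", 0), ("chr3", 3),
        ("chr5", 1), ("chr5", 4),
        ("chr6", 2), ("chr6", 5),
    ]


def peak_fixture_scenario(seed: int = 0, n_scattered: int = 40) -> ScenarioConfig:
    """Planted-DMR world: clustered fixture windows plus scattered DMRs.

    Global shifts are zeroed so that differential signal is confined to the
    planted intervals; with a genome-wide shift every cytosine is weakly
    differential and region-level clustering is no longer identifiable.
    """
    sc = ScenarioConfig(
        seed=seed,
        global_shift={"CGN": 0.0, "CHG": 0.0, "CHH": 0.0},
        peak_fixture=PeakFixture(windows=default_peak_windows()),
    )
    rng = stable_stream(seed, "scattered-dmrs")
    autosomes = [c for c in sc.chrom_lengths if c != sc.chloroplast]
    fixture_iv = {(d.chrom, d.start // DEFAULT_WINDOW) for d in sc.peak_fixture.intervals()}
    planted: list[PlantedDMR] = []
    while len(planted) < n_scattered:
        chrom = autosomes[rng.integers(len(autosomes))]
        start = int(rng.integers(0, sc.chrom_lengths[chrom] - 600))
        if (chrom, start // DEFAULT_WINDOW) in fixture_iv:
            continue  # keep scattered DMRs out of fixture windows
        if any(p.chrom == chrom and abs(p.start - start) < 2000 for p in planted):
            continue
        planted.append(PlantedDMR(chrom, start, start + 600, "CHG", 0.4))
    sc.planted_dmrs = sorted(planted, key=lambda p: (p.chrom, p.start))
    sc.validate()
    return sc
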