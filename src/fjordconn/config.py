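"""Configuration objects for synthetic scenarios, drifter seeding and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a synthetic fjord-chain scenario.

    The scenario emulates a sequence of fjords strung along a coastal boundary
    current, with a monotone along-path temperature gradient broken by one
    sharp step (a bioclimatic-subzone barrier), and two marker-gene ASV tables
    (16S prokaryotes, 18S picoeukaryotes) whose compositional divergence is
    planted as a function of hydrodynamic distance and temperature difference.

    Parameters
    ----------
    grid_nx, grid_ny : int
        Grid cell counts along and across the channel.
    cell_size : float
        Grid spacing in km.
    n_fjords : int
        Number of fjords placed downstream along the current path.
    current_speed : float
        Peak along-shore current speed, km day⁻¹.
    meander_amplitude : float
        Dimensionless amplitude of cross-shore meandering (and fjord
        exchange flow), as a fraction of ``current_speed``. Must be ≤ 2 so
        that all speeds stay below twice the nominal current speed.
    temp_range : tuple of float
        (cold end, warm end) surface temperature in °C. The warm end sits at
        the upstream (temperate) end of the path.
    barrier_position : float
        Along-path fraction in [0, 1] at which the temperature step sits.
    barrier_step : float
        Size of the inter-subzone temperature step, °C.
    n_asv_pro, n_asv_euk : int
        Number of ASVs per marker table.
    decay_rate_pro, decay_rate_euk : float
        Planted compositional divergence (CLR variance per coordinate) per
        unit hydrodynamic distance.
    temp_sensitivity_pro, temp_sensitivity_euk : float
        Planted divergence per °C of temperature difference. Prokaryotes are
        given roughly twice the eukaryotic sensitivity by default.
    seq_depth : int
        Reads per sample (multinomial total).
    richness_cold_penalty_pro : float
        Fraction of prokaryotic ASVs excluded (occupancy forced to zero) at
        the coldest site; intermediate sites are penalized proportionally to
        their coldness, with nested exclusion sets.
    seed : int
        RNG seed; identical configs reproduce identical scenarios.
    """

    grid_nx: int = 96
    grid_ny: int = 24
    cell_size: float = 4.0
    n_fjords: int = 21
    current_speed: float = 10.0
    meander_amplitude: float = 0.3
    temp_range: tuple[float, float] = (-1.0, 12.0)
    barrier_position: float = 0.5
    barrier_step: float = 3.0
    n_asv_pro: int = 300
    n_asv_euk: int = 300
    decay_rate_pro: float = 2.5
    decay_rate_euk: float = 2.5
    temp_sensitivity_pro: float = 0.4
    temp_sensitivity_euk: float = 0.2
    seq_depth: int = 20000
    richness_cold_penalty_pro: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(grid_nx=self.grid_nx, grid_ny=self.grid_ny,
                      n_fjords=self.n_fjords, n_asv_pro=self.n_asv_pro,
                      n_asv_euk=self.n_asv_euk)
        for name, v in counts.items():
            if v < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")
        if self.grid_nx < 16 or self.grid_ny < 16:
            # velocity-field generation needs room for coast + open water
            if min(self.grid_nx, self.grid_ny) < 16:
                raise ConfigError("grid must be at least 16x16 cells")
        if self.seq_depth < 100:
            raise ConfigError("seq_depth must be >= 100")
        if not 0.0 <= self.barrier_position <= 1.0:
            raise ConfigError("barrier_position must lie in [0, 1]")
        for name in ("decay_rate_pro", "decay_rate_euk",
                     "temp_sensitivity_pro", "temp_sensitivity_euk"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.richness_cold_penalty_pro <= 1.0:
            raise ConfigError("richness_cold_penalty_pro must lie in [0, 1]")
        if self.meander_amplitude < 0 or self.meander_amplitude > 2:
            raise ConfigError("meander_amplitude must lie in [0, 2]")
        cold, warm = self.temp_range
        if warm <= cold:
            raise ConfigError("temp_range must be (cold end, warm end)")
        if warm - cold < self.barrier_step:
            raise ConfigError("barrier_step exceeds the total temperature range")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SeedingSchedule:
    """Cohort seeding plan for Lagrangian drifters.

    Mirrors the release protocol of basin-scale connectivity studies: cohorts
    released at a fixed interval, uniformly over a small square of grid cells
    centred on the site, each tracked for a fixed lifetime.
    """

    cohort_interval: float = 10.0   # days between cohort releases
    floats_per_cohort: int = 50
    seeding_window: int = 3         # side length in grid cells
    lifetime: float = 365.0         # days each drifter is tracked
    n_cohorts: int = 6

    def __post_init__(self) -> None:
        if self.cohort_interval < 1:
            raise ConfigError("cohort_interval must be >= 1 day")
        if self.floats_per_cohort < 1:
            raise ConfigError("floats_per_cohort must be >= 1")
        if self.lifetime < self.cohort_interval:
            raise ConfigError("lifetime must be >= cohort_interval")
        if self.seeding_window < 1 or self.seeding_window % 2 == 0:
            raise ConfigError("seeding_window must be a positive odd cell count")
        if self.n_cohorts < 1:
            raise ConfigError("n_cohorts must be >= 1")

    @property
    def release_times(self) -> list[float]:
        return [k * self.cohort_interval for k in range(self.n_cohorts)]

    @property
    def span(self) -> float:
        """Total simulated days needed to track every cohort to its lifetime."""
        return (self.n_cohorts - 1) * self.cohort_interval + self.lifetime

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_AGE_BINS: tuple[tuple[float, float], ...] = (
    (0.0, 30.0), (0.0, 90.0), (0.0, 180.0), (0.0, 365.0),
)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Exactly one of ``scenario`` (synthetic mode) or the real-input paths
    (``asv_16s_path`` …) must be set.
    """

    scenario: Optional[ScenarioConfig] = None
    asv_16s_path: Optional[str] = None
    asv_18s_path: Optional[str] = None
    metadata_path: Optional[str] = None
    velocity_path: Optional[str] = None
    trophic_path: Optional[str] = None

    schedule: SeedingSchedule = field(default_factory=SeedingSchedule)
    age_bins: Sequence[tuple[float, float]] = DEFAULT_AGE_BINS
    window_size: int = 15
    dt: float = 0.25

    n_perm: int = 999
    alpha: float = 0.05
    perm_max: int = 200
    n_boot: int = 100

    seed: int = 0
    output_dir: str = "fjordconn_results"

    def __post_init__(self) -> None:
        real = [self.asv_16s_path, self.asv_18s_path, self.metadata_path]
        has_real = any(p is not None for p in real)
        if self.scenario is not None and has_real:
            raise ConfigError(
                "set either a synthetic scenario or real input paths, not both")
        if self.scenario is None and not all(p is not None for p in real):
            raise ConfigError(
                "real mode needs asv_16s_path, asv_18s_path and metadata_path")
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ConfigError("window_size must be a positive odd cell count")
        if self.n_perm < 99:
            raise ConfigError("n_perm must be >= 99")
        for lo, hi in self.age_bins:
            if hi <= lo:
                raise ConfigError(f"empty age bin ({lo}, {hi}]")

    @property
    def synthetic(self) -> bool:
        return self.scenario is not None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["scenario"] = self.scenario.to_dict() if self.scenario else None
        d["schedule"] = self.schedule.to_dict()
        d["age_bins"] = [list(b) for b in self.age_bins]
        return d


def pipeline_config_from_yaml(path: str | Path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    scenario = raw.pop("scenario", None)
    schedule = raw.pop("schedule", None)
    bins = raw.pop("age_bins", None)
    kwargs = dict(raw)
    if scenario is not None:
        if "temp_range" in scenario:
            scenario["temp_range"] = tuple(scenario["temp_range"])
        kwargs["scenario"] = ScenarioConfig(**scenario)
    if schedule is not None:
        kwargs["schedule"] = SeedingSchedule(**schedule)
    if bins is not None:
        kwargs["age_bins"] = [tuple(b) for b in bins]
    return PipelineConfig(**kwargs)
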