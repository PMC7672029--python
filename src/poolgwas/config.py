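"""Configuration objects shared across the pipeline.

All tunable constants of the analysis live here: the SNP-selection
thresholds, the association-analysis constants (family-wise alpha, the
r >= 0.3 collinearity threshold, the QQ sample size) and the synthetic-panel
parameters. Defaults mirror the study conditions of the hemp accession panel
the pipeline targets: 123 pooled-DNA accessions (8 plants per pool), three
European field locations with three replicate plots each, a structured
population, and high broad-sense heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

TRAITS = ("FL_Begin", "FL_Full", "VEG", "Sex_det")

#: (mean, sd) of the simulated trait scales. Flowering traits are in degree
#: days (base 1 degree C); the full-flowering *gap* above FL_Begin has its own
#: scale; the sex liability is dimensionless (cut at +/- 1 sd into {1,2,3}).
DEFAULT_TRAIT_SCALES = {
    "FL_Begin": (650.0, 130.0),
    "FL_Full_gap": (160.0, 45.0),
    "Sex_det": (0.0, 1.0),
}


@dataclass(frozen=True)
class PlantedQTL:
    """A causal marker planted by the simulator.

    ``marker_id`` may be left ``None``, in which case the simulator picks a
    well-behaved marker (polymorphic, on its own scaffold) deterministically
    from its RNG stream and records the choice in the truth record.
    """

    trait: str
    variance_fraction: float
    shared_across_locations: bool = True
    marker_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}; expected one of {TRAITS}")
        if not 0.0 < self.variance_fraction < 1.0:
            raise ValueError("variance_fraction must lie in (0, 1)")


@dataclass
class QCThresholds:
    """SNP-selection thresholds applied in order: call rate, biallelic sum,
    minor-allele frequency, major-allele-frequency standard deviation."""

    call_rate_min: float = 1.0
    maf_min: float = 0.02
    biallelic_sum_min: float = 0.95
    major_freq_sd_min: float = 0.1

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class AnalysisConfig:
    """Constants of the association and MultiQTL analysis."""

    alpha: float = 0.05
    r_threshold: float = 0.3
    meff_window: int = 200
    qq_sample_size: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.r_threshold < 1.0:
            raise ValueError("r_threshold must lie in (0, 1)")
        if self.meff_window < 1:
            raise ValueError("meff_window must be >= 1")


@dataclass
class SimConfig:
    """Parameters of the synthetic pooled-frequency panel.

    ``read_depth=None`` means no sequencing sampling noise (infinite depth);
    otherwise per-site depths are Poisson(read_depth) and observed
    frequencies are binomial draws around the pooled truth.
    ``heritability`` may be a single fraction applied to every trait or a
    per-trait mapping; it is the narrow-sense heritability of the
    accession-by-location means that enter the association analysis.
    """

    n_accessions: int = 123
    n_subpops: int = 3
    fst: float = 0.15
    #: drift of accession allele frequencies around their subpopulation
    #: frequency (each accession is a distinct cultivar/landrace, i.e. a
    #: differentiated population in its own right, not 8 plants drawn from a
    #: panmictic subpopulation); Balding-Nichols within subpopulation
    accession_fst: float = 0.2
    n_scaffolds: int = 100
    markers_per_scaffold: tuple[int, int] = (4, 10)
    ld_block_length: int = 10_000
    marker_spacing: int = 400
    mutation_prob: float = 0.05
    pool_size: int = 8
    read_depth: Optional[float] = 30.0
    planted_qtls: list[PlantedQTL] = field(default_factory=list)
    heritability: dict[str, float] | float = 0.93
    env_genetic_correlation: float = 0.8
    n_locations: int = 3
    n_plots: int = 3
    trait_scales: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_SCALES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must lie in [0, 1), got {self.fst}")
        if not 0.0 <= self.accession_fst < 1.0:
            raise ValueError(f"accession_fst must lie in [0, 1), got {self.accession_fst}")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        for name in ("n_accessions", "n_subpops", "n_scaffolds",
                     "ld_block_length", "n_locations", "n_plots"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.markers_per_scaffold
        if not 1 <= lo <= hi:
            raise ValueError("markers_per_scaffold must be a range 1 <= lo <= hi")
        if not 0.0 <= self.env_genetic_correlation <= 1.0:
            raise ValueError("env_genetic_correlation must lie in [0, 1]")
        if isinstance(self.heritability, (int, float)):
            self.heritability = {t: float(self.heritability) for t in TRAITS}
        for t, h2 in self.heritability.items():
            if not 0.0 <= h2 <= 1.0:
                raise ValueError(f"heritability[{t}] must lie in [0, 1]")
        self.planted_qtls = [
            q if isinstance(q, PlantedQTL) else PlantedQTL(**q)
            for q in self.planted_qtls
        ]
        # planted variance fractions must leave room for the polygenic term
        for t in TRAITS:
            tot = sum(q.variance_fraction for q in self.planted_qtls if q.trait == t)
            if tot >= self.heritability.get(t, 0.0) and tot > 0:
                raise ValueError(
                    f"planted variance fractions for {t} sum to {tot}, "
                    f"which must stay below heritability {self.heritability.get(t)}"
                )

    def h2(self, trait: str) -> float:
        return self.heritability[trait]  # type: ignore[index]


def load_config(path: str) -> tuple[SimConfig, AnalysisConfig, QCThresholds]:
    """Parse a YAML config file with optional ``simulation``, ``analysis``
    and ``qc`` sections into the three config objects (missing sections get
    defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = dict(raw.get("simulation", {}))
    if "markers_per_scaffold" in sim_raw:
        sim_raw["markers_per_scaffold"] = tuple(sim_raw["markers_per_scaffold"])
    if "trait_scales" in sim_raw:
        sim_raw["trait_scales"] = {
            k: tuple(v) for k, v in sim_raw["trait_scales"].items()
        }
    sim = SimConfig(**sim_raw)
    ana = AnalysisConfig(**raw.get("analysis", {}))
    qc = QCThresholds(**raw.get("qc", {}))
    return sim, ana, qc
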