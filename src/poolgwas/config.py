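"""Configuration objects for the simulator and the analysis pipeline.

The defaults encode the study design this package emulates: a screening
cohort of 104 lupus patients split into a high-IFN/autoantibody-positive
group and a low-IFN/antibody-negative group across four ancestral
backgrounds, pooled four at a time onto arrays with 8 (or 12) probes per
SNP; and an independent validation cohort of 538 cases and 522 controls.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

ANTIBODIES = ("ro", "la", "sm", "rnp", "dsdna")

IFN_SCENARIOS = ("independent", "antibody_mediated", "cooperative")


class ConfigError(ValueError):
    """Raised when a configuration violates a design invariant."""


@dataclass(frozen=True)
class AncestryArm:
    """Per-ancestry screening-arm sizes (high-IFN group vs low-IFN group)."""

    name: str
    n_high: int
    n_low: int


#: High/low group sizes per self-reported ancestry in the screening cohort.
DEFAULT_SCREEN_DESIGN: tuple[AncestryArm, ...] = (
    AncestryArm("Asian", 8, 8),
    AncestryArm("African", 12, 8),
    AncestryArm("European", 12, 24),
    AncestryArm("Hispanic", 12, 20),
)

#: Validation-cohort case counts per ancestry.
DEFAULT_VALIDATION_CASES: Mapping[str, int] = {
    "African": 280,
    "European": 173,
    "Hispanic": 85,
}

#: Validation-cohort control counts per ancestry.
DEFAULT_VALIDATION_CONTROLS: Mapping[str, int] = {
    "African": 361,
    "European": 161,
}

#: Baseline autoantibody prevalences among cases (typical SLE cohort values).
DEFAULT_ANTIBODY_PREVALENCE: Mapping[str, float] = {
    "ro": 0.30,
    "la": 0.12,
    "sm": 0.15,
    "rnp": 0.25,
    "dsdna": 0.35,
}

#: Loadings of the shared latent factor that induces antibody co-occurrence
#: (Sm and RNP load heavily; the clinically observed Sm/RNP correlation).
DEFAULT_LATENT_LOADING: Mapping[str, float] = {
    "ro": 0.3,
    "la": 0.3,
    "sm": 1.0,
    "rnp": 1.0,
    "dsdna": 0.3,
}


@dataclass(frozen=True)
class Spike:
    """A planted allele-frequency difference between screening groups.

    ``delta`` is added to the high group's A-allele frequency; ``ancestry``
    restricts the spike to one background (``None`` = every ancestry).
    """

    snp: str
    delta: float
    ancestry: str | None = None


@dataclass(frozen=True)
class Effect:
    """A planted genotype→antibody association for the validation cohort.

    ``antibody`` is a single antibody name, or a combination written
    ``"x+y"`` (both positive) / ``"x-y"`` (x positive, y negative).
    ``ancestries`` restricts the effect (``None`` = every ancestry).
    """

    snp: str
    antibody: str
    odds_ratio: float
    ancestries: tuple[str, ...] | None = None


@dataclass(frozen=True)
class IFNModel:
    """How serum IFN-α activity couples to genotype and serology.

    ``scenario`` picks one of three association patterns:

    - ``independent``: carriers of the risk allele at ``snp`` have shifted
      IFN-α regardless of serology;
    - ``antibody_mediated``: subjects positive for ``antibody`` have shifted
      IFN-α regardless of genotype;
    - ``cooperative``: the shift appears only when risk allele and antibody
      co-occur.

    Raw activity is log-normal (``log_mean``/``log_sd`` on the log scale,
    ``shift`` added to the log-mean when the scenario's indicator is on) and
    is reported as a standardized activity score against a healthy
    reference population's mean and SD.
    """

    scenario: str = "independent"
    snp: str | None = None
    antibody: str | None = None
    log_mean: float = 0.0
    log_sd: float = 0.8
    shift: float = 0.8
    ref_mean: float = 1.0
    ref_sd: float = 0.5


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic screening + validation study."""

    seed: int = 0
    n_snps: int = 100
    screen_design: tuple[AncestryArm, ...] = DEFAULT_SCREEN_DESIGN
    pool_size: int = 4
    probes_per_snp: int = 8
    intensity_scale: float = 2000.0
    intensity_noise_sd: float = 50.0
    baseline_maf_range: tuple[float, float] = (0.05, 0.5)
    spike_table: tuple[Spike, ...] = ()
    validation_cases: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_VALIDATION_CASES)
    )
    validation_controls: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_VALIDATION_CONTROLS)
    )
    effect_table: tuple[Effect, ...] = ()
    antibody_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANTIBODY_PREVALENCE)
    )
    control_antibody_prevalence: float = 0.02
    antibody_latent_loading: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LATENT_LOADING)
    )
    genotype_missing_rate: float = 0.0
    ifn_model: IFNModel = field(default_factory=IFNModel)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.pool_size < 1:
            raise ConfigError("pool_size must be >= 1")
        if self.probes_per_snp not in (8, 12):
            raise ConfigError("probes_per_snp must be 8 or 12")
        if self.n_snps < 0:
            raise ConfigError("n_snps must be nonnegative")
        for arm in self.screen_design:
            for label, n in (("high", arm.n_high), ("low", arm.n_low)):
                if n < 0:
                    raise ConfigError(f"{arm.name} {label} group size negative")
                if n % self.pool_size:
                    raise ConfigError(
                        f"{arm.name} {label} group size {n} not divisible by "
                        f"pool_size {self.pool_size}"
                    )
        lo, hi = self.baseline_maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError("baseline_maf_range must lie inside (0, 1)")
        if self.intensity_noise_sd < 0:
            raise ConfigError("intensity_noise_sd must be nonnegative")
        for name, p in self.antibody_prevalence.items():
            if name not in ANTIBODIES:
                raise ConfigError(f"unknown antibody {name!r}")
            if not (0.0 < p < 1.0):
                raise ConfigError(f"prevalence of {name} must be in (0, 1)")
        if not (0.0 < self.control_antibody_prevalence < 1.0):
            raise ConfigError("control_antibody_prevalence must be in (0, 1)")
        if not (0.0 <= self.genotype_missing_rate < 1.0):
            raise ConfigError("genotype_missing_rate must be in [0, 1)")
        for eff in self.effect_table:
            if eff.odds_ratio <= 0:
                raise ConfigError(f"odds ratio for {eff.snp} must be > 0")
        if self.ifn_model.scenario not in IFN_SCENARIOS:
            raise ConfigError(
                f"unknown IFN scenario {self.ifn_model.scenario!r}; "
                f"expected one of {IFN_SCENARIOS}"
            )

    @property
    def ancestry_names(self) -> tuple[str, ...]:
        return tuple(arm.name for arm in self.screen_design)

    def snp_ids(self) -> list[str]:
        width = max(5, len(str(self.n_snps)))
        return [f"snp{i:0{width}d}" for i in range(1, self.n_snps + 1)]

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)
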