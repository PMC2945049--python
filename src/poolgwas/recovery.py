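"""Parameter-recovery and calibration harnesses.

These run the generator and the estimators end to end under controlled
conditions: recovering a configured genotype-antibody odds ratio from
replicate validation cohorts, and calibrating the cross-ancestry Z
statistic under the intensity-noise null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Effect, SimulationConfig
from .screen import screen_all
from .simulate import (
    assign_pools,
    pool_metadata,
    simulate_constant_fraction_intensities,
    simulate_screening_cohort,
    simulate_validation_cohort,
)
from .validate import fit_logistic


@dataclass(frozen=True)
class RecoveryResult:
    """Summary of an odds-ratio recovery experiment."""

    median_or: float
    odds_ratios: tuple[float, ...]
    n_replicates: int
    n_converged: int
    n_per_cohort: int


def recover_effect_or(
    odds_ratio: float,
    cohort_sizes: dict[str, int],
    antibody: str = "la",
    maf: float = 0.3,
    prevalence: float = 0.2,
    n_replicates: int = 500,
    seed: int = 0,
) -> RecoveryResult:
    """Median recovered OR over replicate simulated validation cohorts.

    Each replicate draws a case cohort with HWE genotypes at the given
    minor-allele frequency and antibody status from a pure additive
    logistic model (per-allele log-odds = ln ``odds_ratio``, baseline
    prevalence at genotype zero = ``prevalence``; the generator's latent
    antibody-correlation factor is switched off so the fitted model matches
    the generating model), then refits the additive logistic model and
    records the recovered odds ratio.
    """
    rng = np.random.default_rng([11, seed])
    prevalences = {
        "ro": 0.3, "la": 0.12, "sm": 0.15, "rnp": 0.25, "dsdna": 0.35,
    }
    prevalences[antibody] = prevalence
    n_total = sum(cohort_sizes.values())
    ors: list[float] = []
    for _ in range(n_replicates):
        config = SimulationConfig(
            seed=int(rng.integers(2**31)),
            n_snps=1,
            validation_cases=dict(cohort_sizes),
            validation_controls={},
            baseline_maf_range=(maf, maf),
            effect_table=(Effect("snp00001", antibody, odds_ratio),),
            antibody_prevalence=prevalences,
            antibody_latent_loading={a: 0.0 for a in prevalences},
        )
        cohort = simulate_validation_cohort(config)
        fit = fit_logistic(
            cohort[f"ab_{antibody}"], cohort[["snp00001"]], name=antibody
        )
        if fit.ok and "snp00001" in fit.odds_ratios:
            ors.append(fit.odds_ratios["snp00001"][0])
    return RecoveryResult(
        median_or=float(np.median(ors)) if ors else float("nan"),
        odds_ratios=tuple(ors),
        n_replicates=n_replicates,
        n_converged=len(ors),
        n_per_cohort=n_total,
    )


def null_screen_statistics(
    n_snps: int = 2000,
    seed: int = 0,
    intensity_noise_sd: float = 50.0,
    variant: str = "text",
) -> pd.DataFrame:
    """Screen statistics under the intensity-noise-only null.

    Builds the default 26-pool screening design, fixes every pool's true
    allele-dosage fraction at 0.5 so the only pool-to-pool variation is
    probe noise, and screens ``n_snps`` SNPs. Under this null the
    cross-ancestry Z is approximately standard normal, which is the
    calibration the inverse-SD weighting targets.
    """
    config = SimulationConfig(
        seed=seed, n_snps=1, intensity_noise_sd=intensity_noise_sd
    )
    subjects = simulate_screening_cohort(config)
    pools = assign_pools(subjects, config.pool_size)
    rng = np.random.default_rng([13, seed])
    probes = simulate_constant_fraction_intensities(
        pools, n_snps, config, rng=rng, fraction=0.5
    )
    return screen_all(probes, pool_metadata(pools), variant=variant)
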