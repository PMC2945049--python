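"""Synthetic screening and validation cohorts for the pooled-GWAS pipeline.

No public data exist for the study design this package implements, so every
downstream stage is exercised against cohorts generated here: a screening
cohort of extremes-of-phenotype SLE patients pooled four at a time with
probe-level array intensities, and an individually genotyped validation
cohort with antibody serologies and serum IFN-α activity scores.

Genotypes are drawn at Hardy-Weinberg equilibrium from per-ancestry allele
frequencies; SNPs are simulated independently (no linkage disequilibrium).
"""

from __future__ import annotations

import zlib
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import ANTIBODIES, ConfigError, Effect, SimulationConfig

#: Non-genotype columns of a subject table, in output order.
META_COLUMNS = (
    "subject",
    "ancestry",
    "role",
    "group",
    "ifn_score",
    "age",
    "ab_ro",
    "ab_la",
    "ab_sm",
    "ab_rnp",
    "ab_dsdna",
)


def snp_columns(subjects: pd.DataFrame) -> list[str]:
    """Genotype columns of a subject table (everything non-meta)."""
    known = set(META_COLUMNS) | {"pool"}
    return [c for c in subjects.columns if c not in known]


def _rng_for(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible stream per simulation stage."""
    tag = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng([tag, config.seed])


def _baseline_frequencies(
    config: SimulationConfig, ancestries: Sequence[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Per-(SNP, ancestry) baseline A-allele frequency, uniform on the MAF range."""
    lo, hi = config.baseline_maf_range
    freq = rng.uniform(lo, hi, size=(config.n_snps, len(ancestries)))
    return pd.DataFrame(freq, index=config.snp_ids(), columns=list(ancestries))


def _draw_genotypes(
    freqs: np.ndarray, n_subjects: int, rng: np.random.Generator
) -> np.ndarray:
    """HWE genotypes: minor-allele counts Binomial(2, p) per subject x SNP."""
    return rng.binomial(2, freqs[np.newaxis, :], size=(n_subjects, freqs.size))


def _standardize_ifn(raw: np.ndarray, config: SimulationConfig) -> np.ndarray:
    m = config.ifn_model
    return (raw - m.ref_mean) / m.ref_sd


def simulate_screening_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate the extremes-of-phenotype screening cohort.

    Returns one row per subject with ancestry, role (``screen_high`` /
    ``screen_low``), group index (1 = high-IFN/antibody-positive,
    0 = low-IFN/antibody-negative), antibody statuses, a standardized IFN-α
    activity score, age, and HWE genotypes. High-group subjects carry at
    least one positive antibody; low-group subjects are negative for all
    five. Spiked SNPs get their frequency delta added in the high group.
    """
    config.validate()
    rng = rng if rng is not None else _rng_for(config, "screen")
    snps = config.snp_ids()
    base = _baseline_frequencies(config, config.ancestry_names, rng)

    deltas = pd.DataFrame(
        0.0, index=snps, columns=list(config.ancestry_names)
    )
    for spike in config.spike_table:
        cols = [spike.ancestry] if spike.ancestry else list(config.ancestry_names)
        deltas.loc[spike.snp, cols] += spike.delta

    rows: list[dict] = []
    geno_blocks: list[np.ndarray] = []
    sid = 0
    for arm in config.screen_design:
        for group, n in ((1, arm.n_high), (0, arm.n_low)):
            if n == 0:
                continue
            freqs = base[arm.name].to_numpy().copy()
            if group == 1:
                freqs = np.clip(freqs + deltas[arm.name].to_numpy(), 0.005, 0.995)
            geno_blocks.append(_draw_genotypes(freqs, n, rng))
            m = config.ifn_model
            # High group sits in the top IFN tertile, low group in the bottom.
            raw = np.exp(
                rng.normal(m.log_mean + (1.2 if group else -1.2), m.log_sd, n)
            )
            scores = _standardize_ifn(raw, config)
            ages = rng.normal(40.0, 12.0, n)
            if group == 1:
                ab = np.column_stack(
                    [
                        rng.random(n) < config.antibody_prevalence[a]
                        for a in ANTIBODIES
                    ]
                ).astype(float)
                none_pos = ab.sum(axis=1) == 0
                if none_pos.any():
                    prev = np.array(
                        [config.antibody_prevalence[a] for a in ANTIBODIES]
                    )
                    forced = rng.choice(
                        len(ANTIBODIES), size=none_pos.sum(), p=prev / prev.sum()
                    )
                    ab[np.flatnonzero(none_pos), forced] = 1.0
            else:
                ab = np.zeros((n, len(ANTIBODIES)))
            for i in range(n):
                sid += 1
                row = {
                    "subject": f"S{sid:04d}",
                    "ancestry": arm.name,
                    "role": "screen_high" if group else "screen_low",
                    "group": group,
                    "ifn_score": scores[i],
                    "age": ages[i],
                }
                row.update({f"ab_{a}": ab[i, j] for j, a in enumerate(ANTIBODIES)})
                rows.append(row)

    subjects = pd.DataFrame(rows, columns=list(META_COLUMNS))
    if geno_blocks:
        geno = pd.DataFrame(np.vstack(geno_blocks).astype(float), columns=snps)
        subjects = pd.concat([subjects, geno], axis=1)
    else:
        subjects = subjects.reindex(columns=list(META_COLUMNS) + snps)
    return subjects


def assign_pools(subjects: pd.DataFrame, pool_size: int = 4) -> pd.DataFrame:
    """Partition screening subjects into pools matched on ancestry and group.

    Returns one row per pool: ``pool``, ``ancestry``, ``group`` and the
    tuple of ``members``. Every (ancestry, group) stratum must be divisible
    by ``pool_size``.
    """
    screening = subjects[subjects["role"].str.startswith("screen")]
    pools: list[dict] = []
    for (ancestry, group), stratum in screening.groupby(
        ["ancestry", "group"], sort=False
    ):
        n = len(stratum)
        if n % pool_size:
            label = "high" if group else "low"
            raise ConfigError(
                f"stratum {ancestry}/{label} has {n} subjects, "
                f"not divisible by pool_size {pool_size}"
            )
        ids = stratum["subject"].tolist()
        tag = "high" if group else "low"
        for j in range(n // pool_size):
            pools.append(
                {
                    "pool": f"{ancestry}_{tag}_{j + 1:02d}",
                    "ancestry": ancestry,
                    "group": int(group),
                    "members": tuple(ids[j * pool_size : (j + 1) * pool_size]),
                }
            )
    return pd.DataFrame(pools, columns=["pool", "ancestry", "group", "members"])


def pool_metadata(pools: pd.DataFrame) -> pd.DataFrame:
    """Pool metadata table (pool, ancestry, group) without memberships."""
    return pools[["pool", "ancestry", "group"]].copy()


def simulate_probe_intensities(
    pools: pd.DataFrame,
    subjects: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-pool, per-SNP, per-probe allelic intensities.

    Each pool's true A-allele dosage fraction (pooled minor-allele count
    over ``2 * pool_size`` chromosomes) sets the expected split of a fixed
    total hybridization intensity between the A and B channels; independent
    Gaussian noise (sd ``intensity_noise_sd``, truncated at zero) is added
    per probe channel. With zero noise the relative allele signal
    A/(A+B) of every probe equals the dosage fraction exactly.
    """
    if pools.empty:
        raise ConfigError("no pools to simulate intensities for")
    rng = rng if rng is not None else _rng_for(config, "probes")
    snps = snp_columns(subjects)
    geno = subjects.set_index("subject")[snps]

    fracs = np.empty((len(pools), len(snps)))
    for p, members in enumerate(pools["members"]):
        block = geno.loc[list(members)].to_numpy(dtype=float)
        fracs[p] = block.sum(axis=0) / (2.0 * block.shape[0])

    return _intensity_table(
        fracs, pools["pool"].tolist(), snps, config, rng
    )


def _intensity_table(
    fracs: np.ndarray,
    pool_ids: Sequence[str],
    snps: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_pools, n_snps = fracs.shape
    k = config.probes_per_snp
    scale = config.intensity_scale
    shape = (n_snps, n_pools, k)
    a = scale * fracs.T[:, :, None] + rng.normal(0, config.intensity_noise_sd, shape)
    b = scale * (1.0 - fracs.T[:, :, None]) + rng.normal(
        0, config.intensity_noise_sd, shape
    )
    table = pd.DataFrame(
        {
            "snp": np.repeat(list(snps), n_pools * k),
            "pool": np.tile(np.repeat(list(pool_ids), k), n_snps),
            "probe": np.tile(np.arange(1, k + 1), n_snps * n_pools),
            "intensity_A": np.clip(a, 0.0, None).ravel(),
            "intensity_B": np.clip(b, 0.0, None).ravel(),
        }
    )
    return table


def simulate_constant_fraction_intensities(
    pools: pd.DataFrame,
    n_snps: int,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    fraction: float = 0.5,
) -> pd.DataFrame:
    """Probe table in which every pool shares one true dosage fraction.

    This is the intensity-noise-only null used to calibrate the
    cross-ancestry Z statistic: pool-to-pool variation comes solely from
    probe noise, which is the component the inverse-SD weighting models.
    """
    rng = rng if rng is not None else _rng_for(config, "null-probes")
    width = max(5, len(str(n_snps)))
    snps = [f"snp{i:0{width}d}" for i in range(1, n_snps + 1)]
    fracs = np.full((len(pools), n_snps), fraction)
    return _intensity_table(fracs, pools["pool"].tolist(), snps, config, rng)


def _parse_combination(antibody: str) -> tuple[str, str, str] | None:
    """Split "x+y" / "x-y" effect targets; None for single antibodies."""
    for sep, mode in (("+", "both_positive"), ("-", "x_positive_y_negative")):
        if sep in antibody:
            x, y = antibody.split(sep, 1)
            if x not in ANTIBODIES or y not in ANTIBODIES:
                raise ConfigError(f"unknown antibody combination {antibody!r}")
            return x, y, mode
    if antibody not in ANTIBODIES:
        raise ConfigError(f"unknown antibody {antibody!r}")
    return None


def _effect_dose(
    effects: Iterable[Effect],
    target: str,
    geno: pd.DataFrame,
    ancestry: np.ndarray,
) -> np.ndarray:
    """Sum of ln(OR) x genotype over effects aimed at ``target``."""
    dose = np.zeros(len(geno))
    for eff in effects:
        if eff.antibody != target:
            continue
        g = np.nan_to_num(geno[eff.snp].to_numpy(dtype=float))
        contrib = np.log(eff.odds_ratio) * g
        if eff.ancestries is not None:
            contrib = np.where(np.isin(ancestry, eff.ancestries), contrib, 0.0)
        dose += contrib
    return dose


def simulate_validation_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate the individually genotyped validation cohort.

    Cases and controls share per-(SNP, ancestry) allele frequencies (the
    case-control contrast is null by default); case antibody statuses come
    from logistic models whose per-allele log-odds are the logs of the
    configured effect odds ratios, on top of baseline prevalences and a
    shared latent factor inducing antibody co-occurrence. Serum IFN-α
    activity is log-normal with a location shift wired per the configured
    scenario, then standardized to an activity score.
    """
    config.validate()
    rng = rng if rng is not None else _rng_for(config, "validation")
    snps = config.snp_ids()
    ancestries = sorted(
        set(config.validation_cases) | set(config.validation_controls)
    )
    base = _baseline_frequencies(config, ancestries, rng)

    frames: list[pd.DataFrame] = []
    counters = {"case": 0, "control": 0}
    for role_key, sizes, prefix in (
        ("case", config.validation_cases, "V"),
        ("control", config.validation_controls, "C"),
    ):
        for ancestry in ancestries:
            n = int(sizes.get(ancestry, 0))
            if n == 0:
                continue
            geno = _draw_genotypes(base[ancestry].to_numpy(), n, rng).astype(float)
            if config.genotype_missing_rate > 0:
                mask = rng.random(geno.shape) < config.genotype_missing_rate
                geno[mask] = np.nan
            start = counters[role_key]
            counters[role_key] += n
            frame = pd.DataFrame(geno, columns=snps)
            frame.insert(0, "subject", [f"{prefix}{start + i + 1:04d}" for i in range(n)])
            frame.insert(1, "ancestry", ancestry)
            frame.insert(2, "role", f"validation_{role_key}")
            frames.append(frame)
    cohort = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["subject", "ancestry", "role"] + snps
    )

    is_case = (cohort["role"] == "validation_case").to_numpy()
    n_all = len(cohort)
    geno = cohort[snps]
    ancestry_arr = cohort["ancestry"].to_numpy()

    # Antibody statuses.
    latent = rng.standard_normal(n_all)
    ab = {}
    for name in ANTIBODIES:
        logit_p = np.full(n_all, logit(config.control_antibody_prevalence))
        logit_p[is_case] = (
            logit(config.antibody_prevalence[name])
            + config.antibody_latent_loading.get(name, 0.0) * latent[is_case]
        )
        logit_p += np.where(
            is_case, _effect_dose(config.effect_table, name, geno, ancestry_arr), 0.0
        )
        ab[name] = (rng.random(n_all) < expit(logit_p)).astype(float)

    # Combination effects override their two member antibodies among cases.
    for eff in config.effect_table:
        combo = _parse_combination(eff.antibody)
        if combo is None:
            continue
        x, y, mode = combo
        px, py = config.antibody_prevalence[x], config.antibody_prevalence[y]
        p0 = px * py if mode == "both_positive" else px * (1 - py)
        logit_c = logit(p0) + _effect_dose([eff], eff.antibody, geno, ancestry_arr)
        c = (rng.random(n_all) < expit(logit_c)) & is_case
        on = np.flatnonzero(c)
        ab[x][on] = 1.0
        ab[y][on] = 1.0 if mode == "both_positive" else 0.0
        # Where the combination event is off, redraw the pair conditioned on
        # the complement of the event (baseline prevalences, rejection step).
        off = np.flatnonzero(is_case & ~c)
        for _ in range(200):
            if off.size == 0:
                break
            ab[x][off] = (rng.random(off.size) < px).astype(float)
            ab[y][off] = (rng.random(off.size) < py).astype(float)
            if mode == "both_positive":
                bad = (ab[x][off] == 1) & (ab[y][off] == 1)
            else:
                bad = (ab[x][off] == 1) & (ab[y][off] == 0)
            off = off[bad]
        if off.size:  # force the complement for any stragglers
            if mode == "both_positive":
                ab[y][off] = 0.0
            else:
                ab[y][off] = 1.0

    for name in ANTIBODIES:
        cohort[f"ab_{name}"] = ab[name]

    # Serum IFN-α activity score.
    m = config.ifn_model
    ifn_snp = m.snp if m.snp is not None else (snps[0] if snps else None)
    ifn_ab = m.antibody if m.antibody is not None else "rnp"
    carrier = (
        np.nan_to_num(geno[ifn_snp].to_numpy(dtype=float)) > 0
        if ifn_snp is not None
        else np.zeros(n_all, bool)
    )
    positive = ab[ifn_ab] > 0 if ifn_ab in ab else np.zeros(n_all, bool)
    if m.scenario == "independent":
        indicator = carrier
    elif m.scenario == "antibody_mediated":
        indicator = positive
    else:  # cooperative
        indicator = carrier & positive
    indicator = indicator & is_case
    raw = np.exp(rng.normal(m.log_mean + m.shift * indicator, m.log_sd, n_all))
    cohort["ifn_score"] = _standardize_ifn(raw, config)
    cohort["age"] = np.where(
        is_case, rng.normal(40.0, 12.0, n_all), rng.normal(50.0, 12.0, n_all)
    )
    cohort["group"] = np.nan

    order = [c for c in META_COLUMNS if c in cohort.columns] + snps
    return cohort[order]


def simulate_annotations(
    snps: Sequence[str],
    rng: np.random.Generator,
    frac_near_gene: float = 0.7,
    frac_immune: float = 0.3,
    shared_gene_rate: float = 0.0,
) -> pd.DataFrame:
    """Plausible SNP annotations: coordinates, nearest gene, immune flag.

    Stands in for the expert literature/database review, which enters the
    pipeline only as a boolean annotation input.
    """
    rows = []
    prev_gene = None
    for i, snp in enumerate(snps):
        chrom = int(rng.integers(1, 23))
        pos = int(rng.integers(1, 2.4e8))
        near = rng.random() < frac_near_gene
        if near:
            if prev_gene is not None and rng.random() < shared_gene_rate:
                gene = prev_gene
            else:
                gene = f"GENE{i + 1:04d}"
            prev_gene = gene
            distance = 0 if rng.random() < 0.6 else int(rng.integers(1, 100_000))
            immune = int(rng.random() < frac_immune)
        else:
            gene, distance, immune = "", int(rng.integers(150_000, 1_000_000)), 0
        rows.append(
            {
                "snp": snp,
                "chrom": chrom,
                "pos": pos,
                "gene": gene,
                "distance_bp": distance,
                "immune_flag": immune,
            }
        )
    return pd.DataFrame(rows)
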