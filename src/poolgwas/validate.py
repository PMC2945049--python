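"""Validation-cohort statistics for candidate SNPs.

Covers genotype QC (call rate, exact Hardy-Weinberg test per ancestry),
antibody-SNP logistic screening with backward elimination and SNP-SNP
interaction checks, combination-antibody outcomes with AIC-based model
comparison, genotype-stratified serum IFN-α comparisons (Mann-Whitney),
case-control allelic chi-square tests, Bonferroni thresholds, and
principal-component ancestry adjustment.

P-values are reported unadjusted; Bonferroni thresholds are reported
alongside, never applied silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln
from statsmodels.tools.sm_exceptions import PerfectSeparationError

# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg test P, conditional on allele counts.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of all configurations no more likely
    than the observed one (the standard two-sided exact HWE test).
    Monomorphic samples return P = 1.
    """
    if min(n_het, n_hom_minor, n_hom_major) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom_minor, n_hom_major) + n_het
    if rare == 0:
        return 1.0  # monomorphic
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    keep = hom_c >= 0
    hets, hom_r, hom_c = hets[keep], hom_r[keep], hom_c[keep]
    # log P(h) up to a constant: multinomial x 2^h over allele permutations
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(hom_r + 1)
        - gammaln(hom_c + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[hets == n_het][0]
    return float(probs[probs <= observed * (1 + 1e-12)].sum())


def qc_genotypes(
    subjects: pd.DataFrame,
    snps: list[str] | None = None,
    call_rate_min: float = 0.98,
    hwe_alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-SNP QC report: call rate, per-ancestry exact HWE P, pass flag.

    Passing requires call rate strictly above ``call_rate_min`` and HWE
    P strictly above ``hwe_alpha`` in every ancestral background.
    """
    from .simulate import snp_columns

    if snps is None:
        snps = snp_columns(subjects)
    ancestries = sorted(subjects["ancestry"].unique())
    rows = []
    for snp in snps:
        g = subjects[snp]
        call_rate = float(g.notna().mean()) if len(g) else 0.0
        row: dict = {"snp": snp, "call_rate": call_rate}
        ok = call_rate > call_rate_min
        for anc in ancestries:
            ga = g[subjects["ancestry"] == anc].dropna()
            counts = ga.value_counts()
            p = hwe_exact_p(
                int(counts.get(1, 0)), int(counts.get(2, 0)), int(counts.get(0, 0))
            )
            row[f"hwe_p_{anc}"] = p
            ok = ok and p > hwe_alpha
        row["pass"] = bool(ok)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Logistic association models


@dataclass
class AssociationFit:
    """A fitted logistic model for one binary outcome."""

    outcome: str
    terms: tuple[str, ...]
    coef: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    odds_ratios: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    llf: float = float("nan")
    aic: float = float("nan")
    n: int = 0
    converged: bool = False
    flag: str | None = None

    @property
    def ok(self) -> bool:
        return self.converged and self.flag is None


def odds_ratio_ci(
    coefficient: float, se: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Wald odds ratio and CI: exp(coefficient +/- z * se)."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (
        float(np.exp(coefficient)),
        float(np.exp(coefficient - z * se)),
        float(np.exp(coefficient + z * se)),
    )


def fit_logistic(
    outcome: pd.Series, predictors: pd.DataFrame, name: str | None = None
) -> AssociationFit:
    """Maximum-likelihood logistic fit with Wald tests per term.

    Complete cases only; genotype predictors are expected in additive
    0/1/2 coding. Degenerate designs (constant predictor, single-class
    outcome) and non-convergent or separated fits come back flagged rather
    than raising, so stepwise procedures can drop them.
    """
    name = name or (outcome.name if outcome.name else "outcome")
    data = pd.concat([outcome.rename("_y"), predictors], axis=1).dropna()
    y = data["_y"].astype(float)
    X = data[list(predictors.columns)].astype(float)
    terms = tuple(predictors.columns)
    fit = AssociationFit(outcome=name, terms=terms, n=len(data))
    if len(data) == 0 or y.nunique() < 2:
        fit.flag = "single_class_outcome"
        return fit
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        fit.flag = f"constant_predictor:{','.join(constant)}"
        return fit
    design = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, PerfectSeparationError):
        fit.flag = "separation_or_singular"
        return fit
    fit.converged = bool(res.mle_retvals.get("converged", False))
    if not fit.converged:
        fit.flag = "non_convergence"
    # very large SEs are the fingerprint of quasi-separation
    if np.any(np.asarray(res.bse) > 1e3):
        fit.flag = "separation_or_singular"
        fit.converged = False
    fit.llf = float(res.llf)
    fit.aic = float(res.aic)
    for term in design.columns:
        fit.coef[term] = float(res.params[term])
        fit.se[term] = float(res.bse[term])
        fit.pvalues[term] = float(res.pvalues[term])
        if 0 < res.bse[term] <= 1e3:  # huge se = separated fit, OR meaningless
            fit.odds_ratios[term] = odds_ratio_ci(
                res.params[term], res.bse[term]
            )
    return fit


@dataclass
class StepwiseResult:
    """Final model plus the elimination history."""

    fit: AssociationFit
    eliminated: tuple[str, ...]
    interactions_kept: tuple[str, ...] = ()


def backward_stepwise(
    outcome: pd.Series,
    predictors: pd.DataFrame,
    alpha_stay: float = 0.1,
    test_interactions: bool = True,
    keep: tuple[str, ...] = (),
    name: str | None = None,
) -> StepwiseResult:
    """Backward elimination of SNP predictors at ``P > alpha_stay``.

    Iteratively refits after removing the largest-P term above the stay
    threshold. Terms listed in ``keep`` (e.g. ancestry-indicator
    covariates in joint-ancestry models) are exempt from elimination. An
    empty final model (intercept only, or kept covariates only) is a valid
    result. If two or more SNPs survive, pairwise interaction terms are
    added and subjected to the same elimination, main effects staying in
    place. Flagged fits drop their worst-behaved term and continue; if no
    fit succeeds the flagged fit is returned as-is.
    """
    terms = list(predictors.columns)
    removable = [t for t in terms if t not in keep]
    eliminated: list[str] = []
    while True:
        fit = fit_logistic(outcome, predictors[terms], name=name)
        if not removable:
            break
        if not fit.ok:
            # drop the last term and retry; degenerate designs shrink away
            victim = removable.pop()
            terms.remove(victim)
            eliminated.append(victim)
            continue
        pvals = {t: fit.pvalues[t] for t in removable}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] > alpha_stay:
            removable.remove(worst)
            terms.remove(worst)
            eliminated.append(worst)
        else:
            break
    snp_terms = [t for t in terms if t not in keep]
    if not snp_terms:
        fit = fit_logistic(outcome, predictors[terms], name=name)
        return StepwiseResult(fit=fit, eliminated=tuple(eliminated))

    interactions_kept: tuple[str, ...] = ()
    if test_interactions and len(snp_terms) >= 2:
        design = predictors[terms].copy()
        inter = [
            f"{a}:{b}"
            for i, a in enumerate(snp_terms)
            for b in snp_terms[i + 1 :]
        ]
        for nm in inter:
            a, b = nm.split(":")
            design[nm] = predictors[a] * predictors[b]
        current = list(inter)
        while current:
            trial = fit_logistic(outcome, design[terms + current], name=name)
            if not trial.ok:
                current.pop()
                continue
            pvals = {t: trial.pvalues[t] for t in current}
            worst = max(pvals, key=pvals.get)
            if pvals[worst] > alpha_stay:
                current.remove(worst)
            else:
                fit = trial
                interactions_kept = tuple(current)
                break
    return StepwiseResult(
        fit=fit, eliminated=tuple(eliminated), interactions_kept=interactions_kept
    )


def make_combination_outcome(
    ab_x: pd.Series, ab_y: pd.Series, mode: str
) -> pd.Series:
    """Derived serologic outcome from two antibody statuses.

    ``both_positive``: 1 iff x = 1 and y = 1; ``x_positive_y_negative``:
    1 iff x = 1 and y = 0. Missingness in either input propagates.
    """
    if len(ab_x) != len(ab_y):
        raise ValueError("antibody vectors must have equal length")
    if mode == "both_positive":
        out = ((ab_x == 1) & (ab_y == 1)).astype(float)
    elif mode == "x_positive_y_negative":
        out = ((ab_x == 1) & (ab_y == 0)).astype(float)
    else:
        raise ValueError(f"unknown combination mode {mode!r}")
    out[ab_x.isna() | ab_y.isna()] = np.nan
    return out


def compare_outcome_models(
    fits: list[AssociationFit], min_delta_aic: float = 2.0
) -> tuple[AssociationFit, pd.DataFrame]:
    """Pick the best-fitting outcome for a shared predictor by AIC.

    The first fit is the reference (an individual-antibody outcome); an
    alternative wins only when its AIC undercuts the reference by at least
    ``min_delta_aic`` — the operational reading of "significantly improved
    fit" for non-nested outcomes, where likelihood-ratio tests do not
    apply. Returns the chosen fit and a ranking table with delta-AIC.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ref = fits[0]
    table = pd.DataFrame(
        {
            "outcome": [f.outcome for f in fits],
            "aic": [f.aic for f in fits],
        }
    )
    table["delta_aic"] = table["aic"] - ref.aic
    table = table.sort_values("aic", kind="mergesort").reset_index(drop=True)
    best = min(fits, key=lambda f: f.aic)
    chosen = best if ref.aic - best.aic >= min_delta_aic else ref
    return chosen, table


# ---------------------------------------------------------------------------
# Serum IFN-α comparisons


def ifn_activity_score(raw: float, ref_mean: float, ref_sd: float) -> float:
    """Standardized IFN-α activity: (raw - reference mean) / reference SD."""
    if ref_sd <= 0:
        raise ValueError("reference SD must be positive")
    return (raw - ref_mean) / ref_sd


@dataclass(frozen=True)
class IFNComparison:
    """Two-group comparison of IFN-α activity scores."""

    description: str
    n_x: int
    n_y: int
    median_x: float
    iqr_x: tuple[float, float]
    median_y: float
    iqr_y: tuple[float, float]
    u_statistic: float
    pvalue: float
    method: str


def mann_whitney(
    x, y, description: str = "group comparison"
) -> IFNComparison:
    """Two-sided Mann-Whitney U comparison of two activity-score samples.

    Uses the exact enumeration distribution when the combined sample size
    is at most 20 and there are no ties, and the tie-corrected normal
    approximation (without continuity correction) otherwise — so identical
    samples give P = 1 under either path.
    """
    x = np.asarray(pd.Series(x).dropna(), dtype=float)
    y = np.asarray(pd.Series(y).dropna(), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= 20 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        method = "normal_tie_corrected"
    q_x = np.percentile(x, [25, 75])
    q_y = np.percentile(y, [25, 75])
    return IFNComparison(
        description=description,
        n_x=int(x.size),
        n_y=int(y.size),
        median_x=float(np.median(x)),
        iqr_x=(float(q_x[0]), float(q_x[1])),
        median_y=float(np.median(y)),
        iqr_y=(float(q_y[0]), float(q_y[1])),
        u_statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        method=method,
    )


def ifn_by_genotype(
    subjects: pd.DataFrame,
    snp: str,
    grouping: str = "carrier",
    description: str | None = None,
) -> IFNComparison:
    """IFN-α comparison between genotype groups at one SNP.

    ``grouping="carrier"`` pools minor-allele homozygotes with
    heterozygotes against major-allele homozygotes (the stratified-plot
    convention); ``grouping="homozygote"`` compares the two homozygote
    classes only.
    """
    g = subjects[snp]
    ifn = subjects["ifn_score"]
    if grouping == "carrier":
        x = ifn[g > 0]
        y = ifn[g == 0]
        label = f"{snp} carriers vs non-carriers"
    elif grouping == "homozygote":
        x = ifn[g == 2]
        y = ifn[g == 0]
        label = f"{snp} minor vs major homozygotes"
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return mann_whitney(x, y, description=description or label)


# ---------------------------------------------------------------------------
# Case-control allelic test


@dataclass(frozen=True)
class AllelicTest:
    """2x2 allele-count case-control comparison."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2: float
    pvalue: float
    table: tuple[tuple[int, int], tuple[int, int]]
    flag: str | None = None


def case_control_allele_test(case_genotypes, control_genotypes) -> AllelicTest:
    """Allelic chi-square test of independence with a Woolf-interval OR.

    Each diploid subject contributes two alleles. The chi-square uses one
    degree of freedom without continuity correction. A zero cell leaves the
    odds ratio undefined (flagged) while margins permitting, the chi-square
    is still reported.
    """
    cg = pd.Series(case_genotypes).dropna().astype(float)
    tg = pd.Series(control_genotypes).dropna().astype(float)
    a = int(cg.sum())  # case minor alleles
    b = int(2 * len(cg) - a)
    c = int(tg.sum())
    d = int(2 * len(tg) - c)
    table = ((a, b), (c, d))
    if min(a + b, c + d, a + c, b + d) == 0:
        return AllelicTest(
            float("nan"), float("nan"), float("nan"), float("nan"), float("nan"),
            table, flag="zero_margin",
        )
    chi2, p, _, _ = stats.chi2_contingency(np.array(table), correction=False)
    if min(a, b, c, d) == 0:
        return AllelicTest(
            float("nan"), float("nan"), float("nan"), float(chi2), float(p),
            table, flag="zero_cell",
        )
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return AllelicTest(
        float(np.exp(log_or)),
        float(np.exp(log_or - 1.959963984540054 * se)),
        float(np.exp(log_or + 1.959963984540054 * se)),
        float(chi2),
        float(p),
        table,
    )


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# Principal-component ancestry adjustment


@dataclass
class AncestryPC:
    """PC1-based ancestry split and its concordance with self-report."""

    scores: pd.Series
    bins: pd.Series
    bin_labels: dict[str, str]
    concordance: dict[str, float]
    pvalue: float
    n_snps: int
    split_value: float


def pca_ancestry(
    genotypes: pd.DataFrame,
    labels: pd.Series,
    split: str = "median",
) -> AncestryPC:
    """First genotype principal component as an ancestry axis.

    Missing genotypes are mean-imputed per SNP; columns are standardized;
    PC1 comes from the singular value decomposition, oriented so the first
    subject's score is nonnegative. Subjects are split at the central PC1
    value (``median`` by default, ``midrange`` optionally) into two
    ancestry bins; each self-reported group is assigned the bin holding its
    majority, and the concordance is that majority fraction. The reported
    P-value is the chi-square test of independence between self-report and
    bin.
    """
    X = genotypes.astype(float).to_numpy()
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need at least 2 subjects and 1 SNP")
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("genotype matrix is constant")
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    u, s, _ = np.linalg.svd(Xs, full_matrices=False)
    pc1 = u[:, 0] * s[0]
    if pc1[0] < 0:
        pc1 = -pc1
    scores = pd.Series(pc1, index=genotypes.index, name="pc1")
    if split == "median":
        split_value = float(np.median(pc1))
    elif split == "midrange":
        split_value = float((pc1.min() + pc1.max()) / 2.0)
    else:
        raise ValueError(f"unknown split rule {split!r}")
    bins = pd.Series(
        np.where(pc1 > split_value, "upper", "lower"),
        index=genotypes.index,
        name="ancestry_bin",
    )
    labels = labels.loc[genotypes.index]
    bin_labels: dict[str, str] = {}
    concordance: dict[str, float] = {}
    for grp in labels.dropna().unique():
        in_grp = bins[labels == grp]
        frac_upper = float((in_grp == "upper").mean())
        majority = "upper" if frac_upper >= 0.5 else "lower"
        bin_labels[str(grp)] = majority
        concordance[str(grp)] = max(frac_upper, 1.0 - frac_upper)
    contingency = pd.crosstab(labels, bins)
    if contingency.shape[0] >= 2 and contingency.shape[1] >= 2:
        _, pvalue, _, _ = stats.chi2_contingency(
            contingency.to_numpy(), correction=False
        )
    else:
        pvalue = float("nan")
    return AncestryPC(
        scores=scores,
        bins=bins,
        bin_labels=bin_labels,
        concordance=concordance,
        pvalue=float(pvalue),
        n_snps=int(keep.sum()),
        split_value=split_value,
    )


@dataclass
class RefitResult:
    """Association fits with and without the PC1 ancestry covariate."""

    without_pc: AssociationFit
    with_pc: AssociationFit
    coef_change: dict[str, float]


def refit_with_ancestry_covariate(
    outcome: pd.Series, predictors: pd.DataFrame, pc1: pd.Series
) -> RefitResult:
    """Refit a model adding PC1 as a quantitative ancestry covariate.

    Returns both fits and the change in each original coefficient; no
    automatic judgment about whether the change is meaningful is made.
    """
    base = fit_logistic(outcome, predictors)
    augmented = predictors.copy()
    augmented["pc1"] = pc1
    adjusted = fit_logistic(outcome, augmented)
    change = {}
    for term in predictors.columns:
        if term in base.coef and term in adjusted.coef:
            change[term] = adjusted.coef[term] - base.coef[term]
    return RefitResult(without_pc=base, with_pc=adjusted, coef_change=change)
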