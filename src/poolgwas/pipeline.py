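"""End-to-end stage orchestration: simulate, screen, select, validate, report.

Each stage reads and writes plain-text tables and drops a timestamp-free
JSON manifest (parameters, seed, input/output checksums) next to its
outputs, so a run is reproducible byte for byte from its configuration.
"""

from __future__ import annotations

import itertools
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io, select, validate
from .config import ANTIBODIES, SimulationConfig
from .screen import screen_all
from .simulate import (
    assign_pools,
    pool_metadata,
    simulate_annotations,
    simulate_probe_intensities,
    simulate_screening_cohort,
    simulate_validation_cohort,
    snp_columns,
)

log = logging.getLogger("poolgwas")


def run_simulate(
    config: SimulationConfig, out_dir: str | Path, export_vcf: bool = False
) -> dict[str, Path]:
    """Generate every synthetic input table for the downstream stages."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    comments = {"seed": config.seed, "stage": "simulate"}

    screen_subjects = simulate_screening_cohort(config)
    pools = assign_pools(screen_subjects, config.pool_size)
    probes = simulate_probe_intensities(pools, screen_subjects, config)
    validation = simulate_validation_cohort(config)
    rng = np.random.default_rng([17, config.seed])
    annotations = simulate_annotations(config.snp_ids(), rng)

    paths = {
        "screen_subjects": io.write_table(
            screen_subjects[io.subject_table_columns(screen_subjects)],
            out / "screen_subjects.tsv",
            comments,
        ),
        "pool_metadata": io.write_table(
            pool_metadata(pools), out / "pool_metadata.tsv", comments
        ),
        "probe_intensities": io.write_table(
            probes, out / "probe_intensities.tsv", comments
        ),
        "validation_subjects": io.write_table(
            validation[io.subject_table_columns(validation)],
            out / "validation_subjects.tsv",
            comments,
        ),
        "annotations": io.write_table(
            annotations, out / "annotations.tsv", comments
        ),
    }
    if export_vcf:
        paths["validation_vcf"] = io.write_vcf(
            validation, out / "validation_genotypes.vcf"
        )
    io.write_manifest(
        out / "manifest_simulate.json",
        stage="simulate",
        seed=config.seed,
        parameters={
            "n_snps": config.n_snps,
            "pool_size": config.pool_size,
            "probes_per_snp": config.probes_per_snp,
            "intensity_noise_sd": config.intensity_noise_sd,
        },
        inputs={},
        outputs=paths,
    )
    log.info("simulate: wrote %d tables to %s", len(paths), out)
    return paths


def run_screen(
    probe_path: str | Path,
    pool_meta_path: str | Path,
    out_dir: str | Path,
    variant: str = "text",
    seed: int | None = None,
) -> Path:
    """Screen a probe-intensity table and write the per-SNP statistics."""
    out = Path(out_dir)
    probes = io.read_table(probe_path)
    pool_meta = io.read_table(pool_meta_path)
    results = screen_all(probes, pool_meta, variant=variant)
    path = io.write_table(
        results, out / "screen_results.tsv", {"stage": "screen", "variant": variant}
    )
    io.write_manifest(
        out / "manifest_screen.json",
        stage="screen",
        seed=seed,
        parameters={"variant": variant},
        inputs={"probes": probe_path, "pool_metadata": pool_meta_path},
        outputs={"screen_results": path},
    )
    log.info("screen: %d SNPs scored", len(results))
    return path


def run_select(
    screen_path: str | Path,
    annotation_path: str | Path,
    out_dir: str | Path,
    n_rank: int = 200,
    n_top: int = 50,
    gene_window: int = select.DEFAULT_GENE_WINDOW,
    seed: int | None = None,
) -> dict[str, Path]:
    """Run the multi-step candidate selection and write per-stage tables."""
    out = Path(out_dir)
    results = io.read_table(screen_path)
    annotations = io.read_table(annotation_path)
    candidates = select.run_selection(
        results, annotations, n_rank=n_rank, n_top=n_top, gene_window=gene_window
    )
    table_path = io.write_table(
        select.candidate_table(candidates),
        out / "candidates.tsv",
        {"stage": "select", "n_rank": n_rank, "n_top": n_top},
    )
    summary_path = out / "selection_summary.json"
    summary_path.write_text(
        json.dumps(candidates.stage_counts, indent=2, sort_keys=True) + "\n"
    )
    io.write_manifest(
        out / "manifest_select.json",
        stage="select",
        seed=seed,
        parameters={
            "n_rank": n_rank, "n_top": n_top, "gene_window": gene_window
        },
        inputs={"screen_results": screen_path, "annotations": annotation_path},
        outputs={"candidates": table_path, "summary": summary_path},
    )
    log.info("select: %s", candidates.stage_counts)
    return {"candidates": table_path, "summary": summary_path}


def _ancestry_design(
    cases: pd.DataFrame, members: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Case subset and forced indicator covariates for one ancestry set."""
    subset = cases[cases["ancestry"].isin(members)].copy()
    indicators: list[str] = []
    for extra in list(members)[1:]:
        col = f"anc_{extra}"
        subset[col] = (subset["ancestry"] == extra).astype(float)
        indicators.append(col)
    return subset, indicators


def _fit_row(
    fit: validate.AssociationFit, snp: str, outcome: str, ancestry_set: str
) -> dict:
    or_, lo, hi = fit.odds_ratios.get(snp, (np.nan, np.nan, np.nan))
    return {
        "snp": snp,
        "outcome": outcome,
        "ancestry_set": ancestry_set,
        "odds_ratio": or_,
        "ci_low": lo,
        "ci_high": hi,
        "pvalue": fit.pvalues.get(snp, np.nan),
        "aic": fit.aic,
        "n": fit.n,
        "model": "+".join(fit.terms),
    }


def run_validate(
    subject_path: str | Path,
    out_dir: str | Path,
    alpha_stay: float = 0.1,
    call_rate_min: float = 0.98,
    hwe_alpha: float = 0.01,
    joint_sets: Sequence[Sequence[str]] = (("European", "Hispanic"),),
    candidate_snps: Sequence[str] | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Full validation-stage analysis of a subject table.

    Stages: genotype QC; per-ancestry-set, per-antibody backward-stepwise
    logistic screening (joint sets carry a forced ancestry indicator);
    combination-antibody follow-up with AIC comparison; genotype-stratified
    IFN-α comparisons; case-control allelic tests; PC1 ancestry analysis
    with adjusted refits; Bonferroni thresholds in the run summary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = io.read_table(subject_path)
    snps = snp_columns(subjects)
    if not snps:
        raise ValueError("subject table has no genotype columns")
    if candidate_snps is not None:
        missing = sorted(set(candidate_snps) - set(snps))
        if missing:
            raise ValueError(f"candidate SNPs absent from subject table: {missing}")
        snps = [s for s in snps if s in set(candidate_snps)]

    qc = validate.qc_genotypes(
        subjects, snps, call_rate_min=call_rate_min, hwe_alpha=hwe_alpha
    )
    passing = qc.loc[qc["pass"], "snp"].tolist()
    cases = subjects[subjects["role"] == "validation_case"]
    controls = subjects[subjects["role"] == "validation_control"]

    ancestry_sets: list[tuple[str, ...]] = [
        (a,) for a in sorted(cases["ancestry"].unique())
    ] + [tuple(s) for s in joint_sets]

    assoc_rows: list[dict] = []
    retained: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for members in ancestry_sets:
        subset, indicators = _ancestry_design(cases, members)
        if subset.empty:
            continue
        set_name = "+".join(members)
        for ab in ANTIBODIES:
            outcome = subset[f"ab_{ab}"]
            predictors = subset[passing + indicators]
            step = validate.backward_stepwise(
                outcome,
                predictors,
                alpha_stay=alpha_stay,
                keep=tuple(indicators),
                name=ab,
            )
            kept = [t for t in step.fit.terms if t in passing]
            for snp in kept:
                assoc_rows.append(_fit_row(step.fit, snp, ab, set_name))
                retained.setdefault((set_name, snp), []).append(
                    (ab, step.fit.coef.get(snp, np.nan))
                )

    # Combination-antibody follow-up where one SNP hits >= 2 antibodies.
    best_rows: list[dict] = []
    for (set_name, snp), hits in retained.items():
        members = tuple(set_name.split("+"))
        subset, indicators = _ancestry_design(cases, members)
        predictors = subset[[snp] + indicators]
        if len(hits) < 2:
            ab, _ = hits[0]
            fit = validate.fit_logistic(subset[f"ab_{ab}"], predictors, name=ab)
            if fit.ok:
                best_rows.append(_fit_row(fit, snp, ab, set_name))
            continue
        for (ab1, c1), (ab2, c2) in itertools.combinations(hits, 2):
            mode = "both_positive" if c1 * c2 > 0 else "x_positive_y_negative"
            sep = "+" if mode == "both_positive" else "-"
            combo = validate.make_combination_outcome(
                subset[f"ab_{ab1}"], subset[f"ab_{ab2}"], mode
            )
            fits = [
                validate.fit_logistic(subset[f"ab_{ab}"], predictors, name=ab)
                for ab in (ab1, ab2)
            ]
            fits.sort(key=lambda f: f.aic)
            combo_fit = validate.fit_logistic(
                combo, predictors, name=f"{ab1}{sep}{ab2}"
            )
            usable = [f for f in fits + [combo_fit] if f.ok]
            if len(usable) < 2:
                continue
            chosen, _ = validate.compare_outcome_models(usable)
            best_rows.append(_fit_row(chosen, snp, chosen.outcome, set_name))

    assoc = pd.DataFrame(
        assoc_rows,
        columns=[
            "snp", "outcome", "ancestry_set", "odds_ratio", "ci_low",
            "ci_high", "pvalue", "aic", "n", "model",
        ],
    )
    best = pd.DataFrame(best_rows, columns=assoc.columns)

    # IFN-α comparisons: carriers vs non-carriers, aggregate over cases.
    ifn_rows = []
    for snp in passing:
        try:
            cmp_ = validate.ifn_by_genotype(cases, snp, grouping="carrier")
        except ValueError:
            continue
        ifn_rows.append(
            {
                "snp": snp,
                "comparison": cmp_.description,
                "n_carrier": cmp_.n_x,
                "n_noncarrier": cmp_.n_y,
                "median_carrier": cmp_.median_x,
                "median_noncarrier": cmp_.median_y,
                "u": cmp_.u_statistic,
                "pvalue": cmp_.pvalue,
                "method": cmp_.method,
            }
        )
    ifn = pd.DataFrame(ifn_rows)

    # Case-control allelic tests per ancestry shared by cases and controls.
    cc_rows = []
    shared = sorted(
        set(cases["ancestry"].unique()) & set(controls["ancestry"].unique())
    )
    for snp in passing:
        for anc in shared + ["all"]:
            cg = cases if anc == "all" else cases[cases["ancestry"] == anc]
            tg = controls if anc == "all" else controls[controls["ancestry"] == anc]
            res = validate.case_control_allele_test(cg[snp], tg[snp])
            cc_rows.append(
                {
                    "snp": snp,
                    "ancestry": anc,
                    "odds_ratio": res.odds_ratio,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "chi2": res.chi2,
                    "pvalue": res.pvalue,
                    "flag": res.flag or "",
                }
            )
    cc = pd.DataFrame(cc_rows)

    # PC1 ancestry analysis and adjusted refits of the best-fit models.
    summary: dict = {
        "n_snps": len(snps),
        "n_snps_pass_qc": len(passing),
        "bonferroni_snps": validate.bonferroni_threshold(0.05, max(len(passing), 1)),
        "bonferroni_snps_x_traits": validate.bonferroni_threshold(
            0.05, max(len(passing) * len(ANTIBODIES), 1)
        ),
    }
    pca_labels = subjects["ancestry"].where(
        subjects["ancestry"].isin(["African", "European"])
    )
    if passing and pca_labels.notna().sum() >= 2:
        try:
            pca = validate.pca_ancestry(subjects[passing], pca_labels)
            summary["pca"] = {
                "concordance": pca.concordance,
                "independence_p": pca.pvalue,
                "n_snps": pca.n_snps,
            }
            pc1_cases = pca.scores.loc[cases.index]
            changes = {}
            for row in best_rows:
                members = tuple(row["ancestry_set"].split("+"))
                subset, indicators = _ancestry_design(cases, members)
                snp = row["snp"]
                outcome_name = row["outcome"]
                mode = None
                if "+" in outcome_name and outcome_name not in ANTIBODIES:
                    ab1, ab2 = outcome_name.split("+")
                    outcome = validate.make_combination_outcome(
                        subset[f"ab_{ab1}"], subset[f"ab_{ab2}"], "both_positive"
                    )
                elif "-" in outcome_name:
                    ab1, ab2 = outcome_name.split("-")
                    outcome = validate.make_combination_outcome(
                        subset[f"ab_{ab1}"], subset[f"ab_{ab2}"],
                        "x_positive_y_negative",
                    )
                else:
                    outcome = subset[f"ab_{outcome_name}"]
                refit = validate.refit_with_ancestry_covariate(
                    outcome,
                    subset[[snp] + indicators],
                    pc1_cases.loc[subset.index],
                )
                if snp in refit.coef_change:
                    changes[f"{row['ancestry_set']}:{snp}:{outcome_name}"] = (
                        refit.coef_change[snp]
                    )
            summary["pc1_adjusted_coef_change"] = changes
        except ValueError as exc:
            summary["pca"] = {"error": str(exc)}

    paths = {
        "qc": io.write_table(qc, out / "qc_report.tsv", {"stage": "validate"}),
        "associations": io.write_table(
            assoc, out / "associations_screening.tsv", {"stage": "validate"}
        ),
        "best_fit": io.write_table(
            best, out / "associations_best_fit.tsv", {"stage": "validate"}
        ),
        "ifn": io.write_table(ifn, out / "ifn_comparisons.tsv", {"stage": "validate"}),
        "case_control": io.write_table(
            cc, out / "case_control.tsv", {"stage": "validate"}
        ),
    }
    summary_path = out / "validation_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    paths["summary"] = summary_path
    io.write_manifest(
        out / "manifest_validate.json",
        stage="validate",
        seed=seed,
        parameters={
            "alpha_stay": alpha_stay,
            "call_rate_min": call_rate_min,
            "hwe_alpha": hwe_alpha,
            "joint_sets": [list(s) for s in joint_sets],
        },
        inputs={"subjects": subject_path},
        outputs=paths,
    )
    log.info(
        "validate: %d/%d SNPs pass QC, %d screening hits, %d best-fit rows",
        len(passing), len(snps), len(assoc), len(best),
    )
    return paths


def run_report(
    validate_dir: str | Path, subject_path: str | Path, out_dir: str | Path
) -> dict[str, Path]:
    """Render the association summary and genotype x serology IFN medians."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vdir = Path(validate_dir)
    best = io.read_table(vdir / "associations_best_fit.tsv")
    subjects = io.read_table(subject_path)
    cases = subjects[subjects["role"] == "validation_case"]

    table_rows = []
    for _, row in best.iterrows():
        table_rows.append(
            {
                "locus": row["snp"],
                "outcome": row["outcome"],
                "ancestry_set": row["ancestry_set"],
                "odds_ratio": round(row["odds_ratio"], 2)
                if pd.notna(row["odds_ratio"]) else np.nan,
                "ci": (
                    f"({row['ci_low']:.2f} to {row['ci_high']:.2f})"
                    if pd.notna(row["ci_low"]) else ""
                ),
                "pvalue": row["pvalue"],
            }
        )
    table1 = pd.DataFrame(
        table_rows,
        columns=["locus", "outcome", "ancestry_set", "odds_ratio", "ci", "pvalue"],
    )

    median_rows = []
    for snp in snp_columns(subjects):
        carrier = cases[snp] > 0
        for label, mask in (("carrier", carrier), ("non-carrier", ~carrier)):
            scores = cases.loc[mask & cases[snp].notna(), "ifn_score"].dropna()
            if scores.empty:
                continue
            q1, q3 = np.percentile(scores, [25, 75])
            median_rows.append(
                {
                    "snp": snp,
                    "genotype_group": label,
                    "n": int(scores.size),
                    "median_ifn": float(np.median(scores)),
                    "iqr_low": float(q1),
                    "iqr_high": float(q3),
                }
            )
    medians = pd.DataFrame(median_rows)

    paths = {
        "association_summary": io.write_table(
            table1, out / "association_summary.tsv", {"stage": "report"}
        ),
        "ifn_medians": io.write_table(
            medians, out / "ifn_medians.tsv", {"stage": "report"}
        ),
    }
    io.write_manifest(
        out / "manifest_report.json",
        stage="report",
        seed=None,
        parameters={},
        inputs={"best_fit": vdir / "associations_best_fit.tsv", "subjects": subject_path},
        outputs=paths,
    )
    return paths
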