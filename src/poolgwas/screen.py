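"""Pooled-DNA screening statistics.

For each SNP and pool, the relative allele signal (RAS) of a probe is
A/(A+B), a proxy for the pool's A-allele frequency. Pools are summarized by
the mean and variance of RAS across the 8 (or 12) probes; groups (high vs
low phenotype) by an inverse-SD-weighted mean of pool RAS values. The
cross-ancestry statistic Studentizes the high-low difference within each
ancestral background and combines the per-ancestry terms Stouffer-style:

    Z = (1/sqrt(K)) * sum_k (r_{1,k} - r_{0,k}) / sqrt(v_{0,k} + v_{1,k})

which down-weights SNPs with noisy probe signals, respects allele-frequency
heterogeneity between ancestries, and is robust to population
stratification because no between-ancestry contrast is ever formed. The
1/sqrt(K) factor keeps Z approximately standard normal under the
intensity-noise null for any number of ancestries; ``normalize=False``
returns the plain sum of the per-ancestry Studentized terms.

A Silhouette separation score (clusters fixed by phenotype label, absolute
difference of pool mean RAS as the distance) complements Z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Variance floor: a constant-RAS pool gets large but finite weight.
SD_FLOOR = 1e-6


@dataclass(frozen=True)
class PoolSummary:
    """Per-pool RAS summary: mean, unbiased variance, surviving probe count."""

    r_pool: float
    v_pool: float
    n_probes: int
    ok: bool

    @property
    def qc_failed(self) -> bool:
        return not self.ok


@dataclass(frozen=True)
class GroupSummary:
    """Inverse-SD-weighted group summary of pool RAS values."""

    r_group: float
    v_group: float
    weights: tuple[float, ...]
    n_pools: int


def compute_ras(intensity_a: float, intensity_b: float) -> float:
    """Relative allele signal A/(A+B); NaN when both channels are zero."""
    if intensity_a < 0 or intensity_b < 0:
        raise ValueError("intensities must be nonnegative")
    total = intensity_a + intensity_b
    if total == 0:
        return float("nan")
    return intensity_a / total


def ras_array(intensity_a: np.ndarray, intensity_b: np.ndarray) -> np.ndarray:
    """Vectorized RAS with NaN where A+B = 0."""
    a = np.asarray(intensity_a, dtype=float)
    b = np.asarray(intensity_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("intensities must be nonnegative")
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, a / np.where(total > 0, total, 1.0), np.nan)
    return out


def summarize_pool(probe_ras: Sequence[float]) -> PoolSummary:
    """Mean and unbiased variance of a pool's probe RAS values.

    Missing probes (NaN) are dropped; fewer than two surviving probes is a
    QC failure for that pool x SNP.
    """
    values = np.asarray(probe_ras, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        r = float(values[0]) if values.size else float("nan")
        return PoolSummary(r, float("nan"), int(values.size), ok=False)
    return PoolSummary(
        float(values.mean()), float(values.var(ddof=1)), int(values.size), ok=True
    )


def group_weighted_ras(
    pools: Sequence[PoolSummary],
    variant: str = "text",
    sd_floor: float = SD_FLOOR,
) -> GroupSummary:
    """Combine pools of one (SNP, group, ancestry) cell into a group summary.

    ``variant="text"`` (default): weights proportional to the inverse
    standard deviation of each pool's probe RAS values (floored at
    ``sd_floor``), normalized to sum to one; the group variance is the
    sampling variance of the weighted mean, sum w_j^2 v_j / n_probes_j.

    ``variant="printed"``: the literal published formulas, r = sum r_j/v_j
    and v = sum (v_j/n)^2 with n the number of pools. These are not a mean
    and not a variance of one; they are kept for comparison only.
    """
    if not pools:
        raise ValueError("group has no pools")
    r = np.array([p.r_pool for p in pools])
    v = np.array([p.v_pool for p in pools])
    k = np.array([p.n_probes for p in pools], dtype=float)
    if variant == "text":
        sd = np.sqrt(v)
        w = 1.0 / np.maximum(sd, sd_floor)
        w = w / w.sum()
        r_group = float(np.sum(w * r))
        v_group = float(np.sum(w**2 * v / k))
    elif variant == "printed":
        v_safe = np.maximum(v, sd_floor**2)
        w = 1.0 / v_safe
        r_group = float(np.sum(r / v_safe))
        v_group = float(np.sum((v / len(pools)) ** 2))
    else:
        raise ValueError(f"unknown formula variant {variant!r}")
    return GroupSummary(r_group, v_group, tuple(w), len(pools))


def cross_ancestry_z(
    high: Mapping[str, GroupSummary],
    low: Mapping[str, GroupSummary],
    normalize: bool = True,
) -> float:
    """Stouffer-combined Studentized high-low RAS difference across ancestries.

    Ancestries must match between the two sides; an ancestry whose summed
    group variance is zero contributes no term (with a warning). With
    ``normalize`` the sum is divided by sqrt(#terms), giving an
    approximately standard normal statistic under the intensity-noise null.
    Antisymmetric under swapping the high/low labels.
    """
    if set(high) != set(low):
        raise ValueError("high and low sides cover different ancestries")
    if not high:
        raise ValueError("no ancestries supplied")
    terms = []
    for k in sorted(high):
        var = high[k].v_group + low[k].v_group
        if var == 0:
            warnings.warn(
                f"ancestry {k!r} dropped from Z: zero group variance",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        terms.append((high[k].r_group - low[k].r_group) / np.sqrt(var))
    if not terms:
        return float("nan")
    z = float(np.sum(terms))
    if normalize:
        z /= np.sqrt(len(terms))
    return z


def silhouette_score(
    pool_means: Sequence[float], labels: Sequence[int]
) -> float:
    """Mean silhouette of pool RAS means with clusters fixed by phenotype.

    Distance is the absolute difference of the scalar pool means. Per pool,
    s = (b - a) / max(a, b) with a the mean distance to same-labeled pools
    and b the mean distance to the other group; s = 0 when max(a, b) = 0
    and for singleton clusters. Result lies in [-1, 1].
    """
    m = np.asarray(pool_means, dtype=float)
    lab = np.asarray(labels)
    if m.ndim != 1 or m.size != lab.size:
        raise ValueError("pool_means and labels must be equal-length 1-D")
    classes = np.unique(lab)
    if classes.size != 2:
        raise ValueError("both label classes must be non-empty")
    dist = np.abs(m[:, None] - m[None, :])
    s = np.zeros(m.size)
    for i in range(m.size):
        same = lab == lab[i]
        n_same = same.sum() - 1
        if n_same == 0:
            continue  # singleton cluster: s = 0
        a = dist[i, same].sum() / n_same
        b = dist[i, ~same].mean()
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def _silhouette_matrix(means: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise silhouette for a (n_snps, n_pools) matrix of pool means.

    NaN pool means (QC failures) are ignored per row; rows without both
    classes get NaN.
    """
    n_snps, _ = means.shape
    out = np.full(n_snps, np.nan)
    for i in range(n_snps):
        valid = ~np.isnan(means[i])
        lab = labels[valid]
        if valid.sum() < 2 or np.unique(lab).size != 2:
            continue
        out[i] = silhouette_score(means[i, valid], lab)
    return out


def screen_all(
    probe_table: pd.DataFrame,
    pool_meta: pd.DataFrame,
    variant: str = "text",
    sd_floor: float = SD_FLOOR,
    normalize_z: bool = True,
) -> pd.DataFrame:
    """Screen every SNP in a probe-intensity table.

    ``probe_table`` columns: snp, pool, probe, intensity_A, intensity_B.
    ``pool_meta`` columns: pool, ancestry, group (1 = high phenotype).

    Returns one row per SNP — z, silhouette, per-ancestry high-low RAS
    differences (``delta_<ancestry>``) and a ``qc_flag`` — sorted by |z|
    descending. SNPs with no ancestry retaining at least one valid pool on
    each side are flagged ``qc_fail`` rather than dropped.
    """
    required = {"snp", "pool", "probe", "intensity_A", "intensity_B"}
    missing = required - set(probe_table.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    ancestries = sorted(pool_meta["ancestry"].unique())
    delta_cols = [f"delta_{a}" for a in ancestries]
    if probe_table.empty:
        return pd.DataFrame(
            columns=["snp", "z", "silhouette", *delta_cols, "qc_flag"]
        )
    unknown = set(probe_table["pool"]) - set(pool_meta["pool"])
    if unknown:
        raise ValueError(f"pools without metadata: {sorted(unknown)}")

    df = probe_table.copy()
    df["ras"] = ras_array(
        df["intensity_A"].to_numpy(), df["intensity_B"].to_numpy()
    )
    pool_stats = (
        df.groupby(["snp", "pool"])["ras"]
        .agg(r_pool="mean", v_pool="var", n_probes="count")
        .reset_index()
        .merge(pool_meta, on="pool", validate="many_to_one")
    )
    pool_stats["valid"] = pool_stats["n_probes"] >= 2

    valid = pool_stats[pool_stats["valid"]].copy()
    if variant == "text":
        sd = np.sqrt(valid["v_pool"].to_numpy())
        valid["w_raw"] = 1.0 / np.maximum(sd, sd_floor)
        grp = valid.groupby(["snp", "ancestry", "group"], sort=True)
        valid["w"] = valid["w_raw"] / grp["w_raw"].transform("sum")
        valid["wr"] = valid["w"] * valid["r_pool"]
        valid["wv"] = valid["w"] ** 2 * valid["v_pool"] / valid["n_probes"]
        groups = (
            valid.groupby(["snp", "ancestry", "group"], sort=True)
            .agg(r_group=("wr", "sum"), v_group=("wv", "sum"))
            .reset_index()
        )
    elif variant == "printed":
        v_safe = np.maximum(valid["v_pool"].to_numpy(), sd_floor**2)
        valid["rv"] = valid["r_pool"] / v_safe
        grp = valid.groupby(["snp", "ancestry", "group"], sort=True)
        n_pools = grp["pool"].transform("count")
        valid["vn2"] = (valid["v_pool"] / n_pools) ** 2
        groups = (
            grp.agg(r_group=("rv", "sum"), v_group=("vn2", "sum"))
            .reset_index()
        )
    else:
        raise ValueError(f"unknown formula variant {variant!r}")

    wide = groups.pivot_table(
        index=["snp", "ancestry"],
        columns="group",
        values=["r_group", "v_group"],
        aggfunc="first",
    )
    snps = sorted(df["snp"].unique())
    rows = pd.DataFrame(index=pd.Index(snps, name="snp"))
    if not wide.empty and (0 in wide["r_group"].columns) and (
        1 in wide["r_group"].columns
    ):
        both = wide.dropna(subset=[("r_group", 0), ("r_group", 1)])
        delta = both[("r_group", 1)] - both[("r_group", 0)]
        var = both[("v_group", 0)] + both[("v_group", 1)]
        with np.errstate(invalid="ignore", divide="ignore"):
            term = delta / np.sqrt(var)
        term = term.replace([np.inf, -np.inf], np.nan)
        per_snp = term.groupby(level="snp")
        z = per_snp.sum(min_count=1)
        if normalize_z:
            z = z / np.sqrt(per_snp.count().clip(lower=1))
        rows["z"] = z
        dropped = int(var.eq(0).sum())
        if dropped:
            warnings.warn(
                f"{dropped} ancestry term(s) dropped from Z: zero group variance",
                RuntimeWarning,
                stacklevel=2,
            )
        deltas = delta.rename("delta").reset_index().pivot(
            index="snp", columns="ancestry", values="delta"
        )
        for a in ancestries:
            rows[f"delta_{a}"] = deltas[a] if a in deltas.columns else np.nan
    else:
        rows["z"] = np.nan
        for a in ancestries:
            rows[f"delta_{a}"] = np.nan

    # Silhouette over valid pool means, clusters fixed by phenotype group.
    mean_mat = pool_stats.pivot_table(
        index="snp", columns="pool", values="r_pool", aggfunc="first"
    )
    mask = pool_stats.pivot_table(
        index="snp", columns="pool", values="valid", aggfunc="first"
    ).fillna(False)
    mean_mat = mean_mat.where(mask.astype(bool))
    meta = pool_meta.set_index("pool")
    labels = meta.loc[mean_mat.columns, "group"].to_numpy()
    sil = _silhouette_matrix(mean_mat.to_numpy(), labels)
    rows["silhouette"] = pd.Series(sil, index=mean_mat.index)

    rows["qc_flag"] = np.where(rows["z"].notna(), "ok", "qc_fail")
    rows = rows.reset_index()
    rows = rows[["snp", "z", "silhouette", *delta_cols, "qc_flag"]]
    order = (-rows["z"].abs()).fillna(np.inf)
    rows = (
        rows.assign(_order=order)
        .sort_values(["_order", "snp"], kind="mergesort")
        .drop(columns="_order")
        .reset_index(drop=True)
    )
    return rows
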