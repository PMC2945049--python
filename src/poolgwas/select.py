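"""Multi-step candidate-SNP selection from pooled-screen results.

The screening statistic is deliberately permissive, so candidates are
whittled down in stages: (1) rank all SNPs by the weighted RAS statistic
|Z| and keep the top ``n_rank``; (2) drop any whose Silhouette score falls
outside the top ``n_rank`` Silhouette scores; (3) re-rank the survivors by
|Z| and keep the top ``n_top``; (4) keep only SNPs within or near a known
gene whose locus has immune-system relevance, collapsing same-gene
duplicates to the statistically stronger SNP. Each stage is a subset of the
previous one and the whole procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: "Within or near a known gene" proximity window (bp). The field reads
#: "near" generously: validated loci sit >100 kb from their genes' bodies
#: in comparable studies, so the window is configurable.
DEFAULT_GENE_WINDOW = 100_000


@dataclass(frozen=True)
class CandidateSet:
    """Ordered SNP lists surviving each selection stage."""

    top_by_ras: tuple[str, ...] = ()
    dual_top: tuple[str, ...] = ()
    top50: tuple[str, ...] = ()
    final_candidates: tuple[str, ...] = ()

    @property
    def stage_counts(self) -> dict[str, int]:
        return {
            "top_by_ras": len(self.top_by_ras),
            "dual_top": len(self.dual_top),
            "top50": len(self.top50),
            "final_candidates": len(self.final_candidates),
        }

    def check_containment(self) -> None:
        """Raise if the stage-containment invariant is violated."""
        if not (
            set(self.final_candidates)
            <= set(self.top50)
            <= set(self.dual_top)
            <= set(self.top_by_ras)
        ):
            raise AssertionError("selection stages are not nested")


def _ranked(results: pd.DataFrame) -> pd.DataFrame:
    """Usable rows ranked by |z| desc, ties by silhouette desc then SNP id."""
    usable = results.dropna(subset=["z"]).copy()
    usable["_absz"] = usable["z"].abs()
    usable["_sil"] = usable["silhouette"].fillna(-np.inf)
    return usable.sort_values(
        ["_absz", "_sil", "snp"],
        ascending=[False, False, True],
        kind="mergesort",
    )


def select_dual_top(results: pd.DataFrame, n_rank: int = 200) -> CandidateSet:
    """Stages 1-2: top ``n_rank`` by |z|, intersected with the Silhouette top.

    A SNP in the |z| top list survives only if its Silhouette score ranks
    within the top ``n_rank`` Silhouette scores (descending; ties broken by
    SNP id). QC-failed SNPs (z missing) never enter the ranking.
    """
    if results.empty:
        return CandidateSet()
    if n_rank < 1:
        raise ValueError("n_rank must be >= 1")
    by_z = _ranked(results)
    top_by_ras = tuple(by_z["snp"].head(n_rank))
    by_sil = by_z.sort_values(
        ["_sil", "snp"], ascending=[False, True], kind="mergesort"
    )
    sil_top = set(by_sil["snp"].head(n_rank))
    dual = tuple(s for s in top_by_ras if s in sil_top)
    return CandidateSet(top_by_ras=top_by_ras, dual_top=dual)


def rerank_and_truncate(candidates: CandidateSet, n_top: int = 50) -> CandidateSet:
    """Stage 3: keep the top ``n_top`` of the dual-ranked list by |z|.

    ``dual_top`` already carries |z|-descending order, so the re-ranking is
    a truncation.
    """
    return replace(candidates, top50=candidates.dual_top[:n_top])


def annotation_filter(
    candidates: CandidateSet,
    annotations: pd.DataFrame,
    gene_window: int = DEFAULT_GENE_WINDOW,
) -> CandidateSet:
    """Stage 4: gene-proximity and immune-relevance filter.

    ``annotations`` columns: snp, chrom, pos, gene, distance_bp,
    immune_flag. A SNP survives when it lies within ``gene_window`` bp of a
    named gene and that locus is flagged immune-relevant. When several
    surviving SNPs share a gene, only the first in |z| order (the
    statistically stronger one) is retained.
    """
    top = list(candidates.top50)
    ann = annotations.set_index("snp")
    missing = [s for s in top if s not in ann.index]
    if missing:
        raise KeyError(f"SNPs without annotation records: {missing}")
    kept: list[str] = []
    seen_genes: set[str] = set()
    for snp in top:  # |z|-descending order from the previous stage
        rec = ann.loc[snp]
        gene = rec["gene"]
        has_gene = isinstance(gene, str) and gene != ""
        near = has_gene and rec["distance_bp"] <= gene_window
        if not (near and bool(rec["immune_flag"])):
            continue
        if gene in seen_genes:
            continue
        seen_genes.add(gene)
        kept.append(snp)
    return replace(candidates, final_candidates=tuple(kept))


def run_selection(
    results: pd.DataFrame,
    annotations: pd.DataFrame,
    n_rank: int = 200,
    n_top: int = 50,
    gene_window: int = DEFAULT_GENE_WINDOW,
) -> CandidateSet:
    """All four stages; returns the nested candidate set."""
    cs = select_dual_top(results, n_rank=n_rank)
    cs = rerank_and_truncate(cs, n_top=n_top)
    cs = annotation_filter(cs, annotations, gene_window=gene_window)
    cs.check_containment()
    return cs


def candidate_table(candidates: CandidateSet) -> pd.DataFrame:
    """Long-format per-stage membership table (snp, stage)."""
    rows = []
    for stage in ("top_by_ras", "dual_top", "top50", "final_candidates"):
        for rank, snp in enumerate(getattr(candidates, stage), start=1):
            rows.append({"stage": stage, "rank": rank, "snp": snp})
    return pd.DataFrame(rows, columns=["stage", "rank", "snp"])
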