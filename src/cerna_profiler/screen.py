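"""Differential-expression thresholding and term enrichment.

Selection follows the filtering rule FDR <= 0.05 and fold change >= 2:
fold change is computed from condition means of (FPKM + pseudocount),
multiple testing is controlled with Benjamini-Hochberg, and the pass flag
is the conjunction of the two thresholds.  The built-in p-value source is
Welch's t on log2(value + 1) — a deliberately simple stand-in so the
thresholding logic can be exercised end-to-end; externally computed
per-gene p-values (e.g. from a count-based negative-binomial test) can be
supplied instead.

Enrichment is one-sided Fisher's exact (over-representation), i.e. the
hypergeometric upper tail of study hits for each annotation term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix

__all__ = ["DEResult", "EnrichmentResult", "de_screen", "bh_adjust", "enrich_terms"]


@dataclass
class DEResult:
    gene_id: str
    log2_fold_change: float
    p_value: float
    q_value: float
    passes: bool


@dataclass
class EnrichmentResult:
    term_id: str
    k: int  # study genes annotated to the term
    n: int  # study size
    K: int  # background genes annotated to the term
    N: int  # background size
    p_value: float
    significant: bool


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_screen(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    p_source: Mapping[str, float] | str = "builtin_t",
    pseudocount: float = 1.0,
    two_sided_fc: bool = True,
) -> list[DEResult]:
    """Screen genes for differential expression between two conditions.

    log2FC = log2((mean_b + eps) / (mean_a + eps)) over condition means.
    ``p_source`` is either ``"builtin_t"`` (Welch's t on log2(v+1) across
    replicates) or a mapping gene_id -> p-value from an external test.
    A gene passes when |log2FC| >= log2(fc_threshold) (one-sided with
    ``two_sided_fc=False``: log2FC <= -log2(fc) only) and q <= fdr_threshold.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    idx_a = matrix.samples_of_condition(group_a)
    idx_b = matrix.samples_of_condition(group_b)
    a = matrix.values[:, idx_a]
    b = matrix.values[:, idx_b]
    log2fc = np.log2(b.mean(axis=1) + pseudocount) - np.log2(a.mean(axis=1) + pseudocount)

    if isinstance(p_source, str):
        if p_source != "builtin_t":
            raise ValueError(f"unknown p_source {p_source!r}")
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise ValueError("builtin_t needs >= 2 replicates per group")
        la, lb = np.log2(a + 1), np.log2(b + 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)  # zero-variance-in-both genes
    else:
        missing = [g for g in matrix.gene_ids if g not in p_source]
        if missing:
            raise ValueError(f"supplied p table missing genes: {missing[:5]}")
        p = np.array([p_source[g] for g in matrix.gene_ids], dtype=float)

    q = bh_adjust(p)
    log2_thr = np.log2(fc_threshold)
    if two_sided_fc:
        fc_ok = np.abs(log2fc) >= log2_thr
    else:
        fc_ok = log2fc <= -log2_thr
    passes = fc_ok & (q <= fdr_threshold)
    return [
        DEResult(g, float(log2fc[i]), float(p[i]), float(q[i]), bool(passes[i]))
        for i, g in enumerate(matrix.gene_ids)
    ]


def enrich_terms(
    study_genes: set[str],
    background_genes: set[str],
    annotation: Mapping[str, set[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation test of each annotation term in the study set.

    ``annotation`` maps term_id -> set of annotated genes; genes outside
    the background are ignored.  p = P(X >= k) for X hypergeometric with
    population N (background), K successes (term genes in background),
    and n draws (study size).
    """
    if not background_genes:
        raise ValueError("background gene set is empty")
    extra = study_genes - background_genes
    if extra:
        raise ValueError(f"study genes outside background: {sorted(extra)[:5]}")
    N = len(background_genes)
    n = len(study_genes)
    results = []
    for term_id in sorted(annotation):
        term_genes = annotation[term_id] & background_genes
        K = len(term_genes)
        k = len(term_genes & study_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        results.append(EnrichmentResult(term_id, k, n, K, N, p, p < alpha))
    return results
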