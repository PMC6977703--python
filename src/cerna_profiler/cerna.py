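"""Co-expression and ceRNA (lncRNA-miRNA-mRNA) network inference.

Two constructions:

* the co-expression network keeps every gene pair whose Pearson
  correlation across samples reaches a fixed threshold (0.99 by default,
  signed r as printed);
* the ceRNA network first keeps lncRNA x mRNA pairs at or above the 99th
  percentile (nearest-rank) of the full pairwise correlation pool, then
  restricts to triplets in which both the lncRNA and the mRNA carry at
  least one perfect 6mer seed site — an exact reverse complement of the
  shared miRNA's nucleotides 2-7 — so the pair can plausibly compete for
  that miRNA.

G:U wobble pairs are not counted as seed matches by default (the sites
are required to be perfect); a flag enables wobble tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import ExpressionMatrix, MiRNARecord

__all__ = [
    "CoexpressionEdge",
    "SeedMatch",
    "CeRNATriplet",
    "coexpression_network",
    "percentile_pair_threshold",
    "seed_match",
    "build_cerna_network",
]

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class CoexpressionEdge:
    gene_a: str
    gene_b: str
    r: float


@dataclass(frozen=True)
class SeedMatch:
    mirna_id: str
    target_id: str
    site_offsets: tuple[int, ...]  # 0-based offsets of the 6-nt site

    @property
    def n_sites(self) -> int:
        return len(self.site_offsets)


@dataclass(frozen=True)
class CeRNATriplet:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    r_pair: float
    n_sites_lncrna: int
    n_sites_mrna: int


def _pearson_rows(values: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation matrix; zero-variance rows -> NaN."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered @ centered.T) / np.outer(norms, norms)
    corr[norms == 0, :] = np.nan
    corr[:, norms == 0] = np.nan
    return np.clip(corr, -1.0, 1.0, out=corr)


def coexpression_network(
    matrix: ExpressionMatrix,
    gene_subset: Sequence[str] | None = None,
    r_threshold: float = 0.99,
) -> list[CoexpressionEdge]:
    """All unordered gene pairs with Pearson r >= ``r_threshold``.

    Zero-variance genes are skipped (their correlation is undefined).
    Edges come back canonically ordered (gene_a < gene_b) and sorted.
    """
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    sub = matrix if gene_subset is None else matrix.subset(gene_subset)
    corr = _pearson_rows(sub.values)
    edges = []
    for i in range(sub.n_genes):
        for j in range(i + 1, sub.n_genes):
            r = corr[i, j]
            if not math.isnan(r) and r >= r_threshold:
                a, b = sorted((sub.gene_ids[i], sub.gene_ids[j]))
                edges.append(CoexpressionEdge(a, b, float(r)))
    edges.sort(key=lambda e: (e.gene_a, e.gene_b))
    return edges


def percentile_pair_threshold(correlations: Sequence[float], percentile: float = 99.0) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th order statistic.

    The retained set is every value >= the returned threshold, so ties at
    the threshold are kept.  Deterministic and interpolation-free.
    """
    vals = np.asarray(correlations, dtype=float)
    if vals.size == 0:
        raise ValueError("empty correlation list")
    if not (0 < percentile <= 100):
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    rank = math.ceil(percentile / 100.0 * vals.size)  # 1-based
    return float(np.sort(vals)[rank - 1])


def seed_match(
    mirna: MiRNARecord,
    target_sequence: str,
    target_id: str = "",
    seed_start: int = 1,
    seed_length: int = 6,
    allow_gu_wobble: bool = False,
) -> SeedMatch:
    """All perfect seed sites of ``mirna`` in a target sequence.

    The seed is miRNA positions 2-7 (``seed_start=1`` 0-based, length 6,
    the TargetScan 6mer convention); a site is an exact occurrence of its
    reverse complement in the target.  DNA/RNA alphabets are normalized
    internally.  Overlapping sites all count.  With ``allow_gu_wobble``
    a site position pairing G:U also counts as matched.
    """
    seed = mirna.sequence[seed_start : seed_start + seed_length]
    if len(seed) < seed_length:
        raise ValueError(f"miRNA {mirna.mirna_id} too short for the seed window")
    if set(seed) - set("ACGU"):
        raise ValueError(f"ambiguous bases in seed of {mirna.mirna_id}")
    target = target_sequence.upper().replace("U", "T")
    seed_dna = seed.replace("U", "T")
    site = seed_dna.translate(_DNA_COMPLEMENT)[::-1]  # what a perfect site looks like
    offsets = []
    if not allow_gu_wobble:
        start = target.find(site)
        while start != -1:
            offsets.append(start)
            start = target.find(site, start + 1)
    else:
        # pairing test per position: seed base vs target base (antiparallel)
        seed_rev = seed_dna[::-1]
        for off in range(0, len(target) - seed_length + 1):
            window = target[off : off + seed_length]
            ok = True
            for sb, tb in zip(seed_rev, window):
                wc = sb.translate(_DNA_COMPLEMENT) == tb
                gu = (sb == "G" and tb == "T") or (sb == "T" and tb == "G")
                if not (wc or gu):
                    ok = False
                    break
            if ok:
                offsets.append(off)
    return SeedMatch(mirna.mirna_id, target_id, tuple(offsets))


def build_cerna_network(
    matrix: ExpressionMatrix,
    lncrna_ids: Sequence[str],
    mrna_ids: Sequence[str],
    mirnas: Sequence[MiRNARecord],
    sequences: dict[str, str],
    percentile: float = 99.0,
) -> list[CeRNATriplet]:
    """Infer lncRNA-miRNA-mRNA triplets.

    Step 1 computes Pearson correlations for every lncRNA x mRNA pair
    across all samples; step 2 keeps pairs at/above the nearest-rank
    ``percentile`` of that pool; step 3 expands kept pairs over the miRNA
    set and retains triplets where both members carry >= 1 perfect 6mer
    seed site of the shared miRNA.  Output is deterministic (sorted) and
    invariant to input ordering.
    """
    lnc_ids = sorted(set(lncrna_ids))
    m_ids = sorted(set(mrna_ids))
    if not lnc_ids or not m_ids:
        return []
    sub = matrix.subset(lnc_ids + m_ids)
    corr = _pearson_rows(sub.values)
    n_lnc = len(lnc_ids)
    pair_corr = corr[:n_lnc, n_lnc:]
    finite = pair_corr[~np.isnan(pair_corr)]
    if finite.size == 0:
        return []
    threshold = percentile_pair_threshold(finite.tolist(), percentile)

    kept_pairs = [
        (lnc_ids[i], m_ids[j], float(pair_corr[i, j]))
        for i in range(n_lnc)
        for j in range(len(m_ids))
        if not math.isnan(pair_corr[i, j]) and pair_corr[i, j] >= threshold
    ]

    site_cache: dict[tuple[str, str], SeedMatch] = {}

    def sites(mirna: MiRNARecord, tid: str) -> SeedMatch:
        key = (mirna.mirna_id, tid)
        if key not in site_cache:
            if tid not in sequences:
                raise KeyError(f"no sequence for retained pair member {tid!r}")
            site_cache[key] = seed_match(mirna, sequences[tid], tid)
        return site_cache[key]

    triplets = []
    for lnc, mrna, r in kept_pairs:
        for mirna in sorted(mirnas, key=lambda m: m.mirna_id):
            s_l = sites(mirna, lnc)
            s_m = sites(mirna, mrna)
            if s_l.n_sites >= 1 and s_m.n_sites >= 1:
                triplets.append(
                    CeRNATriplet(lnc, mirna.mirna_id, mrna, r, s_l.n_sites, s_m.n_sites)
                )
    triplets.sort(key=lambda t: (t.lncrna_id, t.mirna_id, t.mrna_id))
    return triplets
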