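"""Short-series model-profile clustering over an ordered condition axis.

The method enumerates every integer-valued candidate expression shape over
T ordered conditions (each shape starts at 0 and moves by at most ``c``
units between successive conditions), converts each gene's expression to a
log2-ratio series relative to the first condition, assigns each gene to its
best-correlated shape, and scores each shape's gene count against a
permutation null.  For four conditions and unit steps (c=1) the candidate
set has 3^3 - 1 = 26 non-flat shapes; the monotone-decreasing shape
[0, -1, -1, -2] captures genes that fall from Sham to PD and again from
NLID to LID.

Significance follows the short time-series clustering approach: each
gene's condition series is permuted, re-referenced to its new first
element, and re-assigned; a shape attracting many more genes than its
permutation-expected count is unlikely under the null hypothesis that
condition order carries no signal.  The p-value is the upper binomial
tail with per-gene success probability expected/n.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import ExpressionMatrix

__all__ = [
    "ModelProfileSet",
    "GeneSeries",
    "ProfileAssignment",
    "ProfileSignificance",
    "enumerate_profiles",
    "to_log2_series",
    "assign_profiles",
    "profile_significance",
    "select_pattern_genes",
]


@dataclass(frozen=True)
class ModelProfileSet:
    """The enumerated candidate expression shapes over T ordered conditions.

    Profile ids are assigned in lexicographic order of the shape vectors,
    so they are stable across runs and machines.
    """

    T: int
    c: int
    exclude_flat: bool
    profiles: tuple[tuple[int, ...], ...]

    def __len__(self) -> int:
        return len(self.profiles)

    def id_of(self, shape) -> int:
        shape = tuple(int(x) for x in shape)
        try:
            return self.profiles.index(shape)
        except ValueError:
            raise KeyError(f"shape {shape} not in profile set") from None

    def as_array(self) -> np.ndarray:
        return np.array(self.profiles, dtype=float)


@dataclass
class GeneSeries:
    """A gene's per-condition log2 ratio relative to the first condition."""

    gene_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite series for {self.gene_id}")
        if self.values[0] != 0.0:
            raise ValueError(f"series for {self.gene_id} must start at 0")


@dataclass
class ProfileAssignment:
    gene_id: str
    profile_id: int | None
    similarity: float | None
    reason: str | None = None  # set when unassigned: zero-variance / below-min

    @property
    def assigned(self) -> bool:
        return self.profile_id is not None


@dataclass
class ProfileSignificance:
    profile_id: int
    observed_count: int
    expected_count: float
    p_value: float


def enumerate_profiles(T: int, c: int = 1, exclude_flat: bool = True) -> ModelProfileSet:
    """Exhaustively enumerate candidate shapes.

    Every shape starts at 0 and each successive difference lies in
    [-c, +c]; the flat (all-zero) shape is dropped when ``exclude_flat``.
    The count is (2c+1)^(T-1), minus one if the flat shape is excluded.
    """
    if T < 2:
        raise ValueError(f"need at least 2 ordered conditions, got T={T}")
    if c < 1:
        raise ValueError(f"unit change c must be >= 1, got {c}")
    steps = range(-c, c + 1)
    shapes = []
    for diffs in itertools.product(steps, repeat=T - 1):
        shape = (0, *itertools.accumulate(diffs))
        if exclude_flat and all(x == 0 for x in shape):
            continue
        shapes.append(shape)
    shapes.sort()
    return ModelProfileSet(T=T, c=c, exclude_flat=exclude_flat, profiles=tuple(shapes))


def to_log2_series(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> list[GeneSeries]:
    """Collapse replicates to condition means and take log2 ratios vs the
    first condition: series_t = log2((mean_t + eps) / (mean_0 + eps))."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    means = matrix.condition_means()
    ratios = np.log2(means + pseudocount) - np.log2(means[:, [0]] + pseudocount)
    ratios[:, 0] = 0.0
    return [GeneSeries(g, ratios[i]) for i, g in enumerate(matrix.gene_ids)]


def _similarity_matrix(series_values: np.ndarray, profile_arr: np.ndarray) -> np.ndarray:
    """Pearson correlation of every series against every profile vector.

    Rows with zero variance get NaN similarities (handled by the caller).
    Shapes: series (n, T), profiles (m, T) -> (n, m).
    """
    s = series_values - series_values.mean(axis=1, keepdims=True)
    p = profile_arr - profile_arr.mean(axis=1, keepdims=True)
    s_norm = np.linalg.norm(s, axis=1)
    p_norm = np.linalg.norm(p, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (s @ p.T) / np.outer(s_norm, p_norm)
    sim[s_norm == 0] = np.nan
    return sim


def assign_profiles(
    series: list[GeneSeries],
    profiles: ModelProfileSet,
    min_similarity: float = 0.0,
) -> list[ProfileAssignment]:
    """Assign each gene to the best-correlated shape.

    Genes whose series has zero variance (no change across conditions) or
    whose best correlation falls below ``min_similarity`` come back
    unassigned with a reason code.  Ties go to the smallest profile id,
    which ``np.argmax`` delivers because profile ids follow array order.
    """
    if not series:
        return []
    T = profiles.T
    for s in series:
        if s.values.shape != (T,):
            raise ValueError(
                f"series length {s.values.shape[0]} for {s.gene_id} "
                f"does not match T={T}"
            )
    values = np.vstack([s.values for s in series])
    sim = _similarity_matrix(values, profiles.as_array())
    out = []
    for i, s in enumerate(series):
        if np.isnan(sim[i]).all():
            out.append(ProfileAssignment(s.gene_id, None, None, "zero-variance"))
            continue
        j = int(np.nanargmax(sim[i]))
        best = float(sim[i, j])
        if best < min_similarity:
            out.append(ProfileAssignment(s.gene_id, None, best, "below-min-similarity"))
        else:
            out.append(ProfileAssignment(s.gene_id, j, best))
    return out


def _permutation_counts(
    values: np.ndarray,
    profiles: ModelProfileSet,
    perms: list[tuple[int, ...]],
    min_similarity: float,
) -> np.ndarray:
    """Per-profile assigned-gene counts for each permutation of the
    condition axis.  Each permuted series is re-referenced so its first
    element is 0 (the transform the observed data received)."""
    profile_arr = profiles.as_array()
    counts = np.zeros((len(perms), len(profiles)), dtype=float)
    for k, perm in enumerate(perms):
        permuted = values[:, list(perm)]
        permuted = permuted - permuted[:, [0]]
        sim = _similarity_matrix(permuted, profile_arr)
        valid = ~np.isnan(sim).all(axis=1)
        if valid.any():
            best_j = np.nanargmax(np.where(np.isnan(sim), -np.inf, sim)[valid], axis=1)
            best_v = np.nanmax(sim[valid], axis=1)
            keep = best_v >= min_similarity
            counts[k] = np.bincount(best_j[keep], minlength=len(profiles))
    return counts


def profile_significance(
    assignments: list[ProfileAssignment],
    series: list[GeneSeries],
    profiles: ModelProfileSet,
    permutations: str | int = "exhaustive",
    rng_seed: int | None = None,
    min_similarity: float = 0.0,
    include_identity: bool = True,
) -> list[ProfileSignificance]:
    """Permutation significance of each shape's observed gene count.

    The null permutes the condition order of every gene's series,
    re-references, and re-assigns; ``expected_count`` is the mean assigned
    count across permutations and the p-value is the upper binomial tail
    P(X >= observed) with X ~ Binom(n_genes, expected/n_genes).  For T=4
    the exhaustive null has all 4! = 24 permutations; the identity is
    included by default (conservative) and can be dropped.
    """
    if not any(a.assigned for a in assignments):
        raise ValueError("no assigned genes; nothing to test")
    T = profiles.T
    if permutations == "exhaustive":
        perms = [p for p in itertools.permutations(range(T))]
    else:
        n_draws = int(permutations)
        if n_draws < 10:
            raise ValueError("sampled mode needs at least 10 draws")
        rng = np.random.default_rng(rng_seed)
        perms = [tuple(rng.permutation(T)) for _ in range(n_draws)]
    if not include_identity:
        perms = [p for p in perms if p != tuple(range(T))] or perms
    values = np.vstack([s.values for s in series])
    counts = _permutation_counts(values, profiles, perms, min_similarity)
    expected = counts.mean(axis=0)
    observed = np.zeros(len(profiles), dtype=int)
    for a in assignments:
        if a.assigned:
            observed[a.profile_id] += 1
    n_genes = len(series)
    results = []
    for j in range(len(profiles)):
        p_success = min(max(expected[j] / n_genes, 0.0), 1.0)
        p_val = float(stats.binom.sf(observed[j] - 1, n_genes, p_success))
        results.append(
            ProfileSignificance(
                profile_id=j,
                observed_count=int(observed[j]),
                expected_count=float(expected[j]),
                p_value=min(p_val, 1.0),
            )
        )
    return results


def select_pattern_genes(
    assignments: list[ProfileAssignment],
    significance: list[ProfileSignificance] | None,
    target_shape,
    profiles: ModelProfileSet,
    alpha: float = 0.05,
) -> tuple[list[str], ProfileSignificance | None]:
    """Genes assigned to ``target_shape``, with that shape's significance.

    This reproduces the selection of the monotone-decreasing pattern
    (high in Sham, lower in PD/NLID, lowest in LID).
    """
    pid = profiles.id_of(target_shape)
    genes = [a.gene_id for a in assignments if a.assigned and a.profile_id == pid]
    sig = None
    if significance is not None:
        by_id = {s.profile_id: s for s in significance}
        sig = by_id.get(pid)
    return genes, sig
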