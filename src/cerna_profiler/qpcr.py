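"""qRT-PCR relative quantification and validation correlations.

Relative expression follows the comparative-Ct (2^-ddCt) method: per
sample, dCt = mean Ct(target) - mean Ct(reference gene, e.g. GAPDH);
ddCt = dCt - mean dCt of the calibrator condition (sham by default); the
relative quantity is 2^-ddCt, so the calibrator condition has geometric
mean 1 by construction.  Replicate wells are averaged on the Ct scale.

Validation correlations (expression vs expression, expression vs the
abnormal-involuntary-movements score) are plain Pearson r with a
two-sided t-test p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["CtRow", "CtTable", "RelativeQuantity", "ddct", "pearson_with_score"]


@dataclass
class CtRow:
    sample_id: str
    condition: str
    gene: str
    ct_replicates: list[float]

    def __post_init__(self) -> None:
        if not self.ct_replicates:
            raise ValueError(f"no Ct replicates for {self.sample_id}/{self.gene}")
        for ct in self.ct_replicates:
            if not (0 < ct < 50):
                raise ValueError(
                    f"Ct {ct} out of range (0, 50) for {self.sample_id}/{self.gene}"
                )

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_replicates))


@dataclass
class CtTable:
    rows: list[CtRow] = field(default_factory=list)

    def genes(self) -> set[str]:
        return {r.gene for r in self.rows}

    def mean_ct(self, sample_id: str, gene: str) -> float:
        for r in self.rows:
            if r.sample_id == sample_id and r.gene == gene:
                return r.mean_ct
        raise KeyError(f"no Ct measurement for sample {sample_id!r}, gene {gene!r}")

    def samples_with(self, gene: str) -> list[CtRow]:
        return [r for r in self.rows if r.gene == gene]


@dataclass
class RelativeQuantity:
    sample_id: str
    condition: str
    gene: str
    delta_ct: float
    delta_delta_ct: float
    rq: float  # 2 ** -delta_delta_ct, exactly


def ddct(
    table: CtTable,
    target_gene: str,
    reference_gene: str,
    calibrator_condition: str,
) -> list[RelativeQuantity]:
    """Comparative-Ct relative quantification of ``target_gene``.

    Every sample measuring the target must also measure the reference
    gene; a missing reference measurement is an error naming the sample.
    """
    target_rows = table.samples_with(target_gene)
    if not target_rows:
        raise ValueError(f"no measurements for target gene {target_gene!r}")
    dct = {}
    for row in target_rows:
        try:
            ref = table.mean_ct(row.sample_id, reference_gene)
        except KeyError:
            raise ValueError(
                f"sample {row.sample_id!r} lacks the reference gene "
                f"{reference_gene!r}"
            ) from None
        dct[row.sample_id] = row.mean_ct - ref
    calib = [dct[r.sample_id] for r in target_rows if r.condition == calibrator_condition]
    if not calib:
        raise ValueError(
            f"calibrator condition {calibrator_condition!r} has no samples"
        )
    calib_mean = float(np.mean(calib))
    out = []
    for row in target_rows:
        ddct_val = dct[row.sample_id] - calib_mean
        out.append(
            RelativeQuantity(
                sample_id=row.sample_id,
                condition=row.condition,
                gene=target_gene,
                delta_ct=dct[row.sample_id],
                delta_delta_ct=ddct_val,
                rq=2.0 ** (-ddct_val),
            )
        )
    return out


def pearson_with_score(
    values: Sequence[float], scores: Sequence[float]
) -> tuple[float, float]:
    """Pearson r between paired vectors and its two-sided t-test p-value.

    Used for expression-vs-expression and expression-vs-AIM-score
    correlations across animals.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
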