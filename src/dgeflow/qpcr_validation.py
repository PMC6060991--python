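"""qRT-PCR arithmetic: standard curves, delta-delta-CT folds, concordance.

The dilution-series standard curve regresses mean CT on log10(input amount);
amplification efficiency is 10^(-1/slope) - 1 (a perfect doubling per cycle
gives slope -1/log10(2) ~ -3.3219 and 100% efficiency). Relative expression
uses the delta-delta-CT method with base-2 amplification:

    dCT  = mean CT(target) - mean CT(reference gene), per sample
    ddCT = dCT(test) - dCT(calibrator)
    fold = 2^(-ddCT)

Technical replicates are aggregated by the arithmetic mean of CT before any
delta is taken; their SD is carried for reporting only. An
efficiency-corrected fold (base 1+E) is available as a variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class DilutionSeries:
    """CT values measured on a serial dilution of template."""

    amounts: tuple[float, ...]  # ng, any order; >= 3 distinct points
    ct_values: tuple[tuple[float, ...], ...]  # replicates per amount

    def __post_init__(self) -> None:
        if len(self.amounts) < 3:
            raise ValidationError("a standard curve needs at least 3 dilution points")
        if any(a <= 0 for a in self.amounts):
            raise ValidationError("input amounts must be strictly positive")
        if len(self.ct_values) != len(self.amounts):
            raise ValidationError("one CT replicate group per amount is required")
        if any(len(g) == 0 for g in self.ct_values):
            raise ValidationError("each dilution point needs at least one CT value")


@dataclass(frozen=True)
class QPCRMeasurement:
    """Target and reference-gene CT triplicates for one sample."""

    sample_id: str
    target_ct: tuple[float, ...]
    reference_ct: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.target_ct) == 0:
            raise ValidationError(f"{self.sample_id}: target CT values missing")
        if len(self.reference_ct) == 0:
            raise ValidationError(f"{self.sample_id}: reference CT values missing")
        if any(ct <= 0 for ct in self.target_ct + self.reference_ct):
            raise ValidationError(f"{self.sample_id}: CT values must be positive")

    @property
    def delta_ct(self) -> float:
        return float(np.mean(self.target_ct) - np.mean(self.reference_ct))


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float
    efficiency: float  # fraction; 1.0 == 100%


def standard_curve(series: DilutionSeries) -> StandardCurve:
    """Least-squares fit of mean CT against log10(input amount)."""
    x = np.log10(np.asarray(series.amounts, dtype=float))
    y = np.array([np.mean(g) for g in series.ct_values])
    fit = stats.linregress(x, y)
    if abs(fit.slope) < 1e-12:
        raise ValidationError(
            "standard curve is flat (slope 0): efficiency is undefined"
        )
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency=float(efficiency),
    )


def ddct_fold_change(
    test: QPCRMeasurement,
    calibrator: QPCRMeasurement,
    efficiency: float | None = None,
) -> float:
    """Fold change of the test sample relative to the calibrator.

    With ``efficiency`` given (fraction, e.g. 0.93), the amplification base
    2 is replaced by 1 + efficiency.
    """
    base = 2.0 if efficiency is None else 1.0 + efficiency
    if base <= 1.0:
        raise ValidationError("efficiency must be > 0")
    ddct = test.delta_ct - calibrator.delta_ct
    return float(base ** (-ddct))


def expression_concordance(
    qpcr_log2_folds: Sequence[float],
    seq_log2_folds: Sequence[float],
) -> float:
    """Pearson correlation between qPCR and sequencing log2 fold changes."""
    a = np.asarray(qpcr_log2_folds, dtype=float)
    b = np.asarray(seq_log2_folds, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValidationError("concordance needs two equal-length vectors of >= 3 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("fold changes must be finite")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("correlation undefined: a vector has zero variance")
    return float(stats.pearsonr(a, b)[0])
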