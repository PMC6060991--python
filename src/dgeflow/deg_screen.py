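"""Exact two-library test for differential tag counts, FDR and the DE screen.

Between two DGE libraries of sizes N1 and N2, a gene observed with x tags in
the first library yields a conditional distribution for the count y in the
second library (Audic & Claverie):

    P(y | x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

which is a negative binomial with r = x+1 and success probability
N1/(N1+N2). All probabilities are computed in log space with log-gamma so
x + y up to 1e6 is safe. Significance is judged on a doubled smaller tail,
Benjamini-Hochberg adjusted, combined with a pseudocounted log2 ratio of
library-size-normalized counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .expression import CountMatrix

logger = logging.getLogger(__name__)

#: Stop extending an infinite tail sum once terms have dropped this many
#: nats below the largest term seen; past the mode the terms decay at least
#: geometrically, so the truncated mass is below ~1e-20 of the tail.
_TAIL_DROP_NATS = 60.0
_TAIL_BLOCK = 512


@dataclass(frozen=True)
class ScreenThresholds:
    """Significance cut-offs of the DE screen."""

    fdr_max: float = 0.001
    abs_log2_min: float = 1.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max <= 1):
            raise ValidationError("fdr_max must be in (0, 1]")
        if self.abs_log2_min < 0:
            raise ValidationError("abs_log2_min must be >= 0")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")


@dataclass(frozen=True)
class DEGRecord:
    """One gene in one pairwise library comparison."""

    gene_id: str
    comparison: tuple[str, str]  # (reference library, test library)
    x: int
    y: int
    log2_ratio: float
    p_value: float
    fdr: float
    direction: str  # up / down / ns


def _validate_counts_sizes(x: int, y: int, n1: float, n2: float) -> None:
    if x < 0 or y < 0:
        raise ValidationError("tag counts must be non-negative")
    if int(x) != x or int(y) != y:
        raise ValidationError("tag counts must be integers")
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("library sizes must be positive")


def _log_pmf(ys: np.ndarray, x: int, n1: float, n2: float) -> np.ndarray:
    """log P(y | x) for an array of y values."""
    logr = np.log(n2) - np.log(n1)
    log1pr = np.log1p(n2 / n1)
    ys = np.asarray(ys, dtype=float)
    return (
        ys * logr
        + gammaln(x + ys + 1.0)
        - gammaln(x + 1.0)
        - gammaln(ys + 1.0)
        - (x + ys + 1.0) * log1pr
    )


def ac_probability(y: int, x: int, n1: float, n2: float) -> float:
    """P(y | x): probability of observing y tags in library 2 given x in 1."""
    _validate_counts_sizes(x, y, n1, n2)
    return float(np.exp(_log_pmf(np.array([y]), x, n1, n2)[0]))


def _log_lower_tail(x: int, y: int, n1: float, n2: float) -> float:
    """log P(Y <= y | x), by finite summation."""
    return float(logsumexp(_log_pmf(np.arange(y + 1), x, n1, n2)))


def _log_upper_tail(x: int, y: int, n1: float, n2: float) -> float:
    """log P(Y >= y | x), summed upward in blocks until terms are negligible."""
    blocks = []
    start = y
    running_max = -np.inf
    while True:
        ys = np.arange(start, start + _TAIL_BLOCK)
        lp = _log_pmf(ys, x, n1, n2)
        blocks.append(lp)
        running_max = max(running_max, float(lp.max()))
        # stop only once past the mode (terms decreasing) and far below peak
        if lp[-1] < lp[0] and lp[-1] < running_max - _TAIL_DROP_NATS:
            break
        start += _TAIL_BLOCK
    return float(logsumexp(np.concatenate(blocks)))


def ac_pvalue_two_sided(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided exact p-value: min(1, 2 * smaller tail) of P(.|x).

    The smaller tail is summed directly in log space; the larger one follows
    from the complement (no cancellation risk, it is O(1)).
    """
    _validate_counts_sizes(x, y, n1, n2)
    mean = (x + 1) * n2 / n1
    log_point = _log_pmf(np.array([y]), x, n1, n2)[0]
    if y <= mean:
        lower = np.exp(_log_lower_tail(x, y, n1, n2))
        upper = 1.0 - lower + np.exp(log_point)
    else:
        upper = np.exp(_log_upper_tail(x, y, n1, n2))
        lower = 1.0 - upper + np.exp(log_point)
    return float(min(1.0, 2.0 * min(lower, upper)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_ratio(x: int, y: int, n1: float, n2: float, pseudocount: float = 1.0) -> float:
    """log2 of the pseudocounted, library-size-normalized count ratio (test/ref)."""
    _validate_counts_sizes(x, y, n1, n2)
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    return float(np.log2(((y + pseudocount) / n2) / ((x + pseudocount) / n1)))


def screen_degs(
    matrix: CountMatrix,
    comparison: tuple[str, str],
    thresholds: ScreenThresholds = ScreenThresholds(),
    gene_lengths=None,
) -> pd.DataFrame:
    """Exact-test screen of one library pair of a count matrix.

    Parameters
    ----------
    comparison
        (reference library, test library) labels; the log2 ratio is
        test over reference.
    gene_lengths
        Optional gene_id -> length mapping; when given, RPKM columns for
        both libraries are attached.

    Returns
    -------
    DataFrame with one row per gene observed in either library, columns
    gene_id, x, y, log2_ratio, p_value, fdr, direction. Genes with zero
    tags in both libraries carry no information and are excluded before
    testing so they do not dilute the BH correction.
    """
    ref, test = comparison
    for lib in (ref, test):
        if lib not in matrix.counts.columns:
            raise KeyError(f"library {lib!r} not in count matrix")
    n1 = float(matrix.library_sizes[ref])
    n2 = float(matrix.library_sizes[test])
    xs = matrix.counts[ref].to_numpy()
    ys = matrix.counts[test].to_numpy()
    keep = (xs > 0) | (ys > 0)
    genes = matrix.gene_ids[keep]
    xs, ys = xs[keep], ys[keep]

    pvals = np.array([ac_pvalue_two_sided(x, y, n1, n2) for x, y in zip(xs, ys)])
    fdr = bh_adjust(pvals)
    pc = thresholds.pseudocount
    ratios = np.log2(((ys + pc) / n2) / ((xs + pc) / n1))
    significant = (fdr <= thresholds.fdr_max) & (np.abs(ratios) >= thresholds.abs_log2_min)
    direction = np.where(~significant, "ns", np.where(ratios > 0, "up", "down"))

    out = pd.DataFrame(
        {
            "gene_id": genes,
            "x": xs,
            "y": ys,
            "log2_ratio": ratios,
            "p_value": pvals,
            "fdr": fdr,
            "direction": direction,
        }
    ).reset_index(drop=True)
    if gene_lengths is not None:
        lengths = pd.Series(gene_lengths).reindex(out["gene_id"])
        out.insert(3, "rpkm_ref", 1e9 * out["x"].to_numpy() / (n1 * lengths.to_numpy()))
        out.insert(4, "rpkm_test", 1e9 * out["y"].to_numpy() / (n2 * lengths.to_numpy()))
    return out


def deg_summary(records: pd.DataFrame) -> tuple[int, int]:
    """(number up-regulated, number down-regulated) in a screen table."""
    if len(records) == 0:
        return (0, 0)
    counts = records["direction"].value_counts()
    return int(counts.get("up", 0)), int(counts.get("down", 0))
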