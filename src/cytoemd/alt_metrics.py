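"""Baseline comparison measures: PB statistic, chi-square, Mahalanobis, MFI delta.

These are the measures EMD is benchmarked against.  PB and chi-square bin
both samples with bins derived from the control (probability binning of
Roederer et al.), so a pure location shift past the bin edges saturates
them; the Mahalanobis distance collapses the comparison to the two sample
means; MFI deltas track a single channel's median.  None of them combines
frequency and location the way a transport distance does, which is exactly
the contrast the shift-series experiment exposes.

Formulas (the binned ones operate on occupancy fractions p_i, q_i over the
B control-derived bins, dropping bins empty in both samples):

    ChS(c, t)  = sum_i (p_i - q_i)^2 / (p_i + q_i)        (symmetric chi-square)
    PB(c, t)   = (n_H * ChS - (B - 1)) / sqrt(2 (B - 1))  (standardized T(chi))

with n_H = 2 n_c n_t / (n_c + n_t) the harmonic-mean sample size.  Under the
null of identical distributions n_H * ChS is approximately chi-square with
B - 1 degrees of freedom, so PB has mean ~0 and variance ~1.  Once the test
sample has left every interior control bin, all its mass sits in one
unbounded edge bin: ChS saturates just below its supremum of 2 and PB
plateaus accordingly, no matter how much further the sample moves.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import DegenerateInputError
from .flow_io import EventMatrix
from .signatures import BinningSchema, apply_schema, build_schema

__all__ = [
    "ComparisonScore",
    "pb_statistic",
    "chi_square",
    "mahalanobis",
    "mfi_delta",
    "lower_median",
]


@dataclass(frozen=True)
class ComparisonScore:
    """One measure value for one (control, test) sample pair."""

    measure: str  # EMD | PB | ChS | MD | MFI_delta
    value: float
    channels: tuple[str, ...]
    control_id: str = "control"
    test_id: str = "test"

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise DegenerateInputError(f"{self.measure} score is not finite")

    def to_json(self) -> str:
        return json.dumps(
            {
                "measure": self.measure,
                "value": self.value,
                "channels": list(self.channels),
                "control": self.control_id,
                "test": self.test_id,
            }
        )


def _shared_fractions(
    control: EventMatrix,
    test: EventMatrix,
    schema: Union[BinningSchema, str],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Bin both samples with control-derived bins; drop bins empty in both."""
    if isinstance(schema, str):
        if schema != "auto":
            raise DegenerateInputError(f"schema must be a BinningSchema or 'auto'")
        schema = build_schema(control, "auto")
    c = apply_schema(control, schema)
    t = apply_schema(test, schema)
    keep = (c + t) > 0
    p = c[keep] / c.sum()
    q = t[keep] / t.sum()
    if p.size < 2:
        raise DegenerateInputError(
            f"need at least 2 occupied bins for a binned statistic, got {p.size}"
        )
    return p, q, int(keep.sum())


def chi_square(
    control: EventMatrix,
    test: EventMatrix,
    schema: Union[BinningSchema, str] = "auto",
) -> float:
    """Symmetric chi-square divergence over control-derived bins.

    Computed on occupancy fractions, so it is symmetric under swapping the
    samples and equals 0 for identical frequency vectors; it approaches its
    supremum of 2 as the samples' bin occupancies become disjoint.
    """
    p, q, _ = _shared_fractions(control, test, schema)
    return float(((p - q) ** 2 / (p + q)).sum())


def pb_statistic(
    control: EventMatrix,
    test: EventMatrix,
    schema: Union[BinningSchema, str] = "auto",
) -> float:
    """Probability-binning statistic T(chi), standardized to null mean ~0, SD ~1.

    Grows with distributional difference but saturates once the two samples
    no longer share bins: past that point additional separation carries no
    further evidence against the null, so the statistic plateaus.
    """
    p, q, n_bins = _shared_fractions(control, test, schema)
    chs = float(((p - q) ** 2 / (p + q)).sum())
    n_h = 2.0 * control.n_events * test.n_events / (control.n_events + test.n_events)
    dof = n_bins - 1
    return (n_h * chs - dof) / math.sqrt(2.0 * dof)


def mahalanobis(
    control: EventMatrix,
    test: EventMatrix,
    ridge: float = 0.0,
) -> float:
    """Mahalanobis distance between sample means under pooled covariance.

    sqrt((mu_c - mu_t)' S^-1 (mu_c - mu_t)) with S the pooled sample
    covariance.  ``ridge`` adds epsilon * I for near-singular pools.
    """
    d = control.n_channels
    if control.n_events < d + 1 or test.n_events < d + 1:
        raise DegenerateInputError(
            f"need at least d+1={d + 1} events per sample for a pooled covariance"
        )
    mu_c = control.values.mean(axis=0)
    mu_t = test.values.mean(axis=0)
    s_c = np.cov(control.values, rowvar=False, ddof=1)
    s_t = np.cov(test.values, rowvar=False, ddof=1)
    n_c, n_t = control.n_events, test.n_events
    pooled = ((n_c - 1) * s_c + (n_t - 1) * s_t) / (n_c + n_t - 2)
    pooled = np.atleast_2d(pooled) + ridge * np.eye(d)
    delta = mu_c - mu_t
    try:
        solved = np.linalg.solve(pooled, delta)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(
            f"pooled covariance is singular ({exc}); pass ridge > 0 to regularize"
        ) from exc
    value = float(np.sqrt(delta @ solved))
    if not math.isfinite(value):
        raise DegenerateInputError(
            "pooled covariance is numerically singular; pass ridge > 0 to regularize"
        )
    return value


def lower_median(x: np.ndarray) -> float:
    """Median with the lower-median convention for even-length samples."""
    x = np.sort(np.asarray(x, dtype=float).ravel())
    if x.size == 0:
        raise DegenerateInputError("median of an empty sample")
    return float(x[(x.size - 1) // 2])


def mfi_delta(control: EventMatrix, test: EventMatrix, channel: str) -> float:
    """Signed shift in median fluorescence intensity on one channel."""
    return lower_median(test.column(channel)) - lower_median(control.column(channel))
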