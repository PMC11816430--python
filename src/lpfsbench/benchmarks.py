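"""Observed-score severity benchmarks from the test characteristic curve.

The test characteristic curve (TCC) maps a latent severity value theta to the
expected observed total score, E[T | theta] = sum over items of the expected
item score.  Because the latent scale is identified as N(0, 1) by the
estimation prior, anchoring benchmarks at "latent mean + m SD" reduces to
evaluating the TCC at theta = m.  Continuous thresholds are rounded half
away from zero to suggested integer cut-offs, and respondents are classified
by half-open score intervals (lower bound inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ValidationError
from .irt import GRMItemParams, expected_probs
from .reference import (
    DANISH_COMPARISON_CUTOFFS,
    DEFAULT_MULTIPLIERS,
    MULTIPLIER_PERCENTILE_LABELS,
)


class SeverityClass(str, Enum):
    HEALTHY = "healthy"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"
    EXTREMELY_SEVERE = "extremely_severe"
    SEVERE_OR_EXTREME = "severe_or_extreme"  # pooled top two classes


#: Unpooled class order from the lowest score interval upward.
CLASS_ORDER = (
    SeverityClass.HEALTHY,
    SeverityClass.MILD,
    SeverityClass.MODERATE,
    SeverityClass.SEVERE,
    SeverityClass.EXTREMELY_SEVERE,
)

POOLED_CLASS_ORDER = (
    SeverityClass.HEALTHY,
    SeverityClass.MILD,
    SeverityClass.MODERATE,
    SeverityClass.SEVERE_OR_EXTREME,
)

_BENCHMARK_LABELS = ("mild", "moderate", "severe", "extremely severe")


def expected_item_score(params, theta) -> np.ndarray:
    """E[X | theta] on the 1..K scale: sum over k of k P(X = k | theta)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    probs = expected_probs(params, theta)
    k = np.arange(1, probs.shape[1] + 1)
    return probs @ k


def test_characteristic_curve(items: Sequence, theta) -> np.ndarray:
    """Expected total score at each theta; strictly increasing for valid items."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if len(items) == 0:
        raise ValidationError("at least one item parameter set is required")
    total = np.zeros(len(theta))
    for p in items:
        total += expected_item_score(p, theta)
    return total


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (31.91 -> 32)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


@dataclass(frozen=True)
class SeverityBenchmarks:
    """Continuous thresholds and suggested integer cut-offs per SD multiplier."""

    multipliers: tuple[float, ...]
    continuous: tuple[float, ...]
    cutoffs: tuple[int, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        cont = np.asarray(self.continuous)
        if (np.diff(cont) <= 0).any():
            raise ValidationError("continuous thresholds must be strictly increasing")
        if (np.diff(np.asarray(self.cutoffs)) < 0).any():
            raise ValidationError("integer cut-offs must be non-decreasing")

    def as_table(self, comparison: Sequence[float] | None = DANISH_COMPARISON_CUTOFFS) -> pd.DataFrame:
        rows = {
            "multiplier": list(self.multipliers),
            "percentile": [
                MULTIPLIER_PERCENTILE_LABELS.get(m, "") for m in self.multipliers
            ],
            "label": list(self.labels),
            "continuous_threshold": list(self.continuous),
            "suggested_cutoff": list(self.cutoffs),
        }
        if comparison is not None and len(comparison) == len(self.multipliers):
            rows["comparison_cutoff"] = list(comparison)
        return pd.DataFrame(rows)


def derive_benchmarks(
    items: Sequence[GRMItemParams],
    multipliers: Sequence[float] = DEFAULT_MULTIPLIERS,
) -> SeverityBenchmarks:
    """Evaluate the TCC at each latent-SD multiplier and round to cut-offs."""
    multipliers = tuple(float(m) for m in multipliers)
    cont = test_characteristic_curve(items, np.asarray(multipliers))
    if (np.diff(cont) <= 1e-6).any():
        raise ValidationError(
            "expected scores are not strictly increasing across multipliers; "
            "item parameters imply a flat or non-monotone score curve"
        )
    cutoffs = tuple(round_half_away(c) for c in cont)
    labels = tuple(
        _BENCHMARK_LABELS[i] if i < len(_BENCHMARK_LABELS) else f"level {i + 1}"
        for i in range(len(multipliers))
    )
    return SeverityBenchmarks(
        multipliers=multipliers,
        continuous=tuple(float(c) for c in cont),
        cutoffs=cutoffs,
        labels=labels,
    )


def classify(
    score: int,
    benchmarks: SeverityBenchmarks,
    pool_extreme: bool = False,
    score_range: tuple[int, int] = (12, 48),
) -> SeverityClass:
    """Assign a total score to a severity class via half-open intervals.

    healthy < c1 <= mild < c2 <= moderate < c3 <= severe < c4 <= extreme;
    with pooling the top two classes merge into severe_or_extreme.
    """
    lo, hi = score_range
    if not (lo <= score <= hi):
        raise ValidationError(f"total score {score} outside [{lo}, {hi}]")
    c = benchmarks.cutoffs
    if score < c[0]:
        return SeverityClass.HEALTHY
    if score < c[1]:
        return SeverityClass.MILD
    if score < c[2]:
        return SeverityClass.MODERATE
    if pool_extreme:
        return SeverityClass.SEVERE_OR_EXTREME
    if len(c) >= 4 and score >= c[3]:
        return SeverityClass.EXTREMELY_SEVERE
    return SeverityClass.SEVERE


def classify_scores(
    scores: np.ndarray,
    benchmarks: SeverityBenchmarks,
    pool_extreme: bool = False,
) -> list[SeverityClass]:
    return [classify(int(s), benchmarks, pool_extreme) for s in np.asarray(scores)]


def expected_score_table(
    items: Sequence,
    lower: float = -3.0,
    upper: float = 3.0,
    step: float = 0.5,
) -> pd.DataFrame:
    """Two-column (theta, expected score) table of the TCC on a regular grid."""
    n_steps = int(round((upper - lower) / step))
    theta = lower + step * np.arange(n_steps + 1)
    return pd.DataFrame(
        {"theta": theta, "expected_score": test_characteristic_curve(items, theta)}
    )
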