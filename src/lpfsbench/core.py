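"""Shared data model, configuration, logging and CSV input/output.

Category codes are 1-based everywhere a user sees them (matching the printed
questionnaire, so totals span 12-48); the IRT estimation routines convert to
0-based indices internally at a single boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .reference import ITEM_IDS, MAX_TOTAL, MIN_TOTAL, N_CATEGORIES

log = logging.getLogger("lpfsbench")


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a simple stderr handler to the package logger (idempotent)."""
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        log.addHandler(handler)
    log.setLevel(level)


class ValidationError(ValueError):
    """Raised when an input matrix or table violates an invariant."""


COVARIATE_CONTINUOUS = ("NA", "DT", "DL", "DN", "AN", "age")
COVARIATE_BINARY = ("sex", "rel", "diag", "therapy")
TRAIT_COLUMNS = ("NA", "DT", "DL", "DN", "AN")


@dataclass(frozen=True)
class ResponseMatrix:
    """n x m matrix of integer Likert responses with 1-based category codes."""

    values: np.ndarray
    item_ids: tuple[str, ...] = ITEM_IDS
    n_categories: int = N_CATEGORIES

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValidationError(f"responses must be 2-D, got shape {values.shape}")
        n, m = values.shape
        if n < 1:
            raise ValidationError("at least one respondent is required")
        if m < 2:
            raise ValidationError(f"at least two items are required, got {m}")
        if m != len(self.item_ids):
            raise ValidationError(
                f"{m} response columns but {len(self.item_ids)} item labels"
            )
        if not np.issubdtype(values.dtype, np.integer):
            if np.isnan(np.asarray(values, dtype=float)).any():
                raise ValidationError("missing responses are not allowed")
            as_int = values.astype(int)
            if not np.array_equal(as_int, values.astype(float)):
                raise ValidationError("responses must be integers")
            values = as_int
        bad = (values < 1) | (values > self.n_categories)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"response {values[r, c]} out of range 1..{self.n_categories} "
                f"at row {r}, column {self.item_ids[c]!r}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def zero_based(self) -> np.ndarray:
        """The single 1-based -> 0-based conversion boundary."""
        return self.values - 1


def total_scores(responses: ResponseMatrix) -> np.ndarray:
    """Row sums of the response matrix (12..48 for the full instrument)."""
    return responses.values.sum(axis=1)


@dataclass(frozen=True)
class CovariateFrame:
    """Per-respondent validity covariates, row-aligned with a ResponseMatrix.

    Continuous columns: five PiCD pathological-trait means (NA, DT, DL, DN,
    AN) on the 1-5 instrument scale, plus age in years.  Binary columns
    (0/1): sex (1 = woman), romantic relationship, psychiatric diagnosis,
    psychotherapy seeking.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in TRAIT_COLUMNS:
            if col in df.columns:
                vals = df[col].to_numpy(dtype=float)
                if np.isnan(vals).any():
                    raise ValidationError(f"missing values in covariate {col!r}")
                if (vals < 1).any() or (vals > 5).any():
                    raise ValidationError(f"trait {col!r} outside the 1-5 instrument range")
        for col in COVARIATE_BINARY:
            if col in df.columns:
                vals = df[col].to_numpy()
                if not np.isin(vals, (0, 1)).all():
                    raise ValidationError(f"binary covariate {col!r} must be 0/1")

    @property
    def n(self) -> int:
        return len(self.data)

    def continuous(self) -> list[str]:
        return [c for c in COVARIATE_CONTINUOUS if c in self.data.columns]

    def binary(self) -> list[str]:
        return [c for c in COVARIATE_BINARY if c in self.data.columns]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable pipeline settings.

    quadrature_nodes / quadrature_bound control the latent grid used for
    marginal maximum likelihood; multipliers are the latent-SD anchors of the
    severity benchmarks; pool_extreme merges the top two severity classes for
    group comparisons (small expected counts).
    """

    quadrature_nodes: int = 61
    quadrature_bound: float = 6.0
    em_tol: float = 1e-4
    em_max_cycles: int = 500
    multipliers: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5)
    seed: int = 0
    pool_extreme: bool = True
    parallel_analysis_sims: int = 100

    def __post_init__(self) -> None:
        if self.quadrature_nodes < 21:
            raise ValidationError("quadrature_nodes must be at least 21")
        mult = np.asarray(self.multipliers, dtype=float)
        if (mult <= 0).any() or (np.diff(mult) <= 0).any():
            raise ValidationError("multipliers must be positive and strictly increasing")

    def with_seed(self, seed: int) -> "AnalysisConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# CSV readers / writers


def read_responses(path: str | Path, expected_items: int = 12) -> ResponseMatrix:
    """Read a respondents-by-items CSV with a header row of item labels.

    Any covariate columns present are ignored here; use ``read_covariates``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    item_cols = [c for c in df.columns if c.upper().startswith("LPFS")]
    if not item_cols:
        item_cols = list(df.columns[:expected_items])
    if len(item_cols) != expected_items:
        raise ValidationError(
            f"{path} has {len(item_cols)} item columns, expected {expected_items}"
        )
    sub = df[item_cols]
    if sub.isna().any().any():
        r = int(sub.isna().any(axis=1).idxmax())
        raise ValidationError(f"missing response in row {r} of {path}")
    return ResponseMatrix(values=sub.to_numpy(), item_ids=tuple(item_cols))


def write_responses(
    responses: ResponseMatrix,
    path: str | Path,
    covariates: CovariateFrame | None = None,
) -> None:
    df = pd.DataFrame(responses.values, columns=list(responses.item_ids))
    if covariates is not None:
        if covariates.n != responses.n:
            raise ValidationError("covariate rows do not match response rows")
        df = pd.concat([df, covariates.data.reset_index(drop=True)], axis=1)
    df.to_csv(path, index=False)


def read_covariates(path: str | Path) -> CovariateFrame:
    df = pd.read_csv(path)
    cols = [c for c in COVARIATE_CONTINUOUS + COVARIATE_BINARY if c in df.columns]
    if not cols:
        raise ValidationError(f"{path} contains no recognised covariate columns")
    return CovariateFrame(data=df[cols])


def write_tsv(df: pd.DataFrame, path: str | Path, float_fmt: str = "%.4f") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_fmt)
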