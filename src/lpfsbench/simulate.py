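"""Synthetic cohorts with the statistical structure the analysis assumes.

Item responses are drawn from a unidimensional graded response model with
theta ~ N(mean, sd); the default item parameters are the published Polish
calibration, so the generator doubles as the parameter-recovery fixture.
Validity covariates are linear-in-theta with additive Gaussian noise
(continuous; clipped to the instrument range) or Bernoulli draws from a
logistic link on theta (binary).  The default covariate effects are
illustrative magnitudes consistent with the reported severity-group
contrasts, not population estimates.

One seed drives a splittable generator (numpy SeedSequence), so adding or
removing covariates never perturbs the response draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import CovariateFrame, ResponseMatrix, ValidationError
from .irt import GRMItemParams, grm_cumulative_probs
from .reference import ITEM_IDS, REFERENCE_GRM_PARAMS


def reference_items() -> list[GRMItemParams]:
    """The published 12-item GRM calibration as parameter objects."""
    return [
        GRMItemParams(a=row.a, b=np.array([row.b1, row.b2, row.b3]))
        for row in REFERENCE_GRM_PARAMS.itertuples()
    ]


@dataclass(frozen=True)
class ContinuousCovariateModel:
    """value = intercept + slope * theta + N(0, sd), clipped to clip range."""

    intercept: float
    slope: float
    sd: float
    clip: tuple[float, float] | None = (1.0, 5.0)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("residual SD must be non-negative")


@dataclass(frozen=True)
class BinaryCovariateModel:
    """P(outcome) = logistic(intercept + slope * theta)."""

    intercept: float
    slope: float


def default_covariate_models() -> dict[str, ContinuousCovariateModel | BinaryCovariateModel]:
    """Illustrative covariate-generating models for the default cohort.

    Trait slopes give healthy-vs-impaired contrasts of roughly the reported
    size; anankastia and sex are null covariates (no theta effect), matching
    the study's findings; age declines with severity; binary intercepts match
    the reported marginal prevalences (relationship ~65%, diagnosis ~8%,
    psychotherapy ~13%).
    """
    return {
        "NA": ContinuousCovariateModel(intercept=2.80, slope=0.40, sd=0.55),
        "DT": ContinuousCovariateModel(intercept=2.60, slope=0.38, sd=0.55),
        "DL": ContinuousCovariateModel(intercept=2.25, slope=0.32, sd=0.60),
        "DN": ContinuousCovariateModel(intercept=2.25, slope=0.45, sd=0.58),
        "AN": ContinuousCovariateModel(intercept=3.40, slope=0.0, sd=0.48),
        "age": ContinuousCovariateModel(
            intercept=48.3, slope=-5.0, sd=14.5, clip=(18.0, 81.0)
        ),
        "sex": BinaryCovariateModel(intercept=0.08, slope=0.0),  # P(woman) ~ 0.52
        "rel": BinaryCovariateModel(intercept=0.65, slope=-0.05),
        "diag": BinaryCovariateModel(intercept=-2.45, slope=0.40),
        "therapy": BinaryCovariateModel(intercept=-1.95, slope=0.55),
    }


@dataclass(frozen=True)
class SimulationSpec:
    """Generating model for one synthetic cohort."""

    items: tuple[GRMItemParams, ...] = field(default_factory=lambda: tuple(reference_items()))
    item_ids: tuple[str, ...] = ITEM_IDS
    n: int = 530
    seed: int = 0
    latent_mean: float = 0.0
    latent_sd: float = 1.0
    covariates: Mapping[str, ContinuousCovariateModel | BinaryCovariateModel] = field(
        default_factory=default_covariate_models
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be at least 1")
        if self.latent_sd <= 0:
            raise ValidationError("latent SD must be positive")
        if len(self.items) != len(self.item_ids):
            raise ValidationError("item parameter count must match item labels")

    def rngs(self) -> tuple[np.random.Generator, np.random.Generator]:
        """Independent streams for (responses, covariates) from one seed."""
        children = np.random.SeedSequence(self.seed).spawn(2)
        return (np.random.default_rng(children[0]), np.random.default_rng(children[1]))

    # -- YAML round trip (CLI convenience) -------------------------------
    def to_yaml(self) -> str:
        payload = {
            "n": self.n,
            "seed": self.seed,
            "latent_mean": self.latent_mean,
            "latent_sd": self.latent_sd,
            "items": {
                iid: {"a": float(p.a), "b": [float(x) for x in p.b]}
                for iid, p in zip(self.item_ids, self.items)
            },
            "covariates": {
                name: (
                    {
                        "kind": "continuous",
                        "intercept": m.intercept,
                        "slope": m.slope,
                        "sd": m.sd,
                        "clip": list(m.clip) if m.clip else None,
                    }
                    if isinstance(m, ContinuousCovariateModel)
                    else {"kind": "binary", "intercept": m.intercept, "slope": m.slope}
                )
                for name, m in self.covariates.items()
            },
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationSpec":
        payload = yaml.safe_load(text)
        items = []
        ids = []
        for iid, p in payload["items"].items():
            ids.append(iid)
            items.append(GRMItemParams(a=p["a"], b=np.asarray(p["b"], dtype=float)))
        covs: dict = {}
        for name, m in payload.get("covariates", {}).items():
            if m["kind"] == "continuous":
                clip = tuple(m["clip"]) if m.get("clip") else None
                covs[name] = ContinuousCovariateModel(
                    intercept=m["intercept"], slope=m["slope"], sd=m["sd"], clip=clip
                )
            else:
                covs[name] = BinaryCovariateModel(
                    intercept=m["intercept"], slope=m["slope"]
                )
        return cls(
            items=tuple(items),
            item_ids=tuple(ids),
            n=payload["n"],
            seed=payload.get("seed", 0),
            latent_mean=payload.get("latent_mean", 0.0),
            latent_sd=payload.get("latent_sd", 1.0),
            covariates=covs,
        )


def simulate_responses(
    spec: SimulationSpec, theta: np.ndarray | None = None
) -> tuple[ResponseMatrix, np.ndarray]:
    """Draw GRM responses; returns the matrix and the latent values used.

    A respondent's category is found by comparing one uniform draw with the
    cumulative curves P(X >= k+1 | theta): the category code is 1 plus the
    number of cumulative curves exceeding the draw.
    """
    rng_resp, _ = spec.rngs()
    if theta is None:
        theta = spec.latent_mean + spec.latent_sd * rng_resp.standard_normal(spec.n)
    else:
        theta = np.asarray(theta, dtype=float)
        if len(theta) != spec.n:
            raise ValidationError("theta length must equal spec.n")
    values = np.empty((spec.n, len(spec.items)), dtype=int)
    for i, params in enumerate(spec.items):
        cum = grm_cumulative_probs(params, theta)  # (n, K-1)
        u = rng_resp.uniform(size=spec.n)
        values[:, i] = 1 + (u[:, None] < cum).sum(axis=1)
    return ResponseMatrix(values=values, item_ids=spec.item_ids), theta


def simulate_covariates(theta: np.ndarray, spec: SimulationSpec) -> CovariateFrame:
    """Draw the covariate battery conditional on the latent values."""
    theta = np.asarray(theta, dtype=float)
    if len(theta) != spec.n:
        raise ValidationError("theta length must equal spec.n")
    _, rng_cov = spec.rngs()
    cols: dict[str, np.ndarray] = {}
    for name, model in spec.covariates.items():
        if isinstance(model, ContinuousCovariateModel):
            vals = (
                model.intercept
                + model.slope * theta
                + model.sd * rng_cov.standard_normal(spec.n)
            )
            if model.clip is not None:
                vals = np.clip(vals, *model.clip)
            cols[name] = vals
        else:
            from scipy.special import expit

            p = expit(model.intercept + model.slope * theta)
            cols[name] = (rng_cov.uniform(size=spec.n) < p).astype(int)
    return CovariateFrame(data=pd.DataFrame(cols))


def simulate_cohort(spec: SimulationSpec) -> tuple[ResponseMatrix, CovariateFrame, np.ndarray]:
    responses, theta = simulate_responses(spec)
    covariates = simulate_covariates(theta, spec)
    return responses, covariates, theta
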