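"""Model parameters: values, sampling distributions, validation, and IO.

Every input of the cost-effectiveness model lives in a :class:`ParameterSet`:
age-banded annual cardiovascular event risks, anxiety risk, relative risks
for prior disease and for aircraft-noise exposure, event costs, per-person
exposure (delay) costs, utilities, and the run settings (start age, discount
rate, exposed population).  Stochastic fields carry a
:class:`DistributionSpec` used by the probabilistic sensitivity analysis;
fields without one are treated as fixed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from .distributions import (
    beta_params_from_moments,
    gamma_params_from_moments,
    lognormal_params_from_ci,
)

__all__ = [
    "DistributionSpec",
    "AgeBand",
    "AgeBandedRisk",
    "ParameterSet",
    "default_parameter_set",
    "sample_parameter_set",
    "draw_parameter_arrays",
    "load_parameters",
    "save_parameters",
]

_FAMILIES = ("beta", "gamma", "lognormal", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one scalar parameter.

    ``beta`` and ``gamma`` are parameterised by (mean, se) and fitted by
    moments; ``lognormal`` by (mean, ci_low, ci_high) with a symmetric
    log-scale 95% interval; ``fixed`` never varies.
    """

    family: str
    mean: float
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family == "beta":
            # raises with a named bound if (mean, se) is infeasible
            beta_params_from_moments(self.mean, self.se)
        elif self.family == "gamma":
            gamma_params_from_moments(self.mean, self.se)
        elif self.family == "lognormal":
            lognormal_params_from_ci(self.mean, self.ci_low, self.ci_high)

    def draw(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the fitted distribution (array of ``size`` or scalar)."""
        if self.family == "beta":
            a, b = beta_params_from_moments(self.mean, self.se)
            return rng.beta(a, b, size=size)
        if self.family == "gamma":
            shape, scale = gamma_params_from_moments(self.mean, self.se)
            return rng.gamma(shape, scale, size=size)
        if self.family == "lognormal":
            mu, sigma = lognormal_params_from_ci(self.mean, self.ci_low, self.ci_high)
            return rng.lognormal(mu, sigma, size=size)
        return np.full(size, self.mean) if size is not None else self.mean


@dataclass(frozen=True)
class AgeBand:
    age_low: int
    age_high: int | None  # None = open-ended terminal band
    probability: float
    se: float


@dataclass(frozen=True)
class AgeBandedRisk:
    """Annual event probability by contiguous, non-overlapping age bands."""

    bands: tuple[AgeBand, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("AgeBandedRisk needs at least one band")
        for i, b in enumerate(self.bands):
            if not 0.0 < b.probability < 1.0:
                raise ValueError(
                    f"band {i}: probability {b.probability} outside (0, 1)"
                )
            if b.age_high is not None and b.age_high < b.age_low:
                raise ValueError(f"band {i}: age_high < age_low")
        for prev, nxt in zip(self.bands, self.bands[1:]):
            if prev.age_high is None:
                raise ValueError("open-ended band must be last")
            if nxt.age_low != prev.age_high + 1:
                raise ValueError(
                    f"bands not contiguous at ages {prev.age_high}/{nxt.age_low}"
                )

    @property
    def min_age(self) -> int:
        return self.bands[0].age_low

    def band_index(self, age: float) -> int:
        if age < self.min_age:
            raise ValueError(f"age {age} below risk coverage ({self.min_age}+)")
        for i, b in enumerate(self.bands):
            if b.age_high is None or age <= b.age_high:
                return i
        raise AssertionError("unreachable: last band is open-ended")

    def probability(self, age: float) -> float:
        return self.bands[self.band_index(age)].probability

    def with_probabilities(self, probs) -> "AgeBandedRisk":
        if len(probs) != len(self.bands):
            raise ValueError("probability vector length mismatch")
        return AgeBandedRisk(
            tuple(
                dataclasses.replace(b, probability=float(p))
                for b, p in zip(self.bands, probs)
            )
        )


def _default_cvd_risk() -> AgeBandedRisk:
    return AgeBandedRisk(
        (
            AgeBand(35, 44, 0.0015, 0.0004),
            AgeBand(45, 54, 0.0071, 0.0018),
            AgeBand(55, 64, 0.0149, 0.0037),
            AgeBand(65, 74, 0.0266, 0.0067),
            AgeBand(75, 84, 0.0478, 0.0120),
            AgeBand(85, None, 0.0681, 0.0170),
        )
    )


def _default_distributions() -> dict[str, DistributionSpec]:
    return {
        "p_anxiety_base": DistributionSpec("beta", 0.18, se=0.0070),
        "rr_cvd_prior": DistributionSpec("lognormal", 1.965, ci_low=1.67, ci_high=2.30),
        "rr_anx_cvd": DistributionSpec("lognormal", 1.66, ci_low=1.49, ci_high=1.82),
        "rr_cvd_noise": DistributionSpec("lognormal", 1.14, ci_low=1.08, ci_high=1.20),
        "rr_anx_noise": DistributionSpec("lognormal", 1.79, ci_low=1.00, ci_high=3.06),
        "cost_cvd_direct": DistributionSpec("gamma", 23229.0, se=5807.0),
        "cost_cvd_indirect": DistributionSpec("gamma", 12837.0, se=3209.0),
        "cost_anx_direct": DistributionSpec("gamma", 2814.0, se=704.0),
        "cost_anx_indirect": DistributionSpec("gamma", 313.0, se=78.0),
        "exposure_op_cost_pp": DistributionSpec("gamma", 1516.0, se=379.0),
        "exposure_prod_loss_pp": DistributionSpec("gamma", 238.0, se=59.0),
        "disutil_cvd_event": DistributionSpec("beta", 0.283, se=0.0130),
        # se from the stated 25% coefficient of variation
        "disutil_anxiety": DistributionSpec("beta", 0.16, se=0.04),
        "u_prior_cvd": DistributionSpec("beta", 0.844, se=0.0096),
    }


@dataclass
class ParameterSet:
    """All inputs of the noise-exposure cost-effectiveness model.

    Defaults are the base-case values of the LaGuardia TNNIS departure-route
    analysis (2016 US dollars).
    """

    cvd_risk: AgeBandedRisk = field(default_factory=_default_cvd_risk)
    rr_cvd_prior: float = 1.965
    p_anxiety_base: float = 0.18
    rr_anx_cvd: float = 1.66
    rr_cvd_noise: float = 1.14
    rr_anx_noise: float = 1.79
    anxiety_odds_ratio: float = 2.0
    cost_cvd_direct: float = 23229.0
    cost_cvd_indirect: float = 12837.0
    cost_anx_direct: float = 2814.0
    cost_anx_indirect: float = 313.0
    exposure_op_cost_pp: float = 1516.0
    exposure_prod_loss_pp: float = 238.0
    disutil_cvd_event: float = 0.283
    disutil_anxiety: float = 0.16
    u_prior_cvd: float = 0.844
    u_no_cvd: float = 1.0
    cvd_prevalence_init: float = 0.35
    cvd_case_fatality: float | None = None  # None -> life-table column
    prior_cvd_mort_multiplier: float = 1.0
    start_age: int = 41
    discount_rate: float = 0.03
    population_60db: int = 83_807
    population_65db: int | None = None
    distributions: dict[str, DistributionSpec] = field(
        default_factory=_default_distributions
    )

    # fields drawn in the probabilistic analysis, in a fixed sampling order
    STOCHASTIC_FIELDS = (
        "p_anxiety_base",
        "rr_cvd_prior",
        "rr_anx_cvd",
        "rr_cvd_noise",
        "rr_anx_noise",
        "cost_cvd_direct",
        "cost_cvd_indirect",
        "cost_anx_direct",
        "cost_anx_indirect",
        "exposure_op_cost_pp",
        "exposure_prod_loss_pp",
        "disutil_cvd_event",
        "disutil_anxiety",
        "u_prior_cvd",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        probs = {
            "p_anxiety_base": self.p_anxiety_base,
            "cvd_prevalence_init": self.cvd_prevalence_init,
            "discount_rate": self.discount_rate,
        }
        if self.cvd_case_fatality is not None:
            probs["cvd_case_fatality"] = self.cvd_case_fatality
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("disutil_cvd_event", "disutil_anxiety", "u_prior_cvd", "u_no_cvd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in (
            "cost_cvd_direct",
            "cost_cvd_indirect",
            "cost_anx_direct",
            "cost_anx_indirect",
            "exposure_op_cost_pp",
            "exposure_prod_loss_pp",
        ):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "rr_cvd_prior",
            "rr_anx_cvd",
            "rr_cvd_noise",
            "rr_anx_noise",
            "anxiety_odds_ratio",
            "prior_cvd_mort_multiplier",
        ):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        if self.start_age < self.cvd_risk.min_age:
            raise ValueError(
                f"start_age {self.start_age} below CVD-risk coverage "
                f"({self.cvd_risk.min_age}+)"
            )

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    @property
    def exposure_cost_pp(self) -> float:
        """Annual per-person delay cost borne under the limited-use arm."""
        return self.exposure_op_cost_pp + self.exposure_prod_loss_pp


def default_parameter_set() -> ParameterSet:
    return ParameterSet()


def draw_parameter_arrays(
    base: ParameterSet, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw ``n`` independent parameter vectors as a dict of arrays.

    Keys are the stochastic scalar field names plus ``"cvd_band_probs"``
    (shape ``(n, n_bands)``).  Fields lacking a :class:`DistributionSpec`
    (or specified as ``fixed``) are returned as constant arrays.
    """
    out: dict[str, np.ndarray] = {}
    for name in ParameterSet.STOCHASTIC_FIELDS:
        spec = base.distributions.get(name)
        if spec is None:
            out[name] = np.full(n, getattr(base, name), dtype=float)
        else:
            try:
                out[name] = np.asarray(spec.draw(rng, size=n), dtype=float)
            except ValueError as exc:
                raise ValueError(f"invalid distribution for field {name!r}: {exc}")
    band_cols = []
    for b in base.cvd_risk.bands:
        band_cols.append(
            DistributionSpec("beta", b.probability, se=b.se).draw(rng, size=n)
        )
    out["cvd_band_probs"] = np.column_stack(band_cols)
    return out


def sample_parameter_set(base: ParameterSet, seed: int) -> ParameterSet:
    """One random draw of every stochastic field; deterministic given seed."""
    rng = np.random.default_rng(seed)
    arrays = draw_parameter_arrays(base, 1, rng)
    changes = {
        name: float(arrays[name][0]) for name in ParameterSet.STOCHASTIC_FIELDS
    }
    changes["cvd_risk"] = base.cvd_risk.with_probabilities(
        np.clip(arrays["cvd_band_probs"][0], 1e-12, 1 - 1e-12)
    )
    return base.replace(**changes)


# ---------------------------------------------------------------------------
# YAML IO


def _spec_to_dict(spec: DistributionSpec) -> dict:
    d = {"family": spec.family, "mean": spec.mean}
    if spec.se is not None:
        d["se"] = spec.se
    if spec.ci_low is not None:
        d["ci"] = [spec.ci_low, spec.ci_high]
    return d


def _spec_from_dict(d: Mapping) -> DistributionSpec:
    ci = d.get("ci")
    return DistributionSpec(
        d["family"],
        float(d["mean"]),
        se=float(d["se"]) if "se" in d else None,
        ci_low=float(ci[0]) if ci else None,
        ci_high=float(ci[1]) if ci else None,
    )


def save_parameters(params: ParameterSet, path) -> None:
    doc = {
        "cvd_risk": [
            {
                "age_low": b.age_low,
                "age_high": b.age_high,
                "probability": b.probability,
                "se": b.se,
            }
            for b in params.cvd_risk.bands
        ],
        "values": {
            name: getattr(params, name)
            for name in (
                "rr_cvd_prior",
                "p_anxiety_base",
                "rr_anx_cvd",
                "rr_cvd_noise",
                "rr_anx_noise",
                "anxiety_odds_ratio",
                "cost_cvd_direct",
                "cost_cvd_indirect",
                "cost_anx_direct",
                "cost_anx_indirect",
                "exposure_op_cost_pp",
                "exposure_prod_loss_pp",
                "disutil_cvd_event",
                "disutil_anxiety",
                "u_prior_cvd",
                "u_no_cvd",
                "cvd_prevalence_init",
                "cvd_case_fatality",
                "prior_cvd_mort_multiplier",
                "start_age",
                "discount_rate",
                "population_60db",
                "population_65db",
            )
        },
        "distributions": {
            name: _spec_to_dict(spec) for name, spec in params.distributions.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_parameters(path) -> ParameterSet:
    """Read a :class:`ParameterSet` from a YAML parameter file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    missing = {"cvd_risk", "values"} - set(doc)
    if missing:
        raise ValueError(f"parameter file {path}: missing sections {sorted(missing)}")
    bands = tuple(
        AgeBand(
            int(b["age_low"]),
            None if b.get("age_high") is None else int(b["age_high"]),
            float(b["probability"]),
            float(b["se"]),
        )
        for b in doc["cvd_risk"]
    )
    values = dict(doc["values"])
    for key in ("start_age", "population_60db"):
        if key in values:
            values[key] = int(values[key])
    if values.get("population_65db") is not None:
        values["population_65db"] = int(values["population_65db"])
    dists = {
        name: _spec_from_dict(d) for name, d in (doc.get("distributions") or {}).items()
    }
    kwargs = dict(values)
    if dists:
        kwargs["distributions"] = dists
    return ParameterSet(cvd_risk=AgeBandedRisk(bands), **kwargs)
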