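"""Distribution fitting and epidemiological conversion arithmetic.

Probabilistic sensitivity analysis assigns each model input a sampling
distribution constrained to its natural support: beta for probabilities and
utilities, gamma for costs, log-normal for relative risks.  Published input
tables report only a mean with a standard error or a 95% range, so the rules
here recover distribution parameters from exactly those summaries:

* beta and gamma by the method of moments,
* log-normal by a symmetric 95% interval on the log scale,
* odds ratios converted to relative risks with Zhang & Yu's formula
  ``RR = OR / (1 - p0 + p0 * OR)``.
"""

from __future__ import annotations

import math

__all__ = [
    "beta_params_from_moments",
    "gamma_params_from_moments",
    "lognormal_params_from_ci",
    "or_to_rr",
]

#: z quantile spanning a central 95% normal interval (conventional 1.96).
Z95 = 1.96


def beta_params_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Fit a beta distribution to a (mean, standard error) pair.

    Solves the method-of-moments equations ``alpha + beta = m(1-m)/se^2 - 1``
    and ``alpha = m (alpha + beta)``.

    Parameters
    ----------
    mean : float
        Target mean, strictly inside (0, 1).
    se : float
        Target standard error (standard deviation of the distribution),
        strictly positive and satisfying ``se^2 < mean (1 - mean)``.

    Returns
    -------
    (alpha, beta) : tuple of float
        Positive shape parameters whose implied mean and variance match the
        inputs to machine precision.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie in (0, 1); got {mean}")
    if se <= 0.0:
        raise ValueError(f"beta se must be > 0; got {se}")
    bound = mean * (1.0 - mean)
    if se * se >= bound:
        raise ValueError(
            f"infeasible beta variance: se^2={se * se:.6g} must be below "
            f"mean*(1-mean)={bound:.6g}"
        )
    nu = bound / (se * se) - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_params_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Fit a gamma distribution (shape, scale) to a (mean, standard error) pair.

    ``shape * scale = mean`` and ``shape * scale^2 = se^2``, hence
    ``shape = (mean/se)^2`` and ``scale = se^2/mean``.
    """
    if mean <= 0.0:
        raise ValueError(f"gamma mean must be > 0; got {mean}")
    if se <= 0.0:
        raise ValueError(f"gamma se must be > 0; got {se}")
    shape = (mean / se) ** 2
    scale = se * se / mean
    return shape, scale


def lognormal_params_from_ci(
    mean: float, ci_low: float, ci_high: float
) -> tuple[float, float]:
    """Fit a log-normal distribution to a ratio with a 95% range.

    ``sigma = (ln ci_high - ln ci_low) / (2 * 1.96)`` and ``mu`` is the
    midpoint of the log interval, which keeps the fitted 95% interval exactly
    at the reported range.  A degenerate range (low == high) yields a point
    mass (``sigma = 0``).
    """
    if ci_low <= 0.0 or ci_high <= 0.0:
        raise ValueError(
            f"log-normal interval bounds must be > 0; got ({ci_low}, {ci_high})"
        )
    if ci_low > ci_high:
        raise ValueError(f"ci_low={ci_low} exceeds ci_high={ci_high}")
    if not ci_low <= mean <= ci_high:
        raise ValueError(
            f"mean {mean} falls outside the interval ({ci_low}, {ci_high})"
        )
    sigma = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z95)
    mu = 0.5 * (math.log(ci_low) + math.log(ci_high))
    return mu, sigma


def or_to_rr(odds_ratio: float, baseline_risk: float) -> float:
    """Convert an odds ratio to a relative risk at a given baseline risk.

    ``RR = OR / (1 - p0 + p0 * OR)``.  For ``OR > 1`` the result lies strictly
    between 1 and the odds ratio; it is increasing in the odds ratio and
    decreasing in the baseline risk.
    """
    if odds_ratio <= 0.0:
        raise ValueError(f"odds ratio must be > 0; got {odds_ratio}")
    if not 0.0 < baseline_risk < 1.0:
        raise ValueError(f"baseline risk must lie in (0, 1); got {baseline_risk}")
    return odds_ratio / (1.0 - baseline_risk + baseline_risk * odds_ratio)
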