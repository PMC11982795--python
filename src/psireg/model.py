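"""Mean response of the soil-to-stem water potential gradient.

The daily-maximum water potential gradient ``delta_psi`` is modelled as a
saturating function of vapour pressure deficit whose asymptote ``theta`` and
curvature rate ``lam`` are constant while the soil is wetter than a
changepoint and decay (or grow) exponentially below it:

    delta_psi = theta(psi_soil) * (1 - exp(-lam(psi_soil) * vpd)) + eps

    theta(psi_soil) = theta0                                    psi_soil >= tau
                    = theta0 * exp(-alpha * (tau - psi_soil))   psi_soil <  tau

    lam(psi_soil)   = lambda0                                   psi_soil >= tau
                    = lambda0 * exp(-beta * (tau - psi_soil))   psi_soil <  tau

with ``tau`` the soil water potential changepoint and ``eps ~ N(0, sigma^2)``
residual noise.  Exponential decay keeps both ``theta`` and ``lam`` strictly
positive for any finite soil water potential, and ``alpha = beta = 0``
collapses the surface to the no-changepoint limiting case.

Plant-year levels perturb ``theta0`` and ``lambda0`` multiplicatively through
correlated Gaussian offsets on the log scale, preserving positivity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PopulationParams",
    "RandomEffectSpec",
    "theta_at",
    "lambda_at",
    "mean_delta_psi",
    "vpd_at_fraction",
    "log_likelihood",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PopulationParams:
    """Population-level parameter vector of the changepoint response surface.

    Attributes
    ----------
    theta0 : float
        Asymptote of the gradient at hydrated soil (MPa, > 0).
    lambda0 : float
        Curvature rate at hydrated soil (kPa^-1, > 0).
    alpha : float
        Exponential decay rate of ``theta`` below the changepoint (MPa^-1,
        >= 0); 0 disables the threshold response of the asymptote.
    beta : float
        Exponential rate of change of ``lam`` below the changepoint
        (MPa^-1); negative values make the curvature *increase* as the soil
        dries.
    psi_threshold : float
        Soil water potential changepoint (MPa, <= 0).
    sigma : float
        Residual standard deviation (MPa, > 0).
    """

    theta0: float
    lambda0: float
    alpha: float = 0.0
    beta: float = 0.0
    psi_threshold: float = 0.0
    sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.theta0 <= 0:
            raise ValueError(f"theta0 must be > 0, got {self.theta0}")
        if self.lambda0 <= 0:
            raise ValueError(f"lambda0 must be > 0, got {self.lambda0}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.psi_threshold > 0:
            raise ValueError(
                f"psi_threshold must be <= 0 MPa, got {self.psi_threshold}"
            )

    def to_json(self) -> str:
        """Serialize with unit-annotated keys."""
        return json.dumps(
            {
                "theta0_mpa": self.theta0,
                "lambda0_per_kpa": self.lambda0,
                "alpha_per_mpa": self.alpha,
                "beta_per_mpa": self.beta,
                "psi_threshold_mpa": self.psi_threshold,
                "sigma_mpa": self.sigma,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PopulationParams":
        d = json.loads(text)
        return cls(
            theta0=d["theta0_mpa"],
            lambda0=d["lambda0_per_kpa"],
            alpha=d["alpha_per_mpa"],
            beta=d["beta_per_mpa"],
            psi_threshold=d["psi_threshold_mpa"],
            sigma=d["sigma_mpa"],
        )


@dataclass
class RandomEffectSpec:
    """Correlated plant-year offsets on log(theta0) and log(lambda0).

    ``offsets[level]`` is a 2-vector ``(d_log_theta0, d_log_lambda0)`` so the
    level-specific parameters are ``theta0 * exp(offsets[0])`` and
    ``lambda0 * exp(offsets[1])``.
    """

    sd_log_theta0: float = 0.0
    sd_log_lambda0: float = 0.0
    correlation: float = 0.0
    offsets: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (-1.0 < self.correlation < 1.0):
            raise ValueError(
                f"correlation must lie in (-1, 1), got {self.correlation}"
            )
        if self.sd_log_theta0 < 0 or self.sd_log_lambda0 < 0:
            raise ValueError("random-effect SDs must be >= 0")

    @property
    def covariance(self) -> np.ndarray:
        s1, s2, r = self.sd_log_theta0, self.sd_log_lambda0, self.correlation
        return np.array([[s1 * s1, r * s1 * s2], [r * s1 * s2, s2 * s2]])

    def level_params(self, level: str, p: PopulationParams) -> tuple[float, float]:
        """Return (theta0, lambda0) for one plant-year level."""
        if level not in self.offsets:
            raise KeyError(f"unknown plant-year level: {level!r}")
        off = np.asarray(self.offsets[level], dtype=float)
        return p.theta0 * math.exp(off[0]), p.lambda0 * math.exp(off[1])


def theta_at(psi_soil, p: PopulationParams):
    """Asymptote of the gradient at the given soil water potential.

    Continuous at the changepoint; equal to ``theta0`` at and above it.
    Accepts scalars or arrays.
    """
    psi = np.asarray(psi_soil, dtype=float)
    deficit = np.maximum(p.psi_threshold - psi, 0.0)
    out = p.theta0 * np.exp(-p.alpha * deficit)
    return out if out.ndim else float(out)


def lambda_at(psi_soil, p: PopulationParams):
    """Curvature rate at the given soil water potential (mirror of theta_at)."""
    psi = np.asarray(psi_soil, dtype=float)
    deficit = np.maximum(p.psi_threshold - psi, 0.0)
    out = p.lambda0 * np.exp(-p.beta * deficit)
    return out if out.ndim else float(out)


def mean_delta_psi(vpd, psi_soil, p: PopulationParams):
    """Expected daily-maximum gradient at (vpd, psi_soil).

    ``theta(psi_soil) * (1 - exp(-lam(psi_soil) * vpd))``: zero at vpd = 0,
    strictly increasing in vpd, bounded above by ``theta(psi_soil)``.
    """
    v = np.asarray(vpd, dtype=float)
    if np.any(v < 0):
        raise ValueError("vpd must be >= 0 kPa")
    out = theta_at(psi_soil, p) * -np.expm1(-lambda_at(psi_soil, p) * v)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def vpd_at_fraction(f: float, lam: float) -> float:
    """VPD at which the gradient reaches fraction ``f`` of its asymptote.

    Inverse of the saturating curve: ``-log(1 - f) / lam``.
    """
    if not 0.0 < f < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {f}")
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    return -math.log1p(-f) / lam


def log_likelihood(
    records: Sequence,
    p: PopulationParams,
    re: RandomEffectSpec | None = None,
) -> float:
    """Gaussian log likelihood of observed daily records under the model.

    Each record needs ``delta_psi_max``, ``vpd_max_day``, ``psi_soil_day``
    attributes (or mapping keys) and, when ``re`` carries offsets, a
    ``season_label`` plant-year level present in ``re.offsets``.
    """
    total = 0.0
    for rec in records:
        get = rec.get if isinstance(rec, Mapping) else lambda k, r=rec: getattr(r, k)
        level = get("season_label")
        if re is not None and re.offsets:
            th0, lm0 = re.level_params(level, p)
        else:
            th0, lm0 = p.theta0, p.lambda0
        level_p = PopulationParams(
            theta0=th0,
            lambda0=lm0,
            alpha=p.alpha,
            beta=p.beta,
            psi_threshold=p.psi_threshold,
            sigma=p.sigma,
        )
        mu = mean_delta_psi(get("vpd_max_day"), get("psi_soil_day"), level_p)
        resid = get("delta_psi_max") - mu
        total += (
            -0.5 * _LOG_2PI
            - math.log(p.sigma)
            - 0.5 * (resid / p.sigma) ** 2
        )
    return total
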