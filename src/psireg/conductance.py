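"""Whole-plant diffusive conductance predicted from the gradient surface.

Under constant soil-to-leaf hydraulic conductance, canopy diffusive
conductance is proportional to the water-potential gradient divided by VPD,
so the fitted gradient surface translates directly into a normalized
conductance surface:

    gc(vpd, psi_soil)  ∝  theta(psi_soil) * (1 - exp(-lam(psi_soil) * vpd)) / vpd

The proportionality constant cancels under normalization to the surface
maximum; the vpd -> 0 limit is the analytic value ``theta * lam``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import PopulationParams, lambda_at, theta_at

__all__ = ["gc_relative", "fractional_decline", "gc_surface"]


def gc_relative(vpd, psi_soil, p: PopulationParams, k_soil_plant=None):
    """Un-normalized conductance index at (vpd, psi_soil).

    ``theta(psi) * (1 - exp(-lam(psi) * vpd)) / vpd`` with the continuous
    extension ``theta(psi) * lam(psi)`` at vpd = 0.  ``k_soil_plant`` is an
    optional hook for a user-supplied hydraulic-conductance function of soil
    potential; by default it is constant and cancels on normalization.
    """
    v = np.asarray(vpd, dtype=float)
    if np.any(v < 0):
        raise ValueError("vpd must be >= 0 kPa")
    psi = np.asarray(psi_soil, dtype=float)
    th = theta_at(psi, p)
    lam = lambda_at(psi, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(v == 0, th * lam, th * -np.expm1(-lam * v) / np.where(v == 0, 1.0, v))
    if k_soil_plant is not None:
        out = out * np.asarray(k_soil_plant(psi), dtype=float)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def fractional_decline(vpd_hi: float, psi_soil: float, p: PopulationParams) -> float:
    """Percent decline of conductance from the low-VPD limit to ``vpd_hi``.

    ``100 * (1 - gc(vpd_hi) / gc(0+))`` at fixed soil potential; strictly
    increasing in ``vpd_hi`` because ``(1 - exp(-x)) / x`` is strictly
    decreasing.
    """
    if vpd_hi < 0:
        raise ValueError("vpd_hi must be >= 0")
    return 100.0 * (1.0 - gc_relative(vpd_hi, psi_soil, p) / gc_relative(0.0, psi_soil, p))


def gc_surface(
    p: PopulationParams,
    vpd_grid,
    psi_grid,
    k_soil_plant=None,
) -> pd.DataFrame:
    """Normalized conductance surface on a (vpd, psi_soil) grid.

    Long-format frame ``vpd_kpa, psi_soil_mpa, gc_pct`` with the grid
    maximum at 100%.  A log-scaled soil axis, if wanted, is a plotting
    choice and not applied here.
    """
    vpd_grid = np.atleast_1d(np.asarray(vpd_grid, dtype=float))
    psi_grid = np.atleast_1d(np.asarray(psi_grid, dtype=float))
    if vpd_grid.size == 0 or psi_grid.size == 0:
        raise ValueError("grids must be nonempty")
    vv, pp_ = np.meshgrid(vpd_grid, psi_grid, indexing="ij")
    raw = gc_relative(vv.ravel(), pp_.ravel(), p, k_soil_plant=k_soil_plant)
    pct = (raw / raw.max()) * 100.0  # ties at the max give exactly 100
    return pd.DataFrame(
        {"vpd_kpa": vv.ravel(), "psi_soil_mpa": pp_.ravel(), "gc_pct": pct}
    )
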