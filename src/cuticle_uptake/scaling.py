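"""Dimensional scaling and parameter inference for droplet-array uptake assays.

The dimensionless simulation output ``M(T)`` maps onto dimensional data
through two reference scales fixed by the deposit geometry and the cuticular
transport parameters:

* ``t_ref = r_dep**2 / D_cut`` — the reference time (six times the time for
  a molecule undergoing 3D Brownian motion in the cuticle to travel a mean
  square displacement of ``r_dep**2``, via ``<r^2> = 6 D t``),
* ``m_ref = c_sat_cut * r_dep**3`` — the mass of active ingredient in a cube
  of saturated cuticle with side ``r_dep``.

Fitting the master curve ``mass(t) = n_droplets * m_ref * M(t / t_ref)`` to
measured leaf-extract masses by bounded least squares therefore infers
``D_cut`` and ``c_sat_cut`` directly.  Saturation concentrations are carried
in ppm understood as mass per volume, g m^-3 (equivalently mg L^-1), which
is consistent with a cuticle density near 1 g cm^-3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import CoverageError, DomainError, InsufficientDataError
from .pde import DimlessCurve, loglog_interp

__all__ = [
    "Geometry",
    "TransportParams",
    "FitResult",
    "AssaySchemaError",
    "ASSAY_COLUMNS",
    "compute_Zmax",
    "reference_scales",
    "dimensionalize",
    "fit_uptake",
    "csat_to_Kcw",
    "pathway_criterion_G",
    "load_assay_csv",
    "validate_assay",
]

#: required assay CSV schema (header names)
ASSAY_COLUMNS = ("time_min", "mass_LW_ug", "mass_TL_ug", "batch", "replicate")


class AssaySchemaError(ValueError):
    """An assay table is missing required columns or contains invalid values."""


@dataclass(frozen=True)
class Geometry:
    """Deposit/cuticle geometry of one droplet-array assay.

    Parameters
    ----------
    r_dep_m
        Deposit (droplet contact) disk radius in metres.
    z_max_m
        Cuticle thickness in metres.
    n_droplets
        Droplets applied per leaf (each an independent deposit).
    """

    r_dep_m: float
    z_max_m: float
    n_droplets: int = 1

    def __post_init__(self) -> None:
        if not (self.r_dep_m > 0 and self.z_max_m > 0):
            raise DomainError("r_dep_m and z_max_m must be positive")
        if self.n_droplets < 1:
            raise DomainError("n_droplets must be >= 1")

    @property
    def Z_max(self) -> float:
        """Dimensionless cuticle thickness z_max / r_dep."""
        return self.z_max_m / self.r_dep_m


@dataclass(frozen=True)
class TransportParams:
    """Cuticular and aqueous transport parameters of the active ingredient.

    ``D`` values in m^2 s^-1; saturation concentrations in ppm = g m^-3.
    ``c_sat_aq`` is optional: the partition coefficient ``K_cw`` and the
    pathway criterion ``G`` are only defined when it is known.
    """

    D_cut: float
    c_sat_cut: float
    D_aq: float = 1e-10
    c_sat_aq: float | None = None

    def __post_init__(self) -> None:
        for name in ("D_cut", "c_sat_cut", "D_aq"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")
        if self.c_sat_aq is not None and not self.c_sat_aq > 0:
            raise DomainError("c_sat_aq must be positive when given")


def compute_Zmax(geometry: Geometry) -> float:
    """Dimensionless cuticle thickness ``Z_max = z_max / r_dep``."""
    return geometry.Z_max


def reference_scales(
    geometry: Geometry, D_cut: float, c_sat_cut: float
) -> tuple[float, float]:
    """Reference time (s) and reference mass (g) for given transport parameters.

    ``t_ref = r_dep^2 / D_cut``; ``m_ref = c_sat_cut * r_dep^3`` with
    ``c_sat_cut`` in g m^-3.
    """
    if not (D_cut > 0 and c_sat_cut > 0):
        raise DomainError("D_cut and c_sat_cut must be positive")
    t_ref = geometry.r_dep_m**2 / D_cut
    m_ref = c_sat_cut * geometry.r_dep_m**3
    return t_ref, m_ref


def dimensionalize(
    curve: DimlessCurve, t_ref: float, m_ref: float, n_droplets: int = 1
) -> pd.DataFrame:
    """Convert a dimensionless curve to a dimensional mass-vs-time table.

    Returns a DataFrame with columns ``time_s``, ``time_min``, ``mass_ug``
    (total over the droplet array) and ``rate_ug_min``.
    """
    if not (t_ref > 0 and m_ref > 0 and n_droplets >= 1):
        raise DomainError("t_ref, m_ref must be positive and n_droplets >= 1")
    t_s = curve.T * t_ref
    mass_g = n_droplets * m_ref * curve.M
    rate_g_s = n_droplets * m_ref * curve.rate / t_ref
    return pd.DataFrame(
        {
            "time_s": t_s,
            "time_min": t_s / 60.0,
            "mass_ug": mass_g * 1e6,
            "rate_ug_min": rate_g_s * 1e6 * 60.0,
        }
    )


def validate_assay(
    data: pd.DataFrame,
    applied_dose_ug: float | None = None,
    recovery_rtol: float = 0.5,
) -> pd.DataFrame:
    """Validate an assay table against the required schema and invariants."""
    missing = [c for c in ASSAY_COLUMNS if c not in data.columns]
    if missing:
        raise AssaySchemaError(f"assay table missing required column(s): {missing}")
    bad = data.index[data["time_min"] < 0]
    if len(bad):
        raise AssaySchemaError(f"negative times at rows {list(bad[:5])}")
    for col in ("mass_LW_ug", "mass_TL_ug"):
        bad = data.index[data[col] < 0]
        if len(bad):
            raise AssaySchemaError(f"negative {col} at rows {list(bad[:5])}")
    if applied_dose_ug is not None:
        tot = data["mass_LW_ug"] + data["mass_TL_ug"]
        bad = data.index[tot > applied_dose_ug * (1.0 + recovery_rtol)]
        if len(bad):
            raise AssaySchemaError(
                f"recovered mass exceeds applied dose beyond tolerance at rows "
                f"{list(bad[:5])}"
            )
    return data


def load_assay_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read and validate an assay CSV (schema: time_min, mass_LW_ug, mass_TL_ug, batch, replicate)."""
    df = pd.read_csv(path)
    return validate_assay(df, **kwargs)


@dataclass
class FitResult:
    """Least-squares fit of the dimensionless master curve to assay data."""

    t_ref_hat: float
    m_ref_hat: float
    t_ref_se: float
    m_ref_se: float
    D_cut_hat: float
    c_sat_cut_hat: float
    D_cut_se: float
    c_sat_cut_se: float
    r_squared: float
    residuals_ug: np.ndarray
    fitted: pd.DataFrame
    n_points: int
    geometry: Geometry

    def ci(self, which: str = "D_cut", level_sigma: float = 1.96) -> tuple[float, float]:
        """Normal-theory confidence interval computed on the log scale.

        Log-scale intervals respect positivity and match the relative
        standard errors the optimiser actually measures.
        """
        est, se = {
            "D_cut": (self.D_cut_hat, self.D_cut_se),
            "c_sat_cut": (self.c_sat_cut_hat, self.c_sat_cut_se),
            "t_ref": (self.t_ref_hat, self.t_ref_se),
            "m_ref": (self.m_ref_hat, self.m_ref_se),
        }[which]
        rel = se / est
        return est * np.exp(-level_sigma * rel), est * np.exp(level_sigma * rel)

    def summary(self) -> str:
        return (
            f"D_cut = {self.D_cut_hat:.3g} +/- {self.D_cut_se:.2g} m^2/s; "
            f"c_sat_cut = {self.c_sat_cut_hat:.3g} +/- {self.c_sat_cut_se:.2g} ppm; "
            f"R^2 = {self.r_squared:.4f} (n = {self.n_points})"
        )


def _check_coverage(master: DimlessCurve, T_needed: np.ndarray) -> None:
    lo, hi = master.T[0], master.T[-1]
    # the short-time end extrapolates exactly (Cottrellian power law), so only
    # warn there; beyond the long-time end the shape is not known
    if T_needed.max() > hi * 1.05:
        raise CoverageError(
            f"data imply dimensionless times up to {T_needed.max():.3g} but the "
            f"master curve ends at {hi:.3g}; re-simulate with a larger T_max"
        )


def fit_uptake(
    data: pd.DataFrame,
    master: DimlessCurve,
    geometry: Geometry,
    weights: Sequence[float] | None = None,
) -> FitResult:
    """Infer (t_ref, m_ref) — hence D_cut and c_sat_cut — from assay data.

    Minimises ``sum_i w_i (mass_TL_i - n m_ref M(t_i / t_ref))^2`` over the
    log-parameters with a trust-region-reflective bounded least-squares
    solver; the master curve enters only through log-log interpolation, so it
    is computed once per ``Z_max`` and purely rescaled during optimisation.

    The fitted mass is the leaf-extract (TL) compartment summed over the
    droplet array, droplets being far enough apart to be diffusionally
    independent.  Weights default to uniform.
    """
    validate_assay(data)
    t_s = data["time_min"].to_numpy(dtype=float) * 60.0
    y_ug = data["mass_TL_ug"].to_numpy(dtype=float)
    pos = t_s > 0
    if np.unique(t_s[pos]).size < 3:
        raise InsufficientDataError("need at least 3 distinct positive time points")
    if np.ptp(np.log10(t_s[pos])) < 1.0:
        warnings.warn(
            "assay times span less than one decade; t_ref is weakly constrained",
            stacklevel=2,
        )
    w = np.ones_like(y_ug) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)
    n = geometry.n_droplets

    def model_mass_ug(t_ref: float, m_ref: float) -> np.ndarray:
        M = np.zeros_like(t_s)
        M[pos] = master.M_at(t_s[pos] / t_ref)
        return n * m_ref * 1e6 * M

    # grid initialisation: closed-form optimal m_ref for each candidate t_ref
    t_lo = t_s[pos].min() / master.T[-1]
    t_hi = t_s[pos].max() / master.T[0] * 1e2
    cands = np.geomspace(t_lo, t_hi, 60)
    best = None
    for tr in cands:
        Mi = model_mass_ug(tr, 1.0)
        denom = np.sum(w * Mi**2)
        if denom <= 0:
            continue
        mr = max(np.sum(w * y_ug * Mi) / denom, 1e-300)
        sse = np.sum(w * (y_ug - mr * Mi) ** 2)
        if best is None or sse < best[0]:
            best = (sse, tr, mr)
    if best is None:
        raise InsufficientDataError("could not bracket t_ref from the data")
    _, tr0, mr0 = best

    def resid(theta: np.ndarray) -> np.ndarray:
        t_ref, m_ref = np.exp(theta)
        return sw * (y_ug - model_mass_ug(t_ref, m_ref))

    theta0 = np.log([tr0, mr0])
    lb = theta0 - np.log(1e6)
    ub = theta0 + np.log(1e6)
    sol = least_squares(resid, theta0, bounds=(lb, ub), method="trf", xtol=1e-12)
    if not sol.success:
        raise RuntimeError(f"trust-region fit did not converge: {sol.message}")
    if np.any(np.isclose(sol.x, lb)) or np.any(np.isclose(sol.x, ub)):
        raise RuntimeError(
            "fit converged on a parameter bound; the data do not identify the "
            "scales within the searched range"
        )
    t_ref_hat, m_ref_hat = np.exp(sol.x)
    _check_coverage(master, t_s[pos] / t_ref_hat)

    # linearised covariance in log-parameter space
    dof = max(len(y_ug) - 2, 1)
    s2 = 2.0 * sol.cost / dof
    JTJ = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(JTJ)
    se_log = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    t_ref_se = t_ref_hat * se_log[0]
    m_ref_se = m_ref_hat * se_log[1]

    D_cut_hat = geometry.r_dep_m**2 / t_ref_hat
    c_sat_cut_hat = m_ref_hat / geometry.r_dep_m**3
    yhat = model_mass_ug(t_ref_hat, m_ref_hat)
    residuals = y_ug - yhat
    ss_tot = np.sum(w * (y_ug - np.average(y_ug, weights=w)) ** 2)
    r2 = 1.0 - np.sum(w * residuals**2) / ss_tot if ss_tot > 0 else np.nan
    fitted = pd.DataFrame(
        {"time_min": t_s / 60.0, "mass_TL_ug": y_ug, "fitted_ug": yhat}
    )
    return FitResult(
        t_ref_hat=float(t_ref_hat),
        m_ref_hat=float(m_ref_hat),
        t_ref_se=float(t_ref_se),
        m_ref_se=float(m_ref_se),
        D_cut_hat=float(D_cut_hat),
        c_sat_cut_hat=float(c_sat_cut_hat),
        D_cut_se=float(D_cut_hat * se_log[0]),
        c_sat_cut_se=float(c_sat_cut_hat * se_log[1]),
        r_squared=float(r2),
        residuals_ug=residuals,
        fitted=fitted,
        n_points=len(y_ug),
        geometry=geometry,
    )


def csat_to_Kcw(c_sat_cut: float, c_sat_aq: float) -> tuple[float, float]:
    """Cuticle-water partition coefficient and its log10 from the two solubilities."""
    if not (c_sat_cut > 0 and c_sat_aq > 0):
        raise DomainError("both saturation concentrations must be positive")
    K = c_sat_cut / c_sat_aq
    return K, float(np.log10(K))


def pathway_criterion_G(params: TransportParams) -> tuple[float, str]:
    """Direct-vs-indirect pathway competition criterion.

    ``G = (D_cut c_sat_cut) / (D_aq c_sat_aq)`` compares transport capacity
    through the cuticle by direct particle contact against the
    dissolution-plus-aqueous-diffusion (indirect) route; ``G < 1`` predicts
    indirect dominance.  This product-ratio form matches the symbols the
    criterion is defined with but should be verified against its original
    derivation before quantitative use (see docs/methods.md).
    """
    if params.c_sat_aq is None:
        raise InsufficientDataError(
            "pathway criterion needs the aqueous saturation concentration c_sat_aq"
        )
    G = (params.D_cut * params.c_sat_cut) / (params.D_aq * params.c_sat_aq)
    label = "indirect-dominant" if G < 1 else "direct-dominant"
    return G, label
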