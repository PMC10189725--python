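"""Synthetic uptake-assay and deposit-observation generators.

Emulates the destructive-sampling droplet-array design used for the model's
calibration data: each record is an independent leaf carrying an array of
identical droplets (by default 20 droplets of 0.2 uL at 375 ppm), sampled
once at its time point and split into two recovered compartments — a surface
wash (LW) and a leaf extract (TL).  The noiseless forward model is the
dimensionless master curve rescaled by (t_ref, m_ref); measurement noise is
multiplicative lognormal with unit mean and a stated coefficient of
variation, applied independently to the two compartments.

Everything is driven by one integer seed and is bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .deposit import DepositObservation, applied_dose
from .errors import CoverageError, DomainError
from .pde import DimlessCurve
from .scaling import Geometry, reference_scales

__all__ = ["SynthConfig", "DEFAULT_TIMES_MIN", "gen_assay", "gen_deposit"]

#: default destructive-sampling schedule (minutes): dense within the first
#: hour where the fast uptake regime lives, sparse out to 24 h
DEFAULT_TIMES_MIN = (5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0, 120.0, 360.0, 1440.0)


@dataclass(frozen=True)
class SynthConfig:
    """True parameters and design of a synthetic droplet-array uptake assay.

    Defaults reproduce the reference assay conditions: 20 droplets of 0.2 uL
    of a 375 ppm suspension per leaf, 2 batches of 3 replicates per time
    point, 10% multiplicative measurement noise.
    """

    geometry: Geometry
    D_cut: float
    c_sat_cut: float
    times_min: tuple[float, ...] = DEFAULT_TIMES_MIN
    replicates_per_batch: int = 3
    n_batches: int = 2
    cv: float = 0.10
    droplet_volume_uL: float = 0.2
    concentration_ppm: float = 375.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise DomainError("cv must be >= 0")
        t = np.asarray(self.times_min, dtype=float)
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise DomainError("times_min must be non-negative and strictly increasing")
        if not (self.D_cut > 0 and self.c_sat_cut > 0):
            raise DomainError("true D_cut and c_sat_cut must be positive")

    @property
    def applied_dose_ug(self) -> float:
        return applied_dose(
            self.droplet_volume_uL, self.concentration_ppm, self.geometry.n_droplets
        )


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def noiseless_masses(config: SynthConfig, master: DimlessCurve) -> pd.DataFrame:
    """Forward-model (noise-free) TL and LW masses at the design time points."""
    t_ref, m_ref = reference_scales(config.geometry, config.D_cut, config.c_sat_cut)
    t = np.asarray(config.times_min, dtype=float) * 60.0
    T = t[t > 0] / t_ref
    if T.size and T.max() > master.T[-1] * 1.05:
        raise CoverageError(
            f"design times reach T={T.max():.3g} beyond the master curve end "
            f"{master.T[-1]:.3g}; simulate a wider curve"
        )
    M = np.zeros_like(t)
    M[t > 0] = master.M_at(t[t > 0] / t_ref)
    tl = config.geometry.n_droplets * m_ref * 1e6 * M
    dose = config.applied_dose_ug
    if np.any(tl > dose):
        raise DomainError(
            "configured uptake exceeds the applied dose; the saturated-disk "
            "model no longer applies at these parameters"
        )
    return pd.DataFrame(
        {"time_min": config.times_min, "mass_TL_ug": tl, "mass_LW_ug": dose - tl}
    )


def gen_assay(config: SynthConfig, master: DimlessCurve) -> pd.DataFrame:
    """Generate one synthetic destructive-sampling assay table.

    Returns the standard assay schema (``time_min, mass_LW_ug, mass_TL_ug,
    batch, replicate``), one row per sampled leaf, deterministic under
    ``config.seed``.
    """
    base = noiseless_masses(config, master)
    rng = np.random.default_rng(config.seed)
    rows = []
    for _, rec in base.iterrows():
        for batch in range(1, config.n_batches + 1):
            n = config.replicates_per_batch
            eps_tl = _lognormal_unit_mean(rng, config.cv, n)
            eps_lw = _lognormal_unit_mean(rng, config.cv, n)
            for rep in range(1, n + 1):
                rows.append(
                    {
                        "time_min": rec["time_min"],
                        "mass_LW_ug": rec["mass_LW_ug"] * eps_lw[rep - 1],
                        "mass_TL_ug": rec["mass_TL_ug"] * eps_tl[rep - 1],
                        "batch": batch,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


#: per-field noise CVs accepted by gen_deposit
_PERTURBABLE = (
    "A_total_mm2",
    "ring_area_fraction",
    "ring_thickness_mean_um",
    "mean_particle_volume_um3",
    "solid_density_g_cm3",
    "interior_count_density_per_cm2",
    "x_sep_um",
    "applied_mass_per_droplet_ug",
)


def gen_deposit(
    seed: int,
    template: DepositObservation,
    cvs: dict[str, float] | float = 0.0,
) -> DepositObservation:
    """Perturb a deposit-observation template with lognormal field noise.

    ``cvs`` is either one CV applied to every perturbable field or a mapping
    of field name to CV.  The area-closure invariant is re-imposed after
    perturbation (interior area recomputed from the perturbed total area and
    ring fraction); ring_area_fraction is kept inside (0, 1) by perturbing
    its logit-free ratio and clipping away from the boundaries.
    """
    rng = np.random.default_rng(seed)
    if not isinstance(cvs, dict):
        cvs = {name: float(cvs) for name in _PERTURBABLE}
    unknown = set(cvs) - set(_PERTURBABLE)
    if unknown:
        raise ValueError(f"unknown field(s) in cvs: {sorted(unknown)}")
    updates: dict[str, float] = {}
    for name in _PERTURBABLE:
        cv = cvs.get(name, 0.0)
        value = getattr(template, name)
        if value is None or cv == 0.0:
            continue
        factor = float(_lognormal_unit_mean(rng, cv, 1)[0])
        new = value * factor
        if name == "ring_area_fraction":
            new = float(np.clip(new, 1e-3, 1.0 - 1e-3))
        updates[name] = new
    out = replace(template, A_interior_mm2=None, **updates)
    return out
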