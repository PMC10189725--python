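"""Arithmetic on dried-deposit observations: coffee-ring partition and spacing.

A drying suspension droplet pins its contact line and deposits most of its
solid load in a rim ring (coffee-ring effect), leaving a sparse array of
particles in the interior.  These helpers convert segmented-image statistics
(areas, particle volumes, counts) into the quantities the uptake model
needs: surface mass densities, interparticle spacing, the aqueous
diffusion-zone overlap time, and the ring/interior mass split.

Units are explicit in argument names throughout (areas mm^2, particle
volumes um^3, surface densities ug cm^-2, spacings um, solid density
g cm^-3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InsufficientDataError

__all__ = [
    "DepositObservation",
    "interior_particle_density",
    "spacing_from_density",
    "overlap_time",
    "ring_mass_fraction",
    "applied_dose",
]

#: tolerated relative mismatch between A_interior + ring area and A_total
AREA_CLOSURE_RTOL = 0.05


@dataclass
class DepositObservation:
    """Measured geometry and particle statistics of one dried deposit.

    Attributes
    ----------
    A_total_mm2
        Total deposit area including the interior (mm^2).
    ring_area_fraction
        Fraction of the total area occupied by the rim ring, in (0, 1).
    A_interior_mm2
        Interior (non-ring) area (mm^2); defaults to the closure value
        ``(1 - ring_area_fraction) * A_total_mm2``.
    ring_thickness_mean_um
        Mean radial thickness of the ring (um), informational.
    mean_particle_volume_um3
        Mean per-particle volume from segmented images (um^3).
    solid_density_g_cm3
        Density of the solid active ingredient (g cm^-3).
    interior_count_density_per_cm2
        Particle count per cm^2 in the deposit interior (optional).
    x_sep_um
        Mean interparticle separation in the interior (um), if measured.
    applied_mass_per_droplet_ug
        Applied active-ingredient mass per droplet (ug), informational.
    """

    A_total_mm2: float
    ring_area_fraction: float
    A_interior_mm2: float | None = None
    ring_thickness_mean_um: float | None = None
    mean_particle_volume_um3: float | None = None
    solid_density_g_cm3: float | None = None
    interior_count_density_per_cm2: float | None = None
    x_sep_um: float | None = None
    applied_mass_per_droplet_ug: float | None = None

    def __post_init__(self) -> None:
        if not self.A_total_mm2 > 0:
            raise DomainError("A_total_mm2 must be positive")
        if not 0.0 < self.ring_area_fraction < 1.0:
            raise DomainError("ring_area_fraction must lie in (0, 1)")
        closure = (1.0 - self.ring_area_fraction) * self.A_total_mm2
        if self.A_interior_mm2 is None:
            self.A_interior_mm2 = closure
        else:
            mismatch = abs(self.A_interior_mm2 + self.ring_area_mm2 - self.A_total_mm2)
            if mismatch > AREA_CLOSURE_RTOL * self.A_total_mm2:
                raise DomainError(
                    f"interior + ring area misses A_total by {mismatch:.3g} mm^2 "
                    f"(> {AREA_CLOSURE_RTOL:.0%} of total)"
                )
            elif mismatch > 0:
                warnings.warn(
                    f"area closure mismatch of {mismatch / self.A_total_mm2:.2%} "
                    "tolerated",
                    stacklevel=2,
                )
        for name in (
            "mean_particle_volume_um3",
            "solid_density_g_cm3",
            "interior_count_density_per_cm2",
            "x_sep_um",
            "applied_mass_per_droplet_ug",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DomainError(f"{name} must be non-negative")

    @property
    def ring_area_mm2(self) -> float:
        """Ring area as ring_area_fraction * A_total (the reported convention)."""
        return self.ring_area_fraction * self.A_total_mm2

    def particle_mass_pg(self) -> float:
        """Mean single-particle mass (pg) from volume and solid density."""
        if self.mean_particle_volume_um3 is None or self.solid_density_g_cm3 is None:
            raise InsufficientDataError(
                "particle mass needs mean_particle_volume_um3 and solid_density_g_cm3"
            )
        # um^3 -> cm^3 is 1e-12; g -> pg is 1e12
        return self.mean_particle_volume_um3 * self.solid_density_g_cm3


def interior_particle_density(obs: DepositObservation) -> float:
    """Surface mass density of particles in the deposit interior (ug cm^-2).

    ``count density x mean particle volume x solid density``; needs all three
    statistics on the observation.
    """
    if obs.interior_count_density_per_cm2 is None:
        raise InsufficientDataError(
            "interior_particle_density needs interior_count_density_per_cm2"
        )
    mass_g = obs.particle_mass_pg() * 1e-12
    return obs.interior_count_density_per_cm2 * mass_g * 1e6  # g -> ug


def spacing_from_density(
    surface_density_ug_cm2: float,
    particle_mass_pg: float,
    lattice: str = "square",
) -> float:
    """Mean interparticle separation (um) implied by a surface mass density.

    Assumes one particle per lattice cell: ``x_sep = sqrt(m / sigma)`` on a
    square lattice (the default convention), or the hexagonal-packing
    equivalent ``sqrt(2 m / (sqrt(3) sigma))``.
    """
    if not (surface_density_ug_cm2 > 0 and particle_mass_pg > 0):
        raise DomainError("density and particle mass must be positive")
    area_cm2 = (particle_mass_pg * 1e-12) / (surface_density_ug_cm2 * 1e-6)
    if lattice == "square":
        sep_cm = np.sqrt(area_cm2)
    elif lattice == "hexagonal":
        sep_cm = np.sqrt(2.0 * area_cm2 / np.sqrt(3.0))
    else:
        raise ValueError(f"lattice must be square|hexagonal, got {lattice!r}")
    return float(sep_cm * 1e4)


def overlap_time(x_sep_um: float, D_aq_m2_s: float) -> float:
    """Time (s) for aqueous diffusion zones of neighbouring particles to overlap.

    ``t = x_sep^2 / D_aq``.  Past this time the dissolved concentration at
    the cuticle surface is effectively uniform, which justifies the uniform
    saturated-disk boundary condition of the uptake model.
    """
    if not (x_sep_um > 0 and D_aq_m2_s > 0):
        raise DomainError("x_sep and D_aq must be positive")
    return (x_sep_um * 1e-6) ** 2 / D_aq_m2_s


def ring_mass_fraction(
    obs: DepositObservation,
    interior_density_ug_cm2: float,
    ring_density_ug_cm2: float,
) -> float:
    """Fraction of deposited mass residing in the coffee ring after drying."""
    if interior_density_ug_cm2 < 0 or ring_density_ug_cm2 < 0:
        raise DomainError("densities must be non-negative")
    mm2_to_cm2 = 1e-2
    m_ring = ring_density_ug_cm2 * obs.ring_area_mm2 * mm2_to_cm2
    m_int = interior_density_ug_cm2 * obs.A_interior_mm2 * mm2_to_cm2
    total = m_ring + m_int
    if total == 0:
        raise DomainError("at least one compartment must carry mass")
    return m_ring / total


def applied_dose(
    droplet_volume_uL: float, concentration_ppm: float, n_droplets: int = 1
) -> float:
    """Total applied active-ingredient mass (ug) for a droplet array.

    ppm is read as mg L^-1 (mass per volume of spray liquid).
    """
    if droplet_volume_uL < 0 or concentration_ppm < 0 or n_droplets < 1:
        raise DomainError("volume/concentration must be >= 0 and n_droplets >= 1")
    mg = droplet_volume_uL * 1e-6 * concentration_ppm
    return mg * 1e3 * n_droplets
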