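"""Axisymmetric diffusion simulator for the saturated-disk / wax-reservoir model.

Solves the dimensionless Fickian problem in a thin cuticle slab: a saturated
unit disk (C = 1) on the top face, zero flux on every other boundary (the
"wax reservoir" condition: no escape into the air above or the tissue
below), zero initial concentration.  Lengths are scaled by the deposit
contact radius, so the slab occupies ``0 <= Z <= Z_max``, ``0 <= R <= R_max``
with the contact disk at ``R <= 1, Z = 0``.

Discretisation: vertex-centred finite volumes on a tensor-product grid that
is refined toward the flux singularity at the disk edge (R = 1, Z = 0),
marched with backward Euler on a log-spaced time schedule.  The solver works
on the saturation deficit ``u = 1 - C``; this makes the boundary influx
(``sum g_e u_e`` over disk-adjacent edges) free of floating-point
cancellation even when the rate has decayed by ten orders of magnitude.

An optional Richardson pass (a second march with halved steps, extrapolated
pointwise) removes the leading first-order time-stepping error; a step-size
cap resolves the exponential saturation decay in the 1D plane-sheet mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import (
    ConfigurationError,
    DomainError,
    MassBalanceError,
    SolverError,
)

__all__ = [
    "GridSpec",
    "Grid",
    "ConcentrationField",
    "DimlessCurve",
    "build_grid",
    "step_implicit",
    "simulate_uptake",
    "simulate_1d",
    "simulate_radial_exterior",
]


# --------------------------------------------------------------------------
# curves


def loglog_interp(x, xs, ys, extrapolate: bool = True):
    """Piecewise-linear interpolation of log(ys) vs log(xs).

    Outside the table the end-segment slopes are continued (power-law
    extrapolation), which matches the Cottrellian short-time limit exactly.
    """
    x = np.asarray(x, dtype=float)
    lx, lxs, lys = np.log(x), np.log(xs), np.log(ys)
    out = np.interp(lx, lxs, lys)
    if extrapolate:
        lo = lx < lxs[0]
        hi = lx > lxs[-1]
        if np.any(lo):
            s = (lys[1] - lys[0]) / (lxs[1] - lxs[0])
            out = np.where(lo, lys[0] + s * (lx - lxs[0]), out)
        if np.any(hi):
            s = (lys[-1] - lys[-2]) / (lxs[-1] - lxs[-2])
            out = np.where(hi, lys[-1] + s * (lx - lxs[-1]), out)
    res = np.exp(out)
    return float(res) if res.ndim == 0 else res


@dataclass
class DimlessCurve:
    """Dimensionless uptake curve: times ``T``, cumulative mass ``M``, rate ``dM/dT``."""

    T: np.ndarray
    M: np.ndarray
    rate: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if not (self.T.shape == self.M.shape == self.rate.shape):
            raise ValueError("T, M, rate must have identical shapes")

    def validate(self, quad_rtol: float = 0.05) -> None:
        """Check monotonicity, positivity and the M / integral-of-rate identity."""
        if np.any(self.M < -1e-300):
            raise ValueError("M must be non-negative")
        if np.any(np.diff(self.M) < -1e-9 * np.max(self.M)):
            raise ValueError("M must be non-decreasing")
        if np.any(self.rate <= 0):
            raise ValueError("rate must be strictly positive")
        dT = np.diff(self.T)
        quad = np.concatenate(
            ([0.0], np.cumsum(0.5 * (self.rate[1:] + self.rate[:-1]) * dT))
        )
        # any Riemann sum of the sampled rate lies within the cumulative
        # trapezoid-rectangle gap of `quad`; allow that ambiguity on top of
        # the stated quadrature tolerance
        gap = np.concatenate(
            ([0.0], np.cumsum(0.5 * np.abs(np.diff(self.rate)) * dT))
        )
        dM = self.M - self.M[0]
        scale = max(dM[-1], 1e-300)
        if np.max(np.abs(quad - dM) - gap) > quad_rtol * scale:
            raise ValueError("integral of rate disagrees with M beyond tolerance")

    def M_at(self, T):
        return loglog_interp(T, self.T, self.M)

    def rate_at(self, T):
        return loglog_interp(T, self.T, self.rate)


# --------------------------------------------------------------------------
# grid


@dataclass(frozen=True)
class GridSpec:
    """Mesh and time-schedule parameters for the axisymmetric simulator.

    Parameters
    ----------
    T_min, T_max
        First and last dimensionless output times of interest.  The march
        itself starts ``ramp_decades`` earlier so that the impulsive start
        has healed by ``T_min``.
    steps_per_decade
        Backward-Euler steps per decade of T (log-spaced schedule).
    n_z
        Target number of layers across the cuticle thickness (uniform when
        that resolves the first output time, otherwise graded from the
        surface).
    r_expansion
        Geometric expansion factor of the radial spacing away from the disk
        edge R = 1.
    h_min
        Smallest radial spacing at the edge singularity; default
        ``min(Z_max/4, 1e-3)``.
    R_max
        Outer radial truncation; default ``1 + 6 sqrt(T_max)`` so the
        diffusion front never reaches it.
    dT_cap_factor
        If set, caps the time step at ``dT_cap_factor * Z_max**2``; needed
        only when the exponential plane-sheet decay must be resolved to high
        relative accuracy (the 1D mode sets it automatically).
    richardson
        Run a second march with halved steps and extrapolate away the
        leading O(dT) error.
    solver
        ``"splu"`` (sparse direct, default) or ``"bicgstab"`` (with ILU
        preconditioner).
    """

    T_min: float
    T_max: float
    steps_per_decade: int = 40
    n_z: int = 24
    r_expansion: float = 1.12
    h_min: float | None = None
    R_max: float | None = None
    r_spacing_max: float | None = None
    z_expansion: float = 1.15
    ramp_decades: float = 2.0
    dT_cap_factor: float | None = None
    richardson: bool = True
    solver: str = "splu"
    residual_rtol: float = 1e-10

    def __post_init__(self) -> None:
        if not (0 < self.T_min < self.T_max):
            raise ConfigurationError("need 0 < T_min < T_max")
        if self.steps_per_decade < 4:
            raise ConfigurationError("steps_per_decade must be >= 4")
        if self.n_z < 8:
            raise ConfigurationError("n_z must be >= 8")
        if not (1.0 < self.r_expansion <= 1.25):
            raise ConfigurationError("r_expansion must lie in (1, 1.25]")
        if self.ramp_decades < 1.0:
            raise ConfigurationError("ramp_decades must be >= 1 (start early)")
        if self.solver not in ("splu", "bicgstab"):
            raise ConfigurationError(f"unknown solver {self.solver!r}")

    @property
    def T_start(self) -> float:
        return self.T_min / 10**self.ramp_decades


def _graded_widths(h0: float, total: float, growth: float, h_max: float) -> np.ndarray:
    """Geometric spacing sequence from h0, capped at h_max, scaled to sum to total."""
    widths = []
    h, acc = h0, 0.0
    while acc < total:
        widths.append(h)
        acc += h
        h = min(h * growth, h_max)
    w = np.asarray(widths)
    return w * (total / w.sum())


@dataclass(frozen=True)
class Grid:
    """Tensor-product (R, Z) node set with finite-volume metric arrays."""

    Z_max: float
    r: np.ndarray
    z: np.ndarray
    spec: GridSpec

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.r), len(self.z)

    @property
    def n_nodes(self) -> int:
        return len(self.r) * len(self.z)

    def dirichlet_mask(self) -> np.ndarray:
        """Boolean (nr, nz) mask of saturated disk nodes (Z = 0, R <= 1)."""
        mask = np.zeros(self.shape, dtype=bool)
        mask[self.r <= 1.0 + 1e-12, 0] = True
        return mask

    def control_areas(self) -> np.ndarray:
        """Annular control areas per radial node, pi*(rb_out^2 - rb_in^2)."""
        r = self.r
        rb = np.concatenate(([r[0]], 0.5 * (r[:-1] + r[1:]), [r[-1]]))
        return np.pi * (rb[1:] ** 2 - rb[:-1] ** 2)

    def control_heights(self) -> np.ndarray:
        z = self.z
        zb = np.concatenate(([z[0]], 0.5 * (z[:-1] + z[1:]), [z[-1]]))
        return zb[1:] - zb[:-1]

    def volumes(self) -> np.ndarray:
        """Control volumes, shape (nr, nz)."""
        return np.outer(self.control_areas(), self.control_heights())


def build_grid(Z_max: float, spec: GridSpec) -> Grid:
    """Construct the edge-refined tensor grid for a cuticle of thickness Z_max.

    Radial nodes are spaced ``h_min`` at the disk edge R = 1 and expand
    geometrically toward the axis and toward ``R_max``; the axis R = 0, the
    edge R = 1 and the outer boundary are grid nodes.  Z layers are uniform
    when ``Z_max/n_z`` resolves the first output's diffusion length and
    surface-graded otherwise.
    """
    if not Z_max > 0:
        raise ConfigurationError(f"Z_max must be positive, got {Z_max}")
    h_min = spec.h_min if spec.h_min is not None else min(Z_max / 4.0, 1e-3)
    if h_min > min(Z_max / 4.0, 1e-3) + 1e-15:
        raise ConfigurationError(
            f"h_min={h_min} too coarse; need <= min(Z_max/4, 1e-3)"
        )
    R_max_default = 1.0 + 6.0 * np.sqrt(spec.T_max)
    R_max = spec.R_max if spec.R_max is not None else R_max_default
    if R_max < R_max_default - 1e-12:
        raise ConfigurationError(
            f"R_max={R_max} too small; diffusion front needs >= {R_max_default:.3g}"
        )
    sp_max = (
        spec.r_spacing_max
        if spec.r_spacing_max is not None
        else max(0.1, np.sqrt(spec.T_max) / 5.0)
    )
    # radial: [0, 1] built leftward from the edge, [1, R_max] rightward
    w_in = _graded_widths(h_min, 1.0, spec.r_expansion, min(0.25, sp_max))
    r_in = 1.0 - np.concatenate(([0.0], np.cumsum(w_in)))[::-1]
    r_in[0] = 0.0
    w_out = _graded_widths(h_min, R_max - 1.0, spec.r_expansion, sp_max)
    r_out = 1.0 + np.cumsum(w_out)
    r = np.concatenate((r_in, r_out))
    # axial: uniform when it resolves sqrt(T_min)/8, else surface-graded
    dz_needed = np.sqrt(spec.T_min) / 8.0
    if Z_max / spec.n_z <= dz_needed:
        z = np.linspace(0.0, Z_max, spec.n_z + 1)
    else:
        wz = _graded_widths(dz_needed, Z_max, spec.z_expansion, Z_max / 8.0)
        z = np.concatenate(([0.0], np.cumsum(wz)))
        z[-1] = Z_max
    grid = Grid(Z_max=Z_max, r=r, z=z, spec=spec)
    if grid.n_nodes > 5e5:
        raise ConfigurationError(
            f"grid would have {grid.n_nodes} nodes; refine the spec"
        )
    return grid


# --------------------------------------------------------------------------
# operator assembly


def _edges(grid: Grid):
    """Flattened edge lists (a, b, conductance) of the axisymmetric Laplacian."""
    nr, nz = grid.shape
    r, z = grid.r, grid.z
    A_r = grid.control_areas()
    w_z = grid.control_heights()
    idx = np.arange(nr * nz).reshape(nr, nz)
    # radial edges between (i, j) and (i+1, j)
    rmid = 0.5 * (r[:-1] + r[1:])
    dr = np.diff(r)
    g_r = (2.0 * np.pi * rmid / dr)[:, None] * w_z[None, :]
    ar = idx[:-1, :].ravel()
    br = idx[1:, :].ravel()
    gr = g_r.ravel()
    # axial edges between (i, j) and (i, j+1)
    dz = np.diff(z)
    g_z = A_r[:, None] / dz[None, :]
    az = idx[:, :-1].ravel()
    bz = idx[:, 1:].ravel()
    gz = g_z.ravel()
    return (
        np.concatenate((ar, az)),
        np.concatenate((br, bz)),
        np.concatenate((gr, gz)),
    )


@dataclass(frozen=True)
class _Operator:
    """Stiffness on the unknown (non-Dirichlet) nodes, in deficit form."""

    K: sp.csr_matrix
    V: np.ndarray  # control volumes of unknowns
    flux_vec: np.ndarray  # influx through the disk = flux_vec @ u
    unknown: np.ndarray  # flat indices of unknown nodes
    n_total: int
    #: total control volume of the saturated Dirichlet cells; counted in M(T)
    #: as instantaneously saturated mass, which keeps M second-order accurate
    V_dirichlet: float = 0.0


def _assemble(grid: Grid) -> _Operator:
    a, b, g = _edges(grid)
    mask = grid.dirichlet_mask().ravel()
    n = mask.size
    is_unk = ~mask
    renum = np.full(n, -1, dtype=np.int64)
    unknown = np.flatnonzero(is_unk)
    renum[unknown] = np.arange(unknown.size)
    ua, ub = is_unk[a], is_unk[b]
    both = ua & ub
    rows = np.concatenate((renum[a[both]], renum[b[both]]))
    cols = np.concatenate((renum[b[both]], renum[a[both]]))
    vals = np.concatenate((-g[both], -g[both]))
    diag = np.zeros(unknown.size)
    np.add.at(diag, renum[a[both]], g[both])
    np.add.at(diag, renum[b[both]], g[both])
    flux_vec = np.zeros(unknown.size)
    # edges joining an unknown to a Dirichlet (u = 0) node
    for unk_nodes, sel in ((a, ua & ~ub), (b, ub & ~ua)):
        tgt = renum[unk_nodes[sel]]
        np.add.at(diag, tgt, g[sel])
        np.add.at(flux_vec, tgt, g[sel])
    m = unknown.size
    K = sp.coo_matrix(
        (
            np.concatenate((vals, diag)),
            (
                np.concatenate((rows, np.arange(m))),
                np.concatenate((cols, np.arange(m))),
            ),
        ),
        shape=(m, m),
    ).tocsr()
    vol = grid.volumes().ravel()
    V = vol[unknown]
    V_dir = float(vol[mask].sum())
    return _Operator(
        K=K, V=V, flux_vec=flux_vec, unknown=unknown, n_total=n, V_dirichlet=V_dir
    )


# --------------------------------------------------------------------------
# time marching


def _schedule(T_start: float, T_end: float, steps_per_decade: int, dT_cap: float):
    rho = 10.0 ** (1.0 / steps_per_decade)
    times = [T_start]
    while times[-1] < T_end * (1.0 - 1e-12):
        t = times[-1]
        times.append(min(t * rho, t + dT_cap, T_end))
    return np.asarray(times)


def _refine_schedule(times: np.ndarray) -> np.ndarray:
    """Split every interval at its geometric midpoint (keeps nesting).

    The implicit first step [0, T_start] is split arithmetically.
    """
    mids = np.sqrt(times[:-1] * times[1:])
    out = np.empty(2 * len(times) - 1)
    out[0::2] = times
    out[1::2] = mids
    return np.concatenate(([times[0] / 2.0], out))


def _march(op: _Operator, times: np.ndarray, solver: str, residual_rtol: float):
    """Backward-Euler march of the deficit field; returns (flux, M) at `times`."""
    u = np.ones(op.V.size)
    flux = np.empty(len(times))
    M = np.empty(len(times))
    Mcum, tprev = 0.0, 0.0
    factor_cache: tuple[float, Callable] | None = None
    prec = None
    for k, T in enumerate(times):
        dT = T - tprev
        A = (op.K + sp.diags(op.V / dT)).tocsc()
        b = (op.V / dT) * u
        if solver == "splu":
            if factor_cache is not None and factor_cache[0] == dT:
                lu = factor_cache[1]
            else:
                lu = spla.splu(A)
                factor_cache = (dT, lu)
            u_new = lu.solve(b)
            # one iterative-refinement pass keeps the residual at machine level
            u_new += lu.solve(b - A @ u_new)
            info = 0
        else:
            if prec is None:
                ilu = spla.spilu(A, drop_tol=1e-5, fill_factor=20)
                prec = spla.LinearOperator(A.shape, ilu.solve)
            u_new, info = spla.bicgstab(A, b, x0=u, rtol=1e-12, maxiter=2000, M=prec)
        # normwise backward error: ||r|| / (||A|| ||x|| + ||b||)
        denom = (
            spla.norm(A, np.inf) * np.linalg.norm(u_new, np.inf)
            + np.linalg.norm(b, np.inf)
        )
        res = np.linalg.norm(A @ u_new - b, np.inf) / max(denom, 1e-300)
        if info != 0 or res > residual_rtol:
            raise SolverError(
                f"linear solve failed at T={T:.3g}: info={info}, "
                f"relative residual={res:.3e} (contract {residual_rtol:.1e})"
            )
        u = u_new
        f = float(op.flux_vec @ u)
        Mcum += dT * f
        flux[k] = f
        M[k] = Mcum + op.V_dirichlet
        tprev = T
    # exact discrete identity: cumulative influx == mass deficit swallowed
    M_inv = np.sum(op.V) - float(op.V @ u)
    resid = abs(Mcum - M_inv) / max(M_inv, 1e-300)
    if resid > 1e-2:
        raise MassBalanceError(
            f"cumulative influx and volume-integrated mass differ by {resid:.2%}"
        )
    return flux, M, resid


def _run(op: _Operator, spec: GridSpec, Z_max: float) -> DimlessCurve:
    dT_cap = (
        spec.dT_cap_factor * Z_max**2 if spec.dT_cap_factor is not None else np.inf
    )
    times = _schedule(spec.T_start, spec.T_max, spec.steps_per_decade, dT_cap)
    flux, M, resid = _march(op, times, spec.solver, spec.residual_rtol)
    if spec.richardson:
        times_f = _refine_schedule(times)
        flux_f, M_f, resid_f = _march(op, times_f, spec.solver, spec.residual_rtol)
        fc, ff = flux, flux_f[1::2]
        # safeguarded pointwise extrapolation of the O(dT) error
        flux = ff * np.clip(2.0 - fc / ff, 0.25, 4.0)
        Mc, Mf = M, M_f[1::2]
        M = Mf * np.clip(2.0 - Mc / np.maximum(Mf, 1e-300), 0.25, 4.0)
        M = np.maximum.accumulate(M)
        resid = max(resid, resid_f)
    keep = times >= spec.T_min * (1.0 - 1e-9)
    T, M, flux = times[keep], M[keep], flux[keep]
    # independent rate estimate: centred differencing of M on the log grid
    with np.errstate(divide="ignore", invalid="ignore"):
        rate_from_M = np.gradient(M, np.log(T)) / T
    sig = flux > 1e-3 * flux.max()
    agree = np.max(
        np.abs(rate_from_M[sig] - flux[sig]) / flux[sig]
    ) if np.any(sig) else 0.0
    diag = {
        "mass_balance_residual": resid,
        "rate_agreement_max_reldiff": float(agree),
        "n_steps": len(times),
        "n_unknowns": op.V.size,
    }
    if agree > 0.25:
        raise MassBalanceError(
            f"flux-quadrature and dM/dT rate estimates disagree by {agree:.1%}"
        )
    curve = DimlessCurve(T=T, M=M, rate=flux, diagnostics=diag)
    curve.validate()
    return curve


# --------------------------------------------------------------------------
# public operations


@dataclass
class ConcentrationField:
    """Dimensionless concentration C on the (R, Z) node set of a grid."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def validate(self, atol: float = 1e-9) -> None:
        """Maximum principle (0 <= C <= 1) and saturated disk nodes."""
        if np.any(self.values < -atol) or np.any(self.values > 1 + atol):
            raise ValueError("concentration violates the maximum principle")
        disk = self.grid.dirichlet_mask()
        if not np.allclose(self.values[disk], 1.0, atol=atol):
            raise ValueError("disk boundary nodes must be saturated (C = 1)")

    @classmethod
    def initial(cls, grid: Grid) -> "ConcentrationField":
        """Zero concentration everywhere except the saturated disk."""
        v = np.zeros(grid.shape)
        v[grid.dirichlet_mask()] = 1.0
        return cls(grid=grid, values=v)


def step_implicit(
    field: ConcentrationField, dT: float, grid: Grid | None = None
) -> ConcentrationField:
    """One backward-Euler step of the axisymmetric diffusion problem.

    Solves ``(I - dT L) C_new = C_old`` with the saturated-disk Dirichlet
    condition and zero-flux (wax reservoir, symmetry axis, outer truncation)
    conditions built into the discrete operator.
    """
    if not dT > 0:
        raise DomainError("dT must be positive")
    grid = grid if grid is not None else field.grid
    op = _assemble(grid)
    u = 1.0 - field.values.ravel()[op.unknown]
    A = (op.K + sp.diags(op.V / dT)).tocsc()
    b = (op.V / dT) * u
    u_new = spla.splu(A).solve(b)
    res = np.linalg.norm(A @ u_new - b) / max(np.linalg.norm(b), 1e-300)
    if res > grid.spec.residual_rtol:
        raise SolverError(f"implicit step residual {res:.3e} exceeds contract")
    values = np.ones(op.n_total)
    values[op.unknown] = 1.0 - u_new
    return ConcentrationField(grid=grid, values=values.reshape(grid.shape))


def simulate_uptake(Z_max: float, spec: GridSpec) -> DimlessCurve:
    """Full axisymmetric simulation of dimensionless uptake M(T) and dM/dT.

    Marches the implicit stepper from a zero-concentration initial state over
    a log-spaced schedule starting two decades before ``spec.T_min``.  The
    primary rate is the discrete boundary-flux quadrature (exact for the
    discrete system); a centred-difference ``dM/dT`` estimate is kept as a
    cross-check and the two must agree where the rate is significant.
    """
    grid = build_grid(Z_max, spec)
    op = _assemble(grid)
    return _run(op, spec, Z_max)


def _assemble_1d_slab(Z_max: float, n_layers: int) -> _Operator:
    """Plane-sheet operator: saturated face at z=0, impermeable back, unit area.

    Flux and mass are per unit area; callers multiply by the disk area pi.
    """
    dz = Z_max / n_layers
    m = n_layers  # unknowns: nodes 1..n (node 0 is Dirichlet)
    V = np.full(m, dz)
    V[-1] = dz / 2.0
    g = 1.0 / dz
    main = np.full(m, 2.0 * g)
    main[-1] = g
    K = sp.diags(
        [np.full(m - 1, -g), main, np.full(m - 1, -g)], [-1, 0, 1]
    ).tocsr()
    flux_vec = np.zeros(m)
    flux_vec[0] = g
    return _Operator(
        K=K, V=V, flux_vec=flux_vec, unknown=np.arange(1, m + 1),
        n_total=m + 1, V_dirichlet=dz / 2.0,
    )


def simulate_1d(Z_max: float, spec: GridSpec) -> DimlessCurve:
    """1D plane-sheet reference mode: disk covering the whole top face.

    Identical physics with no radial pathway; the numerical analogue of the
    Crank series solution.  The time step is capped at ``1e-4 * Z_max**2`` in
    the saturation-decay phase so the exponential decay rate is resolved to
    a few tenths of a percent.
    """
    if not Z_max > 0:
        raise ConfigurationError(f"Z_max must be positive, got {Z_max}")
    n_layers = max(200, spec.n_z)
    cap = spec.dT_cap_factor if spec.dT_cap_factor is not None else 1e-4
    spec_1d = replace(spec, dT_cap_factor=cap, richardson=False)
    op = _assemble_1d_slab(Z_max, n_layers)
    curve = _run(op, spec_1d, Z_max)
    # per-unit-area -> whole-disk quantities
    return DimlessCurve(
        T=curve.T,
        M=np.pi * curve.M,
        rate=np.pi * curve.rate,
        diagnostics=curve.diagnostics,
    )


def _assemble_radial_exterior(
    T_min: float, T_max: float, expansion: float = 1.08
) -> _Operator:
    """Exterior-of-cylinder operator: saturated surface at R=1, unit height."""
    h0 = min(np.sqrt(T_min / 100.0) / 4.0, 1e-2)
    R_max = 1.0 + 8.0 * np.sqrt(T_max)
    w = _graded_widths(h0, R_max - 1.0, expansion, np.sqrt(T_max) / 2.0)
    r = 1.0 + np.concatenate(([0.0], np.cumsum(w)))
    rb = np.concatenate(([r[0]], 0.5 * (r[:-1] + r[1:]), [r[-1]]))
    V_all = np.pi * (rb[1:] ** 2 - rb[:-1] ** 2)  # 2*pi*r*dr, unit height
    g_all = 2.0 * np.pi * 0.5 * (r[:-1] + r[1:]) / np.diff(r)
    m = len(r) - 1  # node 0 (R = 1) is Dirichlet
    diag = np.zeros(m)
    np.add.at(diag, np.arange(m - 1), g_all[1:])
    np.add.at(diag, np.arange(1, m), g_all[1:])
    diag[0] += g_all[0]
    K = sp.diags([-g_all[1:], diag, -g_all[1:]], [-1, 0, 1]).tocsr()
    flux_vec = np.zeros(m)
    flux_vec[0] = g_all[0]
    return _Operator(
        K=K, V=V_all[1:], flux_vec=flux_vec, unknown=np.arange(1, m + 1),
        n_total=m + 1, V_dirichlet=float(V_all[0]),
    )


def simulate_radial_exterior(
    T_min: float,
    T_max: float,
    steps_per_decade: int = 80,
    richardson: bool = True,
) -> DimlessCurve:
    """1D radial diffusion outward from a saturated unit-radius cylinder.

    Returns the flux density per unit cylinder area as ``rate`` (and its
    cumulative integral as ``M``).  This is the independent numerical oracle
    for the cylinder-limit closed form: multiply by ``A_c = 2 pi Z_max`` to
    compare with ``limits.cylinder_rate``.
    """
    spec = GridSpec(
        T_min=T_min,
        T_max=T_max,
        steps_per_decade=steps_per_decade,
        richardson=richardson,
    )
    op = _assemble_radial_exterior(T_min, T_max)
    curve = _run(op, spec, 1.0)
    area = 2.0 * np.pi  # unit-height lateral area of the unit cylinder
    return DimlessCurve(
        T=curve.T,
        M=curve.M / area,
        rate=curve.rate / area,
        diagnostics=curve.diagnostics,
    )
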