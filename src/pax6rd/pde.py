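"""Method-of-lines discretisation and time integration.

Space is discretised with second-order central differences on a regular
grid: a 1D line with periodic or zero-flux ends, or a 2D raster restricted
to a boolean tissue mask.  Zero-flux boundaries use ghost-node reflection
(the ghost value mirrors the interior neighbour), so the discrete flux
across the boundary — and across the mask edge in 2D — is exactly zero;
explants exchange no material with the bathing medium.  Time stepping is
explicit Euler with an enforced diffusive stability bound.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage.measure import label as cc_label

from .model import FieldState, ShhField, SPECIES, VARIANTS
from .params import ModelParameters

__all__ = [
    "Grid1D",
    "DomainMask2D",
    "SolverSettings",
    "SimulationResult",
    "StabilityBoundError",
    "IntegrationError",
    "laplacian_1d",
    "laplacian_2d_masked",
    "integrate",
]

BOUNDARIES = ("zero_flux", "periodic")


class StabilityBoundError(ValueError):
    """The requested time step violates the explicit diffusive bound."""


class IntegrationError(RuntimeError):
    """Non-finite fields encountered during time stepping."""

    def __init__(self, message: str, t: float, state: FieldState | None = None):
        super().__init__(message)
        self.t = t
        self.diagnostic_state = state


@dataclass(frozen=True)
class Grid1D:
    """Uniform 1D grid of cell centres."""

    n_points: int
    dx: float
    boundary: str = "zero_flux"

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError(f"n_points must be >= 3, got {self.n_points}")
        if self.dx <= 0:
            raise ValueError(f"dx must be > 0, got {self.dx}")
        if self.boundary not in BOUNDARIES:
            raise ValueError(f"boundary must be one of {BOUNDARIES}, got {self.boundary!r}")

    @property
    def length(self) -> float:
        return self.n_points * self.dx

    @property
    def shape(self) -> tuple[int, ...]:
        return (self.n_points,)

    @property
    def x(self) -> np.ndarray:
        """Cell-centre coordinates."""
        return (np.arange(self.n_points) + 0.5) * self.dx


@dataclass
class DomainMask2D:
    """Boolean raster of a tissue-shaped 2D domain (True = tissue).

    Row-major raster, origin top-left, x rightward (columns), y downward
    (rows); orientation angles are measured from the +x axis.  Zero-flux
    boundary conditions apply on the mask edge.
    """

    mask: np.ndarray
    dx: float
    long_axis: float | None = None
    short_axis: float | None = None
    orientation_deg: float = 0.0
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {self.mask.shape}")
        if self.dx <= 0:
            raise ValueError(f"dx must be > 0, got {self.dx}")
        n_interior = int(self.mask.sum())
        if n_interior == 0:
            raise ValueError("mask is empty")
        n_components = int(cc_label(self.mask, connectivity=1).max())
        if n_components != 1:
            raise ValueError(f"mask must have exactly one connected component, found {n_components}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape

    @property
    def n_interior(self) -> int:
        return int(self.mask.sum())

    @property
    def boundary(self) -> str:
        return "zero_flux"

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) cell-centre coordinate rasters in physical units."""
        ny, nx = self.mask.shape
        x = (np.arange(nx) + 0.5) * self.dx
        y = (np.arange(ny) + 0.5) * self.dx
        return np.meshgrid(x, y)


@dataclass(frozen=True)
class SolverSettings:
    """Explicit-Euler integration settings.

    ``dt=None`` selects the largest step satisfying both the diffusive
    bound dt <= dx^2/(4*max D) and a reaction-resolution cap.
    """

    t_end: float
    dt: float | None = None
    snapshot_interval: float | None = None
    rng_seed: int = 0
    integrator: str = "euler"
    backend: str = "auto"  # auto | numba | numpy
    safety: float = 0.9

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError(f"t_end must be > 0, got {self.t_end}")
        if self.dt is not None and self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.integrator != "euler":
            raise ValueError(f"unknown integrator {self.integrator!r}")


@dataclass
class SimulationResult:
    """Time-stamped snapshots of the field state plus run metadata."""

    times: np.ndarray
    snapshots: np.ndarray  # (n_snapshots, 5, *grid) in SPECIES order
    params: ModelParameters
    variant: str
    geometry: Grid1D | DomainMask2D
    seed: int | None = None
    scenario: str | None = None
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.snapshots = np.asarray(self.snapshots, dtype=float)
        if len(self.times) != len(self.snapshots):
            raise ValueError("times and snapshots length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("snapshot timestamps must be strictly increasing")

    @property
    def n_snapshots(self) -> int:
        return len(self.times)

    def state(self, index: int = -1) -> FieldState:
        return FieldState.from_stack(self.snapshots[index])

    @property
    def final_state(self) -> FieldState:
        return self.state(-1)

    def species_series(self, species: str, point) -> np.ndarray:
        """Time series of one species at a fixed probe point (grid index)."""
        i = SPECIES.index(species)
        idx = (slice(None), i) + (tuple(np.atleast_1d(point)) if not np.isscalar(point) else (point,))
        return self.snapshots[idx]

    def content_hash(self) -> str:
        """SHA-256 over timestamps and snapshot bytes (determinism checks)."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.times).tobytes())
        h.update(np.ascontiguousarray(self.snapshots).tobytes())
        return h.hexdigest()


def laplacian_1d(field: np.ndarray, dx: float, boundary: str = "zero_flux") -> np.ndarray:
    """Second-order central-difference Laplacian on a 1D grid.

    Zero-flux ends use ghost-node reflection (ghost = first interior
    neighbour) so the boundary flux vanishes exactly; periodic wraps.
    Also accepts stacked (n_species, n) arrays (the last axis is spatial).
    """
    field = np.asarray(field, dtype=float)
    n = field.shape[-1]
    if n < 3:
        raise ValueError(f"field must have length >= 3, got {n}")
    if boundary == "periodic":
        left = np.roll(field, 1, axis=-1)
        right = np.roll(field, -1, axis=-1)
    elif boundary == "zero_flux":
        left = np.empty_like(field)
        right = np.empty_like(field)
        left[..., 1:] = field[..., :-1]
        left[..., 0] = field[..., 0]  # ghost mirrors across the face: zero flux
        right[..., :-1] = field[..., 1:]
        right[..., -1] = field[..., -1]
    else:
        raise ValueError(f"boundary must be one of {BOUNDARIES}, got {boundary!r}")
    return (left + right - 2.0 * field) / (dx * dx)


class _MaskedLaplacian:
    """Precomputed 5-point stencil on a masked raster with mirrored ghosts.

    A neighbour outside the mask is replaced by the centre value (ghost
    reflection), i.e. it simply drops out of the difference — the discrete
    normal flux across the mask edge is exactly zero, and total mass on the
    mask is conserved under pure diffusion.
    """

    def __init__(self, mask: np.ndarray, dx: float):
        self.mask = np.asarray(mask, dtype=bool)
        self.dx2 = dx * dx
        m = self.mask
        pad = np.pad(m, 1, constant_values=False)
        # neighbour-inside indicators, aligned with the unpadded raster
        self.up = pad[:-2, 1:-1] & m
        self.down = pad[2:, 1:-1] & m
        self.left = pad[1:-1, :-2] & m
        self.right = pad[1:-1, 2:] & m

    def __call__(self, field: np.ndarray) -> np.ndarray:
        f = np.asarray(field, dtype=float)
        # accumulate (neighbour - centre) over the in-mask neighbours
        up, down, left, right = self.up, self.down, self.left, self.right
        diff = np.zeros_like(f)
        diff[..., 1:, :] += np.where(up[1:, :], f[..., :-1, :] - f[..., 1:, :], 0.0)
        diff[..., :-1, :] += np.where(down[:-1, :], f[..., 1:, :] - f[..., :-1, :], 0.0)
        diff[..., :, 1:] += np.where(left[:, 1:], f[..., :, :-1] - f[..., :, 1:], 0.0)
        diff[..., :, :-1] += np.where(right[:, :-1], f[..., :, 1:] - f[..., :, :-1], 0.0)
        return np.where(self.mask, diff, 0.0) / self.dx2


def laplacian_2d_masked(field: np.ndarray, dx: float, mask: np.ndarray) -> np.ndarray:
    """5-point Laplacian on a masked raster; zero normal flux at mask edge.

    Output is zero outside the mask.  ``field`` may carry leading axes
    (e.g. the species axis); the trailing two axes must match the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    field = np.asarray(field, dtype=float)
    if field.shape[-2:] != mask.shape:
        raise ValueError(f"field shape {field.shape} incompatible with mask {mask.shape}")
    n_components = int(cc_label(mask, connectivity=1).max())
    if n_components != 1:
        raise ValueError(f"mask must have exactly one connected component, found {n_components}")
    return _MaskedLaplacian(mask, dx)(field)


def max_stable_dt(geometry: Grid1D | DomainMask2D, params: ModelParameters) -> float:
    """Diffusive explicit-Euler bound dt <= dx^2 / (4 * max D)."""
    d_max = max(params.diffusivities)
    if d_max == 0:
        return np.inf
    return geometry.dx**2 / (4.0 * d_max)


def _default_dt(geometry, params: ModelParameters, safety: float) -> float:
    diff_bound = max_stable_dt(geometry, params)
    # resolve the fastest linear reaction timescale as well
    p = params
    scale = max(p.R_tot, p.K_hill, 1.0)
    fastest = max(
        p.delta_P, p.delta_F, p.delta_T, p.delta_C,
        p.k_off, p.k_u, p.k_on * scale, p.k_b * scale, 1e-12,
    )
    react_bound = 0.2 / fastest
    dt = safety * min(diff_bound, react_bound)
    if not np.isfinite(dt):
        dt = 0.01
    return dt


def integrate(
    params: ModelParameters,
    initial: FieldState,
    geometry: Grid1D | DomainMask2D,
    shh: ShhField | None = None,
    variant: str = "B",
    settings: SolverSettings | None = None,
) -> SimulationResult:
    """Integrate the reaction-diffusion system by explicit Euler.

    Deterministic given identical inputs.  Fields are clamped to zero on
    tiny negative excursions (tracked in ``metadata['clamp_events']`` and
    ``metadata['min_excursion']``); NaN/Inf aborts with a diagnostic
    snapshot attached to the raised :class:`IntegrationError`.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    if settings is None:
        raise ValueError("settings is required")
    if initial.shape != geometry.shape:
        raise ValueError(f"initial state shape {initial.shape} != geometry shape {geometry.shape}")
    if variant == "D" and shh is None:
        raise ValueError("variant D requires an Shh field")

    is_2d = isinstance(geometry, DomainMask2D)
    dt = settings.dt if settings.dt is not None else _default_dt(geometry, params, settings.safety)
    bound = max_stable_dt(geometry, params)
    if dt > bound * (1 + 1e-12):
        raise StabilityBoundError(
            f"dt={dt:g} violates the diffusive stability bound dx^2/(4*maxD)={bound:g}"
        )

    snap_dt = settings.snapshot_interval or settings.t_end
    n_steps_snap = max(1, int(round(snap_dt / dt)))
    n_snaps = max(1, int(round(settings.t_end / (n_steps_snap * dt))))

    if shh is not None:
        if shh.S.shape != geometry.shape:
            raise ValueError("Shh field shape does not match geometry")
        h_full = 1.0 / (1.0 + params.gamma * shh.S) if variant == "D" else np.ones(geometry.shape)
    else:
        h_full = np.ones(geometry.shape)

    from .pde_kernels import euler_chunk, neighbours_1d, neighbours_masked

    full0 = initial.stack().astype(float).copy()
    if is_2d:
        mask = geometry.mask
        full0 = np.where(mask, full0, 0.0)
        points, nbrs = neighbours_masked(mask)
        y = np.ascontiguousarray(full0[:, mask])
        h_flat = np.ascontiguousarray(h_full[mask], dtype=float)
    else:
        mask = None
        nbrs = neighbours_1d(geometry.n_points, geometry.boundary)
        y = np.ascontiguousarray(full0)
        h_flat = np.ascontiguousarray(h_full, dtype=float)

    p = params
    par = (p.rho_P, p.sigma_P, p.n_hill, p.K_hill, p.rho_F, p.rho_T,
           p.delta_P, p.delta_F, p.delta_T, p.delta_C,
           p.k_on, p.k_off, p.k_b, p.k_u, p.R_tot, p.beta)
    D = np.array(params.diffusivities)
    inv_dx2 = 1.0 / geometry.dx**2
    freeze_P = variant == "A"

    def to_full(y_flat: np.ndarray) -> np.ndarray:
        if mask is None:
            return y_flat.copy()
        out = np.zeros((5,) + mask.shape)
        out[:, mask] = y_flat
        return out

    times = [0.0]
    snaps = [to_full(y)]
    clamp_events = 0
    min_excursion = 0.0
    t = 0.0

    for _ in range(n_snaps):
        ce, me = euler_chunk(
            y, nbrs, h_flat, par, D, inv_dx2, dt, n_steps_snap, freeze_P,
            backend=settings.backend,
        )
        clamp_events += int(ce)
        min_excursion = min(min_excursion, float(me))
        t += n_steps_snap * dt
        if not np.all(np.isfinite(y)):
            raise IntegrationError(
                f"non-finite fields at t={t:g}", t=t,
                state=FieldState.from_stack(np.nan_to_num(to_full(y))),
            )
        times.append(t)
        snaps.append(to_full(y))

    result = SimulationResult(
        times=np.array(times),
        snapshots=np.array(snaps),
        params=params,
        variant=variant,
        geometry=geometry,
        seed=settings.rng_seed,
        metadata={
            "dt": dt,
            "clamp_events": clamp_events,
            "min_excursion": float(min_excursion),
            "integrator": settings.integrator,
        },
    )
    result.final_state.validate(R_tot=params.R_tot)
    return result
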