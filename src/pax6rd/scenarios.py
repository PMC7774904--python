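"""Synthetic simulation scenarios: the pipeline's data layer.

Generates everything the simulations consume — initial-condition fields,
1D grids, explant-shaped 2D domain masks, static Shh gradients — and binds
them into the canonical scenario configurations: a prescribed regional
Pax6 pattern driving the morphogens (variant A), de-novo polarisation from
a noisy homogeneous Pax6 field (variant B, small and large 1D domains),
repolarisation of a pre-patterned explant (variant C) and Shh positional
information with its loss-of-function perturbations (variant D).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import yaml

from .model import FieldState, ShhField, homogeneous_steady_state, _morphogen_steady
from .params import ModelParameters, apply_lof, reference_parameters
from .pde import DomainMask2D, Grid1D

__all__ = [
    "ScenarioConfig",
    "ScenarioBundle",
    "noisy_homogeneous_ic",
    "prepattern_ic",
    "explant_mask",
    "shh_gradient",
    "build_scenario",
    "load_scenario_config",
    "canonical_config",
    "CANONICAL_SCENARIOS",
]

IC_KINDS = ("noisy_homogeneous", "distal_high_prepattern", "fixed_pax6_source")

CANONICAL_SCENARIOS = (
    "fig4B", "fig4D", "fig4E", "fig4H", "fig5C", "fig5D", "fig5E", "fig5G", "fig5I",
)


@dataclass
class ScenarioConfig:
    """Self-contained description of one simulation scenario.

    Geometry is either 1D (``length``, ``n_points``, ``boundary``) or a 2D
    capsule/ellipse explant (``long_axis``, ``short_axis``, ``dx``).  The
    Shh spec gives peak magnitude, functional form and direction; absent
    means no Shh input (variants A-C).
    """

    name: str
    variant: str
    ic: str
    rng_seed: int = 0
    # 1D geometry
    length: float | None = None
    n_points: int | None = None
    boundary: str = "zero_flux"
    # 2D geometry
    long_axis: float | None = None
    short_axis: float | None = None
    dx: float | None = None
    explant_shape: str = "capsule"
    # IC details
    noise_amplitude: float = 0.05
    prepattern_high: float | None = None
    prepattern_low: float | None = None
    prepattern_axis: str = "short"
    prepattern_profile: str = "linear"
    # Shh spec
    shh_peak: float | None = None
    shh_form: str = "linear"
    shh_direction: str = "long"
    shh_inverted: bool = False
    # perturbation
    lof: str | None = None
    # integration
    t_end: float = 100.0
    snapshot_interval: float = 1.0
    extras: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in ("A", "B", "C", "D"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.ic not in IC_KINDS:
            raise ValueError(f"unknown IC kind {self.ic!r}; expected one of {IC_KINDS}")
        if self.variant == "A" and self.ic != "fixed_pax6_source":
            raise ValueError("variant A requires ic='fixed_pax6_source'")
        if self.variant == "D" and self.shh_peak is None:
            raise ValueError("variant D requires an Shh spec (shh_peak; 0 encodes Shh LOF)")
        is_1d = self.length is not None
        is_2d = self.long_axis is not None
        if is_1d == is_2d:
            raise ValueError("specify exactly one of 1D (length) or 2D (long_axis) geometry")

    @property
    def is_2d(self) -> bool:
        return self.long_axis is not None

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: v for k, v in d.items() if v not in (None, {},)}

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class ScenarioBundle:
    """Integrate-ready bundle produced by :func:`build_scenario`."""

    config: ScenarioConfig
    params: ModelParameters
    initial: FieldState
    geometry: Grid1D | DomainMask2D
    shh: ShhField | None
    variant: str


def _quasi_steady_given_P(params: ModelParameters, P: np.ndarray) -> FieldState:
    """Morphogen/receptor fields in local quasi-steady state for a fixed P.

    Iterates the effective-activity fixed point per grid point (B feeds
    back on P* through beta), then fills F, T, C, B from the algebraic
    balances.
    """
    P = np.asarray(P, dtype=float)
    Pstar = P.copy()
    for _ in range(200):
        F, T, C, B = _morphogen_steady(params, Pstar)
        Pstar_new = P / (1.0 + params.beta * B)
        if np.max(np.abs(Pstar_new - Pstar)) < 1e-14 * (1.0 + np.max(np.abs(Pstar))):
            Pstar = Pstar_new
            break
        Pstar = 0.5 * (Pstar + Pstar_new)
    F, T, C, B = _morphogen_steady(params, Pstar)
    return FieldState(P, F, T, C, B)


def noisy_homogeneous_ic(
    steady_state: FieldState,
    noise_amplitude: float,
    seed: int,
    geometry: Grid1D | DomainMask2D,
) -> FieldState:
    """Homogeneous-but-noisy Pax6 field over a steady-state background.

    P = P* (1 + eps) with eps ~ Uniform(-a, a) i.i.d. per grid point; the
    other species start exactly at their steady-state values (only Pax6 is
    noisy).  Deterministic for a given seed.
    """
    if not (0.0 < noise_amplitude <= 0.2):
        raise ValueError(f"noise_amplitude must be in (0, 0.2], got {noise_amplitude}")
    shape = geometry.shape
    values = [float(np.asarray(getattr(steady_state, s)).ravel()[0]) for s in "PFTCB"]
    state = FieldState.uniform(values, shape)
    rng = np.random.default_rng(seed)
    eps = rng.uniform(-noise_amplitude, noise_amplitude, size=shape)
    state.P = state.P * (1.0 + eps)
    if isinstance(geometry, DomainMask2D):
        for s in "PFTCB":
            arr = getattr(state, s)
            arr[~geometry.mask] = 0.0
    if state.P.min() < 0:
        raise ValueError("noise amplitude produced negative concentrations")
    return state


def prepattern_ic(
    geometry: Grid1D | DomainMask2D,
    params: ModelParameters,
    high_value: float,
    low_value: float,
    axis: str = "short",
    profile: str = "linear",
) -> FieldState:
    """Graded distal-high Pax6 pre-pattern with quasi-steady morphogens.

    For the 2D explant, "distal" is one end of the SHORT axis: explant
    collapse shortens the former proximal-distal dimension, so the initial
    polarity lies perpendicular to the long axis and the repolarisation
    readout is the swing of the pattern onto the long axis.
    """
    if not (high_value > low_value >= 0):
        raise ValueError("need high_value > low_value >= 0")
    if profile not in ("step", "linear"):
        raise ValueError(f"unknown profile {profile!r}")
    if isinstance(geometry, Grid1D):
        if axis == "long":
            raise ValueError("axis 'long' undefined for 1D geometry")
        frac = (np.arange(geometry.n_points) + 0.5) / geometry.n_points
    else:
        if axis not in ("short", "long"):
            raise ValueError(f"unknown axis {axis!r}")
        X, Y = geometry.coordinates()
        coord = Y if axis == "short" else X
        lo = coord[geometry.mask].min()
        hi = coord[geometry.mask].max()
        frac = (coord - lo) / (hi - lo)
    if profile == "step":
        P = np.where(frac < 0.5, high_value, low_value).astype(float)
    else:
        P = high_value + (low_value - high_value) * frac
    state = _quasi_steady_given_P(params, P)
    if isinstance(geometry, DomainMask2D):
        for s in "PFTCB":
            getattr(state, s)[~geometry.mask] = 0.0
    return state


def explant_mask(
    long_axis: float,
    short_axis: float,
    dx: float,
    shape: str = "capsule",
) -> DomainMask2D:
    """Explant-shaped domain mask: a capsule (default) or ellipse raster.

    The long axis runs along +x (rows are the short axis).  The capsule —
    a rectangle with semicircular caps — matches the elongated outline of
    a collapsed optic-vesicle explant and has an unambiguous long axis.
    """
    if not (long_axis >= short_axis):
        raise ValueError("long_axis must be >= short_axis")
    if not (short_axis > 4 * dx):
        raise ValueError(f"resolution too coarse: short_axis must exceed 4*dx={4*dx:g}")
    if shape not in ("capsule", "ellipse"):
        raise ValueError(f"unknown explant shape {shape!r}")
    nx = int(np.ceil(long_axis / dx)) + 2
    ny = int(np.ceil(short_axis / dx)) + 2
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dx
    X, Y = np.meshgrid(x, y)
    cx, cy = nx * dx / 2.0, ny * dx / 2.0
    a, b = long_axis / 2.0, short_axis / 2.0
    if shape == "ellipse":
        mask = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0
    else:
        half_seg = a - b  # straight segment half-length
        ux = np.clip(X - cx, -half_seg, half_seg)
        mask = (X - cx - ux) ** 2 + (Y - cy) ** 2 <= b * b
    return DomainMask2D(
        mask=mask,
        dx=dx,
        long_axis=long_axis,
        short_axis=short_axis,
        orientation_deg=0.0,
        metadata={"shape": shape},
    )


def shh_gradient(
    geometry: Grid1D | DomainMask2D,
    peak: float,
    form: str = "linear",
    direction: str = "long",
    inverted: bool = False,
    decay_length: float | None = None,
) -> ShhField:
    """Static ventral-high to dorsal-low Shh activity gradient.

    S decreases monotonically from ``peak`` at the ventral end to 0
    (linear) or exponentially with ``decay_length`` (default: half the
    axis extent).  ``inverted`` swaps the ventral and dorsal ends;
    ``peak=0`` yields the identically-zero field (Shh LOF).
    """
    if peak < 0:
        raise ValueError("peak must be >= 0")
    if form not in ("linear", "exponential"):
        raise ValueError(f"unknown form {form!r}")
    if isinstance(geometry, Grid1D):
        frac = (np.arange(geometry.n_points) + 0.5) / geometry.n_points
        extent = geometry.length
    else:
        if direction not in ("long", "short"):
            raise ValueError(f"unknown direction {direction!r}")
        X, Y = geometry.coordinates()
        coord = X if direction == "long" else Y
        lo = coord[geometry.mask].min()
        hi = coord[geometry.mask].max()
        frac = np.clip((coord - lo) / (hi - lo), 0.0, 1.0)
        extent = hi - lo
    if inverted:
        frac = 1.0 - frac
    if form == "linear":
        S = peak * (1.0 - frac)
    else:
        if decay_length is None:
            decay_length = extent / 2.0
        S = peak * np.exp(-frac * extent / decay_length)
    if isinstance(geometry, DomainMask2D):
        S = np.where(geometry.mask, S, 0.0)
    return ShhField(S=S, direction=direction, inverted=inverted, metadata={"peak": peak, "form": form})


def _fixed_source_profile(geometry: Grid1D, high: float, low: float) -> np.ndarray:
    """Regionally restricted Pax6 source: high central (distal) third."""
    n = geometry.n_points
    frac = (np.arange(n) + 0.5) / n
    P = np.full(n, low, dtype=float)
    P[(frac >= 1.0 / 3.0) & (frac < 2.0 / 3.0)] = high
    return P


def build_scenario(
    config: ScenarioConfig,
    params: ModelParameters | None = None,
) -> ScenarioBundle:
    """Bind a scenario config into an integrate-ready bundle.

    Applies the config's LOF tag to the (reference, unless given)
    parameter set, constructs geometry, initial condition and Shh field,
    and returns everything :func:`pax6rd.pde.integrate` needs.  Fully
    reproducible from the config alone.
    """
    if params is None:
        params = reference_parameters()
    if config.lof is not None:
        params = apply_lof(params, config.lof)

    if config.is_2d:
        geometry: Grid1D | DomainMask2D = explant_mask(
            config.long_axis, config.short_axis, config.dx, shape=config.explant_shape
        )
    else:
        geometry = Grid1D(
            n_points=config.n_points, dx=config.length / config.n_points, boundary=config.boundary
        )

    steady = homogeneous_steady_state(params, variant="B" if config.variant != "A" else "A")

    if config.ic == "noisy_homogeneous":
        initial = noisy_homogeneous_ic(
            steady, config.noise_amplitude, config.rng_seed, geometry
        )
    elif config.ic == "distal_high_prepattern":
        high = config.prepattern_high if config.prepattern_high is not None else 2.0 * float(steady.P[0])
        low = config.prepattern_low if config.prepattern_low is not None else 0.1 * float(steady.P[0])
        initial = prepattern_ic(
            geometry, params, high, low,
            axis=config.prepattern_axis, profile=config.prepattern_profile,
        )
        # seeded multiplicative Pax6 jitter: real explants are noisy, and an
        # exactly axis-symmetric pre-pattern could never break symmetry
        if config.noise_amplitude > 0:
            rng = np.random.default_rng(config.rng_seed)
            initial.P = initial.P * (
                1.0 + rng.uniform(-config.noise_amplitude, config.noise_amplitude, initial.P.shape)
            )
            if config.is_2d:
                initial.P[~geometry.mask] = 0.0
    else:  # fixed_pax6_source (variant A)
        if config.is_2d:
            raise ValueError("fixed_pax6_source is a 1D scenario")
        high = config.prepattern_high if config.prepattern_high is not None else 2.0 * float(steady.P[0])
        low = config.prepattern_low if config.prepattern_low is not None else 0.05 * float(steady.P[0])
        P = _fixed_source_profile(geometry, high, low)
        initial = _quasi_steady_given_P(params, P)

    shh = None
    if config.variant == "D":
        shh = shh_gradient(
            geometry,
            peak=config.shh_peak,
            form=config.shh_form,
            direction=config.shh_direction,
            inverted=config.shh_inverted,
        )

    return ScenarioBundle(
        config=config,
        params=params,
        initial=initial,
        geometry=geometry,
        shh=shh,
        variant=config.variant,
    )


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    data = yaml.safe_load(Path(path).read_text())
    return ScenarioConfig.from_dict(data)


def canonical_config(name: str) -> ScenarioConfig:
    """Load one of the shipped canonical scenario configs by name."""
    if name not in CANONICAL_SCENARIOS:
        raise ValueError(f"unknown canonical scenario {name!r}; expected one of {CANONICAL_SCENARIOS}")
    resource = importlib.resources.files("pax6rd") / "configs" / f"{name}.yaml"
    with importlib.resources.as_file(resource) as path:
        return load_scenario_config(path)
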