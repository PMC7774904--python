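"""Reaction kinetics of the Pax6/Fst/Tgfb2 network.

Governing reaction terms (diffusion handled in :mod:`pax6rd.pde`), with
effective Pax6 activity P* = P / (1 + beta*B) and Shh attenuation
h = 1 / (1 + gamma*S):

    dP/dt = h * [rho_P * (P*)^n / (K^n + (P*)^n) + sigma_P] - delta_P * P
    dF/dt = rho_F * P* - k_on*F*T + k_off*C - delta_F * F
    dT/dt = rho_T * P* - k_on*F*T + k_off*C - k_b*T*(R_tot - B) + k_u*B - delta_T * T
    dC/dt = k_on*F*T - k_off*C - delta_C * C
    dB/dt = k_b*T*(R_tot - B) - k_u*B

Model variants: ``A`` freezes P (a prescribed regional Pax6 pattern drives
the morphogens); ``B`` and ``C`` are the self-organising network without
Shh (B: 1D, C: 2D explant — identical kinetics); ``D`` adds the static Shh
field.  Receptor conservation is built in: free receptors are R_tot - B.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import brentq

from .params import ModelParameters, ParameterError

__all__ = [
    "FieldState",
    "ShhField",
    "SPECIES",
    "VARIANTS",
    "pax6_activity",
    "reaction_rates",
    "reaction_rates_stacked",
    "homogeneous_steady_state",
    "SteadyStateError",
]

SPECIES = ("P", "F", "T", "C", "B")
VARIANTS = ("A", "B", "C", "D")

_NEG_TOL = 1e-9


class SteadyStateError(RuntimeError):
    """Raised when the homogeneous steady-state solver fails to converge."""


@dataclass
class FieldState:
    """Concentration fields of the five species on a common spatial grid."""

    P: np.ndarray
    F: np.ndarray
    T: np.ndarray
    C: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(getattr(self, s), dtype=float) for s in SPECIES]
        shape = arrays[0].shape
        for name, arr in zip(SPECIES, arrays):
            if arr.shape != shape:
                raise ValueError(
                    f"field {name} has shape {arr.shape}, expected {shape}"
                )
            setattr(self, name, arr)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.P.shape

    def stack(self) -> np.ndarray:
        """Stack fields into a (5, *grid) array in SPECIES order."""
        return np.stack([getattr(self, s) for s in SPECIES])

    @classmethod
    def from_stack(cls, y: np.ndarray) -> "FieldState":
        y = np.asarray(y, dtype=float)
        if y.shape[0] != len(SPECIES):
            raise ValueError(f"expected leading axis of length 5, got {y.shape}")
        return cls(*(y[i] for i in range(len(SPECIES))))

    @classmethod
    def uniform(cls, values, shape: tuple[int, ...]) -> "FieldState":
        """Spatially uniform state from per-species scalars (SPECIES order)."""
        return cls(*(np.full(shape, float(v)) for v in values))

    def copy(self) -> "FieldState":
        return FieldState(*(getattr(self, s).copy() for s in SPECIES))

    def validate(self, R_tot: float | None = None) -> None:
        """Check non-negativity (to integrator tolerance) and receptor bound."""
        for name in SPECIES:
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"field {name} contains non-finite values")
            if arr.min(initial=0.0) < -_NEG_TOL:
                raise ValueError(
                    f"field {name} has negative values below tolerance: min={arr.min()}"
                )
        if R_tot is not None and self.B.max(initial=0.0) > R_tot * (1 + 1e-9) + _NEG_TOL:
            raise ValueError(f"B exceeds R_tot={R_tot}: max={self.B.max()}")


@dataclass
class ShhField:
    """Static Shh activity field S >= 0; S identically zero encodes Shh LOF."""

    S: np.ndarray
    direction: str = "none"
    inverted: bool = False
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.size and self.S.min() < 0:
            raise ValueError(f"Shh field must be non-negative, min={self.S.min()}")

    @classmethod
    def zero(cls, shape: tuple[int, ...]) -> "ShhField":
        return cls(S=np.zeros(shape), direction="none")


def pax6_activity(P: np.ndarray, B: np.ndarray, beta: float) -> np.ndarray:
    """Effective Pax6 transcriptional activity P* = P / (1 + beta*B).

    Receptor-bound Tgfβ2 activates Smad3, which blocks Pax6–DNA binding;
    the inhibition therefore acts on Pax6 *activity* (used in every
    transcription term, including Pax6's own autoregulation), not on the
    Pax6 concentration itself.
    """
    P = np.asarray(P, dtype=float)
    B = np.asarray(B, dtype=float)
    if P.shape != B.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs B {B.shape}")
    if beta < 0:
        raise ParameterError(f"beta must be >= 0, got {beta}")
    return P / (1.0 + beta * B)


def reaction_rates_stacked(
    y: np.ndarray,
    params: ModelParameters,
    h: np.ndarray | float = 1.0,
    variant: str = "B",
) -> np.ndarray:
    """Reaction rates on a stacked (5, *grid) array; hot path of the solver.

    ``h`` is the precomputed Shh attenuation 1/(1 + gamma*S) (1.0 when no
    Shh input).  Rates at a point depend only on that point's concentrations.
    """
    P, F, T, C, B = y
    p = params
    Pstar = P / (1.0 + p.beta * B)
    free_R = p.R_tot - B
    assoc = p.k_on * F * T  # Fst + Tgfβ2 -> complex
    dissoc = p.k_off * C
    bind = p.k_b * T * free_R  # Tgfβ2 + receptor -> signalling complex
    unbind = p.k_u * B

    Pn = Pstar**p.n_hill
    hill = Pn / (p.K_hill**p.n_hill + Pn)
    dP = h * (p.rho_P * hill + p.sigma_P) - p.delta_P * P
    dF = p.rho_F * Pstar - assoc + dissoc - p.delta_F * F
    dT = p.rho_T * Pstar - assoc + dissoc - bind + unbind - p.delta_T * T
    dC = assoc - dissoc - p.delta_C * C
    dB = bind - unbind

    if variant == "A":
        dP = np.zeros_like(dP)
    return np.stack([dP, dF, dT, dC, dB])


def reaction_rates(
    state: FieldState,
    params: ModelParameters,
    shh: ShhField | None = None,
    variant: str = "B",
) -> FieldState:
    """Per-species reaction rate fields for a model variant.

    Variant ``A`` freezes Pax6 (dP/dt = 0).  Variants ``B``/``C`` ignore any
    Shh input (the self-organising network in isolation).  Variant ``D``
    requires an Shh field, which attenuates Pax6 production by
    1/(1 + gamma*S).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}; expected one of {VARIANTS}")
    if variant == "D":
        if shh is None:
            raise ValueError("variant D requires an Shh field (use ShhField.zero for Shh LOF)")
        if shh.S.shape != state.shape:
            raise ValueError(f"Shh field shape {shh.S.shape} != state shape {state.shape}")
        h = 1.0 / (1.0 + params.gamma * shh.S)
    else:
        h = 1.0
    rates = reaction_rates_stacked(state.stack(), params, h=h, variant=variant)
    return FieldState.from_stack(rates)


def _morphogen_steady(params: ModelParameters, Pstar):
    """Steady F, T, C, B given effective Pax6 activity P* (vectorised).

    At steady state the receptor reaction balances, so the T equation
    reduces to rho_T*P* = J + delta_T*T with the net sequestration flux
    J = a*F*T, a = k_on*delta_C/(k_off + delta_C); eliminating F yields a
    quadratic in T with a single non-negative root.
    """
    p = params
    Pstar = np.asarray(Pstar, dtype=float)
    denom = p.k_off + p.delta_C
    if p.k_on > 0 and denom == 0:
        raise SteadyStateError(
            "no steady state: irreversible, non-degrading complex accumulates without bound"
        )
    a = p.k_on * p.delta_C / denom if denom > 0 else 0.0
    if p.delta_F <= 0 or p.delta_T <= 0:
        raise SteadyStateError("delta_F and delta_T must be > 0 for a morphogen steady state")
    if a == 0:
        F = p.rho_F * Pstar / p.delta_F
        T = p.rho_T * Pstar / p.delta_T
    else:
        # a*delta_T*T^2 + (delta_F*delta_T + a*(rho_F - rho_T)*P*)*T - rho_T*P**delta_F = 0
        qa = a * p.delta_T
        qb = p.delta_F * p.delta_T + a * (p.rho_F - p.rho_T) * Pstar
        qc = -p.rho_T * Pstar * p.delta_F
        disc = np.sqrt(qb * qb - 4.0 * qa * qc)
        T = np.where(qb >= 0, 2.0 * np.abs(qc) / (qb + disc), (disc - qb) / (2.0 * qa))
        F = p.rho_F * Pstar / (p.delta_F + a * T)
    C = p.k_on * F * T / denom if denom > 0 else np.zeros_like(T)
    B = p.R_tot * p.k_b * T / (p.k_b * T + p.k_u) if (p.k_b > 0 or p.k_u > 0) else np.zeros_like(T)
    if p.k_b == 0:
        B = np.zeros_like(T)
    return F, T, C, B


def _B_given_P(params: ModelParameters, P: float, max_iter: int = 200) -> float:
    """Inner fixed point for receptor occupancy B given total Pax6 P."""
    p = params
    Pstar = P
    B = 0.0
    for _ in range(max_iter):
        _, _, _, B_new = _morphogen_steady(p, Pstar)
        B = 0.5 * B + 0.5 * float(B_new)
        Pstar_new = P / (1.0 + p.beta * B)
        if abs(Pstar_new - Pstar) < 1e-15 * (1.0 + abs(Pstar)):
            Pstar = Pstar_new
            break
        Pstar = Pstar_new
    return B


def homogeneous_steady_state(
    params: ModelParameters,
    variant: str = "B",
    S: float = 0.0,
    tol: float = 1e-10,
) -> FieldState:
    """Spatially uniform steady state of the reaction system.

    Reduces the five algebraic balance equations to a scalar root problem in
    P (morphogen and receptor balances solved exactly given P*), locates the
    Pax6-positive root by bracketed bisection on a scan grid, and returns
    the uniform state on a single grid point.  ``S`` is the uniform Shh
    level (variant D); the receptor occupancy satisfies the binding isotherm
    B* = R_tot*k_b*T*/(k_b*T* + k_u).

    Raises
    ------
    SteadyStateError
        If no root is found or the residual exceeds ``tol``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    p = params
    h = 1.0 / (1.0 + p.gamma * S) if variant == "D" else 1.0

    def p_residual(P: float) -> float:
        B = _B_given_P(p, P)
        Pstar = P / (1.0 + p.beta * B)
        Pn = Pstar**p.n_hill
        hill = Pn / (p.K_hill**p.n_hill + Pn)
        return h * (p.rho_P * hill + p.sigma_P) - p.delta_P * P

    if p.delta_P <= 0:
        raise SteadyStateError("delta_P must be > 0 for a homogeneous steady state")
    P_upper = h * (p.rho_P + p.sigma_P) / p.delta_P + p.K_hill
    if P_upper == 0 or (p.rho_P == 0 and p.sigma_P == 0):
        P_root = 0.0
    else:
        # Scan downward so the largest (Pax6-positive, stable-branch) root is taken.
        scan = np.linspace(P_upper, 0.0, 160)
        vals = [p_residual(x) for x in scan]
        P_root = None
        for i in range(len(scan) - 1):
            if vals[i] == 0.0:
                P_root = float(scan[i])
                break
            if vals[i] * vals[i + 1] < 0:
                P_root = brentq(p_residual, scan[i + 1], scan[i], xtol=1e-14, rtol=1e-15)
                break
        if P_root is None:
            if abs(vals[-1]) < tol:
                P_root = 0.0
            else:
                raise SteadyStateError(
                    f"no steady-state root found in (0, {P_upper:g}]; "
                    f"residual at 0: {vals[-1]:g}"
                )

    B = _B_given_P(p, P_root)
    Pstar = P_root / (1.0 + p.beta * B)
    F, T, C, B = (float(v) for v in _morphogen_steady(p, Pstar))
    state = FieldState.uniform((P_root, F, T, C, B), shape=(1,))
    shh = ShhField(S=np.full((1,), S)) if variant == "D" else None
    residual = np.abs(reaction_rates(state, p, shh=shh, variant=variant).stack()).max()
    if variant == "A":
        # P is frozen in variant A; check the morphogen sub-system only.
        rates = reaction_rates_stacked(state.stack(), p, variant="B")
        residual = np.abs(rates[1:]).max()
    if residual > tol:
        raise SteadyStateError(f"steady-state residual {residual:g} exceeds tolerance {tol:g}")
    return state
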