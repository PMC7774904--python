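"""Linear stability analysis of the homogeneous steady state.

For a perturbation ~ exp(lambda*t + i*k*x) about the uniform steady state,
the growth rate lambda(k) is an eigenvalue of J - k^2 * D, where J is the
reaction Jacobian and D = diag(0, D_F, D_T, D_C, 0) (Pax6 and the membrane
receptor complex do not diffuse).  A Turing instability requires the state
to be stable without diffusion (max Re lambda(0) < 0) but unstable in a
finite band of wavenumbers; the fastest-growing mode sets the expected
pattern wavelength 2*pi/k_max and hence the number of Pax6 poles a domain
of a given size can accommodate.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .model import FieldState, SPECIES, VARIANTS, reaction_rates_stacked
from .params import ModelParameters

__all__ = [
    "DispersionResult",
    "reaction_jacobian",
    "dispersion_relation",
    "default_k_values",
    "predicted_pole_count",
]

# Dead-band around zero growth: sign decisions ignore |Re lambda| below this,
# so round-off cannot flip a classification.
GROWTH_DEADBAND = 1e-9


@dataclass
class DispersionResult:
    """Growth rate versus wavenumber and the resulting Turing classification.

    ``classification`` is one of ``stable`` (no growing mode at any k),
    ``turing`` (stationary finite-k instability), ``oscillatory_turing``
    (the fastest-growing finite-k mode has a nonzero frequency) or ``hopf``
    (the homogeneous mode itself oscillates unstably).
    """

    k_values: np.ndarray
    growth_rates: np.ndarray
    frequencies: np.ndarray
    classification: str
    k_max: float
    lambda_pattern: float
    metadata: dict = dc_field(default_factory=dict)

    @property
    def max_growth_rate(self) -> float:
        return float(self.growth_rates.max())

    @property
    def is_unstable(self) -> bool:
        return self.classification != "stable"


def reaction_jacobian(
    params: ModelParameters,
    steady_state: FieldState,
    variant: str = "B",
    S: float = 0.0,
    residual_tol: float = 1e-8,
) -> np.ndarray:
    """Analytic 5x5 Jacobian of the reaction terms at a uniform steady state.

    Entry (i, j) is d(rate of species i)/d(concentration of species j),
    species ordered (P, F, T, C, B).  Refuses steady states whose reaction
    residual exceeds ``residual_tol``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    p = params
    P, F, T, C, B = (float(np.asarray(getattr(steady_state, s)).ravel()[0]) for s in SPECIES)
    h = 1.0 / (1.0 + p.gamma * S) if variant == "D" else 1.0

    y = np.array([P, F, T, C, B])[:, None]
    rates = reaction_rates_stacked(y, p, h=h, variant=variant)
    check = rates if variant != "A" else rates[1:]
    residual = np.abs(check).max()
    if residual > residual_tol:
        raise ValueError(
            f"steady-state reaction residual {residual:g} exceeds {residual_tol:g}; "
            "refusing to linearise"
        )

    inhib = 1.0 + p.beta * B
    Pstar = P / inhib
    dPs_dP = 1.0 / inhib
    dPs_dB = -p.beta * P / inhib**2

    # d/dP* of the Hill production term
    n, K = p.n_hill, p.K_hill
    Pn = Pstar**n
    Kn = K**n
    if Pstar > 0:
        dhill = n * Kn * Pstar ** (n - 1.0) / (Kn + Pn) ** 2
    else:
        dhill = 0.0 if n > 1 else 1.0 / K

    J = np.zeros((5, 5))
    # P row
    J[0, 0] = h * p.rho_P * dhill * dPs_dP - p.delta_P
    J[0, 4] = h * p.rho_P * dhill * dPs_dB
    # F row
    J[1, 0] = p.rho_F * dPs_dP
    J[1, 1] = -p.k_on * T - p.delta_F
    J[1, 2] = -p.k_on * F
    J[1, 3] = p.k_off
    J[1, 4] = p.rho_F * dPs_dB
    # T row
    J[2, 0] = p.rho_T * dPs_dP
    J[2, 1] = -p.k_on * T
    J[2, 2] = -p.k_on * F - p.k_b * (p.R_tot - B) - p.delta_T
    J[2, 3] = p.k_off
    J[2, 4] = p.rho_T * dPs_dB + p.k_b * T + p.k_u
    # C row
    J[3, 1] = p.k_on * T
    J[3, 2] = p.k_on * F
    J[3, 3] = -p.k_off - p.delta_C
    # B row
    J[4, 2] = p.k_b * (p.R_tot - B)
    J[4, 4] = -p.k_b * T - p.k_u

    if variant == "A":
        J[0, :] = 0.0
    return J


def default_k_values(
    domain_length: float, dx: float, n_k: int = 256
) -> np.ndarray:
    """Log-spaced wavenumber grid from 2*pi/(10*L) to 2*pi/(2*dx).

    Brackets every mode resolvable on the grid: ten domain lengths down to
    the two-cell Nyquist wavelength.
    """
    k_lo = 2.0 * np.pi / (10.0 * domain_length)
    k_hi = 2.0 * np.pi / (2.0 * dx)
    return np.geomspace(k_lo, k_hi, n_k)


def dispersion_relation(
    params: ModelParameters,
    steady_state: FieldState,
    k_values: np.ndarray,
    variant: str = "B",
    S: float = 0.0,
) -> DispersionResult:
    """Dispersion relation: leading growth rate at each sampled wavenumber.

    For each k the eigenvalues of J - k^2*diag(0, D_F, D_T, D_C, 0) are
    computed; ``growth_rates`` holds the maximal real part and
    ``frequencies`` the |Im| of the corresponding leading eigenvalue.
    k = 0 is always evaluated (for the without-diffusion classification)
    and prepended if absent.
    """
    k_values = np.asarray(k_values, dtype=float)
    if k_values.ndim != 1 or k_values.size == 0:
        raise ValueError("k_values must be a non-empty 1D array")
    if np.any(k_values < 0):
        raise ValueError("k_values must be >= 0")
    if np.any(np.diff(k_values) < 0):
        raise ValueError("k_values must be sorted ascending")
    if k_values[0] > 0:
        k_values = np.concatenate([[0.0], k_values])

    J = reaction_jacobian(params, steady_state, variant=variant, S=S)
    D = np.diag(params.diffusivities)

    growth = np.empty_like(k_values)
    freq = np.empty_like(k_values)
    for i, k in enumerate(k_values):
        lam = np.linalg.eigvals(J - (k * k) * D)
        if not np.all(np.isfinite(lam)):
            raise ArithmeticError(f"non-finite eigenvalues at k={k}")
        lead = lam[np.argmax(lam.real)]
        growth[i] = lead.real
        freq[i] = abs(lead.imag)

    i_max = int(np.argmax(growth))
    k_max = float(k_values[i_max])
    tol = GROWTH_DEADBAND
    growth_at_0 = growth[k_values == 0.0][0]
    freq_at_0 = freq[k_values == 0.0][0]
    unstable_band = growth > tol

    if growth_at_0 > tol:
        classification = "hopf" if freq_at_0 > tol else "unstable_homogeneous"
    elif not unstable_band.any():
        classification = "stable"
    elif freq[i_max] > tol:
        classification = "oscillatory_turing"
    else:
        classification = "turing"

    lambda_pattern = 2.0 * np.pi / k_max if (k_max > 0 and unstable_band.any()) else np.inf
    return DispersionResult(
        k_values=k_values,
        growth_rates=growth,
        frequencies=freq,
        classification=classification,
        k_max=k_max,
        lambda_pattern=float(lambda_pattern),
        metadata={"variant": variant, "S": S, "growth_at_0": float(growth_at_0)},
    )


def predicted_pole_count(
    domain_length: float,
    dispersion: DispersionResult,
    boundary: str = "zero_flux",
) -> tuple[int, int]:
    """Inclusive range of expected Pax6 pole counts for a 1D domain.

    Mode selection is approximate: the range is round(L / lambda_pattern)
    plus/minus one, floored at zero.  Under zero-flux boundaries the
    pattern locks onto cosine modes whose half-wavelength end lobes count
    as full poles, which the +/-1 margin absorbs.
    """
    if dispersion.classification not in ("turing", "oscillatory_turing"):
        raise ValueError(
            f"pole count undefined for classification {dispersion.classification!r}"
        )
    if boundary not in ("zero_flux", "periodic"):
        raise ValueError(f"unknown boundary {boundary!r}")
    n = int(round(domain_length / dispersion.lambda_pattern))
    return (max(0, n - 1), n + 1)
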