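"""Kinetic and transport parameters of the Pax6/Fst/Tgfb2 network.

The network couples five species: the transcription factor Pax6 (P), the
secreted Tgfβ antagonist follistatin (F), the diffusible ligand Tgfβ2 (T),
the Fst:Tgfβ2 sequestration complex (C) and the activated Tgfβ2:receptor
signalling complex (B).  Pax6 autoregulates and drives production of both
Fst and Tgfb2; Fst reversibly sequesters Tgfβ2 into fast-diffusing
complexes; receptor-bound Tgfβ2 inhibits Pax6 transcriptional activity
(Smad3-mediated); an optional static Shh field suppresses Pax6 production.
Units of space, time and concentration are arbitrary but internally
consistent.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "ModelParameters",
    "ParameterError",
    "apply_lof",
    "load_parameters",
    "save_parameters",
    "reference_parameters",
]

LOF_TAGS = ("tgfb_lof", "shh_lof", "double_lof")


class ParameterError(ValueError):
    """Raised for out-of-range or inconsistent model parameters."""


@dataclass(frozen=True)
class ModelParameters:
    """All kinetic, diffusion and coupling constants of the network.

    Attributes
    ----------
    rho_P, sigma_P : float
        Maximal autoregulatory and basal Pax6 production rates (conc/time).
    n_hill, K_hill : float
        Hill coefficient (>= 1) and half-maximal effective Pax6 activity of
        Pax6 autoregulation.
    rho_F, rho_T : float
        Fst / Tgfb2 production rates per unit effective Pax6 activity (1/time).
    delta_P, delta_F, delta_T, delta_C : float
        First-order decay rates (1/time).  Complex decay destroys both
        constituents; Tgfβ2 is released only through ``k_off``.
    k_on, k_off : float
        Fst–Tgfβ2 association (1/(conc·time)) and complex dissociation
        (1/time) rates.
    k_b, k_u : float
        Tgfβ2–receptor binding (1/(conc·time)) and unbinding (1/time) rates.
    R_tot : float
        Total receptor concentration per grid point (conc, > 0).
    beta : float
        Strength of Pax6 functional inhibition by the receptor complex B
        (1/conc); effective activity is P* = P / (1 + beta * B).
    gamma : float
        Strength of Pax6 transcriptional suppression by Shh (1/conc).
    D_F, D_T, D_C : float
        Diffusion coefficients of free Fst, free Tgfβ2 and the Fst:Tgfβ2
        complex (length^2/time).  Pax6 (intracellular) and the receptor
        complex (membrane-bound) do not diffuse.
    """

    rho_P: float
    sigma_P: float
    n_hill: float
    K_hill: float
    rho_F: float
    rho_T: float
    delta_P: float
    delta_F: float
    delta_T: float
    delta_C: float
    k_on: float
    k_off: float
    k_b: float
    k_u: float
    R_tot: float
    beta: float
    gamma: float
    D_F: float
    D_T: float
    D_C: float

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            value = getattr(self, field.name)
            if not isinstance(value, (int, float)):
                raise ParameterError(f"{field.name} must be numeric, got {value!r}")
            object.__setattr__(self, field.name, float(value))
            if value < 0:
                raise ParameterError(f"{field.name} must be >= 0, got {value}")
        if self.R_tot <= 0:
            raise ParameterError(f"R_tot must be > 0, got {self.R_tot}")
        if self.n_hill < 1:
            raise ParameterError(f"n_hill must be >= 1, got {self.n_hill}")
        if self.K_hill <= 0:
            raise ParameterError(f"K_hill must be > 0, got {self.K_hill}")

    @property
    def diffusivities(self) -> tuple[float, float, float, float, float]:
        """Per-species diffusion coefficients in (P, F, T, C, B) order."""
        return (0.0, self.D_F, self.D_T, self.D_C, 0.0)

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "ModelParameters":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        missing = names - set(data)
        if missing:
            raise ParameterError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in data.items()})


def apply_lof(params: ModelParameters, which: str) -> ModelParameters:
    """Return a copy of ``params`` with a loss-of-function coupling zeroed.

    ``tgfb_lof`` removes the Smad3-mediated inhibition of Pax6 by receptor-
    bound Tgfβ2 (beta = 0), mimicking SIS3 treatment.  ``shh_lof`` removes
    the Shh suppression of Pax6 (gamma = 0), mimicking cyclopamine.
    ``double_lof`` applies both.  All other fields are bit-identical.
    """
    if which == "tgfb_lof":
        return params.replace(beta=0.0)
    if which == "shh_lof":
        return params.replace(gamma=0.0)
    if which == "double_lof":
        return params.replace(beta=0.0, gamma=0.0)
    raise ParameterError(f"unknown loss-of-function tag {which!r}; expected one of {LOF_TAGS}")


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set as a flat key-value YAML file."""
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))


def load_parameters(path: str | Path) -> ModelParameters:
    """Read a flat key-value YAML parameter file."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: expected a mapping of parameter names to values")
    return ModelParameters.from_dict(data)


def reference_parameters() -> ModelParameters:
    """The pinned reference parameter set.

    Located by a documented parameter sweep (the ``sweep`` CLI verb) subject
    to: the homogeneous steady state is stable without diffusion but
    Turing-unstable with the shipped diffusivities (D_C > D_F); collapsing
    the differential diffusion (D_C = D_F) removes the instability; the Pax6
    reaction alone is monostable; and the unstable mode is oscillatory at
    the reference ``beta`` but stationary once ``beta`` is raised (see the
    methods note).
    """
    resource = importlib.resources.files("pax6rd") / "configs" / "reference_params.yaml"
    with importlib.resources.as_file(resource) as path:
        return load_parameters(path)
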