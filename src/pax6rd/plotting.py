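"""Static plots: 1D kymographs, final profiles and 2D snapshots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .model import SPECIES
from .pde import DomainMask2D, SimulationResult

__all__ = ["kymograph", "snapshot_2d", "final_profile"]


def kymograph(result: SimulationResult, species: str = "P", ax=None):
    """Space-time plot of one species for a 1D run (time on x, space on y)."""
    i = SPECIES.index(species)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    img = result.snapshots[:, i].T
    ax.imshow(
        img,
        aspect="auto",
        origin="lower",
        extent=[result.times[0], result.times[-1], 0, img.shape[0] * result.geometry.dx],
        cmap="viridis",
    )
    ax.set_xlabel("time")
    ax.set_ylabel("position")
    ax.set_title(species)
    return ax


def snapshot_2d(result: SimulationResult, species: str = "P", index: int = -1, ax=None):
    """Final (or chosen) snapshot of one species on a 2D masked domain."""
    if not isinstance(result.geometry, DomainMask2D):
        raise TypeError("snapshot_2d requires a 2D masked geometry")
    i = SPECIES.index(species)
    if ax is None:
        _, ax = plt.subplots()
    field = np.where(result.geometry.mask, result.snapshots[index, i], np.nan)
    ax.imshow(field, origin="upper", cmap="viridis")
    ax.set_title(f"{species} at t={result.times[index]:g}")
    ax.set_axis_off()
    return ax


def final_profile(result: SimulationResult, species: str = "P", ax=None):
    """Final 1D profile (or long-axis profile for 2D runs)."""
    from .metrics import axis_profile

    i = SPECIES.index(species)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    if isinstance(result.geometry, DomainMask2D):
        pos, prof = axis_profile(result.snapshots[-1, i], result.geometry)
    else:
        pos = result.geometry.x
        prof = result.snapshots[-1, i]
    ax.plot(pos, prof)
    ax.set_xlabel("position along long axis")
    ax.set_ylabel(f"{species} abundance")
    return ax
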