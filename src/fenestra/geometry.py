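"""Compartment geometry of the permeation pathway.

The receptor is reduced to a cylinder-based region model along the membrane
normal (z, increasing from the intracellular to the extracellular side, Å):
an intracellular bath below the pore mouth, the transmembrane pore, a central
vestibule in the extracellular domain, lateral fenestrations opening through
the vestibule's side wall, an apical aperture through its ceiling, and the
extracellular bath everywhere above/outside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = ["Region", "RegionModel", "assign_region", "assign_regions", "region_with_margin"]


class Region:
    """Region labels for a single ion position."""

    IC = "IC"
    PORE = "PORE"
    VESTIBULE = "VESTIBULE"
    EC = "EC"
    FENESTRATION = "FENESTRATION"
    MEMBRANE_EXTERIOR = "MEMBRANE_EXTERIOR"

    #: compartments an ion can durably occupy; PORE/FENESTRATION/MEMBRANE_EXTERIOR
    #: are transit regions a committed crossing passes through
    TERMINAL = frozenset({"IC", "VESTIBULE", "EC"})


@dataclass(frozen=True)
class RegionModel:
    """Geometry of the compartment model.

    Parameters
    ----------
    z_ic : float
        z-plane of the intracellular pore mouth (Å).
    z_ec : float
        z-plane of the vestibule floor / top of the transmembrane pore (Å).
    z_vest_top : float
        z-plane of the vestibule ceiling, the constriction separating the
        central from the outer vestibule (Å).
    axis_xy : tuple of float
        (x, y) of the pore axis (Å).
    r_vest : float
        radius of the vestibule cylinder (Å).
    r_apical : float
        radius of the apical aperture in the z_vest_top disc (Å).
    fen_band : tuple of float
        (z_lo, z_hi) of the lateral-fenestration band on the vestibule side
        wall (Å); must lie within [z_ec, z_vest_top].
    fen_width : float
        radial depth of the fenestration tunnels beyond r_vest (Å).
    hysteresis : float
        margin δz an ion must penetrate beyond a boundary before a region
        change is committed (Å).

    The defaults describe a GlyR-like open construct (pore ≈ 40 Å tall,
    vestibule ≈ 30 Å) and are a template: every analysis accepts arbitrary
    values.
    """

    z_ic: float = 0.0
    z_ec: float = 40.0
    z_vest_top: float = 70.0
    axis_xy: Tuple[float, float] = (0.0, 0.0)
    r_vest: float = 15.0
    r_apical: float = 5.0
    fen_band: Tuple[float, float] = (45.0, 60.0)
    fen_width: float = 10.0
    hysteresis: float = 2.0

    def __post_init__(self) -> None:
        if not (self.z_ic < self.z_ec < self.z_vest_top):
            raise ValueError("require z_ic < z_ec < z_vest_top")
        lo, hi = self.fen_band
        if not (self.z_ec <= lo < hi <= self.z_vest_top):
            raise ValueError("fen_band must lie within [z_ec, z_vest_top]")
        if not (0 < self.r_apical < self.r_vest):
            raise ValueError("require 0 < r_apical < r_vest")
        if self.fen_width <= 0:
            raise ValueError("fen_width must be positive")
        if self.hysteresis < 0:
            raise ValueError("hysteresis must be >= 0")

    def radial(self, x: float, y: float) -> float:
        ax, ay = self.axis_xy
        return math.hypot(x - ax, y - ay)


def assign_region(position, model: RegionModel) -> str:
    """Map one (x, y, z) position (Å) to a region label.

    Raises ``ValueError`` on non-finite coordinates.
    """
    x, y, z = (float(v) for v in position)
    if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
        raise ValueError(f"non-finite coordinates {position!r}")
    r = model.radial(x, y)
    if z < model.z_ic:
        return Region.IC
    if z < model.z_ec:
        return Region.PORE if r <= model.r_vest else Region.MEMBRANE_EXTERIOR
    if z <= model.z_vest_top:
        if r <= model.r_vest:
            return Region.VESTIBULE
        lo, hi = model.fen_band
        if lo <= z <= hi and r <= model.r_vest + model.fen_width:
            return Region.FENESTRATION
        return Region.EC
    return Region.EC


def assign_regions(positions: np.ndarray, model: RegionModel) -> np.ndarray:
    """Vectorised :func:`assign_region` over an (n, 3) array of positions."""
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("positions must be an (n, 3) array")
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite coordinates in positions")
    z = pos[:, 2]
    ax, ay = model.axis_xy
    r = np.hypot(pos[:, 0] - ax, pos[:, 1] - ay)
    out = np.full(len(pos), Region.EC, dtype=object)
    out[z < model.z_ic] = Region.IC
    in_pore_band = (z >= model.z_ic) & (z < model.z_ec)
    out[in_pore_band & (r <= model.r_vest)] = Region.PORE
    out[in_pore_band & (r > model.r_vest)] = Region.MEMBRANE_EXTERIOR
    in_vest_band = (z >= model.z_ec) & (z <= model.z_vest_top)
    out[in_vest_band & (r <= model.r_vest)] = Region.VESTIBULE
    lo, hi = model.fen_band
    fen = (z >= lo) & (z <= hi) & (r > model.r_vest) & (r <= model.r_vest + model.fen_width)
    out[fen] = Region.FENESTRATION
    return out


def region_with_margin(position, model: RegionModel, margin: float) -> str | None:
    """Region label if the position lies at least ``margin`` inside the
    region's bounding surfaces, else ``None``.

    This is the committing test of the hysteresis scheme: an ion changes its
    committed region only once it has penetrated ``margin`` (δz) beyond every
    boundary of the new region, which suppresses thermal recrossing noise.
    With ``margin == 0`` it reduces to :func:`assign_region`.
    """
    raw = assign_region(position, model)
    if margin == 0:
        return raw
    x, y, z = (float(v) for v in position)
    r = model.radial(x, y)
    d = margin
    if raw == Region.IC:
        return raw if z <= model.z_ic - d else None
    if raw == Region.PORE:
        ok = (model.z_ic + d <= z <= model.z_ec - d) and r <= model.r_vest - d
        return raw if ok else None
    if raw == Region.VESTIBULE:
        ok = (model.z_ec + d <= z <= model.z_vest_top - d) and r <= model.r_vest - d
        return raw if ok else None
    if raw == Region.FENESTRATION:
        lo, hi = model.fen_band
        ok = (lo + d <= z <= hi - d) and (model.r_vest + d <= r <= model.r_vest + model.fen_width - d)
        return raw if ok else None
    if raw == Region.MEMBRANE_EXTERIOR:
        ok = (model.z_ic + d <= z <= model.z_ec - d) and r >= model.r_vest + d
        return raw if ok else None
    # EC: committed when clearly above the ceiling or clearly outside the
    # fenestrated wall
    if z >= model.z_vest_top + d:
        return Region.EC
    if z >= model.z_ec + d and r >= model.r_vest + model.fen_width + d:
        return Region.EC
    return None
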