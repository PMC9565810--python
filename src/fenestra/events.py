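"""Permeation-event detection and vestibular occupancy.

The detector is a compartment state machine. Each ion carries a *committed*
region that only changes when the ion penetrates the hysteresis margin δz
beyond the boundary of a new region (see
:func:`fenestra.geometry.region_with_margin`); thermal recrossings inside the
margin emit nothing. Permeation events are emitted on transitions between the
terminal compartments (intracellular bath, vestibule, extracellular bath):

* VESTIBULE → IC: transmembrane, inward (chloride moving EC→IC).
* IC → VESTIBULE: transmembrane, outward.
* EC → VESTIBULE: inward, classified *lateral* if the crossing traverses the
  side wall within the fenestration band (or the transit passed through the
  FENESTRATION region), *apical* if it traverses the ceiling disc within
  ``r_apical`` of the axis.
* VESTIBULE → EC: outward, same classification.

Direction labels are geometric; the mapping to electrical current sign (for
an anion, inward chloride movement is outward current) is done once in
:mod:`fenestra.currents`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import Region, RegionModel, assign_region, assign_regions, region_with_margin
from .tracks import IonTrack, unwrap_track

__all__ = [
    "PermeationEvent",
    "EventLog",
    "OccupancySeries",
    "detect_events",
    "detect_events_all",
    "vestibule_occupancy",
    "read_events_tsv",
    "write_events_tsv",
]

PATHWAYS = ("transmembrane", "lateral", "apical")
DIRECTIONS = ("inward", "outward")


@dataclass(frozen=True)
class PermeationEvent:
    """One classified crossing."""

    ion_id: str
    time: float  # ns, commit time
    pathway: str  # transmembrane | lateral | apical
    direction: str  # inward | outward (geometric, see module docstring)

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise ValueError(f"unknown pathway {self.pathway!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class EventLog:
    """Events from one run, with the metadata current estimates need."""

    events: list[PermeationEvent]
    total_time: float  # ns
    voltage: float = 0.0  # mV
    n_ions: int = 0

    def __post_init__(self) -> None:
        if self.total_time <= 0:
            raise ValueError("total_time must be positive")
        self.events = sorted(self.events, key=lambda e: e.time)

    def count(self, pathway: str | None = None, direction: str | None = None) -> int:
        return sum(
            1
            for e in self.events
            if (pathway is None or e.pathway == pathway)
            and (direction is None or e.direction == direction)
        )

    def rate(self, pathway: str | None = None, direction: str | None = None) -> float:
        """Event rate in events/ns."""
        return self.count(pathway, direction) / self.total_time

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ns": [e.time for e in self.events],
                "ion_id": [e.ion_id for e in self.events],
                "pathway": [e.pathway for e in self.events],
                "direction": [e.direction for e in self.events],
            }
        )


@dataclass
class OccupancySeries:
    """Per-frame ion count in the vestibule."""

    times: np.ndarray
    counts: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def sd(self) -> float:
        return float(np.std(self.counts))


def _segment_crossing_pathway(positions: np.ndarray, model: RegionModel, entering: bool) -> str:
    """Classify an EC↔vestibule crossing from the coordinate segment.

    ``positions`` spans from the last committed frame in the source terminal
    to the commit frame in the destination. For an entry the *last* raw
    crossing into the vestibule is classified; for an exit the *first* raw
    crossing out of it (the two choices are mirror images, preserving
    time-reversal symmetry).
    """
    raw = assign_regions(positions, model)
    if Region.FENESTRATION in raw:
        return "lateral"
    if entering:
        idx = [j for j in range(len(raw) - 1) if raw[j] != Region.VESTIBULE and raw[j + 1] == Region.VESTIBULE]
        j = idx[-1] if idx else None
    else:
        idx = [j for j in range(len(raw) - 1) if raw[j] == Region.VESTIBULE and raw[j + 1] != Region.VESTIBULE]
        j = idx[0] if idx else None
    if j is None:
        # degenerate (coarse frames); fall back on the endpoint heights
        z_out = positions[0, 2] if entering else positions[-1, 2]
        return "apical" if z_out > model.z_vest_top else "lateral"
    p0, p1 = positions[j], positions[j + 1]
    z0, z1 = p0[2], p1[2]
    top = model.z_vest_top
    if (z0 - top) * (z1 - top) < 0:
        # crosses the ceiling plane; apical if within the aperture there
        t = (top - z0) / (z1 - z0)
        xy = p0[:2] + t * (p1[:2] - p0[:2])
        if model.radial(xy[0], xy[1]) <= model.r_apical:
            return "apical"
    r0 = model.radial(p0[0], p0[1])
    r1 = model.radial(p1[0], p1[1])
    if (r0 - model.r_vest) * (r1 - model.r_vest) < 0:
        # exact crossing of the cylinder r = r_vest along the straight segment
        ax, ay = model.axis_xy
        ux, uy = p0[0] - ax, p0[1] - ay
        dx, dy = p1[0] - p0[0], p1[1] - p0[1]
        a = dx * dx + dy * dy
        b = 2.0 * (ux * dx + uy * dy)
        c = ux * ux + uy * uy - model.r_vest**2
        disc = b * b - 4.0 * a * c
        ts = []
        if a > 0 and disc >= 0:
            sq = math.sqrt(disc)
            ts = [t for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)) if 0.0 < t < 1.0]
        t = ts[0] if ts else (model.r_vest - r0) / (r1 - r0)
        z_cross = z0 + t * (z1 - z0)
        lo, hi = model.fen_band
        if lo <= z_cross <= hi:
            return "lateral"
    # ambiguous: decide by where the non-vestibule endpoint sits
    z_out = z0 if entering else z1
    return "apical" if z_out > top else "lateral"


def _emit(src: str, dst: str, seg: np.ndarray, model: RegionModel, ion_id: str, time: float) -> list[PermeationEvent]:
    """Events for a committed terminal→terminal transition over segment seg."""
    ev: list[PermeationEvent] = []
    if {src, dst} == {Region.VESTIBULE, Region.IC}:
        direction = "inward" if dst == Region.IC else "outward"
        ev.append(PermeationEvent(ion_id, time, "transmembrane", direction))
    elif {src, dst} == {Region.VESTIBULE, Region.EC}:
        entering = dst == Region.VESTIBULE
        pathway = _segment_crossing_pathway(seg, model, entering)
        ev.append(PermeationEvent(ion_id, time, pathway, "inward" if entering else "outward"))
    else:
        # direct IC↔EC transition: the ion necessarily transited the
        # vestibule between committed frames; decompose into both crossings
        if dst == Region.IC:  # EC -> IC
            pathway = _segment_crossing_pathway(seg, model, True)
            ev.append(PermeationEvent(ion_id, time, pathway, "inward"))
            ev.append(PermeationEvent(ion_id, time, "transmembrane", "inward"))
        else:  # IC -> EC
            ev.append(PermeationEvent(ion_id, time, "transmembrane", "outward"))
            pathway = _segment_crossing_pathway(seg, model, False)
            ev.append(PermeationEvent(ion_id, time, pathway, "outward"))
    return ev


def detect_events(
    track: IonTrack,
    model: RegionModel,
    *,
    unwrap: bool = True,
    hysteresis: float | None = None,
) -> list[PermeationEvent]:
    """Detect and classify permeation events on one ion track.

    Parameters
    ----------
    track : IonTrack
        at least two frames.
    model : RegionModel
        compartment geometry.
    unwrap : bool
        apply minimal-image unwrapping along z first (default True).
    hysteresis : float, optional
        override ``model.hysteresis`` (Å).

    Returns events in time order; a track that never leaves one region yields
    an empty list.
    """
    if len(track) < 2:
        raise ValueError("track must have at least 2 frames")
    if unwrap:
        track = unwrap_track(track)
    margin = model.hysteresis if hysteresis is None else hysteresis
    pos = track.positions
    times = track.times

    events: list[PermeationEvent] = []
    last_terminal: str | None = None
    seg_start = 0  # index of last frame committed in last_terminal
    for i in range(len(track)):
        lab = region_with_margin(pos[i], model, margin)
        if lab is None:
            continue
        if lab in Region.TERMINAL:
            if last_terminal is None:
                last_terminal = lab
                seg_start = i
            elif lab == last_terminal:
                seg_start = i
            else:
                seg = pos[seg_start : i + 1]
                events.extend(_emit(last_terminal, lab, seg, model, track.ion_id, float(times[i])))
                last_terminal = lab
                seg_start = i
    return events


def detect_events_all(
    tracks: Iterable[IonTrack],
    model: RegionModel,
    *,
    voltage: float = 0.0,
    unwrap: bool = True,
) -> EventLog:
    """Run :func:`detect_events` over an ensemble and assemble an EventLog.

    Total time is the common span of the tracks (they are expected to share a
    frame grid).
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks given")
    events: list[PermeationEvent] = []
    for t in tracks:
        events.extend(detect_events(t, model, unwrap=unwrap))
    total_time = float(max(t.times[-1] - t.times[0] for t in tracks))
    return EventLog(events=events, total_time=total_time, voltage=voltage, n_ions=len(tracks))


def vestibule_occupancy(
    tracks: Sequence[IonTrack],
    model: RegionModel,
    species: str | None = "chloride",
) -> OccupancySeries:
    """Per-frame count of ions inside the vestibule.

    All tracks must share the same frame grid. ``species=None`` counts every
    ion.
    """
    tracks = [t for t in tracks if species is None or t.species == species]
    if not tracks:
        raise ValueError("no tracks of the requested species")
    times = tracks[0].times
    for t in tracks[1:]:
        if len(t.times) != len(times) or not np.allclose(t.times, times):
            raise ValueError("tracks do not share a frame grid")
    counts = np.zeros(len(times), dtype=int)
    for t in tracks:
        counts += assign_regions(t.positions, model) == Region.VESTIBULE
    return OccupancySeries(times=times.copy(), counts=counts)


def write_events_tsv(log: EventLog, path: str | Path) -> None:
    df = log.to_dataframe()
    with open(path, "w") as fh:
        fh.write(f"# total_time_ns={log.total_time:.6f}\tvoltage_mV={log.voltage:g}\tn_ions={log.n_ions}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_events_tsv(path: str | Path) -> EventLog:
    total_time, voltage, n_ions = None, 0.0, 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                key, _, val = tok.partition("=")
                if key == "total_time_ns":
                    total_time = float(val)
                elif key == "voltage_mV":
                    voltage = float(val)
                elif key == "n_ions":
                    n_ions = int(val)
            df = pd.read_csv(fh, sep="\t")
        else:
            df = pd.read_csv(path, sep="\t")
    if total_time is None:
        total_time = float(df["time_ns"].max()) if len(df) else 1.0
        warnings.warn("event file lacks a total_time header; using last event time")
    events = [
        PermeationEvent(str(r.ion_id), float(r.time_ns), str(r.pathway), str(r.direction))
        for r in df.itertuples()
    ]
    return EventLog(events=events, total_time=total_time, voltage=voltage, n_ions=n_ions)
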