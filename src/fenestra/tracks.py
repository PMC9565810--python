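"""Ion trajectory containers and I/O.

An :class:`IonTrack` is the time-ordered 3D path of a single ion, the raw
input of permeation analysis. Tracks are exchanged as tab-separated text with
columns ``frame, time_ns, ion_id, species, x, y, z, box_z`` (Å, ns); standard
MD trajectory formats can be ingested through MDAnalysis behind the same
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IonTrack",
    "unwrap_track",
    "read_tracks_tsv",
    "write_tracks_tsv",
    "tracks_from_md",
]

TRACK_COLUMNS = ["frame", "time_ns", "ion_id", "species", "x", "y", "z", "box_z"]


@dataclass
class IonTrack:
    """Time-ordered positions of one ion.

    Attributes
    ----------
    ion_id : str
        identifier of the ion.
    species : str
        ion species label, e.g. ``"chloride"`` or ``"sodium"``.
    times : ndarray, shape (n,)
        frame times in ns, strictly increasing.
    positions : ndarray, shape (n, 3)
        (x, y, z) coordinates in Å.
    box_z : ndarray, shape (n,)
        periodic box length along z per frame, Å.
    """

    ion_id: str
    species: str
    times: np.ndarray
    positions: np.ndarray
    box_z: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.box_z = np.asarray(self.box_z, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        n = len(self.times)
        if len(self.positions) != n or len(self.box_z) != n:
            raise ValueError("times, positions and box_z must have equal length")
        if n >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.box_z <= 0):
            raise ValueError("box_z must be positive")

    def __len__(self) -> int:
        return len(self.times)

    def reversed(self) -> "IonTrack":
        """Time-reversed copy on the same (increasing) time grid."""
        return replace(
            self,
            times=self.times,
            positions=self.positions[::-1].copy(),
            box_z=self.box_z[::-1].copy(),
        )


def unwrap_track(track: IonTrack) -> IonTrack:
    """Remove periodic-boundary jumps along z by minimal-image continuation.

    Successive z displacements are mapped into (-box_z/2, +box_z/2] and summed
    cumulatively; an exact half-box displacement is assigned a positive sign
    (deterministic tie break). x and y are untouched.
    """
    z = track.positions[:, 2]
    if len(z) < 2:
        return track
    dz = np.diff(z)
    box = track.box_z[1:]
    # wrapped displacement in (-box/2, box/2]; ceil places +box/2 on the
    # positive side
    wrapped = dz - box * np.ceil(dz / box - 0.5)
    new_z = np.concatenate([[z[0]], z[0] + np.cumsum(wrapped)])
    pos = track.positions.copy()
    pos[:, 2] = new_z
    return replace(track, positions=pos)


def write_tracks_tsv(tracks: Iterable[IonTrack], path: str | Path) -> None:
    """Write tracks to the tab-separated exchange format (one row per frame)."""
    frames = []
    for t in tracks:
        df = pd.DataFrame(
            {
                "frame": np.arange(len(t)),
                "time_ns": t.times,
                "ion_id": t.ion_id,
                "species": t.species,
                "x": t.positions[:, 0],
                "y": t.positions[:, 1],
                "z": t.positions[:, 2],
                "box_z": t.box_z,
            }
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRACK_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_tracks_tsv(path: str | Path) -> list[IonTrack]:
    """Read tracks from the tab-separated exchange format."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track file missing columns: {sorted(missing)}")
    tracks = []
    for ion_id, grp in df.groupby("ion_id", sort=True):
        grp = grp.sort_values("time_ns")
        tracks.append(
            IonTrack(
                ion_id=str(ion_id),
                species=str(grp["species"].iloc[0]),
                times=grp["time_ns"].to_numpy(),
                positions=grp[["x", "y", "z"]].to_numpy(),
                box_z=grp["box_z"].to_numpy(),
            )
        )
    return tracks


def tracks_from_md(
    topology: str | Path,
    trajectory: str | Path | Sequence[str | Path] | None = None,
    selection: str = "resname CLA CL",
    species: str = "chloride",
) -> list[IonTrack]:
    """Extract ion tracks from a standard MD trajectory (XTC/TRR/DCD + GRO/PDB).

    Requires MDAnalysis (optional dependency). Times are converted from ps to
    ns; coordinates are taken as stored (Å) — run :func:`unwrap_track` before
    event detection if the trajectory is wrapped.
    """
    import MDAnalysis as mda  # deferred: optional dependency

    u = mda.Universe(str(topology)) if trajectory is None else mda.Universe(str(topology), trajectory)
    ions = u.select_atoms(selection)
    if len(ions) == 0:
        raise ValueError(f"selection {selection!r} matched no atoms")
    n_frames = len(u.trajectory)
    times = np.empty(n_frames)
    box_z = np.empty(n_frames)
    pos = np.empty((n_frames, len(ions), 3))
    for i, ts in enumerate(u.trajectory):
        times[i] = ts.time / 1000.0  # ps -> ns
        box_z[i] = ts.dimensions[2]
        pos[i] = ions.positions
    return [
        IonTrack(
            ion_id=str(atom.ix),
            species=species,
            times=times,
            positions=pos[:, j, :].copy(),
            box_z=box_z.copy(),
        )
        for j, atom in enumerate(ions)
    ]
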