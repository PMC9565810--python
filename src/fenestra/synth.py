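"""Synthetic ion trajectories with known ground-truth crossing rates.

The generator emulates what matters to the detection bookkeeping of real
computational-electrophysiology data — ions dwelling in compartments,
thermal jitter, and pathway-specific crossings rendered as continuous
excursions through the correct gate geometry — without any physics (no
electrostatics, no ion–ion interaction, no membrane).

Crossings are scheduled as Poisson processes per pathway and direction
(events/ns, ensemble totals). Transmembrane rates are voltage modulated the
same way as the kinetic model: the direction along the electrochemical
gradient is scaled by (1 + drift_gain·|V|), the direction against it by
exp(−drift_gain·|V|); lateral and apical rates are voltage independent. Each
scheduled crossing is assigned to an idle ion in the source compartment (or
dropped if none is available — dropped events are absent from the ground
truth) and rendered over several frames through pathway-specific waypoints,
so the detector's hysteresis logic is genuinely exercised. Idle ions perform
mean-reverting (Ornstein–Uhlenbeck-style) jitter around a compartment
anchor, a modeling convenience that keeps them from drifting through walls.

Identical configuration and seed give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .events import DIRECTIONS, PATHWAYS, EventLog, PermeationEvent
from .geometry import Region, RegionModel
from .tracks import IonTrack

__all__ = [
    "PathwayRates",
    "GeneratorConfig",
    "GroundTruth",
    "RecoveryReport",
    "generate_tracks",
    "recovery_report",
    "occupancy_rates",
]


@dataclass(frozen=True)
class PathwayRates:
    """Ensemble crossing rates in events/ns, per pathway and direction.

    Directions are geometric: ``tm_inward`` is vestibule→IC chloride
    movement, ``lat_inward``/``api_inward`` are EC→vestibule.
    """

    tm_inward: float = 0.0
    tm_outward: float = 0.0
    lat_inward: float = 0.0
    lat_outward: float = 0.0
    api_inward: float = 0.0
    api_outward: float = 0.0

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "tm_inward": self.tm_inward,
            "tm_outward": self.tm_outward,
            "lat_inward": self.lat_inward,
            "lat_outward": self.lat_outward,
            "api_inward": self.api_inward,
            "api_outward": self.api_outward,
        }


# (pathway, direction) -> (source compartment, destination compartment)
_STREAMS = {
    ("transmembrane", "inward"): (Region.VESTIBULE, Region.IC),
    ("transmembrane", "outward"): (Region.IC, Region.VESTIBULE),
    ("lateral", "inward"): (Region.EC, Region.VESTIBULE),
    ("lateral", "outward"): (Region.VESTIBULE, Region.EC),
    ("apical", "inward"): (Region.EC, Region.VESTIBULE),
    ("apical", "outward"): (Region.VESTIBULE, Region.EC),
}

_RATE_KEYS = {
    ("transmembrane", "inward"): "tm_inward",
    ("transmembrane", "outward"): "tm_outward",
    ("lateral", "inward"): "lat_inward",
    ("lateral", "outward"): "lat_outward",
    ("apical", "inward"): "api_inward",
    ("apical", "outward"): "api_outward",
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic run.

    ``duration`` (ns), ``dt`` (ns/frame) and ``n_ions`` size the ensemble;
    ``rates`` are the scheduled crossing intensities; ``voltage`` (mV) and
    ``drift_gain`` (per mV) modulate the transmembrane rates; ``noise_sd``
    (Å) scales the positional jitter; ``n_render`` is the number of frames a
    crossing excursion spans; ``seed`` is mandatory.
    """

    geometry: RegionModel = field(default_factory=RegionModel)
    n_ions: int = 30
    duration: float = 100.0
    dt: float = 0.1
    rates: PathwayRates = field(default_factory=PathwayRates)
    drift_gain: float = 0.0
    voltage: float = 0.0
    noise_sd: float = 0.5
    seed: int = 0
    n_render: int = 8
    n_vest_init: int = 3
    box_z: float = 170.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration / self.dt < 10:
            raise ValueError("need at least 10 frames (duration/dt)")
        if self.n_render < 5:
            raise ValueError("crossings must span >= 5 frames")
        if self.noise_sd < 0 or self.drift_gain < 0:
            raise ValueError("noise_sd and drift_gain must be >= 0")
        g = self.geometry
        if g.z_vest_top - g.z_ec < 4 * g.hysteresis or g.r_vest < 3 * g.hysteresis:
            raise ValueError("geometry too small to render excursions cleanly")

    def effective_rates(self) -> dict[tuple[str, str], float]:
        """Scheduled intensities after voltage modulation of the
        transmembrane streams (positive voltage drives chloride influx, i.e.
        geometric inward)."""
        r = self.rates.as_dict()
        out = {stream: r[key] for stream, key in _RATE_KEYS.items()}
        if self.voltage != 0:
            up = 1.0 + self.drift_gain * abs(self.voltage)
            down = math.exp(-self.drift_gain * abs(self.voltage))
            if self.voltage > 0:
                out[("transmembrane", "inward")] *= up
                out[("transmembrane", "outward")] *= down
            else:
                out[("transmembrane", "outward")] *= up
                out[("transmembrane", "inward")] *= down
        return out


@dataclass
class GroundTruth:
    """True (rendered) events and the realized per-stream rates."""

    log: EventLog
    realized_rates: dict[tuple[str, str], float]
    scheduled_rates: dict[tuple[str, str], float]


class _Ion:
    __slots__ = ("ion_id", "compartment", "pos", "anchor", "path", "pending")

    def __init__(self, ion_id: str, compartment: str, pos: np.ndarray, anchor: np.ndarray):
        self.ion_id = ion_id
        self.compartment = compartment
        self.pos = pos
        self.anchor = anchor
        self.path: list[np.ndarray] = []  # upcoming rendered frames
        self.pending: tuple[str, str] | None = None

    @property
    def idle(self) -> bool:
        return not self.path


def _anchor(rng: np.random.Generator, g: RegionModel, compartment: str) -> np.ndarray:
    ax, ay = g.axis_xy
    phi = rng.uniform(0, 2 * math.pi)
    if compartment == Region.EC:
        r = rng.uniform(8.0, 30.0)
        z = g.z_vest_top + rng.uniform(10.0, 20.0)
    elif compartment == Region.IC:
        r = rng.uniform(0.0, 25.0)
        z = g.z_ic - rng.uniform(10.0, 20.0)
    else:  # vestibule: keep well clear of every boundary
        r = rng.uniform(0.0, max(g.r_vest - 5.0, 1.0))
        z = 0.5 * (g.z_ec + g.z_vest_top)
    return np.array([ax + r * math.cos(phi), ay + r * math.sin(phi), z])


def _waypoints(
    rng: np.random.Generator, g: RegionModel, pathway: str, direction: str, start: np.ndarray, dest: np.ndarray
) -> list[np.ndarray]:
    """Gate waypoints a rendered crossing passes through (start/dest excluded)."""
    ax, ay = g.axis_xy
    h = g.hysteresis
    clear = h + 2.0  # penetration beyond each plane that guarantees a commit
    axis = lambda z: np.array([ax, ay, z])
    if pathway == "transmembrane":
        pore_mid = axis(0.5 * (g.z_ic + g.z_ec))
        below = axis(g.z_ic - clear - 2.0)
        above = axis(g.z_ec + clear + 2.0)
        pts = [above, pore_mid, below]
        return pts if direction == "inward" else pts[::-1]
    if pathway == "lateral":
        lo, hi = g.fen_band
        z_f = 0.5 * (lo + hi)
        phi = rng.uniform(0, 2 * math.pi)
        u = np.array([math.cos(phi), math.sin(phi)])
        r_out = g.r_vest + g.fen_width + clear + 2.0
        ring = lambda r, z: np.array([ax + r * u[0], ay + r * u[1], z])
        # approach descends outside the fenestrated wall so the EC-side leg
        # never clips the vestibule or the apical disc
        above = ring(r_out, g.z_vest_top + clear + 2.0)
        outside = ring(r_out, z_f)
        tunnel = ring(g.r_vest + 0.5 * g.fen_width, z_f)
        inside = ring(max(g.r_vest - clear - 2.0, 0.0), z_f)
        pts = [above, outside, tunnel, inside]
        return pts if direction == "inward" else pts[::-1]
    # apical: through the ceiling disc close to the axis
    above = axis(g.z_vest_top + clear + 2.0)
    inside = axis(g.z_vest_top - clear - 2.0)
    pts = [above, inside]
    return pts if direction == "inward" else pts[::-1]


def _render_path(
    rng: np.random.Generator,
    g: RegionModel,
    pathway: str,
    direction: str,
    start: np.ndarray,
    dest: np.ndarray,
    n_render: int,
    jitter: float,
) -> list[np.ndarray]:
    pts = [start] + _waypoints(rng, g, pathway, direction, start, dest) + [dest]
    pts = np.asarray(pts)
    # arc-length parameterisation over the waypoint polyline
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] == 0:
        return [dest.copy() for _ in range(n_render)]
    s = np.linspace(0, cum[-1], n_render + 1)[1:]
    path = []
    for si in s:
        j = min(np.searchsorted(cum, si, side="right") - 1, len(seg) - 1)
        frac = (si - cum[j]) / seg[j] if seg[j] > 0 else 0.0
        p = pts[j] + frac * (pts[j + 1] - pts[j])
        path.append(p + rng.normal(0.0, jitter, 3))
    path[-1] = dest.copy()  # land exactly on the new anchor
    return path


def generate_tracks(config: GeneratorConfig) -> tuple[list[IonTrack], GroundTruth]:
    """Generate an ion-track ensemble and its ground truth.

    Returns one :class:`IonTrack` per ion (shared frame grid) and a
    :class:`GroundTruth` whose log contains every rendered crossing with its
    pathway, direction, ion and mid-excursion time.
    """
    g = config.geometry
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration / config.dt)) + 1
    times = np.arange(n_frames) * config.dt

    ions: list[_Ion] = []
    n_vest = min(config.n_vest_init, config.n_ions)
    n_rest = config.n_ions - n_vest
    n_ec = (n_rest + 1) // 2
    comps = [Region.VESTIBULE] * n_vest + [Region.EC] * n_ec + [Region.IC] * (n_rest - n_ec)
    for i, comp in enumerate(comps):
        a = _anchor(rng, g, comp)
        ions.append(_Ion(f"ion{i:03d}", comp, a.copy(), a))

    streams = list(_STREAMS)
    eff = config.effective_rates()
    truth_events: list[PermeationEvent] = []
    positions = np.empty((n_frames, config.n_ions, 3))
    theta = 2.0  # OU mean-reversion rate, 1/ns
    sqrt_dt = math.sqrt(config.dt)
    render_jitter = min(0.3 * config.noise_sd, 0.5)

    for f in range(n_frames):
        t = times[f]
        # crossings are not scheduled in the last n_render frames: a
        # truncated excursion would be an uncommitted (hence untrue) event
        can_schedule = 0 < f <= n_frames - 1 - config.n_render
        if f > 0 and can_schedule:
            # schedule crossings for this frame interval
            for stream in streams:
                lam = eff[stream] * config.dt
                if lam <= 0:
                    continue
                for _ in range(rng.poisson(lam)):
                    src, dst = _STREAMS[stream]
                    candidates = [i for i in ions if i.idle and i.compartment == src]
                    if not candidates:
                        continue  # dropped: no eligible ion
                    ion = candidates[rng.integers(len(candidates))]
                    dest = _anchor(rng, g, dst)
                    ion.path = _render_path(
                        rng, g, stream[0], stream[1], ion.pos, dest, config.n_render, render_jitter
                    )
                    ion.pending = stream
                    ion.compartment = dst
                    ion.anchor = dest
                    truth_events.append(
                        PermeationEvent(
                            ion.ion_id,
                            float(t + 0.5 * config.n_render * config.dt),
                            stream[0],
                            stream[1],
                        )
                    )
        if f > 0:
            # advance ions
            for ion in ions:
                if ion.path:
                    ion.pos = ion.path.pop(0)
                else:
                    drift = theta * (ion.anchor - ion.pos) * config.dt
                    ion.pos = ion.pos + drift + rng.normal(0.0, config.noise_sd * sqrt_dt, 3)
        for j, ion in enumerate(ions):
            positions[f, j] = ion.pos

    tracks = [
        IonTrack(
            ion_id=ion.ion_id,
            species="chloride",
            times=times.copy(),
            positions=positions[:, j].copy(),
            box_z=np.full(n_frames, config.box_z),
        )
        for j, ion in enumerate(ions)
    ]
    log = EventLog(
        events=truth_events, total_time=float(times[-1] - times[0]), voltage=config.voltage, n_ions=config.n_ions
    )
    realized = {s: log.count(s[0], s[1]) / log.total_time for s in streams}
    return tracks, GroundTruth(log=log, realized_rates=realized, scheduled_rates=eff)


@dataclass
class RecoveryReport:
    """Detector fidelity versus the generator ground truth."""

    rate_errors: dict[tuple[str, str], float]  # relative, detected vs realized truth
    misclassified: int  # matched events with wrong pathway/direction
    missed: int  # truth events with no detected partner
    spurious: int  # detected events with no truth partner
    n_truth: int
    n_detected: int


def recovery_report(detected: EventLog, truth: GroundTruth, time_tol: float = 5.0) -> RecoveryReport:
    """Compare a detected event log against generator ground truth.

    Events are matched per ion, greedily by time within ``time_tol`` ns;
    matched pairs with differing pathway or direction count as
    misclassifications.
    """
    rate_errors = {}
    for stream, true_rate in truth.realized_rates.items():
        det = detected.count(stream[0], stream[1]) / detected.total_time
        if true_rate > 0:
            rate_errors[stream] = (det - true_rate) / true_rate
        else:
            rate_errors[stream] = float("inf") if det > 0 else 0.0

    by_ion_truth: dict[str, list[PermeationEvent]] = {}
    for e in truth.log.events:
        by_ion_truth.setdefault(e.ion_id, []).append(e)
    by_ion_det: dict[str, list[PermeationEvent]] = {}
    for e in detected.events:
        by_ion_det.setdefault(e.ion_id, []).append(e)

    mis = missed = spurious = 0
    for ion_id, tevs in by_ion_truth.items():
        devs = list(by_ion_det.pop(ion_id, []))
        for te in tevs:
            if not devs:
                missed += 1
                continue
            j = int(np.argmin([abs(d.time - te.time) for d in devs]))
            if abs(devs[j].time - te.time) > time_tol:
                missed += 1
                continue
            de = devs.pop(j)
            if de.pathway != te.pathway or de.direction != te.direction:
                mis += 1
        spurious += len(devs)
    spurious += sum(len(v) for v in by_ion_det.values())
    return RecoveryReport(
        rate_errors=rate_errors,
        misclassified=mis,
        missed=missed,
        spurious=spurious,
        n_truth=len(truth.log.events),
        n_detected=len(detected.events),
    )


def occupancy_rates(target_mean: float, churn: float = 1.0) -> PathwayRates:
    """Lateral entry/exit intensities giving a target mean vestibule count.

    Exits are scheduled globally but can only fire when the vestibule is
    occupied, so occupancy behaves like a single-server queue with arrival
    rate λ and service rate μ = ``churn``: mean = ρ/(1−ρ) with ρ = λ/μ, hence
    λ = churn·m/(1+m) for target mean m.
    """
    if target_mean <= 0:
        raise ValueError("target_mean must be positive")
    if churn <= 0:
        raise ValueError("churn must be positive")
    lam = churn * target_mean / (1.0 + target_mean)
    return PathwayRates(lat_inward=lam, lat_outward=churn)
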