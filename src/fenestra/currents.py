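"""Currents, conductances and I–V statistics from permeation-event logs.

A constant electric field E_z applied over a periodic box of height L_z
imposes the transmembrane potential V_m = E_z · L_z. The single-channel
current is estimated by counting transmembrane permeation events per unit
time, I = N·e/T, with a Poisson counting error σ = I/√N, and the conductance
as g = I/V_m.

Sign convention: event directions in :mod:`fenestra.events` are geometric
(inward = chloride moving extracellular→intracellular). For an anion that
geometric inward movement carries an *outward* (positive) electrical
current, so the signed current here is
``I ∝ (inward − outward transmembrane events)`` and an ohmic channel gives
I > 0 at V > 0. Reports follow the patch-clamp presentation: current
magnitudes with branch labels, the negative-voltage branch being the inward
current branch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .events import EventLog

__all__ = [
    "E_CHARGE_PA_NS",
    "FieldSpec",
    "CurrentEstimate",
    "IVDataset",
    "PermeabilityReport",
    "SlopeFit",
    "voltage_from_field",
    "current_from_events",
    "net_transmembrane_count",
    "pathway_fractions",
    "lateral_permeability_ratio",
    "assemble_iv",
    "fit_two_slopes",
    "percent_change",
]

#: one elementary charge per ns expressed in pA (1.602176634e-19 C / 1e-9 s)
E_CHARGE_PA_NS = 160.2176634


def voltage_from_field(E_z: float, L_z: float) -> float:
    """Transmembrane potential V_m = E_z · L_z (mV from mV/Å and Å)."""
    if L_z <= 0:
        raise ValueError("L_z must be positive")
    return E_z * L_z


@dataclass(frozen=True)
class FieldSpec:
    """Constant-field setup: E_z (mV/Å) over L_z (Å), with V_m = E_z·L_z."""

    E_z: float
    L_z: float

    @property
    def V_m(self) -> float:
        return voltage_from_field(self.E_z, self.L_z)


@dataclass(frozen=True)
class CurrentEstimate:
    """Current from event counting with Poisson error.

    ``I`` is the current magnitude in pA, ``N`` the (net) number of
    transmembrane events, ``sigma = I/√N``, ``T`` the observation time in ns,
    ``V`` the voltage in mV and ``sign`` the electrical sign of the current
    (+1 outward).
    """

    I: float
    N: int
    sigma: float
    T: float
    V: float = 0.0
    sign: int = 1

    @property
    def signed_current(self) -> float:
        return self.sign * self.I

    def conductance(self) -> float:
        """Conductance g = I/|V_m| in pS."""
        if self.V == 0:
            raise ValueError("conductance undefined at zero voltage")
        return self.I / abs(self.V) * 1000.0  # pA/mV -> pS


def current_from_events(N: int, T: float, V: float = 0.0, sign: int = 1) -> CurrentEstimate:
    """Current estimate from N net transmembrane events over T ns at V mV."""
    if T <= 0:
        raise ValueError("observation time must be positive")
    if N < 0:
        raise ValueError("event count must be >= 0")
    I = N * E_CHARGE_PA_NS / T
    sigma = I / math.sqrt(N) if N > 0 else 0.0
    return CurrentEstimate(I=I, N=N, sigma=sigma, T=T, V=V, sign=sign)


def net_transmembrane_count(log: EventLog) -> tuple[int, int]:
    """(net transmembrane count along the gradient, electrical current sign).

    Net = |inward − outward| transmembrane events; sign is +1 (outward
    electrical current) when geometric inward chloride events dominate.
    """
    n_in = log.count("transmembrane", "inward")
    n_out = log.count("transmembrane", "outward")
    net = n_in - n_out
    return abs(net), (1 if net >= 0 else -1)


@dataclass
class IVDataset:
    """Signed (V mV, I pA, σ pA) points for one construct."""

    voltages: np.ndarray
    currents: np.ndarray
    sigmas: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if len(set(self.voltages.tolist())) != len(self.voltages):
            raise ValueError("voltages must be unique (pool replicas first)")
        order = np.argsort(self.voltages)
        self.voltages = self.voltages[order]
        self.currents = self.currents[order]
        self.sigmas = self.sigmas[order]


@dataclass
class PermeabilityReport:
    """Pathway-resolved rates and the apical fraction of EC↔vestibule flux."""

    lateral_rate: float  # events/ns
    apical_rate: float
    tm_rate: float
    apical_fraction: float  # percent of EC↔vestibule events


def pathway_fractions(log: EventLog) -> PermeabilityReport:
    """Per-pathway event rates and the apical share of vestibule access.

    ``apical_fraction`` is 100·apical/(apical+lateral) over all
    EC↔vestibule events; NaN (with a warning) when there are none.
    """
    if not log.events:
        raise ValueError("event log is empty")
    n_lat = log.count("lateral")
    n_api = log.count("apical")
    n_tm = log.count("transmembrane")
    if n_lat + n_api == 0:
        warnings.warn("no EC<->vestibule events; apical fraction undefined")
        frac = float("nan")
    else:
        frac = 100.0 * n_api / (n_api + n_lat)
    T = log.total_time
    return PermeabilityReport(
        lateral_rate=n_lat / T, apical_rate=n_api / T, tm_rate=n_tm / T, apical_fraction=frac
    )


def _raw_lateral_ratio(log: EventLog) -> float:
    """Lateral-exit rate over the transmembrane rate along the same flux.

    At strong negative voltage chloride flows IC→vestibule→EC: both the
    lateral exit and the transmembrane entry are geometric *outward* events
    (the transmembrane leg carries the inward electrical current the ratio is
    normalised by).
    """
    n_tm = log.count("transmembrane", "outward")
    if n_tm == 0:
        raise ZeroDivisionError("no transmembrane events in replica")
    return log.count("lateral", "outward") / n_tm


def lateral_permeability_ratio(
    mutant_logs: EventLog | Sequence[EventLog],
    wt_logs: EventLog | Sequence[EventLog],
) -> tuple[float, float]:
    """Lateral permeability ratio of a mutant, normalised to wild type.

    Each replica log contributes a raw ratio (outward lateral rate over the
    transmembrane rate along the same chloride flux); replicas with zero
    transmembrane events are excluded with a warning. Returns
    ``(ratio, sem)`` where the wild type is 1.00 by construction and the SEM
    is over mutant replicas.
    """

    def ratios(logs: EventLog | Sequence[EventLog]) -> list[float]:
        if isinstance(logs, EventLog):
            logs = [logs]
        vals = []
        for lg in logs:
            try:
                vals.append(_raw_lateral_ratio(lg))
            except ZeroDivisionError:
                warnings.warn("replica with zero transmembrane events excluded")
        if not vals:
            raise ValueError("no usable replicas (all lacked transmembrane events)")
        return vals

    mutant = ratios(mutant_logs)
    wt = ratios(wt_logs)
    wt_mean = float(np.mean(wt))
    if wt_mean == 0:
        raise ValueError("wild-type raw ratio is zero; cannot normalise")
    scaled = np.asarray(mutant) / wt_mean
    sem = float(np.std(scaled, ddof=1) / math.sqrt(len(scaled))) if len(scaled) > 1 else 0.0
    return float(np.mean(scaled)), sem


def assemble_iv(runs: Iterable[tuple[float, EventLog]], label: str = "") -> IVDataset:
    """Pool replica event logs per voltage and compute signed currents.

    Replica counts at one voltage are pooled (counts and times summed) before
    the current is computed, so the estimate equals the one from a single
    concatenated log. Duplicate voltage entries are merged, never dropped.
    """
    pooled: dict[float, list[float]] = {}
    for V, log in runs:
        acc = pooled.setdefault(float(V), [0, 0, 0.0])
        acc[0] += log.count("transmembrane", "inward")
        acc[1] += log.count("transmembrane", "outward")
        acc[2] += log.total_time
    if not pooled:
        raise ValueError("no runs given")
    Vs, Is, Ss = [], [], []
    for V in sorted(pooled):
        n_in, n_out, T = pooled[V]
        net, sign = abs(n_in - n_out), (1 if n_in >= n_out else -1)
        est = current_from_events(int(net), T, V=V, sign=sign)
        Vs.append(V)
        Is.append(est.signed_current)
        Ss.append(est.sigma)
    return IVDataset(np.array(Vs), np.array(Is), np.array(Ss), label=label)


@dataclass
class SlopeFit:
    """Separate linear fits of the two I–V branches.

    Slopes are in pS; ``inward_slope`` is the fit through the
    negative-voltage (inward current) branch.
    ``index = inward_slope/outward_slope``.
    """

    inward_slope: float
    outward_slope: float
    inward_stderr: float
    outward_stderr: float
    index: float

    def rounded_index(self) -> float:
        return round(self.index, 2)


def fit_two_slopes(iv: IVDataset, weighted: bool = False) -> SlopeFit:
    """Ordinary least squares line per branch; V = 0 excluded from both.

    With ``weighted=True`` points are weighted by 1/σ² (points with σ = 0 get
    the smallest positive σ present).
    """
    neg = iv.voltages < 0
    pos = iv.voltages > 0
    if neg.sum() < 2 or pos.sum() < 2:
        raise ValueError("need >= 2 points on each branch (V=0 excluded)")

    def branch(mask) -> tuple[float, float]:
        V, I, S = iv.voltages[mask], iv.currents[mask], iv.sigmas[mask]
        if weighted:
            s = S.copy()
            if np.any(s <= 0):
                fill = s[s > 0].min() if np.any(s > 0) else 1.0
                s[s <= 0] = fill
            w = 1.0 / s**2
            W = np.sum(w)
            Vb, Ib = np.sum(w * V) / W, np.sum(w * I) / W
            sxx = np.sum(w * (V - Vb) ** 2)
            slope = np.sum(w * (V - Vb) * (I - Ib)) / sxx
            resid = I - (Ib + slope * (V - Vb))
            dof = max(len(V) - 2, 1)
            stderr = math.sqrt(np.sum(w * resid**2) / dof / sxx)
        else:
            res = stats.linregress(V, I)
            slope, stderr = res.slope, res.stderr
        return float(slope) * 1000.0, float(stderr) * 1000.0  # pA/mV -> pS

    g_in, se_in = branch(neg)
    g_out, se_out = branch(pos)
    if g_out <= 0:
        warnings.warn("non-positive outward slope; rectification index undefined")
        index = float("nan")
    else:
        index = g_in / g_out
    return SlopeFit(g_in, g_out, se_in, se_out, index)


def percent_change(mutant: float, reference: float) -> float:
    """Percent reduction of a mutant value relative to a reference.

    100·(1 − mutant/reference); rounding to the nearest integer percent for
    reporting is the caller's choice (``round(...)``).
    """
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (1.0 - mutant / reference)
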