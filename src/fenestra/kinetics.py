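"""Three-compartment kinetic model of vestibular rectification.

Chloride permeation is modeled as a two-step translocation through three
compartments — the extracellular and intracellular baths, clamped at the same
concentration A0, and the central vestibule B — separated by two barrier
layers. Lateral (k_l, k_-l) and apical (k_a, k_-a) exchange between the
extracellular bath and the vestibule is voltage independent; transmembrane
exchange between the vestibule and the intracellular bath is voltage
dependent: with the reduced voltage v = |V|/V_c, the rate along the
electrochemical gradient grows linearly, k_t·(1 + v), while the rate against
it decays exponentially, k_-t·exp(−v). Both reduce to the base rates at
V = 0. These two functional forms are the minimal choices satisfying the
model's assumptions (linear along, exponential against); they are stated
here explicitly because only the assumptions, not the forms, are fixed by
the physics.

Direction mapping: positive voltage drives chloride from the vestibule into
the cell (chloride influx, outward electrical current); negative voltage
drives chloride from the cell into the vestibule (efflux). The model
predicts vestibular chloride depletion at positive voltage, pumping at
negative voltage, a positive-branch flux plateau at (k_l + k_a)·A0, and —
when lateral translocation is hindered (k_l, k_-l scaled down, emulating
fenestration mutants) — inward rectification.

Rate constants are left in abstract reciprocal-time units; A0 defaults to 1.
A Gillespie stochastic simulator of the same jump process serves as an
independent oracle for the closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KineticParams",
    "SteadyState",
    "tm_rates",
    "steady_state",
    "model_iv",
    "rectification_index_model",
    "gillespie_simulate",
    "GillespieResult",
]


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the three-compartment scheme.

    Defaults are the reference parameter set of the model: lateral exchange
    an order of magnitude faster than transmembrane translocation, apical
    exchange twenty-fold slower than lateral.

    ``V_c`` (mV) sets the reduced voltage v = |V|/V_c; the default 50 mV maps
    the ±250 mV range onto v ∈ [0, 5].
    """

    k_l: float = 0.5
    k_minus_l: float = 0.5
    k_a: float = 0.025
    k_minus_a: float = 0.025
    k_t: float = 0.1
    k_minus_t: float = 0.1
    A0: float = 1.0
    V_c: float = 50.0

    def __post_init__(self) -> None:
        for name in ("k_l", "k_minus_l", "k_a", "k_minus_a", "k_t", "k_minus_t"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.A0 <= 0 or self.V_c <= 0:
            raise ValueError("A0 and V_c must be positive")

    def scaled_lateral(self, factor: float) -> "KineticParams":
        """Mutant scenario: k_l and k_-l scaled together by ``factor``."""
        return replace(self, k_l=self.k_l * factor, k_minus_l=self.k_minus_l * factor)


def tm_rates(V: float, p: KineticParams) -> tuple[float, float]:
    """Voltage-dependent transmembrane rates (k_along, k_against).

    ``k_along`` applies to translocation along the electrochemical gradient
    (vestibule→IC at positive V, IC→vestibule at negative V) and grows
    linearly with |V|; ``k_against`` applies to the reversed direction and
    decays exponentially, making transmembrane translocation essentially
    irreversible at large |V|.
    """
    v = abs(V) / p.V_c
    return p.k_t * (1.0 + v), p.k_minus_t * math.exp(-v)


@dataclass(frozen=True)
class SteadyState:
    """Steady state of the vestibular compartment at one voltage."""

    B_ss: float  # vestibular concentration
    B_ratio: float  # B_ss / A0
    J_net: float  # signed net transmembrane flux (concentration/time)
    V: float  # mV


def steady_state(V: float, p: KineticParams) -> SteadyState:
    """Analytic steady state of the three-compartment scheme.

    Solving d[B]/dt = 0 with clamped baths:

    * V ≥ 0 (chloride influx; transmembrane drives vestibule→IC):
      B_ss = A0·(k_l + k_a + k_against) / (k_-l + k_-a + k_along),
      J = k_along·B_ss − k_against·A0  (reported positive).
    * V < 0 (chloride efflux; transmembrane drives IC→vestibule):
      B_ss = A0·(k_l + k_a + k_along) / (k_-l + k_-a + k_against),
      J = −(k_along·A0 − k_against·B_ss).

    With the symmetric defaults (k_x = k_-x) the V ≥ 0 expression reduces to
    A0·(k_l + k_a + k_against)/(k_l + k_a + k_along). At V = 0 with symmetric
    rates, B_ss = A0 and J = 0 (detailed balance).
    """
    k_along, k_against = tm_rates(V, p)
    entry_la = p.k_l + p.k_a
    exit_la = p.k_minus_l + p.k_minus_a
    if V >= 0:
        denom = exit_la + k_along
        if denom <= 0:
            raise ValueError("all vestibule exit rates vanish")
        B = p.A0 * (entry_la + k_against) / denom
        J = k_along * B - k_against * p.A0
    else:
        denom = exit_la + k_against
        if denom <= 0:
            raise ValueError("all vestibule exit rates vanish")
        B = p.A0 * (entry_la + k_along) / denom
        J = -(k_along * p.A0 - k_against * B)
    return SteadyState(B_ss=B, B_ratio=B / p.A0, J_net=J, V=V)


def model_iv(
    p: KineticParams,
    voltages: Sequence[float],
    lateral_scale: float = 1.0,
    scenario: str | None = None,
) -> pd.DataFrame:
    """Model I–V and occupancy curves over a voltage grid.

    ``lateral_scale`` multiplies k_l and k_-l (1, 1/10, 1/100 are the
    fenestration-mutant scenarios). Returns a DataFrame with columns
    ``V_mV, J_net, B_ratio, scenario``.
    """
    voltages = np.asarray(sorted(voltages), dtype=float)
    if not (voltages.min() < 0 < voltages.max()):
        raise ValueError("voltage grid must span negative and positive values")
    ps = p.scaled_lateral(lateral_scale)
    if scenario is None:
        scenario = "WT" if lateral_scale == 1.0 else f"kl_x{lateral_scale:g}"
    rows = [steady_state(V, ps) for V in voltages]
    return pd.DataFrame(
        {
            "V_mV": voltages,
            "J_net": [r.J_net for r in rows],
            "B_ratio": [r.B_ratio for r in rows],
            "scenario": scenario,
        }
    )


def rectification_index_model(iv: pd.DataFrame, V_probe: float) -> float:
    """|J(−V_probe)| / |J(+V_probe)| from a model I–V table."""
    V = iv["V_mV"].to_numpy()
    J = iv["J_net"].to_numpy()

    def at(v: float) -> float:
        idx = np.where(np.isclose(V, v))[0]
        if len(idx) == 0:
            raise ValueError(f"voltage {v} mV not in grid")
        return float(J[idx[0]])

    j_pos = at(abs(V_probe))
    if j_pos == 0:
        raise ValueError("J(+V_probe) is zero; index undefined")
    return abs(at(-abs(V_probe))) / abs(j_pos)


@dataclass
class GillespieResult:
    """Stochastic-simulation summary.

    ``occupancy_mean`` is the time-averaged vestibule count; ``flux_net`` the
    signed net transmembrane particle flux per unit time (same convention as
    :func:`steady_state` with A0 ↔ n_A); ``counts`` maps
    (pathway, direction-of-vestibule-exchange) to event counts.
    """

    occupancy_mean: float
    flux_net: float
    counts: dict[tuple[str, str], int]
    total_time: float
    times: np.ndarray
    occupancy: np.ndarray


def gillespie_simulate(
    p: KineticParams,
    V: float,
    n_A: int,
    horizon: float,
    seed: int,
    B0: int | None = None,
) -> GillespieResult:
    """Exact stochastic simulation (direct method) of the jump process.

    The vestibule count B is the only fluctuating species; both baths are
    clamped at ``n_A`` particles. Propensities are ``rate·n_A`` for entries
    and ``rate·B`` for exits, with the voltage-dependent transmembrane rates
    of :func:`tm_rates`. ``B0`` defaults to the analytic steady state
    (rounded), which removes the equilibration transient. Randomness comes
    from ``numpy.random.default_rng(seed)``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = np.random.default_rng(seed)
    k_along, k_against = tm_rates(V, p)
    if V >= 0:
        tm_entry, tm_exit = k_against, k_along  # IC->vest, vest->IC
    else:
        tm_entry, tm_exit = k_along, k_against
    if B0 is None:
        B0 = int(round(steady_state(V, p).B_ss / p.A0 * n_A))
    B = int(B0)

    entry_rates = np.array([p.k_l, p.k_a, tm_entry]) * n_A
    exit_unit = np.array([p.k_minus_l, p.k_minus_a, tm_exit])
    labels = [
        ("lateral", "entry"),
        ("apical", "entry"),
        ("transmembrane", "entry"),
        ("lateral", "exit"),
        ("apical", "exit"),
        ("transmembrane", "exit"),
    ]
    counts = {lab: 0 for lab in labels}

    t = 0.0
    weighted_B = 0.0
    times = [0.0]
    occ = [B]
    while t < horizon:
        props = np.concatenate([entry_rates, exit_unit * B])
        total = props.sum()
        if total <= 0:
            weighted_B += B * (horizon - t)
            t = horizon
            break
        dt = rng.exponential(1.0 / total)
        if t + dt > horizon:
            weighted_B += B * (horizon - t)
            t = horizon
            break
        t += dt
        weighted_B += B * dt
        j = int(np.searchsorted(np.cumsum(props), rng.random() * total, side="right"))
        j = min(j, 5)
        counts[labels[j]] += 1
        B += 1 if j < 3 else -1
        times.append(t)
        occ.append(B)

    tm_in_events = counts[("transmembrane", "entry")]  # IC -> vestibule
    tm_out_events = counts[("transmembrane", "exit")]  # vestibule -> IC
    # signed like steady_state: positive flux = vestibule->IC (chloride influx)
    flux = (tm_out_events - tm_in_events) / horizon
    return GillespieResult(
        occupancy_mean=weighted_B / horizon,
        flux_net=flux,
        counts=counts,
        total_time=horizon,
        times=np.asarray(times),
        occupancy=np.asarray(occ, dtype=float),
    )
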