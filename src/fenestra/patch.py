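"""Single-channel recording simulation and amplitude/I–V analysis.

The simulator produces outside-out-style traces: two-state (closed/open)
continuous-time Markov gating, an ohmic open-channel current with separate
slope conductances on the two voltage branches, Gaussian instrument noise,
and an optional low-pass Bessel filter mimicking the acquisition chain
(20 kHz sampling, 1 kHz five-pole filter by default).

Analysis follows the standard single-channel chain: the all-points histogram
of a trace is fitted with the sum of two Gaussian curves; the open-channel
amplitude is the distance between the two means; per-voltage amplitudes over
patches give an I–V relation whose negative- and positive-voltage branches
are fitted by separate lines (slope conductances in pS) to yield the
rectification index. No idealisation or additional filtering is applied
before the histogram fit. Dose-response data are fitted with a one-site Hill
equation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, signal

from .currents import IVDataset, SlopeFit, fit_two_slopes, percent_change

__all__ = [
    "GatingModel",
    "SingleChannelTrace",
    "AmplitudeFit",
    "RectificationReport",
    "HillFit",
    "simulate_trace",
    "fit_amplitude",
    "build_iv",
    "rectification_report",
    "hill_fit",
    "PATCH_VOLTAGES",
]

#: the standard clamp protocol: -100 to +100 mV in 20 mV steps
PATCH_VOLTAGES = tuple(range(-100, 101, 20))


@dataclass(frozen=True)
class GatingModel:
    """Two-state gating plus the open-channel conductances.

    ``gamma_in``/``gamma_out`` (pS) are the slope conductances on the
    negative/positive side of the reversal potential ``V_rev`` (mV, 0 for
    symmetric chloride). ``open_rate``/``close_rate`` are in 1/s;
    ``noise_sd`` in pA. ``sample_rate`` must exceed twice ``filter_cutoff``.
    """

    open_rate: float = 50.0
    close_rate: float = 50.0
    gamma_in: float = 85.16
    gamma_out: float = 60.47
    V_rev: float = 0.0
    noise_sd: float = 0.4
    sample_rate: float = 20_000.0
    filter_cutoff: float = 1_000.0

    def __post_init__(self) -> None:
        if self.gamma_in <= 0 or self.gamma_out <= 0:
            raise ValueError("conductances must be positive")
        if self.sample_rate <= 2 * self.filter_cutoff:
            raise ValueError("sample_rate must exceed 2 * filter_cutoff")

    def open_level(self, V: float) -> float:
        """Open-channel current in pA at voltage V (mV)."""
        gamma = self.gamma_in if V < self.V_rev else self.gamma_out
        return gamma * (V - self.V_rev) * 1e-3  # pS * mV -> pA


@dataclass
class SingleChannelTrace:
    """Sampled current trace at a fixed clamp voltage."""

    samples: np.ndarray  # pA
    voltage: float  # mV
    sample_rate: float  # Hz
    open_states: np.ndarray | None = None  # ground truth, synthetic only


def simulate_trace(
    model: GatingModel,
    V: float,
    duration: float,
    seed: int,
    filtered: bool = True,
) -> SingleChannelTrace:
    """Simulate one trace of ``duration`` seconds at clamp voltage V (mV).

    Gating dwell times are exponential (exact continuous-time Markov chain,
    discretised onto the sample grid); the open level is
    γ(V)·(V − V_rev); Gaussian noise of ``noise_sd`` pA is added; with
    ``filtered=True`` a 5-pole low-pass Bessel filter at ``filter_cutoff``
    is applied.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * model.sample_rate))
    open_states = np.zeros(n, dtype=bool)
    if model.open_rate > 0:
        t, is_open = 0.0, False
        i = 0
        while i < n:
            rate = model.close_rate if is_open else model.open_rate
            if rate <= 0:
                if is_open:
                    open_states[i:] = True
                break
            dwell = rng.exponential(1.0 / rate)
            j = min(n, i + max(1, int(round(dwell * model.sample_rate))))
            if is_open:
                open_states[i:j] = True
            i = j
            is_open = not is_open
    level = model.open_level(V)
    trace = np.where(open_states, level, 0.0) + rng.normal(0.0, model.noise_sd, n)
    if filtered and model.filter_cutoff > 0:
        sos = signal.bessel(5, model.filter_cutoff, fs=model.sample_rate, output="sos")
        trace = signal.sosfilt(sos, trace)
    return SingleChannelTrace(samples=trace, voltage=V, sample_rate=model.sample_rate, open_states=open_states)


@dataclass
class AmplitudeFit:
    """Two-Gaussian fit of an all-points histogram.

    ``amplitude`` = |mean_open − mean_closed| in pA; weights sum to 1.
    """

    mean_closed: float
    mean_open: float
    sd_closed: float
    sd_open: float
    weight_closed: float
    weight_open: float
    amplitude: float
    residual: float  # RMS histogram-density residual


def _two_gauss(x, w, m1, s1, m2, s2):
    g1 = w * np.exp(-0.5 * ((x - m1) / s1) ** 2) / (s1 * math.sqrt(2 * math.pi))
    g2 = (1 - w) * np.exp(-0.5 * ((x - m2) / s2) ** 2) / (s2 * math.sqrt(2 * math.pi))
    return g1 + g2


def fit_amplitude(
    trace: SingleChannelTrace,
    bin_width: float = 0.1,
    min_separation_bins: int = 3,
    max_iter: int = 5000,
) -> AmplitudeFit:
    """Fit the all-points histogram with the sum of two Gaussian curves.

    Initial means are the two highest histogram peaks separated by at least
    ``min_separation_bins`` bins; if no such pair exists the samples are
    split at their median instead. Raises ``ValueError`` with "open state not
    detected" when the fitted components collapse onto one level.
    """
    x = np.asarray(trace.samples, dtype=float)
    lo, hi = x.min(), x.max()
    if hi - lo < 4 * bin_width:
        raise ValueError("open state not detected (degenerate single-mode histogram)")
    edges = np.arange(lo, hi + bin_width, bin_width)
    dens, edges = np.histogram(x, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    peaks, props = signal.find_peaks(dens, distance=min_separation_bins, prominence=0.0)
    if len(peaks) >= 2:
        # the two most prominent modes, not the shoulder of one peak
        top = peaks[np.argsort(props["prominences"])[::-1][:2]]
        m1, m2 = centers[top[0]], centers[top[1]]
    else:
        med = np.median(x)
        m1, m2 = np.mean(x[x <= med]), np.mean(x[x > med])
    s0 = max(np.std(x) / 2, bin_width)
    p0 = [0.5, m1, s0, m2, s0]
    bounds = ([1e-4, lo, bin_width / 10, lo, bin_width / 10], [1 - 1e-4, hi, hi - lo, hi, hi - lo])
    try:
        popt, _ = optimize.curve_fit(_two_gauss, centers, dens, p0=p0, bounds=bounds, maxfev=max_iter)
    except RuntimeError as err:
        raise ValueError(f"amplitude fit did not converge: {err}") from err
    w, mu1, s1, mu2, s2 = popt
    resid = float(np.sqrt(np.mean((dens - _two_gauss(centers, *popt)) ** 2)))
    # order components: closed = the one nearer zero current
    if abs(mu1) <= abs(mu2):
        mc, sc, wc, mo, so, wo = mu1, s1, w, mu2, s2, 1 - w
    else:
        mc, sc, wc, mo, so, wo = mu2, s2, 1 - w, mu1, s1, w
    amplitude = abs(mo - mc)
    if amplitude < 3 * bin_width:
        raise ValueError("open state not detected (components collapsed)")
    return AmplitudeFit(
        mean_closed=float(mc),
        mean_open=float(mo),
        sd_closed=float(sc),
        sd_open=float(so),
        weight_closed=float(wc),
        weight_open=float(wo),
        amplitude=float(amplitude),
        residual=resid,
    )


def build_iv(
    amplitudes: dict[float, Sequence[float]],
    V_rev: float = 0.0,
    label: str = "",
) -> IVDataset:
    """I–V dataset from per-voltage open-channel amplitudes over patches.

    ``amplitudes`` maps clamp voltage (mV) to amplitude magnitudes (pA), one
    per patch; per voltage the mean ± SEM is taken and the sign restored from
    the side of the reversal potential. Voltages at ``V_rev`` are kept with
    their (near-zero) value; slope fitting later excludes V = 0 anyway.
    """
    if len(amplitudes) < 2:
        raise ValueError("need amplitudes at >= 2 voltages")
    Vs, Is, Ss = [], [], []
    for V in sorted(amplitudes):
        vals = np.asarray(list(amplitudes[V]), dtype=float)
        if len(vals) == 0:
            warnings.warn(f"no patches at {V} mV; point skipped")
            continue
        sign = -1.0 if V < V_rev else 1.0
        Vs.append(V)
        Is.append(sign * float(np.mean(vals)))
        Ss.append(float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0)
    n_neg = sum(v < 0 for v in Vs)
    n_pos = sum(v > 0 for v in Vs)
    if n_neg < 2 or n_pos < 2:
        warnings.warn("missing branch: fewer than 2 points on one side of 0 mV")
    return IVDataset(np.array(Vs), np.array(Is), np.array(Ss), label=label)


@dataclass
class RectificationReport:
    """Slope conductances, rectification indices and percent changes."""

    slopes: dict[str, SlopeFit]
    reference: str
    indices: dict[str, float]  # rounded to 2 decimals
    inward_reduction_pct: dict[str, float]  # rounded integer percent vs reference
    outward_reduction_pct: dict[str, float]


def rectification_report(
    constructs: dict[str, SlopeFit | tuple[float, float]],
    reference: str,
) -> RectificationReport:
    """Per-construct rectification indices and percent changes vs a reference.

    ``constructs`` maps labels to :class:`SlopeFit` objects or bare
    ``(inward_pS, outward_pS)`` pairs. Indices are reported to two decimals
    and reductions to the nearest integer percent.
    """
    if reference not in constructs:
        raise ValueError(f"reference {reference!r} not among constructs")

    def as_fit(v) -> SlopeFit:
        if isinstance(v, SlopeFit):
            return v
        g_in, g_out = v
        return SlopeFit(g_in, g_out, 0.0, 0.0, g_in / g_out)

    fits = {k: as_fit(v) for k, v in constructs.items()}
    ref = fits[reference]
    indices = {k: round(f.index, 2) for k, f in fits.items()}
    inward = {k: round(percent_change(f.inward_slope, ref.inward_slope)) for k, f in fits.items()}
    outward = {k: round(percent_change(f.outward_slope, ref.outward_slope)) for k, f in fits.items()}
    return RectificationReport(
        slopes=fits,
        reference=reference,
        indices=indices,
        inward_reduction_pct=inward,
        outward_reduction_pct=outward,
    )


@dataclass
class HillFit:
    """One-site Hill dose-response fit: R = R_max·c^n/(EC50^n + c^n)."""

    EC50: float
    hill_n: float
    R_max: float
    residual: float


def hill_fit(concentrations: Sequence[float], responses: Sequence[float]) -> HillFit:
    """Least-squares fit of the one-site Hill equation.

    Requires ≥ 4 concentrations spanning the transition; raises
    ``ValueError`` with residual diagnostics when the fit cannot converge or
    the responses carry no signal.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(c) < 4:
        raise ValueError("need >= 4 concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if np.max(np.abs(r)) == 0:
        raise ValueError("all responses are zero; nothing to fit")

    def model(cc, ec50, n, rmax):
        return rmax * cc**n / (ec50**n + cc**n)

    half = 0.5 * r.max()
    ec0 = c[int(np.argmin(np.abs(r - half)))]
    p0 = [ec0, 1.0, r.max()]
    bounds = ([c.min() / 100, 0.05, 1e-12], [c.max() * 100, 20.0, 10 * max(r.max(), 1e-12)])
    try:
        popt, _ = optimize.curve_fit(model, c, r, p0=p0, bounds=bounds, maxfev=10000)
    except RuntimeError as err:
        raise ValueError(f"Hill fit did not converge: {err}") from err
    resid = float(np.sqrt(np.mean((r - model(c, *popt)) ** 2)))
    return HillFit(EC50=float(popt[0]), hill_n=float(popt[1]), R_max=float(popt[2]), residual=resid)
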