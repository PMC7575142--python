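"""Postsynaptic-current (PSC) event detection, kinetics and the
oPSC/sPSC ratio as a presynaptic-count estimator.

Detection is by a sliding template fit (matched filter): at every
position a difference-of-exponentials template is fitted to the trace
by least squares (free scale and offset), and the detection statistic is
the fitted scale divided by its standard error.  Crucially the *same*
algorithm, template and alignment serve both spontaneous and
optogenetically evoked events; classification into sPSC/oPSC happens
afterwards purely from the light-pulse times.  Compound (multiphasic)
events — typically multiplet presynaptic spikes — are flagged when the
observed peak clearly exceeds the single-template fit, and contribute
their full peak amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .core import VOLTAGE_CLAMP, Trace
from .synth import psc_kernel

__all__ = [
    "EventParams",
    "PSCEvent",
    "CellEventStats",
    "detect_events",
    "classify_opto",
    "latency_ms",
    "event_stats",
    "fit_kinetics",
    "ratio_histogram",
]


@dataclass
class EventParams:
    """Template and threshold configuration for PSC detection.

    ``polarity`` must state the expected event direction: ``"inward"``
    (negative currents, e.g. EPSCs at −60 mV) or ``"outward"`` (IPSCs at
    0 mV).  ``threshold`` applies to the scale/standard-error detection
    statistic; ``min_separation_ms`` is the minimum peak spacing below
    which overlapping events are treated as one compound event.
    """

    polarity: str = "inward"
    rise_ms: float = 0.5
    decay_ms: float = 6.0
    threshold: float = 4.0
    min_separation_ms: float = 5.0
    min_amp_pa: float = 2.0
    compound_ratio: float = 1.3
    template_len_ms: Optional[float] = None
    smooth_ms: float = 0.3


@dataclass
class PSCEvent:
    """One detected synaptic current."""

    onset_s: float
    peak_s: float
    peak_amp_pA: float  # magnitude
    rise_ms: float = float("nan")
    decay_tau_ms: float = float("nan")
    snippet: Optional[np.ndarray] = None  # baseline-subtracted magnitude
    sampling_rate: float = float("nan")
    kind: str = "spontaneous"
    compound: bool = False
    criterion: float = float("nan")


@dataclass
class CellEventStats:
    """Per-cell amplitude statistics and the presynaptic-count estimate.

    ``ratio`` is mean oPSC / mean sPSC amplitude; rounded it estimates
    how many connected presynaptic neurons the light responses arise
    from, under the premise that each connected source contributes one
    sPSC-sized current per activation.
    """

    n_spsc: int
    n_opsc: int
    mean_spsc_pA: float
    top5_mean_pA: float
    mean_opsc_pA: float
    ratio: float
    est_presyn_count: int
    spsc_rise_ms: float = float("nan")
    spsc_decay_tau_ms: float = float("nan")
    opsc_rise_ms: float = float("nan")
    opsc_decay_tau_ms: float = float("nan")


def _sliding_template_fit(y: np.ndarray, template: np.ndarray):
    """Least-squares scale/offset fit of ``template`` at every position.

    Returns (scale, criterion) arrays of length N-L+1 where criterion is
    scale over its standard error (t-type matched-filter statistic).
    """
    L = template.size
    st = template.sum()
    stt = float(template @ template)
    denom = stt - st * st / L
    ones = np.ones(L)
    sy = signal.fftconvolve(y, ones, mode="valid")
    syy = signal.fftconvolve(y * y, ones, mode="valid")
    sty = signal.fftconvolve(y, template[::-1], mode="valid")
    s = (sty - st * sy / L) / denom
    c = (sy - s * st) / L
    sse = (syy - 2.0 * s * sty - 2.0 * c * sy
           + s * s * stt + 2.0 * s * c * st + L * c * c)
    sse = np.maximum(sse, 0.0)
    sigma2 = sse / max(L - 2, 1)
    se = np.sqrt(np.maximum(sigma2 / denom, 1e-300))
    return s, c, s / se


def detect_events(trace: Trace, params: Optional[EventParams] = None) -> list:
    """Detect PSC events in a voltage-clamp trace by sliding template fit.

    The identical algorithm serves spontaneous and light-evoked events;
    see :func:`classify_opto` for the subsequent labelling.  Peaks of
    the detection statistic closer than ``min_separation_ms`` are
    treated as a single (possibly compound) event.
    """
    if params is None:
        params = EventParams()
    if params.polarity not in ("inward", "outward"):
        raise ValueError("polarity must be 'inward' or 'outward'")
    if trace.clamp_mode != VOLTAGE_CLAMP:
        raise ValueError("event detection requires a voltage-clamp trace")
    fs = trace.sampling_rate
    # work in magnitude space: events deflect positive
    y = -trace.samples if params.polarity == "inward" else trace.samples.copy()

    length_ms = params.template_len_ms or 4.0 * params.decay_ms
    template = psc_kernel(fs, params.rise_ms, params.decay_ms, length_ms)
    L = template.size
    if y.size <= L:
        return []
    s, c, crit = _sliding_template_fit(y, template)

    dist = max(1, int(round(params.min_separation_ms * 1e-3 * fs)))
    # prominence suppresses side-ripples of the criterion around one event;
    # peaks closer than the separation limit collapse onto the strongest
    peaks, _ = signal.find_peaks(crit, height=params.threshold, distance=dist,
                                 prominence=params.threshold)

    width = max(1, int(round(params.smooth_ms * 1e-3 * fs)))
    if width > 1:
        ysm = np.convolve(y, np.ones(width) / width, mode="same")
    else:
        ysm = y
    k_peak = int(np.argmax(template))
    search = k_peak + int(round(2.0 * params.decay_ms * 1e-3 * fs))
    snip_pre = int(round(2e-3 * fs))
    snip_post = int(round(5.0 * params.decay_ms * 1e-3 * fs))

    guard = max(2, int(round(1e-3 * fs)))  # ignore self-subtraction residue
    events = []
    for p in peaks:
        scale = s[p]
        if scale <= 0 or scale < params.min_amp_pa:
            continue
        # residual test for an unresolved second component within the
        # separation limit (multiplet -> compound multiphasic event)
        start = p
        compound = False
        lo = max(0, p - 2 * dist)
        hi_r = min(y.size, p + L + dist)
        seg = y[lo:hi_r] - c[p]
        k0 = p - lo
        m = min(L, seg.size - k0)
        seg[k0:k0 + m] -= scale * template[:m]
        if seg.size > L:
            s2, _, crit2 = _sliding_template_fit(seg, template)
            pos = np.arange(lo, lo + crit2.size)
            mask = ((np.abs(pos - p) >= guard)
                    & (np.abs(pos - p) <= dist)
                    & (crit2 >= params.threshold)
                    & (s2 >= max(params.min_amp_pa, 0.15 * scale)))
            if np.any(mask):
                compound = True
                start = min(p, int(pos[mask].min()))

        if compound:
            b0 = max(0, start - int(round(3e-3 * fs)))
            b1 = max(b0 + 1, start - int(round(0.5e-3 * fs)))
            base = float(np.median(ysm[b0:b1]))
        else:
            base = c[p]
        hi = min(max(p, start) + search, y.size)
        rel = ysm[start:hi] - base
        j = int(np.argmax(rel))
        peak_val = float(rel[j])
        peak_idx = start + j
        if peak_val <= 0:
            continue
        compound = compound or peak_val > params.compound_ratio * scale
        amp = peak_val if compound else float(scale)

        # onset: first 10%-of-peak crossing before the peak
        level = 0.1 * peak_val
        seg = ysm[start:peak_idx + 1] - base
        above = np.nonzero(seg >= level)[0]
        onset_idx = start + (int(above[0]) if above.size else 0)

        lo = max(0, onset_idx - snip_pre)
        hi2 = min(y.size, onset_idx + snip_post)
        snippet = y[lo:hi2] - base

        ev = PSCEvent(
            onset_s=trace.t0 + onset_idx / fs,
            peak_s=trace.t0 + peak_idx / fs,
            peak_amp_pA=float(amp),
            snippet=snippet,
            sampling_rate=fs,
            compound=bool(compound),
            criterion=float(crit[p]),
        )
        if not compound:
            kin = fit_kinetics(snippet, fs, onset_index=onset_idx - lo)
            if kin is not None:
                ev.rise_ms, ev.decay_tau_ms = kin
        events.append(ev)
    return events


def classify_opto(events: Sequence[PSCEvent], light_times: Sequence[float],
                  window_ms: tuple = (1.0, 20.0)) -> list:
    """Label events as optogenetic (onset inside a light window) or
    spontaneous.  Windows are ``[light + window_ms[0], light + window_ms[1])``
    and must not overlap."""
    light_times = np.sort(np.asarray(light_times, dtype=float))
    w0, w1 = window_ms[0] * 1e-3, window_ms[1] * 1e-3
    if light_times.size > 1 and np.any(np.diff(light_times) < (w1 - w0)):
        raise ValueError("light windows overlap")
    for ev in events:
        ev.kind = "spontaneous"
        if light_times.size:
            i = np.searchsorted(light_times, ev.onset_s, side="right") - 1
            if i >= 0 and (light_times[i] + w0) <= ev.onset_s < (light_times[i] + w1):
                ev.kind = "optogenetic"
    return list(events)


def latency_ms(event: PSCEvent, light_time: float) -> float:
    """Latency from light onset to the event's 10 %-of-peak onset, in ms."""
    if event.kind != "optogenetic":
        raise ValueError("latency is defined for optogenetic events only")
    dt = (event.onset_s - light_time) * 1e3
    if dt < 0:
        raise ValueError("event onset precedes the light pulse")
    return float(dt)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def event_stats(events: Sequence[PSCEvent],
                min_spsc_for_top5: int = 20) -> Optional[CellEventStats]:
    """Per-cell amplitude statistics, top-5 % comparison and the
    oPSC/sPSC ratio rounded into a presynaptic-count estimate.

    The top-5 % mean uses the ⌈0.05·n⌉ largest sPSC amplitudes (at least
    one); fewer than ``min_spsc_for_top5`` spontaneous events make the
    top-5 % estimate unreliable and raise.  Returns ``None`` when there
    are no spontaneous events at all (stats unavailable).
    """
    spsc = [e.peak_amp_pA for e in events if e.kind == "spontaneous"]
    opsc = [e.peak_amp_pA for e in events if e.kind == "optogenetic"]
    if not spsc:
        return None
    if len(spsc) < min_spsc_for_top5:
        raise ValueError(
            f"top-5% estimate needs >= {min_spsc_for_top5} spontaneous events"
        )
    amps = np.sort(spsc)[::-1]
    k = max(1, math.ceil(0.05 * amps.size))
    top5 = float(amps[:k].mean())
    mean_spsc = float(np.mean(spsc))
    mean_opsc = float(np.mean(opsc)) if opsc else float("nan")
    if opsc:
        ratio = mean_opsc / mean_spsc
        est = _round_half_up(ratio)
        if est < 1:
            est = 1  # any detected oPSC implies at least one presynaptic source
    else:
        ratio = float("nan")
        est = 0

    def _kin(evts, attr):
        vals = [getattr(e, attr) for e in evts
                if not e.compound and math.isfinite(getattr(e, attr))]
        return float(np.mean(vals)) if vals else float("nan")

    sp = [e for e in events if e.kind == "spontaneous"]
    op = [e for e in events if e.kind == "optogenetic"]
    return CellEventStats(
        n_spsc=len(spsc), n_opsc=len(opsc),
        mean_spsc_pA=mean_spsc, top5_mean_pA=top5,
        mean_opsc_pA=mean_opsc, ratio=float(ratio), est_presyn_count=est,
        spsc_rise_ms=_kin(sp, "rise_ms"),
        spsc_decay_tau_ms=_kin(sp, "decay_tau_ms"),
        opsc_rise_ms=_kin(op, "rise_ms"),
        opsc_decay_tau_ms=_kin(op, "decay_tau_ms"),
    )


def fit_kinetics(snippet: np.ndarray, sampling_rate: float,
                 onset_index: int = 0):
    """20–80 % rise time and single-exponential decay tau of a snippet.

    ``snippet`` is a baseline-subtracted magnitude waveform (events
    positive).  The decay is fitted log-linearly from where the current
    has fallen to 90 % of its peak down to 20 % of peak — the snippet
    must contain the decay down to at least 20 %.  Returns
    ``(rise_ms, decay_tau_ms)`` or ``None`` when no stable fit exists.
    """
    snippet = np.asarray(snippet, dtype=float)
    if snippet.size < 4:
        return None
    fs = sampling_rate
    k_peak = int(np.argmax(snippet))
    peak = snippet[k_peak]
    if peak <= 0:
        return None

    # rise: 20% and 80% upward crossings before the peak
    pre = snippet[onset_index:k_peak + 1]
    if pre.size < 2:
        return None

    def _cross(level):
        above = np.nonzero(pre >= level)[0]
        if not above.size or above[0] == 0:
            return float(above[0]) if above.size else None
        i = above[0]
        frac = (level - pre[i - 1]) / (pre[i] - pre[i - 1] + 1e-300)
        return i - 1 + frac

    t20, t80 = _cross(0.2 * peak), _cross(0.8 * peak)
    if t20 is None or t80 is None or t80 < t20:
        return None
    rise_ms = (t80 - t20) / fs * 1e3

    post = snippet[k_peak:]
    below20 = np.nonzero(post <= 0.2 * peak)[0]
    if not below20.size:
        return None  # decay not contained in the snippet
    below90 = np.nonzero(post <= 0.9 * peak)[0]
    i0 = int(below90[0]) if below90.size else 0
    i1 = int(below20[0])
    if i1 - i0 < 3:
        return None
    seg = post[i0:i1 + 1]
    if np.any(seg <= 0):
        return None
    t = np.arange(seg.size) / fs * 1e3
    slope, _ = np.polyfit(t, np.log(seg), 1)
    if slope >= 0:
        return None
    tau = -1.0 / slope
    return float(rise_ms), float(tau)


def ratio_histogram(stats: Sequence[CellEventStats], bin_width: float = 0.5):
    """Histogram of per-cell oPSC/sPSC amplitude ratios.

    Returns ``(edges, counts, mean, sd)`` over cells with a defined
    ratio; bins are half-open ``[lo, hi)``.
    """
    ratios = np.asarray([s.ratio for s in stats if math.isfinite(s.ratio)])
    if ratios.size == 0:
        raise ValueError("no cell has a defined oPSC/sPSC ratio")
    top = (math.floor(ratios.max() / bin_width) + 1) * bin_width
    edges = np.arange(0.0, top + 0.5 * bin_width, bin_width)
    edges = np.append(edges, edges[-1] + bin_width)
    counts = np.histogram(ratios, bins=edges)[0]
    return edges, counts, float(ratios.mean()), float(ratios.std(ddof=1) if ratios.size > 1 else 0.0)
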