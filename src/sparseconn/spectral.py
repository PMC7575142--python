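"""Spectrograms and beta-gamma (10–80 Hz) band-power analysis of
light-ramp voltage-clamp recordings.

The sweep is high-pass filtered (zero-phase 4th-order Butterworth,
default 10 Hz), then short-time power spectral densities are computed
with Hann-tapered 0.5 s windows at 95 % overlap.  Band power is the
trapezoidal integral of the PSD over frequency bins inside the
half-open band [lo, hi), in pA²; integrating the density over frequency
makes a pure tone of amplitude A contribute A²/2, so band powers read
directly as signal variance in the band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sig

from .core import Session, Trace

__all__ = [
    "SpectralResult",
    "spectrogram",
    "band_power",
    "ramp_power_increase",
    "n_windows",
]


@dataclass
class SpectralResult:
    """Time–frequency power of one sweep plus band-power summaries."""

    times: np.ndarray          # window centres, s
    freqs: np.ndarray          # Hz
    power: np.ndarray          # PSD, freq x time, pA^2/Hz
    band: tuple = (10.0, 80.0)
    baseline_power: float = float("nan")  # band-integrated mean, pA^2
    ramp_power: float = float("nan")
    increase: float = float("nan")
    increase_ratio: float = float("nan")


def n_windows(n_samples: int, nperseg: int, noverlap: int) -> int:
    """Number of short-time windows: floor((N - L)/step) + 1."""
    step = nperseg - noverlap
    return (n_samples - nperseg) // step + 1


def _highpass(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    sos = sig.butter(4, cutoff_hz, btype="highpass", fs=fs, output="sos")
    return sig.sosfiltfilt(sos, x)


def spectrogram(trace: Trace, window_s: float = 0.5,
                overlap_frac: float = 0.95,
                highpass_hz: Optional[float] = 10.0) -> SpectralResult:
    """Short-time PSD of a sweep (Hann taper, density scaling).

    Defaults follow the standard intracellular-oscillation analysis:
    0.5 s windows, 95 % overlap, 10 Hz zero-phase high-pass.  A 5 s
    sweep yields 181 windows.
    """
    fs = trace.sampling_rate
    nperseg = int(round(window_s * fs))
    if trace.n_samples < nperseg:
        raise ValueError("trace shorter than the spectrogram window")
    noverlap = int(round(overlap_frac * nperseg))
    x = trace.samples
    if highpass_hz is not None and highpass_hz > 0 and np.any(x != 0):
        x = _highpass(x, fs, highpass_hz)
    freqs, times, power = sig.spectrogram(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend="constant", scaling="density", mode="psd",
    )
    return SpectralResult(times=times + trace.t0, freqs=freqs, power=power)


def band_power(result: SpectralResult, band: tuple = (10.0, 80.0),
               interval: Optional[tuple] = None) -> float:
    """Mean band-integrated power (pA²) over windows in ``interval``.

    Frequency bins are selected half-open, ``band[0] <= f < band[1]``;
    ``interval`` selects window centres ``interval[0] <= t < interval[1]``
    (whole sweep when omitted).
    """
    fsel = (result.freqs >= band[0]) & (result.freqs < band[1])
    if not np.any(fsel):
        raise ValueError("band contains no frequency bins")
    if interval is None:
        tsel = np.ones(result.times.size, dtype=bool)
    else:
        t0, t1 = interval
        tsel = (result.times >= t0) & (result.times < t1)
    if not np.any(tsel):
        raise ValueError("interval contains no spectrogram windows")
    per_window = np.trapezoid(result.power[np.ix_(fsel, tsel)],
                              result.freqs[fsel], axis=0)
    return float(per_window.mean())


def ramp_power_increase(session: Session, band: tuple = (10.0, 80.0),
                        baseline_s: float = 1.0,
                        window_s: float = 0.5, overlap_frac: float = 0.95,
                        highpass_hz: float = 10.0) -> pd.DataFrame:
    """Per-cell light-ramp band-power increase over pre-ramp baseline.

    For every ``light_ramp`` sweep set the baseline interval is the
    ``baseline_s`` seconds immediately preceding ramp onset and the ramp
    interval is the full ramp.  Returns one row per sweep with
    ``baseline_power``, ``ramp_power`` and ``increase`` (pA²); group
    summaries (mean ± sd) are obtained with :func:`summarize_increase`.
    """
    ramps = session.sweeps("light_ramp")
    if not ramps:
        raise ValueError("session has no light_ramp sweep sets")
    rows = []
    for ss in ramps:
        onset = float(ss.metadata["ramp_onset_s"])
        dur = float(ss.metadata["ramp_duration_s"])
        if onset < baseline_s:
            raise ValueError("recording lacks a pre-ramp baseline interval")
        for trial in ss.trials:
            for cell_id, tr in trial.items():
                res = spectrogram(tr, window_s, overlap_frac, highpass_hz)
                bp = band_power(res, band, (onset - baseline_s, onset))
                rp = band_power(res, band, (onset, onset + dur))
                rows.append({
                    "cell_id": cell_id,
                    "baseline_power": bp,
                    "ramp_power": rp,
                    "increase": rp - bp,
                })
    return pd.DataFrame(rows)


def summarize_increase(per_cell: pd.DataFrame,
                       reference: Optional[pd.DataFrame] = None) -> dict:
    """Group mean ± sd of band-power increases; if a reference group is
    given, also the ratio of this group's mean increase to the
    reference's (e.g. LH relative to mPFC, or blocker relative to
    baseline)."""
    inc = per_cell["increase"].to_numpy(dtype=float)
    out = {
        "n": int(inc.size),
        "mean_increase": float(inc.mean()),
        "sd_increase": float(inc.std(ddof=1)) if inc.size > 1 else 0.0,
    }
    if reference is not None:
        ref = reference["increase"].to_numpy(dtype=float)
        out["increase_ratio"] = float(inc.mean() / ref.mean())
    return out
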