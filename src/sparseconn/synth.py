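"""Synthetic slice-electrophysiology sessions with known ground truth.

Every experimental design exercised by the analysis stages can be
emulated here: 50 Hz five-spike presynaptic trains with evoked PSPs,
hyperpolarising current steps with gap-junction voltage transfer,
Poisson barrages of spontaneous postsynaptic currents (sPSCs) with a
right-skewed (log-normal) amplitude law, light pulses evoking compound
optogenetic PSCs (oPSCs) with millisecond latencies and occasional
multiplets, and 5 s linear light ramps driving either a beta-gamma
(10–80 Hz) oscillatory synaptic current or a tonic current without
oscillation.

Randomness discipline: one global seed in :class:`SimConfig`; each
generator derives an independent substream from a fixed component offset
(``default_rng([seed, offset, index...])``), so a session is fully
reproducible and individual components can be re-drawn independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    CellRecord,
    GroundTruth,
    ProtocolSweepSet,
    Session,
    Trace,
)

__all__ = [
    "SimConfig",
    "OptoConfig",
    "RampConfig",
    "MembraneConfig",
    "psc_kernel",
    "simulate_membrane",
    "generate_ap_train",
    "simulate_connection_session",
    "simulate_spontaneous_pscs",
    "SpontaneousRecording",
    "simulate_opto_trial",
    "simulate_ramp_session",
]

# fixed substream offsets (one per generator component)
_STREAM_TOPOLOGY = 1
_STREAM_CONNECTION = 2
_STREAM_SPONT = 3
_STREAM_OPTO = 4
_STREAM_RAMP = 5
_STREAM_STEP = 6


@dataclass
class OptoConfig:
    """Optogenetic population-activation parameters.

    ``pop_size`` opsin-expressing neurons are nominally activated per
    light pulse, of which ``n_connected`` are synaptically connected to
    the recorded cell.  Each connected source contributes one PSC at a
    latency drawn from N(``latency_mean_ms``, ``latency_jitter_ms``),
    and with probability ``p_multiplet`` a second PSC 3–8 ms later
    (multiplet spike -> compound multiphasic oPSC).
    """

    pop_size: int = 1000
    n_connected: int = 1
    latency_mean_ms: float = 6.0
    latency_jitter_ms: float = 1.0
    p_multiplet: float = 0.1
    pulse_interval_s: float = 0.5


@dataclass
class RampConfig:
    """Linear light-ramp parameters (5 s ramp by default).

    If ``oscillatory``, the ramp recruits a narrowband synaptic-current
    oscillation at ``osc_freq_hz`` (inside ``osc_band``) whose envelope
    scales linearly with light intensity up to ``envelope_pa``
    (cortex-like).  Otherwise the ramp adds only a slow tonic inward
    current of ``tonic_pa`` at full intensity with unchanged sPSC
    statistics (LH-like null).
    """

    duration_s: float = 5.0
    baseline_s: float = 2.0
    oscillatory: bool = True
    osc_freq_hz: float = 40.0
    osc_band: tuple = (10.0, 80.0)
    envelope_pa: float = 20.0
    tonic_pa: float = 30.0


@dataclass
class MembraneConfig:
    """Single-compartment RC membrane with threshold-reset spiking."""

    r_m_mohm: float = 200.0
    c_m_pf: float = 100.0
    v_rest_mv: float = -50.0
    v_thresh_mv: float = -35.0
    v_reset_mv: float = -45.0
    refractory_ms: float = 2.0
    spike_peak_mv: float = 40.0
    spike_width_ms: float = 1.0

    @property
    def tau_ms(self) -> float:
        return self.r_m_mohm * self.c_m_pf / 1000.0


@dataclass
class SimConfig:
    """All tunable parameters of the synthetic generator.

    Amplitude law for sPSCs is log-normal, parameterised by the median
    ``spsc_amp_med_pa`` and the log-sd ``spsc_amp_sigma``; the defaults
    (16.9 pA, 0.605) give a population mean of ~20.3 pA and sd ~13.5 pA,
    the scale of spontaneous currents in hypothalamic recordings.  The
    sPSC rate is not constrained by published data and is a free
    parameter (default 3 Hz, a typical slice value).
    """

    n_cells: int = 4
    region: str = "LH"
    p_chem: float = 0.1
    p_elec: float = 0.02
    psp_amp_mv: float = 0.5
    psp_rise_ms: float = 2.0
    psp_decay_ms: float = 20.0
    psc_rise_ms: float = 0.5
    psc_decay_ms: float = 6.0
    synaptic_delay_ms: float = 1.0
    noise_sd_mv: float = 0.25
    noise_sd_pa: float = 2.0
    spsc_rate_hz: float = 3.0
    spsc_amp_med_pa: float = 16.9
    spsc_amp_sigma: float = 0.605
    elec_coeff_range: tuple = (0.01, 0.1)
    step_pa: float = -50.0
    soma_extent_um: float = 150.0
    sampling_rate: float = 10_000.0
    opto: OptoConfig = field(default_factory=OptoConfig)
    ramp: RampConfig = field(default_factory=RampConfig)
    membrane: MembraneConfig = field(default_factory=MembraneConfig)
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_chem, self.p_elec, self.opto.p_multiplet):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        for tc in (self.psp_rise_ms, self.psp_decay_ms,
                   self.psc_rise_ms, self.psc_decay_ms):
            if not (tc > 0):
                raise ValueError("time constants must be positive")
        if self.sampling_rate < 10_000:
            raise ValueError("sampling_rate must be >= 10 kHz")
        if self.opto.n_connected > self.opto.pop_size:
            raise ValueError("opto.n_connected cannot exceed opto.pop_size")

    def rng(self, offset: int, *extra: int) -> np.random.Generator:
        """Substream generator for one component (fixed offsets)."""
        return np.random.default_rng([int(self.seed), int(offset), *map(int, extra)])


def psc_kernel(sampling_rate: float, rise_ms: float, decay_ms: float,
               length_ms: Optional[float] = None) -> np.ndarray:
    """Peak-normalised difference-of-exponentials synaptic kernel.

    k(t) = (e^(-t/tau_d) - e^(-t/tau_r)) / k_peak, so that "amplitude"
    multipliers equal the event peak.
    """
    if not (decay_ms > rise_ms > 0):
        raise ValueError("need decay_ms > rise_ms > 0")
    if length_ms is None:
        length_ms = 8.0 * decay_ms
    n = int(round(length_ms * 1e-3 * sampling_rate))
    t = np.arange(n) / sampling_rate * 1e3  # ms
    k = np.exp(-t / decay_ms) - np.exp(-t / rise_ms)
    return k / k.max()


def _add_events(samples: np.ndarray, idx: np.ndarray, amps: np.ndarray,
                kernel: np.ndarray) -> None:
    """Add scaled kernels in place at the given sample indices (linear
    superposition; events beyond the trace end are truncated)."""
    n = samples.size
    for i, a in zip(idx, amps):
        if i >= n or i < 0:
            continue
        m = min(kernel.size, n - i)
        samples[i:i + m] += a * kernel[:m]


def _spike_waveform(mem: MembraneConfig, sampling_rate: float) -> np.ndarray:
    """Stereotyped action-potential waveform (triangular, baseline-relative)."""
    n = max(2, int(round(mem.spike_width_ms * 1e-3 * sampling_rate)))
    half = n // 2
    up = np.linspace(0.0, 1.0, half, endpoint=False)
    down = np.linspace(1.0, 0.0, n - half)
    return np.concatenate([up, down])


def generate_ap_train(n_spikes: int, rate_hz: float, start_s: float = 0.0) -> np.ndarray:
    """Times (s) of ``n_spikes`` imposed action potentials at ``rate_hz``.

    The default screening protocol is 5 spikes at 50 Hz: 20 ms spacing.
    """
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    if not (rate_hz > 0):
        raise ValueError("rate_hz must be positive")
    return start_s + np.arange(n_spikes) / rate_hz


def simulate_membrane(config: SimConfig, input_current: Trace) -> Trace:
    """Integrate a single-compartment RC membrane driven by ``input_current``.

    Subthreshold the voltage follows V(t) = V_rest + I R_m (1 - e^(-t/tau))
    with tau = R_m C_m; threshold crossings trigger a stereotyped spike
    waveform followed by reset and an absolute refractory period.
    Returns a current-clamp Trace (mV) with the drive as its stimulus.
    """
    mem = config.membrane
    for v in (mem.r_m_mohm, mem.c_m_pf, mem.v_rest_mv, mem.v_thresh_mv):
        if not math.isfinite(v):
            raise ValueError("membrane parameters must be finite")
    fs = input_current.sampling_rate
    dt_ms = 1e3 / fs
    alpha = math.exp(-dt_ms / mem.tau_ms)
    i_pa = input_current.samples
    n = i_pa.size
    v = np.empty(n)
    v[0] = mem.v_rest_mv
    spike_times = []
    spike_wave = _spike_waveform(mem, fs)
    refr = int(round(mem.refractory_ms * 1e-3 * fs))
    out = np.empty(n)
    i_samp = 0
    while i_samp < n:
        if i_samp > 0:
            v_inf = mem.v_rest_mv + mem.r_m_mohm * i_pa[i_samp - 1] / 1000.0
            v[i_samp] = v_inf + (v[i_samp - 1] - v_inf) * alpha
        if v[i_samp] >= mem.v_thresh_mv:
            spike_times.append(input_current.t0 + i_samp / fs)
            m = min(spike_wave.size, n - i_samp)
            out[i_samp:i_samp + m] = (
                mem.v_thresh_mv
                + (mem.spike_peak_mv - mem.v_thresh_mv) * spike_wave[:m]
            )
            end = min(n, i_samp + m + refr)
            out[i_samp + m:end] = mem.v_reset_mv
            if end < n:
                v[end - 1] = mem.v_reset_mv
            i_samp = end
            continue
        out[i_samp] = v[i_samp]
        i_samp += 1
    tr = Trace(out, fs, CURRENT_CLAMP, t0=input_current.t0,
               stimulus=i_pa.copy())
    tr.spike_times = np.asarray(spike_times)
    return tr


def _presynaptic_trace(config: SimConfig, n: int, ap_times: np.ndarray,
                       rng: np.random.Generator) -> Trace:
    """Current-clamp trace of the driven cell: rest + spikes + noise."""
    mem = config.membrane
    fs = config.sampling_rate
    v = np.full(n, mem.v_rest_mv)
    wave = _spike_waveform(mem, fs) * (mem.spike_peak_mv - mem.v_rest_mv)
    _add_events(v, np.round(ap_times * fs).astype(int), np.ones(ap_times.size), wave)
    v += rng.normal(0.0, config.noise_sd_mv, n)
    return Trace(v, fs, CURRENT_CLAMP)


def _draw_topology(config: SimConfig):
    rng = config.rng(_STREAM_TOPOLOGY)
    n = config.n_cells
    xy = rng.uniform(0.0, config.soma_extent_um, size=(n, 2))
    depth = rng.uniform(12.0, 123.0, size=n)
    chem = np.zeros((n, n))
    mask = rng.random((n, n)) < config.p_chem
    np.fill_diagonal(mask, False)
    chem[mask] = config.psp_amp_mv
    elec = np.zeros((n, n))
    lo, hi = config.elec_coeff_range
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < config.p_elec:
                c = rng.uniform(lo, hi)
                elec[i, j] = elec[j, i] = c
    cells = [
        CellRecord(cell_id=f"c{i}", region=config.region,
                   soma_xy=tuple(xy[i]), depth=float(depth[i]))
        for i in range(n)
    ]
    return cells, chem, elec


def simulate_connection_session(config: SimConfig, n_trials: int = 20,
                                include_steps: bool = True) -> Session:
    """Emulate a multi-patch connectivity screen with known ground truth.

    For each cell taken in turn as the presynaptic cell, ``n_trials``
    simultaneous sweeps are generated in which that cell fires 5 action
    potentials at 50 Hz while all other cells are monitored.  Chemically
    connected followers show PSPs time-locked to each spike (amplitude
    ``psp_amp_mv``, difference-of-exponentials kinetics, 1 ms synaptic
    delay) in Gaussian noise of sd ``noise_sd_mv``.  If
    ``include_steps``, a hyperpolarising current-step sweep set is added
    per cell for electrical-coupling quantification: electrically
    coupled partners show the steady-state step deflection scaled by the
    ground-truth coupling coefficient.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    cells, chem, elec = _draw_topology(config)
    fs = config.sampling_rate
    mem = config.membrane
    ap_times = generate_ap_train(5, 50.0, start_s=0.1)
    dur = 0.35
    n = int(round(dur * fs))
    kernel = psc_kernel(fs, config.psp_rise_ms, config.psp_decay_ms)
    delay = int(round(config.synaptic_delay_ms * 1e-3 * fs))
    ap_idx = np.round(ap_times * fs).astype(int) + delay

    sweep_sets = []
    for i, pre in enumerate(cells):
        rng = config.rng(_STREAM_CONNECTION, i)
        trials = []
        for _ in range(n_trials):
            trial = {pre.cell_id: _presynaptic_trace(config, n, ap_times, rng)}
            for j, post in enumerate(cells):
                if j == i:
                    continue
                v = np.full(n, mem.v_rest_mv)
                if chem[i, j] > 0:
                    _add_events(v, ap_idx, np.full(ap_idx.size, chem[i, j]), kernel)
                v += rng.normal(0.0, config.noise_sd_mv, n)
                trial[post.cell_id] = Trace(v, fs, CURRENT_CLAMP)
            trials.append(trial)
        sweep_sets.append(ProtocolSweepSet(
            protocol="ap_train",
            trials=trials,
            metadata={"pre_id": pre.cell_id, "ap_times": ap_times.tolist()},
        ))

    if include_steps:
        step_window = (0.1, 0.4)
        dur_step = 0.6
        ns = int(round(dur_step * fs))
        i0, i1 = int(step_window[0] * fs), int(step_window[1] * fs)
        tau = mem.tau_ms * 1e-3
        t_rel = np.arange(i1 - i0) / fs
        onoff = 1.0 - np.exp(-t_rel / tau)
        dv_pre = mem.r_m_mohm * config.step_pa / 1000.0  # mV, signed
        for i, pre in enumerate(cells):
            rng = config.rng(_STREAM_STEP, i)
            trials = []
            for _ in range(max(1, n_trials // 4)):
                trial = {}
                stim = np.zeros(ns)
                stim[i0:i1] = config.step_pa
                for j, cell in enumerate(cells):
                    v = np.full(ns, mem.v_rest_mv)
                    dv = dv_pre if j == i else dv_pre * elec[i, j]
                    if dv != 0.0:
                        v[i0:i1] += dv * onoff
                        v[i1:] += dv * np.exp(-np.arange(ns - i1) / fs / tau)
                    v += rng.normal(0.0, config.noise_sd_mv, ns)
                    trial[cell.cell_id] = Trace(
                        v, fs, CURRENT_CLAMP,
                        stimulus=stim if j == i else None,
                    )
                trials.append(trial)
            sweep_sets.append(ProtocolSweepSet(
                protocol="current_step",
                trials=trials,
                metadata={"pre_id": pre.cell_id,
                          "step_window": list(step_window),
                          "step_pa": config.step_pa},
            ))

    gt = GroundTruth(cell_ids=[c.cell_id for c in cells], chem=chem, elec=elec)
    return Session(cells=cells, sweep_sets=sweep_sets, ground_truth=gt)


@dataclass
class SpontaneousRecording:
    """A simulated voltage-clamp trace plus its ground-truth events."""

    trace: Trace
    event_times: np.ndarray
    event_amps: np.ndarray  # magnitudes, pA


def _draw_spsc_train(config: SimConfig, duration: float,
                     rng: np.random.Generator):
    n_ev = rng.poisson(config.spsc_rate_hz * duration)
    times = np.sort(rng.uniform(0.0, duration, n_ev))
    amps = config.spsc_amp_med_pa * np.exp(
        config.spsc_amp_sigma * rng.standard_normal(n_ev))
    return times, amps


def simulate_spontaneous_pscs(config: SimConfig, duration: float,
                              rng: Optional[np.random.Generator] = None,
                              ) -> SpontaneousRecording:
    """Poisson barrage of spontaneous PSCs in a voltage-clamp trace.

    Event times are homogeneous Poisson at ``spsc_rate_hz``; amplitudes
    follow the log-normal law; each event is an inward (negative)
    difference-of-exponentials current; Gaussian noise of sd
    ``noise_sd_pa`` is added.  Ground-truth times and amplitudes are
    returned alongside the trace.
    """
    if not (duration > 0):
        raise ValueError("duration must be positive")
    if rng is None:
        rng = config.rng(_STREAM_SPONT)
    fs = config.sampling_rate
    n = int(round(duration * fs))
    times, amps = _draw_spsc_train(config, duration, rng)
    samples = np.zeros(n)
    kernel = psc_kernel(fs, config.psc_rise_ms, config.psc_decay_ms)
    _add_events(samples, np.round(times * fs).astype(int), -amps, kernel)
    samples += rng.normal(0.0, config.noise_sd_pa, n)
    tr = Trace(samples, fs, VOLTAGE_CLAMP)
    return SpontaneousRecording(tr, times, amps)


def simulate_opto_trial(config: SimConfig, n_pulses: int = 50,
                        trial_index: int = 0,
                        include_opsin_cell: bool = False) -> ProtocolSweepSet:
    """One light-pulse mapping trial: oPSCs superimposed on sPSC background.

    Each of ``n_pulses`` light pulses evokes, from each of the
    ``opto.n_connected`` connected presynaptic opsin+ neurons, one PSC
    with latency ~ N(latency_mean_ms, latency_jitter_ms) and amplitude
    drawn from the same log-normal law as the sPSCs (each connected
    source behaves like one spontaneous-release site).  With probability
    ``p_multiplet`` a source fires a doublet, adding a second PSC 3–8 ms
    later (compound multiphasic oPSC).  If ``include_opsin_cell``, a
    simultaneously recorded opsin+ cell trace carries brief large
    runaway action currents at each pulse, as seen when clamping
    channelrhodopsin-expressing neurons.
    """
    opto = config.opto
    if opto.n_connected > opto.pop_size:
        raise ValueError("n_connected cannot exceed pop_size")
    rng = config.rng(_STREAM_OPTO, trial_index)
    fs = config.sampling_rate
    interval = opto.pulse_interval_s
    duration = (n_pulses + 1) * interval
    n = int(round(duration * fs))
    light_times = (np.arange(n_pulses) + 0.5) * interval

    spsc_times, spsc_amps = _draw_spsc_train(config, duration, rng)
    samples = np.zeros(n)
    kernel = psc_kernel(fs, config.psc_rise_ms, config.psc_decay_ms)
    _add_events(samples, np.round(spsc_times * fs).astype(int), -spsc_amps, kernel)

    ev_times, ev_amps = [], []
    for lt in light_times:
        for _ in range(opto.n_connected):
            lat = rng.normal(opto.latency_mean_ms, opto.latency_jitter_ms)
            lat = max(lat, 0.5)  # conduction + release cannot be instantaneous
            amp = config.spsc_amp_med_pa * math.exp(
                config.spsc_amp_sigma * rng.standard_normal())
            ev_times.append(lt + lat * 1e-3)
            ev_amps.append(amp)
            if rng.random() < opto.p_multiplet:
                gap = rng.uniform(3.0, 8.0)
                amp2 = config.spsc_amp_med_pa * math.exp(
                    config.spsc_amp_sigma * rng.standard_normal())
                ev_times.append(lt + (lat + gap) * 1e-3)
                ev_amps.append(amp2)
    ev_times = np.asarray(ev_times)
    ev_amps = np.asarray(ev_amps)
    _add_events(samples, np.round(ev_times * fs).astype(int), -ev_amps, kernel)
    samples += rng.normal(0.0, config.noise_sd_pa, n)

    # light-intensity command channel (1 ms pulses)
    stim = np.zeros(n)
    pw = int(round(1e-3 * fs))
    for lt in light_times:
        k = int(round(lt * fs))
        stim[k:k + pw] = 1.0

    trial = {"post": Trace(samples, fs, VOLTAGE_CLAMP, stimulus=stim)}
    if include_opsin_cell:
        v = rng.normal(0.0, config.noise_sd_pa, n)
        wave = np.zeros(int(round(1.5e-3 * fs)))
        half = wave.size // 2
        wave[:half] = np.linspace(0, 1, half, endpoint=False)
        wave[half:] = np.linspace(1, 0, wave.size - half)
        _add_events(v, np.round((light_times + 2e-3) * fs).astype(int),
                    np.full(n_pulses, -500.0), wave)
        trial["opsin"] = Trace(v, fs, VOLTAGE_CLAMP)

    return ProtocolSweepSet(
        protocol="light_pulse",
        trials=[trial],
        metadata={
            "light_times": light_times.tolist(),
            "n_connected": opto.n_connected,
            "opsc_times": ev_times.tolist(),
            "opsc_amps": ev_amps.tolist(),
            "spsc_times": spsc_times.tolist(),
            "spsc_amps": spsc_amps.tolist(),
        },
    )


def simulate_ramp_session(config: SimConfig) -> Session:
    """Light-ramp sessions probing locally generated network oscillations.

    Each cell contributes one voltage-clamp sweep: a quiet baseline
    segment, then a linear 0→1 light-intensity ramp of
    ``ramp.duration_s``.  In the oscillatory (cortex-like) condition the
    ramp recruits a narrowband synaptic-current oscillation whose
    envelope grows linearly with light intensity, reaching
    ``envelope_pa`` at full intensity; in the non-oscillatory (LH-like)
    condition the ramp adds only a slow tonic inward current while sPSC
    statistics stay unchanged.
    """
    ramp = config.ramp
    if not (ramp.duration_s > 0):
        raise ValueError("ramp.duration_s must be positive")
    lo, hi = ramp.osc_band
    if not (lo <= ramp.osc_freq_hz <= hi):
        raise ValueError("osc_freq_hz must lie inside osc_band")
    fs = config.sampling_rate
    total = ramp.baseline_s + ramp.duration_s + 0.5
    n = int(round(total * fs))
    t = np.arange(n) / fs
    frac = np.clip((t - ramp.baseline_s) / ramp.duration_s, 0.0, 1.0)
    frac[t > ramp.baseline_s + ramp.duration_s] = 0.0

    cells = [CellRecord(cell_id=f"c{i}", region=config.region)
             for i in range(config.n_cells)]
    sweep_sets = []
    kernel = psc_kernel(fs, config.psc_rise_ms, config.psc_decay_ms)
    for i, cell in enumerate(cells):
        rng = config.rng(_STREAM_RAMP, i)
        spsc_times, spsc_amps = _draw_spsc_train(config, total, rng)
        samples = np.zeros(n)
        _add_events(samples, np.round(spsc_times * fs).astype(int),
                    -spsc_amps, kernel)
        if ramp.oscillatory:
            phase = rng.uniform(0.0, 2 * np.pi)
            f = ramp.osc_freq_hz + rng.uniform(-2.0, 2.0)
            samples += ramp.envelope_pa * frac * np.sin(2 * np.pi * f * t + phase)
        else:
            samples += -ramp.tonic_pa * frac
        samples += rng.normal(0.0, config.noise_sd_pa, n)
        sweep_sets.append(ProtocolSweepSet(
            protocol="light_ramp",
            trials=[{cell.cell_id: Trace(samples, fs, VOLTAGE_CLAMP,
                                         stimulus=frac.copy())}],
            metadata={"ramp_onset_s": ramp.baseline_s,
                      "ramp_duration_s": ramp.duration_s,
                      "oscillatory": ramp.oscillatory},
        ))
    return Session(cells=cells, sweep_sets=sweep_sets)
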