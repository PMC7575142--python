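"""Domain types and conventions for multi-neuron slice electrophysiology.

Unit conventions used throughout the package:

* voltage in mV (current clamp), current in pA (voltage clamp)
* time stored in seconds; durations and latencies *reported* in ms
* distances in µm, sampling rates in Hz
* raw voltage-clamp currents keep their physiological sign (inward
  currents negative at a −60 mV holding potential); every reported
  "amplitude" is a magnitude in pA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CURRENT_CLAMP",
    "VOLTAGE_CLAMP",
    "PROTOCOLS",
    "Trace",
    "CellRecord",
    "ProtocolSweepSet",
    "GroundTruth",
    "Session",
    "FormatError",
    "intersomatic_distance",
]

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"

#: Recognised experimental protocols.
PROTOCOLS = ("ap_train", "current_step", "light_pulse", "light_ramp", "spontaneous")

#: Known genetic labels plus the non-marked catch-all.
CELL_LABELS = (
    "ORX", "MCH", "VGLUT2", "GAD65-GFP", "GAD65-cre", "VGAT",
    "PV/FS", "NPY", "pyramidal", "n.m.",
)


class FormatError(ValueError):
    """A session container or trace violated the documented layout."""


@dataclass
class Trace:
    """One uniformly sampled recorded or simulated signal.

    Parameters
    ----------
    samples
        Signal values: mV for current clamp, pA for voltage clamp.
    sampling_rate
        Samples per second (Hz); must be positive.
    clamp_mode
        ``"current_clamp"`` or ``"voltage_clamp"``.
    t0
        Time of the first sample, in seconds.
    stimulus
        Optional command waveform of the same length: injected current in
        pA, or normalised light intensity in [0, 1].
    """

    samples: np.ndarray
    sampling_rate: float
    clamp_mode: str = CURRENT_CLAMP
    t0: float = 0.0
    stimulus: Optional[np.ndarray] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise FormatError("Trace.samples must be one-dimensional")
        if not (self.sampling_rate > 0):
            raise FormatError("Trace.sampling_rate must be positive")
        if self.clamp_mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise FormatError(f"unknown clamp_mode {self.clamp_mode!r}")
        if self.stimulus is not None:
            self.stimulus = np.asarray(self.stimulus, dtype=np.float64)
            if self.stimulus.shape != self.samples.shape:
                raise FormatError(
                    "Trace.stimulus length "
                    f"{self.stimulus.size} != samples length {self.samples.size}"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Index of the sample at (or immediately after) time ``t`` seconds."""
        return int(round((t - self.t0) * self.sampling_rate))


@dataclass
class CellRecord:
    """Identity and geometry of one recorded neuron.

    ``soma_xy`` is the soma position in the slice plane in µm; ``depth``
    is the distance from the slice surface in µm. ``opsin_positive``
    marks membership in the optogenetically driven population.
    """

    cell_id: str
    label: str = "n.m."
    region: str = "LH"
    soma_xy: Optional[tuple] = None
    depth: float = 0.0
    opsin_positive: bool = False

    def __post_init__(self):
        if self.depth < 0:
            raise FormatError("CellRecord.depth must be >= 0")
        if self.soma_xy is not None:
            x, y = self.soma_xy
            if not (math.isfinite(x) and math.isfinite(y)):
                raise FormatError("CellRecord.soma_xy must be finite")
            self.soma_xy = (float(x), float(y))


@dataclass
class ProtocolSweepSet:
    """Trials of simultaneously recorded traces under one protocol.

    ``trials`` is a list of trial dictionaries mapping ``cell_id`` to the
    :class:`Trace` recorded from that cell during the trial.  Protocol
    specifics live in ``metadata``: ``ap_train`` sweep sets store the
    imposed spike times under ``"ap_times"`` (seconds) and the driven
    cell under ``"pre_id"``; light protocols store ``"light_times"``.
    """

    protocol: str
    trials: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.protocol not in PROTOCOLS:
            raise FormatError(f"unknown protocol {self.protocol!r}")
        rates = set()
        lengths = set()
        for trial in self.trials:
            for tr in trial.values():
                rates.add(tr.sampling_rate)
                lengths.add(tr.n_samples)
        if len(rates) > 1 or len(lengths) > 1:
            raise FormatError(
                "simultaneous traces must share sampling_rate and length"
            )
        if self.protocol == "ap_train" and self.trials:
            if "ap_times" not in self.metadata:
                raise FormatError("ap_train sweep set must store ap_times")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def cell_ids(self) -> list:
        return sorted(self.trials[0]) if self.trials else []


@dataclass
class GroundTruth:
    """Known connectivity of a simulated session.

    ``chem`` holds the directed chemical-connection amplitudes (mV for
    PSPs), zero where unconnected; ``elec`` the symmetric electrical
    coupling coefficients; ``opto_connected`` the per-cell count of
    connected opsin-positive presynaptic neurons. ``cell_ids`` gives the
    row/column order.
    """

    cell_ids: list
    chem: Optional[np.ndarray] = None
    elec: Optional[np.ndarray] = None
    opto_connected: Optional[np.ndarray] = None
    spsc_events: Optional[dict] = None

    def __post_init__(self):
        n = len(self.cell_ids)
        for name in ("chem", "elec"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=np.float64)
                if m.shape != (n, n):
                    raise FormatError(f"GroundTruth.{name} must be {n}x{n}")
                setattr(self, name, m)
        if self.elec is not None and not np.allclose(self.elec, self.elec.T):
            raise FormatError("GroundTruth.elec must be symmetric")


@dataclass
class Session:
    """One recording session: cells, protocol sweep sets, optional truth."""

    cells: list
    sweep_sets: list = field(default_factory=list)
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self):
        ids = {c.cell_id for c in self.cells}
        if len(ids) != len(self.cells):
            raise FormatError("duplicate cell_id in Session.cells")
        for ss in self.sweep_sets:
            for trial in ss.trials:
                unknown = set(trial) - ids
                if unknown:
                    raise FormatError(
                        f"sweep set references unknown cell_ids {sorted(unknown)}"
                    )
        if self.ground_truth is not None:
            if set(self.ground_truth.cell_ids) != ids:
                raise FormatError("ground_truth cell_ids must match session cells")

    def cell(self, cell_id: str) -> CellRecord:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)

    @property
    def cell_ids(self) -> list:
        return [c.cell_id for c in self.cells]

    def sweeps(self, protocol: str) -> list:
        return [s for s in self.sweep_sets if s.protocol == protocol]


def intersomatic_distance(a: CellRecord, b: CellRecord) -> float:
    """Euclidean distance between two somata in the slice plane, in µm.

    Depth is excluded: distances are measured in the 2-D plane, matching
    micrograph-based measurement.  Returns ``nan`` when either soma
    position is unavailable (never silently 0).
    """
    if a.soma_xy is None or b.soma_xy is None:
        return float("nan")
    dx = a.soma_xy[0] - b.soma_xy[0]
    dy = a.soma_xy[1] - b.soma_xy[1]
    return math.hypot(dx, dy)
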