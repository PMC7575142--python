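"""HDF5 session container and CSV/JSON result tables.

Layout of a session file::

    /cells/<cell_id>            attrs: label, region, x, y, depth, opsin_positive
    /sweeps/<NNN>               attrs: protocol, metadata (JSON)
    /sweeps/<NNN>/trial_<KKK>/<cell_id>/samples   attrs: sampling_rate, clamp_mode, t0
    /sweeps/<NNN>/trial_<KKK>/<cell_id>/stimulus  (optional)
    /ground_truth/{chem,elec,opto_connected}      attrs: cell_ids (JSON)

All numeric fields round-trip at full float64 precision.
"""

from __future__ import annotations

import json
import os

import h5py
import numpy as np

from .core import (
    CellRecord,
    FormatError,
    GroundTruth,
    ProtocolSweepSet,
    Session,
    Trace,
)

__all__ = ["read_session", "write_session"]


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_session(session: Session, path) -> None:
    """Write a :class:`Session` to an HDF5 container at ``path``."""
    with h5py.File(path, "w") as f:
        g_cells = f.create_group("cells")
        for c in session.cells:
            g = g_cells.create_group(c.cell_id)
            g.attrs["label"] = c.label
            g.attrs["region"] = c.region
            g.attrs["has_soma_xy"] = c.soma_xy is not None
            if c.soma_xy is not None:
                g.attrs["x"] = c.soma_xy[0]
                g.attrs["y"] = c.soma_xy[1]
            g.attrs["depth"] = c.depth
            g.attrs["opsin_positive"] = bool(c.opsin_positive)

        g_sweeps = f.create_group("sweeps")
        for i, ss in enumerate(session.sweep_sets):
            g = g_sweeps.create_group(f"{i:03d}")
            g.attrs["protocol"] = ss.protocol
            g.attrs["metadata"] = json.dumps(ss.metadata, default=_json_default)
            for k, trial in enumerate(ss.trials):
                gt = g.create_group(f"trial_{k:03d}")
                for cell_id, tr in trial.items():
                    gc = gt.create_group(cell_id)
                    d = gc.create_dataset("samples", data=tr.samples)
                    d.attrs["sampling_rate"] = tr.sampling_rate
                    d.attrs["clamp_mode"] = tr.clamp_mode
                    d.attrs["t0"] = tr.t0
                    if tr.stimulus is not None:
                        gc.create_dataset("stimulus", data=tr.stimulus)

        if session.ground_truth is not None:
            gt = session.ground_truth
            g = f.create_group("ground_truth")
            g.attrs["cell_ids"] = json.dumps(list(gt.cell_ids))
            for name in ("chem", "elec", "opto_connected"):
                arr = getattr(gt, name)
                if arr is not None:
                    g.create_dataset(name, data=np.asarray(arr, dtype=np.float64))
            if gt.spsc_events is not None:
                g.attrs["spsc_events"] = json.dumps(
                    gt.spsc_events, default=_json_default
                )


def read_session(path) -> Session:
    """Read a session container written by :func:`write_session`.

    Raises :class:`~sparseconn.core.FormatError` naming the first
    offending field on a malformed container.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such session file: {path}")
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise FormatError(f"not an HDF5 session container: {path} ({e})") from None
    with f:
        if "cells" not in f:
            raise FormatError("missing group /cells")
        cells = []
        for cell_id in sorted(f["cells"]):
            g = f["cells"][cell_id]
            soma = None
            if g.attrs.get("has_soma_xy", False):
                soma = (float(g.attrs["x"]), float(g.attrs["y"]))
            cells.append(
                CellRecord(
                    cell_id=cell_id,
                    label=str(g.attrs.get("label", "n.m.")),
                    region=str(g.attrs.get("region", "LH")),
                    soma_xy=soma,
                    depth=float(g.attrs.get("depth", 0.0)),
                    opsin_positive=bool(g.attrs.get("opsin_positive", False)),
                )
            )

        sweep_sets = []
        for name in sorted(f.get("sweeps", {})):
            g = f["sweeps"][name]
            if "protocol" not in g.attrs:
                raise FormatError(f"/sweeps/{name} missing protocol attribute")
            trials = []
            for tname in sorted(g):
                gt = g[tname]
                trial = {}
                for cell_id in gt:
                    gc = gt[cell_id]
                    if "samples" not in gc:
                        raise FormatError(
                            f"/sweeps/{name}/{tname}/{cell_id} missing samples"
                        )
                    d = gc["samples"]
                    stim = gc["stimulus"][()] if "stimulus" in gc else None
                    trial[cell_id] = Trace(
                        samples=d[()],
                        sampling_rate=float(d.attrs["sampling_rate"]),
                        clamp_mode=str(d.attrs["clamp_mode"]),
                        t0=float(d.attrs["t0"]),
                        stimulus=stim,
                    )
                trials.append(trial)
            sweep_sets.append(
                ProtocolSweepSet(
                    protocol=str(g.attrs["protocol"]),
                    trials=trials,
                    metadata=json.loads(g.attrs.get("metadata", "{}")),
                )
            )

        ground_truth = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            kw = {}
            for name in ("chem", "elec", "opto_connected"):
                if name in g:
                    kw[name] = g[name][()]
            ev = g.attrs.get("spsc_events")
            ground_truth = GroundTruth(
                cell_ids=json.loads(g.attrs["cell_ids"]),
                spsc_events=json.loads(ev) if ev is not None else None,
                **kw,
            )

    return Session(cells=cells, sweep_sets=sweep_sets, ground_truth=ground_truth)
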