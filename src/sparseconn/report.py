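"""Group statistics and end-to-end pipeline orchestration.

Conventions follow the source field: values reported as mean ± sd,
two-sided tests, no multiple-testing correction (stated explicitly:
the screening design yields a handful of planned comparisons, not a
family of exploratory ones).  Rank-sum p values are exact for group
sizes up to 25 and use the normal approximation above that, so fixture-
scale results are reproducible to the digit.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .core import Session
from .pairwise import (
    ScreenParams,
    distance_histogram,
    measure_coupling,
    rate_table,
    screen_session,
)
from .events import EventParams, classify_opto, detect_events, event_stats
from .spectral import ramp_power_increase, summarize_increase
from .synth import (
    SimConfig,
    simulate_connection_session,
    simulate_opto_trial,
    simulate_ramp_session,
)

__all__ = ["GroupComparison", "compare_groups", "run_pipeline", "PipelineError"]

_EXACT_RANKSUM_N = 25


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class GroupComparison:
    """One two-group comparison reported as in the source field."""

    metric: str
    test: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    statistic: float
    p: float


def compare_groups(a: Sequence[float], b: Sequence[float], test: str,
                   metric: str = "") -> GroupComparison:
    """Two-sided comparison of two groups of values.

    ``test`` is one of ``paired_t``, ``unpaired_t``, ``ranksum``
    (Wilcoxon rank-sum / Mann-Whitney), ``signedrank`` (Wilcoxon
    signed-rank).  Paired tests require equal lengths.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("group values must be finite")
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    if test in ("paired_t", "signedrank") and a.size != b.size:
        raise ValueError(f"{test} requires equal group sizes")

    if test == "paired_t":
        res = stats.ttest_rel(a, b)
    elif test == "unpaired_t":
        res = stats.ttest_ind(a, b)
    elif test == "ranksum":
        if a.size <= _EXACT_RANKSUM_N and b.size <= _EXACT_RANKSUM_N:
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact")
        else:
            res = stats.ranksums(a, b)
    elif test == "signedrank":
        res = stats.wilcoxon(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")

    return GroupComparison(
        metric=metric, test=test, n_a=int(a.size), n_b=int(b.size),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        statistic=float(res.statistic), p=float(res.pvalue),
    )


def _require(config: dict, key: str, stage: str):
    if key not in config:
        raise PipelineError(f"stage '{stage}': missing required config key '{key}'")
    return config[key]


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the configured stages end to end and write a CSV/JSON bundle.

    ``config`` names a ``seed`` and a ``stages`` mapping; supported
    stages are ``connectivity`` (simulate + screen + coupling + rate and
    distance tables), ``opto`` (simulate light-pulse trials + event
    detection + per-cell stats), and ``ramp`` (oscillatory vs
    non-oscillatory light-ramp simulation + band-power contrast).  All
    stage configs are validated up front; any failure aborts with a
    stage-named diagnostic.  Reruns with the same seed produce
    byte-identical CSV outputs.
    """
    out_dir = Path(out_dir)
    seed = config.get("seed", 0)
    stages = _require(config, "stages", "config")
    known = {"connectivity", "opto", "ramp"}
    for name in stages:
        if name not in known:
            raise PipelineError(f"stage '{name}': unknown stage")
    # validate before any compute
    if "opto" in stages and stages["opto"].get("n_connected", 1) < 0:
        raise PipelineError("stage 'opto': n_connected must be >= 0")

    out_dir.mkdir(parents=True, exist_ok=True)
    log = {"seed": int(seed), "sparseconn_version": __version__,
           "python": platform.python_version(), "config": config}
    results: dict = {}

    if "connectivity" in stages:
        st = stages["connectivity"]
        try:
            sim = SimConfig(seed=seed, **st.get("sim", {}))
            session = simulate_connection_session(sim, st.get("n_trials", 20))
            tests = screen_session(session, ScreenParams())
            couplings = measure_coupling(session)
            tests_df = pd.DataFrame([{
                "pre_id": t.pre_id, "post_id": t.post_id,
                "pre_label": t.pre_label, "post_label": t.post_label,
                "n_trials": t.n_trials, "amp": t.evoked_amp,
                "latency_ms": t.latency_ms, "detected": t.detected,
                "distance_um": t.distance_um,
            } for t in tests])
            rates = rate_table(tests, group_by=("region",))
            edges, c_det, c_not, p = distance_histogram(tests)
            tests_df.to_csv(out_dir / "connection_tests.csv", index=False)
            rates.to_csv(out_dir / "rates.csv", index=False)
            results["connectivity"] = {
                "n_tested": len(tests),
                "n_detected": int(sum(t.detected for t in tests)),
                "n_pairs_coupled": int(sum(c.coupled for c in couplings)),
                "distance_ranksum_p": p,
            }
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(f"stage 'connectivity': {e}") from e

    if "opto" in stages:
        st = stages["opto"]
        try:
            sim = SimConfig(seed=seed, **st.get("sim", {}))
            sim.opto.n_connected = st.get("n_connected", sim.opto.n_connected)
            sweep = simulate_opto_trial(sim, n_pulses=st.get("n_pulses", 50))
            trace = sweep.trials[0]["post"]
            events = detect_events(trace, EventParams(polarity="inward"))
            classify_opto(events, sweep.metadata["light_times"])
            stats_ = event_stats(events)
            ev_df = pd.DataFrame([{
                "onset_s": e.onset_s, "peak_amp_pA": e.peak_amp_pA,
                "rise_ms": e.rise_ms, "decay_tau_ms": e.decay_tau_ms,
                "kind": e.kind, "compound": e.compound,
            } for e in events])
            ev_df.to_csv(out_dir / "events.csv", index=False)
            results["opto"] = {
                "n_events": len(events),
                "mean_spsc_pA": stats_.mean_spsc_pA if stats_ else None,
                "mean_opsc_pA": stats_.mean_opsc_pA if stats_ else None,
                "ratio": stats_.ratio if stats_ else None,
                "est_presyn_count": stats_.est_presyn_count if stats_ else None,
            }
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(f"stage 'opto': {e}") from e

    if "ramp" in stages:
        st = stages["ramp"]
        try:
            n_cells = st.get("n_cells", 5)
            osc = SimConfig(seed=seed, n_cells=n_cells)
            osc.ramp.oscillatory = True
            non = SimConfig(seed=seed + 1, n_cells=n_cells)
            non.ramp.oscillatory = False
            df_osc = ramp_power_increase(simulate_ramp_session(osc))
            df_non = ramp_power_increase(simulate_ramp_session(non))
            df_osc.assign(group="oscillatory").to_csv(
                out_dir / "ramp_increase_oscillatory.csv", index=False)
            df_non.assign(group="non_oscillatory").to_csv(
                out_dir / "ramp_increase_non_oscillatory.csv", index=False)
            cmp_ = compare_groups(df_osc["increase"], df_non["increase"],
                                  "ranksum", metric="band_power_increase")
            results["ramp"] = {
                **summarize_increase(df_non, reference=df_osc),
                "oscillatory_mean_increase": float(df_osc["increase"].mean()),
                "ranksum_p": cmp_.p,
            }
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(f"stage 'ramp': {e}") from e

    log["results"] = results
    with open(out_dir / "run_log.json", "w") as f:
        json.dump(log, f, indent=2, default=str)
    return results
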