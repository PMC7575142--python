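"""Detect locally generated network oscillations under light ramps.

5 s linear light ramps are simulated in two regimes: a recurrently
connected (cortex-like) circuit whose synaptic current oscillates in the
10-80 Hz beta-gamma band with light-scaled envelope, and a sparsely
connected circuit that only depolarises tonically.  Band power is
measured on 0.5 s / 95%-overlap Hann spectrograms after a 10 Hz
zero-phase high-pass.
"""

from sparseconn import (
    SimConfig, ramp_power_increase, simulate_ramp_session, summarize_increase,
)

osc_cfg = SimConfig(seed=1, n_cells=5)
osc_cfg.ramp.oscillatory = True
non_cfg = SimConfig(seed=2, n_cells=5)
non_cfg.ramp.oscillatory = False

df_osc = ramp_power_increase(simulate_ramp_session(osc_cfg))
df_non = ramp_power_increase(simulate_ramp_session(non_cfg))

print("oscillatory circuit, per-cell 10-80 Hz band-power increase (pA^2):")
print(" ", df_osc["increase"].round(2).tolist())
print("non-oscillatory circuit:")
print(" ", df_non["increase"].round(2).tolist())

summary = summarize_increase(df_non, reference=df_osc)
print(f"\nnon-oscillatory mean increase = {summary['mean_increase']:.2f} pA^2, "
      f"{100 * summary['increase_ratio']:.1f}% of the oscillatory group's")
print("A sparsely connected circuit shows essentially no beta-gamma power")
print("increase even though every cell is strongly driven by the light ramp.")
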