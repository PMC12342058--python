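"""Slow-wave metrics on one synthetic recording day.

Computes per-epoch delta power, baseline-normalized SWA, relative SWA and
cumulative slow-wave energy (SWE) over the NREM epochs of a generated
day. Normalized SWA self-normalizes to a mean of 100% on the baseline
day; SWE grows only while the animal is in NREM sleep.
"""

import numpy as np

import somnostress as ss

params = ss.SimParams.from_preset("male_resilient", seed=7)
schedule = ss.ProtocolSchedule(days=[ss.DayPlan(0, "baseline")])
hyp = ss.simulate_hypnogram(params, schedule)
s_traj = ss.homeostat_trajectory(hyp, params)
rec = ss.synthesize_signals(hyp, s_traj, params)

bands = ss.epoch_band_powers(rec.channels["eeg_frontal"], rec.fs)
nrem = hyp.mask(ss.NREM)
delta = bands["delta"].to_numpy()

norm = ss.normalized_swa(delta[nrem], delta[nrem])
rel = ss.relative_swa(delta[nrem], bands["total"].to_numpy()[nrem])
swe = ss.slow_wave_energy(delta, nrem)

print(f"NREM epochs               : {nrem.sum()}")
print(f"mean NREM delta power     : {delta[nrem].mean():.0f} uV^2")
print(f"self-normalized SWA mean  : {norm.mean():.1f} %   (100% by construction)")
print(f"mean relative SWA         : {rel.mean():.1f} % of 0.5-30 Hz power")
print(f"final slow-wave energy    : {swe[-1]:.2e} uV^2*s")

tc = ss.swa_timecourse(norm, hyp.epoch_zt_s()[nrem], bin_h=2.0)
print("\nnormalized SWA by 2 h ZT bin (%):")
print(tc.assign(mean=tc['mean'].round(1)).to_string(index=False))
# SWA is highest early in the light phase (high sleep pressure after the
# active dark period) and declines as Process S discharges.
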