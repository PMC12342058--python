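"""Sleep lost during 6 h forced wakefulness and the recovery that follows.

Simulates a baseline day and a sleep-restriction day (forced wake over
ZT0-6), measures sleep lost as baseline-minus-restriction minutes over
the same window, then tracks cumulative recovery sleep across the 18 h
after restriction ends.
"""

import somnostress as ss

params = ss.SimParams.from_preset("female_susceptible", seed=3)
schedule = ss.ProtocolSchedule(days=[
    ss.DayPlan(0, "baseline"),
    ss.DayPlan(1, "sleep_restriction", forced_wake_window=(0.0, 6.0)),
])
hyp = ss.simulate_hypnogram(params, schedule)
base = ss.Hypnogram(hyp.states[:8640])
sr = ss.Hypnogram(hyp.states[8640:])
# the 18 h recovery window runs over ZT6-24 of the restriction day itself

lost = ss.sleep_lost(base, sr)
print("sleep lost during restriction (ZT0-6):")
print(f"  NREM  : {lost[ss.NREM]:6.1f} min")
print(f"  REM   : {lost[ss.REM]:6.1f} min")
# Female mice lose on the order of 145-150 min NREM and ~20 min REM over
# a 6 h light-phase restriction.

curve = ss.recovery_sleep(base, sr, window_zt_h=(6.0, 24.0))
end = curve.iloc[-1]
print("\ncumulative recovery vs baseline over ZT6-24 after restriction:")
print(f"  NREM gain : {end['cum_nrem_gain_min']:6.1f} min")
print(f"  REM gain  : {end['cum_rem_gain_min']:6.1f} min")
# Positive gains indicate homeostatic rebound sleep after the challenge.
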