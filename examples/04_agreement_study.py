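"""Replicate the full agreement study on a small synthetic cohort.

Simulates three subjects across all three postures, extracts HR and RR
from both sensors and the reference for every window length, and prints
the pooled Bland-Altman bias (MOD), 95% limits of agreement and MAE per
sensor and window for the sitting posture, plus the posture effect at a
fixed window.
"""

import imuvitals as iv

report, series, cohort = iv.run_study(n_subjects=3, seed=0)


def row(metric, **labels):
    return float(report.lookup(metric, **labels)["value"].iloc[0])


print("HR agreement, sitting posture (3 subjects pooled):")
print("window   sensor    MOD (bpm)   LOA (bpm)          MAE (bpm)")
for L in (5.0, 25.0, 55.0):
    for sensor in ("acc", "gyr"):
        g = dict(vital="hr", sensor=sensor, posture="sitting", window_s=L)
        print(f"{L:4.0f} s   {sensor}   {row('mod', **g):9.3f}   "
              f"[{row('loa_low', **g):6.3f}, {row('loa_high', **g):6.3f}]   "
              f"{row('mae', **g):9.3f}")

print("\nRR MAE (BrPM) by posture, accelerometer, 25 s window:")
for posture in ("sitting", "standing", "lying"):
    g = dict(vital="rr", sensor="acc", posture=posture, window_s=25.0)
    print(f"  {posture:9s} {row('mae', **g):7.3f}   (n = "
          f"{int(report.lookup('mae', **g)['n'].iloc[0])} windows)")

print("\nStanding carries the highest sensor noise in the simulator, so its")
print("errors are largest; the 5 s window is far worse than 25 s and longer,")
print("because a short window cannot hold a full breathing cycle.")
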