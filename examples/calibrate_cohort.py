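"""Solve the distance-mixture calibration for target cohort statistics.

The generator's true editability is A*exp(-d/L) + B plus noise; the
nearest-reverse-neighbor distance d follows a two-exponential mixture.
calibrate_generator solves the closed-form moment equations so that the
cohort hits a requested mean, SD, and distance-explained variance fraction.
"""

import numpy as np

from alueditability import calibrate_generator, sample_distance_mixture

cal = calibrate_generator(target_mean=1.34, target_sd=1.72,
                          target_fraction=0.28)
print("closed-form solution of the moment equations:")
for key in ("p_close", "m_close", "m_far", "noise_sd"):
    print(f"  {key:10s} = {cal[key]:.4f}")
print(f"achieved mean/SD/fraction: {cal['achieved_mean']:.4f} / "
      f"{cal['achieved_sd']:.4f} / {cal['achieved_fraction']:.4f}")

rng = np.random.default_rng(1)
d = sample_distance_mixture(cal["p_close"], cal["m_close"], cal["m_far"],
                            1_000_000, rng)
signal = 2.9 * np.exp(-d / 800.0) + 0.25
print(f"\nMonte-Carlo check over 1e6 draws: mean {signal.mean():.4f}, "
      f"signal SD {np.std(signal - 0.25):.4f} "
      f"(targets 1.3400 and {1.72 * np.sqrt(0.28):.4f})")
print("\nRoughly a third of elements sit in the tight-pairing component "
      f"(mean gap {cal['m_close']:.0f} bp); the rest are spread with mean "
      f"{cal['m_far']:.0f} bp, producing the long editability tail.")
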