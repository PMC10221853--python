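"""WHAM free-energy reconstruction validated on a known double-well PMF.

The umbrella protocol varies the *stiffness* of a COM z-spring (rest length
1) in 61 equal steps from 0 to 0.3.  Here the biased windows are sampled
exactly from the Boltzmann weights of a synthetic double-well PMF, so the
WHAM estimate can be compared bin-by-bin against the known input — the
standard correctness check before trusting the estimator on MD data.
"""

import numpy as np

from hpbrush.umbrella import WHAMConfig, sample_biased_windows, wham_solve


def double_well(z):
    z1, z2, height, cap = 1.5, 3.9, 3.0, 4.0
    zm = 0.5 * (z1 + z2)
    raw = height * ((z - z1) * (z - z2)) ** 2 / ((zm - z1) * (zm - z2)) ** 2
    return np.minimum(raw, cap)


cfg = WHAMConfig(lz=6.0, bin_width=0.1)
windows = sample_biased_windows(
    double_well, ks=0.005 * np.arange(61), n_samples=10_000,
    config=cfg, support=(0.6, 5.4), seed=12345,
)
profile = wham_solve(windows, cfg)

ok = profile.p > 0
i0 = np.nonzero(ok)[0][np.argmin(profile.pmf[ok])]
ref = double_well(profile.z) - double_well(profile.z[i0])
err = np.abs((profile.pmf - profile.pmf[i0]) - ref)[ok]

print(f"{len(windows)} windows x {windows[0].n} samples, "
      f"converged in {profile.iterations} iterations")
print(f"max |PMF error| over the sampled range: {err.max():.3f} kBT")
print("\n   z    PMF(est)  PMF(true)")
for i in np.nonzero(ok)[0][::6]:
    print(f"{profile.z[i]:5.2f}  {profile.pmf[i] - profile.pmf[i0]:8.2f}  "
          f"{ref[i]:8.2f}")
print(
    "\nErrors below 0.1 kBT mean the estimator adds no bias beyond counting "
    "noise; on MD data the same pipeline turns window samples into the "
    "adsorption free-energy profile along z."
)
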