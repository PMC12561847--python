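"""Interface-pressure benefit of ICOR alignment (synthetic demonstration).

Misalignment between the exoskeleton pivot and the joint's equivalent ICOR
concentrates interface force.  The generator emits Gaussian pressure blobs of
fixed total force whose spread shrinks with misalignment; comparing 3 mm
misalignment (conventional pivot) against 0.5 mm (crossing-type pair) over 20
noisy cycles reproduces the qualitative mechanism: lower peak and mean
pressure and a wider contact area after alignment.
"""

import numpy as np

from handicor.evaluation import (
    generate_pressure_frames,
    paired_t_test,
    percent_reduction,
    summarize_pressure,
)

conditions = {"without_pairs": 3.0, "with_pairs": 0.5}
summaries = {}
for seed, (cond, misalignment) in enumerate(conditions.items(), start=1):
    # independent noise draws per condition, as two separate recordings
    frames = generate_pressure_frames(
        misalignment, noise_sd=0.05, n_cycles=20, seed=seed, condition=cond)
    summaries[cond] = [summarize_pressure(f) for f in frames]
    peak = np.mean([s.peak_pressure for s in summaries[cond]])
    mean = np.mean([s.mean_pressure for s in summaries[cond]])
    area = np.mean([s.active_area for s in summaries[cond]])
    print(f"{cond:14s} (misalignment {misalignment} mm): "
          f"peak {peak:.2f} kPa, mean {mean:.2f} kPa, area {area:.0f} mm^2")

before = summaries["without_pairs"]
after = summaries["with_pairs"]
red = percent_reduction(
    summarize_pressure(generate_pressure_frames(3.0, n_cycles=1)[0]),
    summarize_pressure(generate_pressure_frames(0.5, n_cycles=1)[0]),
)
print(f"noise-free reductions: peak {red['peak']:.1f}%, mean {red['mean']:.1f}%")

t, p, df = paired_t_test(
    [s.peak_pressure for s in before], [s.peak_pressure for s in after])
print(f"paired t-test on per-cycle peaks: t = {t:.2f}, p = {p:.2e} (df = {df})")
# The calibrated default gain places the peak reduction in the 20-30% band
# and the mean reduction in the 15-25% band; the paired test confirms the
# per-cycle difference is far beyond the injected sensor noise.
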