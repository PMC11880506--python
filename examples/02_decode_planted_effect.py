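"""Cross-participant decoding of a planted sex effect, with inference.

Generates a small synthetic cohort in which male and female faces evoke
distinct multivariate patterns from 50 ms to 200 ms — the same patterns in
every participant.  Leave-one-participant-out decoding can only succeed on
such shared patterns, so above-chance accuracy here demonstrates the
cross-participant logic.  The script then runs the full inference chain:
35 ms smoothing, a cluster permutation test against chance, and the
interval-null Bayes-factor time course with its onset/peak.
"""

import warnings

warnings.filterwarnings("ignore")

import facedecode as fd
from facedecode import stats

stim = fd.build_stimulus_set()
effect = fd.EffectSpec(attribute="sex", onset_ms=50, duration_ms=150, amplitude=1.5)
cfg = fd.CohortConfig(n_participants=8, n_channels=16, tmin=-0.1, tmax=0.3,
                      repetitions=6, effects=[effect], seed=0)
epochs, truth = fd.generate_cohort(cfg, stim)
pseudo = fd.bin_average(epochs, bin_size=3, seed=0)

result = fd.loso_timecourse(pseudo, fd.scheme("sex"))
bundle = stats.SeriesBundle.from_decoding(result).smoothed(35)

pre = bundle.values[:, bundle.times_ms < 40].mean()
post = bundle.values[:, (bundle.times_ms >= 60) & (bundle.times_ms < 190)].mean()
print(f"sex decoding accuracy (chance 0.5): pre-onset {pre:.3f}, "
      f"inside planted window {post:.3f}")

clusters = stats.cluster_permutation(bundle, n_perm=2000, seed=0)
for c in clusters.significant(0.05):
    print(f"significant cluster {c.start_ms:.0f}-{c.end_ms:.0f} ms, "
          f"p = {c.p:.4f}, peak Cohen's d = {c.peak_d:.2f} at {c.peak_time_ms:.0f} ms")

bf = stats.bayes_factor_series(bundle)
onset = stats.onset_peak(bf, min_run=7)
print(f"Bayes-factor onset {onset['onset_ms']:.0f} ms "
      f"(planted onset 50 ms), first peak {onset['peak_ms']:.0f} ms, "
      f"peak BF {onset['peak_value']:.1f}")
print("the onset marks when shared sex information first exceeds the "
      "strong-evidence threshold (BF > 10)")
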