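"""Clean a motion-contaminated recording.

Runs the full chain — trim, motion detection, spline correction, wavelet
filtering, 0.009–0.08 Hz band-pass, cubic detrend, baseline correction —
on one synthetic subject. Prints the artifact percentage (how much of the
recording the 1-s window detector flagged) and how strongly the cleaned
signal still tracks the noiseless latent component.
"""

import numpy as np

import nirsnet as nn
from nirsnet.preprocess import bandpass_array

montage = nn.make_montage()
config = nn.CohortConfig(n_asd=1, n_td=1, duration=300.0, seed=2, artifact_rate=4.0)
subjects, truth = nn.simulate_cohort(config, montage)
subject = subjects[0]

raw = nn.simulate_recording(subject, montage, config, truth)
result = nn.clean_series(raw, nn.PreprocessConfig(trim_s=15.0))

n_spikes = sum(ev.kind == "spike" for ev in truth.artifact_log)
n_shifts = sum(ev.kind == "shift" for ev in truth.artifact_log)
print(f"injected events: {n_spikes} spikes, {n_shifts} baseline shifts")
print(f"flagged as motion: {result.artifact_percent:.1f}% of samples")

# compare against the noiseless latent component (same seed, zero noise)
quiet = nn.CohortConfig(
    n_asd=1, n_td=1, duration=300.0, seed=2, artifact_rate=0.0,
    noise=nn.NoiseSpec(pink=0, cardiac=0, respiratory=0, mayer=0, white=0),
)
q_subjects, q_truth = nn.simulate_cohort(quiet, montage)
latent = nn.simulate_subject_series(q_subjects[0], montage, quiet, q_truth)
reference = bandpass_array(nn.trim_edges(latent, 15.0).hbo, latent.sampling_rate)
naive = bandpass_array(nn.trim_edges(raw, 15.0).hbo, raw.sampling_rate)
r_naive = np.mean([
    np.corrcoef(naive[c], reference[c])[0, 1] for c in range(48)
])
r_clean = np.mean([
    np.corrcoef(result.series.hbo[c], reference[c])[0, 1] for c in range(48)
])
print(f"mean correlation with the latent ground truth: "
      f"{r_naive:.3f} band-pass only -> {r_clean:.3f} with motion correction "
      "(the remainder is in-band physiological noise, which no filter can remove)")
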