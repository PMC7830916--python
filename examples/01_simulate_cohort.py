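"""Generate a small synthetic resting-state fNIRS cohort.

Builds the 48-channel montage, draws a 12-subject ASD/TD cohort with
demographics and symptom scores, and synthesizes one subject's HbO/HbR
recording with motion artifacts. The printed numbers summarize the cohort
(group sizes, age span, IQ means) and the recording (shape, amplitude,
number of injected motion events) — the ground truth every later stage is
tested against.
"""

import numpy as np

import nirsnet as nn

montage = nn.make_montage()
config = nn.CohortConfig(n_asd=8, n_td=4, duration=120.0, seed=1)
subjects, truth = nn.simulate_cohort(config, montage)

frame = nn.subjects_to_frame(subjects)
print(f"cohort: {len(subjects)} subjects "
      f"({(frame.group == 'ASD').sum()} ASD, {(frame.group == 'TD').sum()} TD)")
print(f"age span: {frame.age.min():.1f}-{frame.age.max():.1f} years; "
      f"mean FSIQ {frame.fsiq.mean():.1f}")
asd = frame[frame.group == "ASD"]
print(f"ADOS communication {asd.ados_communication.mean():.2f}, "
      f"social {asd.ados_social.mean():.2f} (ASD only)")

series = nn.simulate_recording(subjects[0], montage, config, truth)
print(f"\nrecording for {subjects[0].subject_id}: "
      f"{series.n_channels} channels x {series.n_samples} samples "
      f"at {series.sampling_rate} Hz")
print(f"HbO amplitude SD {np.std(series.hbo):.2f} µM; "
      f"{len(truth.artifact_log)} motion events injected")
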