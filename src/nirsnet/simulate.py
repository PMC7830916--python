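"""Synthetic resting-state fNIRS cohort generator with known ground truth.

Emulates a developmental case-control study: 77 ASD and 40 typically
developing (TD) males aged roughly 6-16.6 years, each contributing an
8-minute resting recording from a 48-channel frontotemporal montage sampled
at 8.7 Hz, with oxy- (HbO) and deoxy-hemoglobin (HbR) chromophores.

The generative model has three layers:

1. **Latent connectivity.** Each subject carries a 48×48 latent correlation
   matrix built block-wise from the montage's anatomical regions (higher
   correlation within a region than between regions, expressed on the
   Fisher-z scale), perturbed by subject-level jitter. Configurable effects
   add an age/diagnosis-dependent shift to one channel's Fisher-z couplings,
   using exactly the design terms the downstream trajectory regression
   estimates (group, centered age, centered age², and their interactions).
2. **Band-limited signal.** The resting-state "neural" component is
   Gaussian noise low-pass filtered below 0.08 Hz and mixed through the
   Cholesky factor of the latent matrix, so the low-frequency correlation
   structure of the noiseless signal matches the latent matrix. HbR is
   generated anti-correlated with HbO (default r = −0.7) with its own
   latent-structured residual.
3. **Nuisance structure.** 1/f noise, cardiac (~1.1 Hz), respiratory
   (~0.25 Hz) and Mayer-wave (~0.1 Hz) oscillations, white measurement
   noise, and optional motion artifacts (brief high-amplitude spikes and
   baseline step shifts applied to the whole probe array, as head motion
   would), all logged in the ground truth.

Everything is reproducible bit-for-bit from ``CohortConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .montage import make_montage, region_blocks
from .series import HemoglobinSeries
from .stats import canonical_term, trajectory_design

#: Table-style demographic moments of the emulated cohort (mean, SD).
DEMOGRAPHICS = {
    "ASD": {"viq": (105.79, 17.44), "piq": (104.68, 14.36), "fsiq": (101.47, 14.85)},
    "TD": {"viq": (106.05, 13.72), "piq": (108.85, 12.66), "fsiq": (105.10, 12.10)},
}
#: ADOS symptom score moments of the emulated ASD group (mean, SD).
ADOS_MOMENTS = {"ados_communication": (2.21, 1.50), "ados_social": (6.79, 2.15)}


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitudes (µM, relative to unit latent signal SD) of nuisance terms."""

    pink: float = 0.5
    cardiac: float = 0.4
    respiratory: float = 0.3
    mayer: float = 0.35
    white: float = 0.1
    cardiac_hz: float = 1.1
    respiratory_hz: float = 0.25
    mayer_hz: float = 0.1


@dataclass(frozen=True)
class EffectSpec:
    """An injected age-by-diagnosis effect on one channel's connectivity.

    ``size`` is the Fisher-z increment added to the channel's couplings per
    standard deviation of the (z-scored) design term. Use
    :func:`nirsnet.recovery.calibrate_effect_size` to translate a target
    standardized regression coefficient on a metric AUC into this scale.
    """

    channel: int  # 1-based channel id
    metric: str
    term: str
    size: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "term", canonical_term(self.term))
        if not np.isfinite(self.size):
            raise ValueError("effect size must be finite")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs of the synthetic cohort; defaults match the
    emulated study (cohort sizes, age range, sampling, recording length)."""

    n_asd: int = 77
    n_td: int = 40
    age_range: tuple[float, float] = (6.0, 16.6)
    sampling_rate: float = 8.7
    duration: float = 480.0
    effects: tuple[EffectSpec, ...] = ()
    artifact_rate: float = 4.0  # motion events per minute
    spike_amplitude_sd: float = 10.0
    shift_amplitude_sd: float = 5.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    hbo_hbr_ratio: float = -0.7
    hbr_amplitude: float = 0.4
    within_region_r: float = 0.45
    cross_hemisphere_r: float = 0.30
    between_region_r: float = 0.12
    latent_jitter_sd: float = 0.05
    ados_link: float = 0.8  # SDs of ADOS score per SD of injected nodal shift
    signal_band_hz: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_asd <= 0 or self.n_td <= 0:
            raise ValueError("group counts must be positive")
        if not (0 < self.age_range[0] < self.age_range[1]):
            raise ValueError("invalid age range")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass
class Subject:
    subject_id: str
    group: str  # "ASD" | "TD"
    age: float
    viq: float
    piq: float
    fsiq: float
    ados_communication: float | None = None
    ados_social: float | None = None


@dataclass
class ArtifactEvent:
    """A logged motion event; channel 0 means the whole probe array."""

    channel: int
    onset: float  # seconds from recording start
    duration: float
    kind: str  # "spike" | "shift"


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would not."""

    covariances: np.ndarray  # (n_subjects, 48, 48) latent correlation matrices
    effects: tuple[EffectSpec, ...]
    design: pd.DataFrame  # standardized design-term values per subject
    subject_index: dict[str, int]
    artifact_log: list[ArtifactEvent] = field(default_factory=list)

    def covariance_of(self, subject_id: str) -> np.ndarray:
        return self.covariances[self.subject_index[subject_id]]


def subjects_to_frame(subjects: list[Subject]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in subjects])


def base_z_matrix(config: CohortConfig, montage: pd.DataFrame) -> np.ndarray:
    """Block-structured baseline connectivity on the Fisher-z scale."""
    n = len(montage)
    region = montage["region"].to_numpy()
    hemi = montage["hemisphere"].to_numpy()
    z = np.full((n, n), np.arctanh(config.between_region_r))
    same_region = region[:, None] == region[None, :]
    same_hemi = hemi[:, None] == hemi[None, :]
    z[same_region] = np.arctanh(config.cross_hemisphere_r)
    z[same_region & same_hemi] = np.arctanh(config.within_region_r)
    np.fill_diagonal(z, 0.0)
    return z


def _nearest_correlation(mat: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to a positive-semidefinite correlation."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, 1e-6, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def simulate_cohort(
    config: CohortConfig, montage: pd.DataFrame | None = None
) -> tuple[list[Subject], GroundTruth]:
    """Draw demographics, symptom scores and latent connectivity matrices."""
    if montage is None:
        montage = make_montage()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_total = config.n_asd + config.n_td
    groups = ["ASD"] * config.n_asd + ["TD"] * config.n_td
    ages = rng.uniform(*config.age_range, size=n_total)
    is_asd = np.array([g == "ASD" for g in groups])

    design = trajectory_design(ages, is_asd, standardize=True)

    # Latent connectivity per subject
    z0 = base_z_matrix(config, montage)
    n_ch = len(montage)
    covariances = np.empty((n_total, n_ch, n_ch))
    shift = np.zeros(n_total)  # summed injected z-shift, drives the ADOS link
    for i in range(n_total):
        jit = rng.normal(0.0, config.latent_jitter_sd, size=(n_ch, n_ch))
        zi = z0 + (jit + jit.T) / 2.0
        for eff in config.effects:
            x = float(design[eff.term].iloc[i])
            delta = eff.size * x
            shift[i] += delta
            c = eff.channel - 1
            zi[c, :] += delta
            zi[:, c] += delta
        np.fill_diagonal(zi, 0.0)
        ri = np.tanh(zi)
        np.fill_diagonal(ri, 1.0)
        covariances[i] = _nearest_correlation(ri)

    # Demographics and symptom scores
    iq = {
        k: np.where(
            is_asd,
            rng.normal(*DEMOGRAPHICS["ASD"][k], size=n_total),
            rng.normal(*DEMOGRAPHICS["TD"][k], size=n_total),
        )
        for k in ("viq", "piq", "fsiq")
    }
    shift_sd = shift.std()
    shift_z = (shift - shift.mean()) / shift_sd if shift_sd > 0 else np.zeros(n_total)
    ados = {}
    for score, (mu, sd) in ADOS_MOMENTS.items():
        raw = rng.normal(mu, sd, size=n_total)
        ados[score] = np.clip(raw - config.ados_link * sd * shift_z, 0.0, None)

    subjects = []
    index: dict[str, int] = {}
    n_asd_seen = n_td_seen = 0
    for i, g in enumerate(groups):
        if g == "ASD":
            n_asd_seen += 1
            sid = f"ASD{n_asd_seen:03d}"
        else:
            n_td_seen += 1
            sid = f"TD{n_td_seen:03d}"
        subjects.append(
            Subject(
                subject_id=sid, group=g, age=float(ages[i]),
                viq=float(iq["viq"][i]), piq=float(iq["piq"][i]),
                fsiq=float(iq["fsiq"][i]),
                ados_communication=float(ados["ados_communication"][i]) if g == "ASD" else None,
                ados_social=float(ados["ados_social"][i]) if g == "ASD" else None,
            )
        )
        index[sid] = i

    truth = GroundTruth(
        covariances=covariances,
        effects=config.effects,
        design=design,
        subject_index=index,
    )
    return subjects, truth


def _lowpass_sos(config: CohortConfig):
    return spsig.butter(
        4, config.signal_band_hz, btype="lowpass", fs=config.sampling_rate, output="sos"
    )


def _band_limited_factors(rng, n_samples: int, n_ch: int, sos) -> np.ndarray:
    w = rng.standard_normal((n_samples, n_ch))
    f = spsig.sosfiltfilt(sos, w, axis=0)
    f = f - f.mean(axis=0)
    sd = f.std(axis=0)
    return f / np.where(sd > 0, sd, 1.0)


def _pink_noise(rng, n_samples: int, n_ch: int) -> np.ndarray:
    white = rng.standard_normal((n_samples, n_ch))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    out = np.fft.irfft(spec * scale[:, None], n=n_samples, axis=0)
    sd = out.std(axis=0)
    return out / np.where(sd > 0, sd, 1.0)


def _physio(rng, t: np.ndarray, n_ch: int, noise: NoiseSpec) -> np.ndarray:
    out = np.zeros((t.size, n_ch))
    for amp, f in (
        (noise.cardiac, noise.cardiac_hz),
        (noise.respiratory, noise.respiratory_hz),
        (noise.mayer, noise.mayer_hz),
    ):
        if amp <= 0:
            continue
        phase = rng.uniform(0, 2 * np.pi, size=n_ch)
        f_jit = f * rng.uniform(0.95, 1.05)
        gain = rng.uniform(0.7, 1.3, size=n_ch)
        out += amp * gain * np.sin(2 * np.pi * f_jit * t[:, None] + phase)
    return out


def simulate_subject_series(
    subject: Subject,
    montage: pd.DataFrame,
    config: CohortConfig,
    truth: GroundTruth,
) -> HemoglobinSeries:
    """Generate one subject's HbO/HbR channel × time recording."""
    idx = truth.subject_index[subject.subject_id]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, idx]))
    n_ch = len(montage)
    T = config.n_samples
    t = np.arange(T) / config.sampling_rate

    cov = truth.covariances[idx]
    L = np.linalg.cholesky(cov + 1e-9 * np.eye(n_ch))
    sos = _lowpass_sos(config)
    latent_hbo = _band_limited_factors(rng, T, n_ch, sos) @ L.T
    latent_ind = _band_limited_factors(rng, T, n_ch, sos) @ L.T
    rho = config.hbo_hbr_ratio
    latent_hbr = rho * latent_hbo + np.sqrt(max(0.0, 1.0 - rho**2)) * latent_ind

    noise = config.noise
    hbo = latent_hbo.copy()
    hbr = config.hbr_amplitude * latent_hbr
    for target, scale in ((hbo, 1.0), (hbr, config.hbr_amplitude)):
        if noise.pink > 0:
            target += scale * noise.pink * _pink_noise(rng, T, n_ch)
        target += scale * _physio(rng, t, n_ch, noise)
        if noise.white > 0:
            target += scale * noise.white * rng.standard_normal((T, n_ch))

    return HemoglobinSeries(
        hbo=hbo.T, hbr=hbr.T, sampling_rate=config.sampling_rate
    )


def inject_artifacts(
    series: HemoglobinSeries,
    rate: float,
    truth: GroundTruth,
    config: CohortConfig,
    subject: Subject,
) -> HemoglobinSeries:
    """Add logged motion spikes and baseline shifts to a recording.

    Events hit all channels at once (head motion moves the whole array) and
    are appended to ``truth.artifact_log`` with channel 0.
    """
    if rate < 0:
        raise ValueError("artifact rate must be non-negative")
    out = series.copy()
    if rate == 0:
        return out
    idx = truth.subject_index[subject.subject_id]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3, idx]))
    fs = series.sampling_rate
    T = series.n_samples
    minutes = T / fs / 60.0
    n_events = rng.poisson(rate * minutes)
    sd_hbo = np.std(out.hbo, axis=1)
    sd_hbr = np.std(out.hbr, axis=1)
    for _ in range(n_events):
        kind = "spike" if rng.random() < 0.6 else "shift"
        if kind == "spike":
            dur = rng.uniform(0.2, 0.8)
            onset = rng.uniform(0, T / fs - dur)
            i0 = int(onset * fs)
            width = max(2, int(round(dur * fs)))
            # half-sine sampled at bin midpoints so even 2-sample spikes
            # carry their full amplitude
            bump = np.sin(np.pi * (np.arange(width) + 0.5) / width)
            sign = rng.choice([-1.0, 1.0])
            gain = rng.uniform(0.8, 1.2, size=series.n_channels)
            amp = config.spike_amplitude_sd * sign * gain
            out.hbo[:, i0 : i0 + width] += (amp * sd_hbo)[:, None] * bump
            out.hbr[:, i0 : i0 + width] += (amp * sd_hbr)[:, None] * bump
            truth.artifact_log.append(ArtifactEvent(0, onset, dur, "spike"))
        else:
            onset = rng.uniform(1.0, T / fs - 1.0)
            i0 = int(onset * fs)
            sign = rng.choice([-1.0, 1.0])
            gain = rng.uniform(0.8, 1.2, size=series.n_channels)
            amp = config.shift_amplitude_sd * sign * gain
            out.hbo[:, i0:] += (amp * sd_hbo)[:, None]
            out.hbr[:, i0:] += (amp * sd_hbr)[:, None]
            truth.artifact_log.append(
                ArtifactEvent(0, onset, T / fs - onset, "shift")
            )
    return out


def simulate_recording(
    subject: Subject,
    montage: pd.DataFrame,
    config: CohortConfig,
    truth: GroundTruth,
) -> HemoglobinSeries:
    """Convenience: clean series plus configured motion artifacts."""
    series = simulate_subject_series(subject, montage, config, truth)
    return inject_artifacts(series, config.artifact_rate, truth, config, subject)
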