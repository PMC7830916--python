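"""Signal cleaning for resting-state fNIRS recordings.

The chain runs in a fixed order:

    trim edges → detect motion → spline correction → wavelet filtering
    → band-pass (0.009–0.08 Hz) → polynomial detrend (order 3)
    → first-sample baseline correction

Motion detection works on 1-second sliding windows: a window is flagged
when the signal excursion (max − min) exceeds an amplitude threshold, or
when the moving standard deviation exceeds a multiple (default 15×) of the
channel's median moving SD. On optical-density input the amplitude
threshold is an absolute OD value (default 0.1); on hemoglobin input —
where absolute units depend on the conversion constants — it is expressed
in multiples of the channel's median windowed excursion, a scale estimate
that stays valid in the presence of baseline step artifacts.

Spline correction fits a smoothing spline inside each flagged segment,
subtracts it, and re-anchors the segment so its endpoints join the
surrounding signal continuously; unflagged samples are untouched. Wavelet
filtering removes detail coefficients that fall outside the central
(1 − α) probability mass of a robust Gaussian fit per decomposition level,
which suppresses the sharp transients splines leave behind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy import ndimage, signal as spsig
from scipy import stats as sps
from scipy.interpolate import make_smoothing_spline

from .series import (
    ArtifactMask,
    HemoglobinSeries,
    OpticalDensitySeries,
    RawIntensitySeries,
)

#: Hemoglobin extinction coefficients, 1/(mM·cm), tabulated approximations
#: at the instrument wavelengths: {wavelength_nm: (HbO, HbR)}.
EXTINCTION_MM_CM = {
    780.0: (0.740, 1.100),
    805.0: (0.880, 0.830),
    830.0: (0.974, 0.693),
}

#: Differential pathlength factors per wavelength (dimensionless defaults).
DEFAULT_DPF = (6.0, 6.0, 6.0)


@dataclass(frozen=True)
class PreprocessConfig:
    trim_s: float = 30.0
    window_s: float = 1.0
    amp_thresh: float = 0.1  # OD units (intensity/OD input)
    amp_thresh_sd: float = 4.0  # robust-SD units (hemoglobin input)
    std_thresh: float = 15.0  # multiple of median moving SD
    spline_p: float = 0.99
    wavelet: str = "db3"
    wavelet_alpha: float = 0.1
    band_low_hz: float = 0.009
    band_high_hz: float = 0.08
    detrend_order: int = 3
    run_spline: bool = True
    run_wavelet: bool = True


# ---------------------------------------------------------------------------
# Optical conversion


def intensity_to_od(raw: RawIntensitySeries) -> OpticalDensitySeries:
    """OD(t) = −log10(I(t) / I_ref), I_ref = per-channel temporal mean."""
    if not np.all(raw.data > 0):
        raise ValueError("raw intensities must be strictly positive")
    ref = raw.data.mean(axis=1, keepdims=True)
    od = -np.log10(raw.data / ref)
    return OpticalDensitySeries(
        data=od, sampling_rate=raw.sampling_rate, wavelengths_nm=raw.wavelengths_nm
    )


def od_to_hemoglobin(
    od: OpticalDensitySeries,
    dpf: tuple[float, ...] = DEFAULT_DPF,
    pathlength_cm: float = 3.0,
    extinction: dict[float, tuple[float, float]] | None = None,
) -> HemoglobinSeries:
    """Modified Beer–Lambert inversion, least squares over 3 wavelengths.

    Solves ΔOD_λ = (ε_HbO,λ ΔHbO + ε_HbR,λ ΔHbR) · d · DPF_λ per sample;
    concentrations come out in mM·(units of ε·cm); with the default
    1/(mM·cm) table and a cm pathlength the output scale is mM, reported
    as-is (relative concentration change).
    """
    table = extinction or EXTINCTION_MM_CM
    try:
        eps = np.array([table[w] for w in od.wavelengths_nm])  # (3, 2)
    except KeyError as exc:
        raise ValueError(f"no extinction coefficients for wavelength {exc}") from None
    A = eps * pathlength_cm * np.asarray(dpf)[:, None]
    if np.linalg.matrix_rank(A) < 2:
        raise np.linalg.LinAlgError("degenerate extinction design")
    pinv = np.linalg.pinv(A)  # (2, 3)
    conc = od.data @ pinv.T  # (n_ch, T, 2)
    return HemoglobinSeries(
        hbo=conc[..., 0], hbr=conc[..., 1], sampling_rate=od.sampling_rate
    )


# ---------------------------------------------------------------------------
# Array-level operators (channel × time)


def _trim_array(data: np.ndarray, fs: float, seconds: float) -> np.ndarray:
    k = int(round(seconds * fs))
    if k == 0:
        return data.copy()
    if data.shape[-2 if data.ndim == 3 else -1] <= 2 * k:
        raise ValueError("recording shorter than twice the trim length")
    if data.ndim == 3:
        return data[:, k:-k, :].copy()
    return data[:, k:-k].copy()


def trim_edges(series, seconds: float = 30.0):
    """Drop round(seconds × fs) samples from both ends of the recording."""
    if seconds < 0:
        raise ValueError("trim length must be non-negative")
    if isinstance(series, HemoglobinSeries):
        return replace(
            series,
            hbo=_trim_array(series.hbo, series.sampling_rate, seconds),
            hbr=_trim_array(series.hbr, series.sampling_rate, seconds),
            t0=series.t0 + seconds,
        )
    if isinstance(series, OpticalDensitySeries):
        return replace(
            series, data=_trim_array(series.data, series.sampling_rate, seconds)
        )
    raise TypeError("trim_edges expects a hemoglobin or optical-density series")


def detect_motion_array(
    data: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    amp_thresh: float = 0.1,
    std_thresh: float = 15.0,
    amp_in_sd_units: bool = False,
) -> ArtifactMask:
    """Flag windows with excessive excursion or moving-SD, per channel."""
    w = max(2, int(round(window_s * fs)))
    if data.shape[1] < w:
        raise ValueError("recording shorter than the detection window")
    mx = ndimage.maximum_filter1d(data, size=w, axis=1, mode="nearest")
    mn = ndimage.minimum_filter1d(data, size=w, axis=1, mode="nearest")
    excursion = mx - mn
    mean = ndimage.uniform_filter1d(data, size=w, axis=1, mode="nearest")
    mean_sq = ndimage.uniform_filter1d(data**2, size=w, axis=1, mode="nearest")
    msd = np.sqrt(np.clip(mean_sq - mean**2, 0.0, None))
    med_msd = np.median(msd, axis=1, keepdims=True)
    med_msd = np.where(med_msd > 0, med_msd, np.inf)

    if amp_in_sd_units:
        # scale reference robust to baseline shifts and to the artifacts
        # themselves: the channel's median windowed excursion
        med_exc = np.median(excursion, axis=1, keepdims=True)
        med_exc = np.where(med_exc > 0, med_exc, 1.0)
        amp_limit = amp_thresh * med_exc
    else:
        amp_limit = amp_thresh
    viol = (excursion > amp_limit) | (msd > std_thresh * med_msd)
    # flag the full extent of every violating window
    mask = ndimage.binary_dilation(viol, structure=np.ones((1, w), dtype=bool))
    return ArtifactMask(mask)


def detect_motion(
    series,
    window_s: float = 1.0,
    amp_thresh: float = 0.1,
    std_thresh: float = 15.0,
    *,
    amp_thresh_sd: float = 4.0,
) -> ArtifactMask:
    """Motion detection on OD (absolute threshold) or hemoglobin (SD units).

    For hemoglobin input the mask is the union over HbO and HbR, since head
    motion contaminates both chromophores.
    """
    if isinstance(series, OpticalDensitySeries):
        masks = [
            detect_motion_array(
                series.data[:, :, k], series.sampling_rate, window_s,
                amp_thresh, std_thresh,
            ).mask
            for k in range(series.data.shape[2])
        ]
        return ArtifactMask(np.logical_or.reduce(masks))
    if isinstance(series, HemoglobinSeries):
        m1 = detect_motion_array(
            series.hbo, series.sampling_rate, window_s,
            amp_thresh_sd, std_thresh, amp_in_sd_units=True,
        )
        m2 = detect_motion_array(
            series.hbr, series.sampling_rate, window_s,
            amp_thresh_sd, std_thresh, amp_in_sd_units=True,
        )
        return m1.union(m2)
    raise TypeError("detect_motion expects a hemoglobin or optical-density series")


def _segments(flags: np.ndarray):
    """Yield (start, stop) index pairs of contiguous True runs."""
    padded = np.diff(np.concatenate([[0], flags.astype(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return zip(starts, stops)


def spline_correct_array(
    data: np.ndarray, mask: np.ndarray, fs: float, smoothing_p: float = 0.99
) -> np.ndarray:
    """Smoothing-spline motion correction inside masked segments.

    Within each flagged run the fitted spline is subtracted (removing the
    artifact's trajectory) and the residual is re-anchored on a straight
    line between the neighboring unmasked samples, so segment endpoints
    join the surrounding signal exactly.
    """
    if mask.shape != data.shape:
        raise ValueError("mask and data shapes differ")
    out = data.copy()
    lam = (1.0 - smoothing_p) / smoothing_p
    n = data.shape[1]
    for ch in range(data.shape[0]):
        flags = mask[ch]
        if flags.all():
            raise ValueError(f"channel {ch}: mask covers the entire recording")
        for a, b in _segments(flags):
            seg = data[ch, a:b]
            t = np.arange(a, b, dtype=float)
            if len(seg) >= 4:
                spl = make_smoothing_spline(t, seg, lam=lam)
                resid = seg - spl(t)
            else:
                resid = np.zeros_like(seg)
            # force residual endpoints to zero, then ramp between neighbors
            if len(resid) > 1:
                ramp = np.linspace(resid[0], resid[-1], len(resid))
            else:
                ramp = resid
            resid = resid - ramp
            left = data[ch, a - 1] if a > 0 else None
            right = data[ch, b] if b < n else None
            if left is None and right is None:  # pragma: no cover - guarded above
                continue
            if left is None:
                left = right
            if right is None:
                right = left
            anchor = np.linspace(left, right, len(seg) + 2)[1:-1]
            out[ch, a:b] = resid + anchor
    return out


def spline_correct(
    series: HemoglobinSeries, mask: ArtifactMask, smoothing_p: float = 0.99
) -> HemoglobinSeries:
    return replace(
        series,
        hbo=spline_correct_array(series.hbo, mask.mask, series.sampling_rate, smoothing_p),
        hbr=spline_correct_array(series.hbr, mask.mask, series.sampling_rate, smoothing_p),
    )


def wavelet_filter_array(
    data: np.ndarray,
    fs: float,
    alpha: float = 0.1,
    wavelet: str = "db3",
    protect_below_hz: float = 0.08,
) -> np.ndarray:
    """Zero outlying detail coefficients per decomposition level.

    A Gaussian is fit robustly (median / MAD) to each level's detail
    coefficients; coefficients outside the central (1 − alpha) probability
    mass are set to zero. The decomposition depth is chosen so that the
    approximation band still contains the hemodynamic band of interest
    (``protect_below_hz``): only out-of-band detail levels are thresholded,
    which removes broadband transients without eroding the slow signal.
    ``alpha <= 0`` keeps every coefficient (identity up to reconstruction
    error).
    """
    if alpha <= 0:
        return data.copy()
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    # deepest level whose approximation band [0, fs / 2^(L+1)] covers the
    # protected band
    depth = max(1, int(np.floor(np.log2(fs / protect_below_hz))) - 1)
    out = np.empty_like(data)
    n = data.shape[1]
    for ch in range(data.shape[0]):
        max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
        coeffs = pywt.wavedec(data[ch], wavelet, mode="symmetric",
                              level=min(depth, max_level))
        for level in range(1, len(coeffs)):
            d = coeffs[level]
            mu = np.median(d)
            sigma = 1.4826 * np.median(np.abs(d - mu))
            if sigma == 0:
                continue
            d[np.abs(d - mu) > z * sigma] = 0.0
        rec = pywt.waverec(coeffs, wavelet, mode="symmetric")
        out[ch] = rec[:n]
    return out


def wavelet_filter(
    series: HemoglobinSeries, alpha: float = 0.1, wavelet: str = "db3"
) -> HemoglobinSeries:
    return replace(
        series,
        hbo=wavelet_filter_array(series.hbo, series.sampling_rate, alpha, wavelet),
        hbr=wavelet_filter_array(series.hbr, series.sampling_rate, alpha, wavelet),
    )


def bandpass_array(
    data: np.ndarray, fs: float, low: float = 0.009, high: float = 0.08
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (order 3, forward-backward)."""
    if not (0 < low < high < fs / 2):
        raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
    sos = spsig.butter(3, [low, high], btype="bandpass", fs=fs, output="sos")
    return spsig.sosfiltfilt(sos, data, axis=1)


def bandpass(
    series: HemoglobinSeries, low: float = 0.009, high: float = 0.08
) -> HemoglobinSeries:
    return replace(
        series,
        hbo=bandpass_array(series.hbo, series.sampling_rate, low, high),
        hbr=bandpass_array(series.hbr, series.sampling_rate, low, high),
    )


def detrend_poly_array(data: np.ndarray, order: int = 3) -> np.ndarray:
    """Subtract a least-squares polynomial of the given order per channel."""
    n = data.shape[1]
    if n <= order + 1:
        raise ValueError("series too short for the requested polynomial order")
    t = np.linspace(-1.0, 1.0, n)
    V = np.polynomial.polynomial.polyvander(t, order)
    coef, *_ = np.linalg.lstsq(V, data.T, rcond=None)
    return data - (V @ coef).T


def detrend_poly(series: HemoglobinSeries, order: int = 3) -> HemoglobinSeries:
    return replace(
        series,
        hbo=detrend_poly_array(series.hbo, order),
        hbr=detrend_poly_array(series.hbr, order),
    )


def baseline_correct(series: HemoglobinSeries) -> HemoglobinSeries:
    """Subtract each channel's first sample."""
    if series.n_samples == 0:
        raise ValueError("empty series")
    return replace(
        series,
        hbo=series.hbo - series.hbo[:, :1],
        hbr=series.hbr - series.hbr[:, :1],
    )


def artifact_fraction(mask: ArtifactMask) -> float:
    """Masked percentage averaged over channels, in [0, 100]."""
    return float(mask.channel_fraction_percent.mean())


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class PreprocessResult:
    series: HemoglobinSeries
    mask: ArtifactMask
    artifact_percent: float


def clean_series(
    series: HemoglobinSeries, config: PreprocessConfig | None = None
) -> PreprocessResult:
    """Run the full cleaning chain on a hemoglobin recording."""
    cfg = config or PreprocessConfig()
    out = trim_edges(series, cfg.trim_s)
    mask = detect_motion(
        out, cfg.window_s, cfg.amp_thresh, cfg.std_thresh,
        amp_thresh_sd=cfg.amp_thresh_sd,
    )
    if cfg.run_spline and mask.mask.any():
        out = spline_correct(out, mask, cfg.spline_p)
    if cfg.run_wavelet:
        out = wavelet_filter(out, cfg.wavelet_alpha, cfg.wavelet)
    out = bandpass(out, cfg.band_low_hz, cfg.band_high_hz)
    out = detrend_poly(out, cfg.detrend_order)
    out = baseline_correct(out)
    if not (np.all(np.isfinite(out.hbo)) and np.all(np.isfinite(out.hbr))):
        raise RuntimeError("non-finite values after preprocessing")
    return PreprocessResult(
        series=out, mask=mask, artifact_percent=artifact_fraction(mask)
    )


def clean_intensity(
    raw: RawIntensitySeries, config: PreprocessConfig | None = None,
    dpf: tuple[float, ...] = DEFAULT_DPF, pathlength_cm: float = 3.0,
) -> PreprocessResult:
    """Full chain from raw light intensity: OD → motion mask on OD → MBLL
    conversion → spline/wavelet/band-pass/detrend/baseline on hemoglobin."""
    cfg = config or PreprocessConfig()
    od = intensity_to_od(raw)
    od = trim_edges(od, cfg.trim_s)
    mask = detect_motion(od, cfg.window_s, cfg.amp_thresh, cfg.std_thresh)
    hemo = od_to_hemoglobin(od, dpf=dpf, pathlength_cm=pathlength_cm)
    out = hemo
    if cfg.run_spline and mask.mask.any():
        out = spline_correct(out, mask, cfg.spline_p)
    if cfg.run_wavelet:
        out = wavelet_filter(out, cfg.wavelet_alpha, cfg.wavelet)
    out = bandpass(out, cfg.band_low_hz, cfg.band_high_hz)
    out = detrend_poly(out, cfg.detrend_order)
    out = baseline_correct(out)
    return PreprocessResult(
        series=out, mask=mask, artifact_percent=artifact_fraction(mask)
    )
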