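"""Predefined acoustic features (PAFs) of a cry and their condition contrasts.

Each cry is summarized by 22 scalar descriptors: seven moments of the amplitude
envelope, eight moments/quantiles of the power spectrum, five statistics of the
time-varying fundamental (including mean pitch saliency), and the average
frequencies of the first two formants.  Pitch and saliency come from a running
short-window autocorrelation: the fundamental is the reciprocal of the lag of
the strongest autocorrelation peak inside the search band, and saliency is that
peak's amplitude relative to lag zero (a tonality measure in [0, 1]).

Scale behaviour: env_mean, env_sd, env_rms and env_max scale linearly with the
waveform amplitude; all other features (envelope shape statistics, spectral
statistics, pitch, saliency, formants) are amplitude-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .synth import CryRecording

__all__ = [
    "FeatureError",
    "PitchTrack",
    "PAFVector",
    "FormantEstimate",
    "FeatureContrastResult",
    "PAF_NAMES",
    "SPECTRAL_SUBSET",
    "amplitude_envelope",
    "summarize_envelope",
    "power_spectrum_summary",
    "track_pitch",
    "estimate_formants",
    "paf_vector",
    "feature_table",
    "feature_condition_contrast",
]


class FeatureError(ValueError):
    """A feature extractor received degenerate input."""


PAF_NAMES = (
    "env_mean", "env_sd", "env_skew", "env_kurtosis", "env_entropy", "env_rms", "env_max",
    "spec_mean", "spec_sd", "spec_skew", "spec_kurtosis", "spec_entropy", "Q1", "Q2", "Q3",
    "meanF0", "MaxF0", "MinF0", "cvF0", "mean_saliency", "F1", "F2",
)

SPECTRAL_SUBSET = (
    "Q1", "Q2", "Q3", "meanF0", "MaxF0", "MinF0", "cvF0", "mean_saliency", "F1", "F2",
)


def _normalized_entropy(weights: np.ndarray) -> float:
    """Shannon entropy of a non-negative weight vector treated as a distribution,
    normalized by log(len) so the result lies in [0, 1]."""
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0 or len(w) < 2:
        raise FeatureError("entropy requires a non-degenerate weight vector")
    p = w / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(len(p)))


# ---------------------------------------------------------------------------
# amplitude envelope

def amplitude_envelope(
    recording: CryRecording, env_sample_rate: int = 1000, cutoff_hz: float = 20.0
) -> tuple[np.ndarray, int]:
    """Smooth amplitude envelope: full-wave rectification + low-pass filtering,
    resampled to ``env_sample_rate`` Hz.  Returns (envelope, envelope rate)."""
    x = np.abs(np.asarray(recording.waveform, dtype=float))
    sos = signal.butter(4, cutoff_hz, btype="low", fs=recording.sample_rate, output="sos")
    env = signal.sosfiltfilt(sos, x)
    env = np.clip(env, 0, None)
    up, down = env_sample_rate, recording.sample_rate
    g = np.gcd(up, down)
    env = signal.resample_poly(env, up // g, down // g)
    return np.clip(env, 0, None), env_sample_rate


def summarize_envelope(envelope: np.ndarray) -> dict[str, float]:
    """The seven envelope statistics: mean, sd, skew, kurtosis, entropy, rms, max.

    Entropy is the Shannon entropy of the time-normalized envelope distribution,
    divided by log(N); a constant envelope therefore scores 1 and an envelope
    concentrated on a single instant scores near 0.
    """
    env = np.asarray(envelope, dtype=float)
    if len(env) < 2:
        raise FeatureError("envelope must have at least 2 samples")
    if np.all(env == 0):
        raise FeatureError("cannot summarize an all-zero envelope")
    return {
        "env_mean": float(env.mean()),
        "env_sd": float(env.std(ddof=0)),
        "env_skew": float(stats.skew(env)),
        "env_kurtosis": float(stats.kurtosis(env)),
        "env_entropy": _normalized_entropy(env),
        "env_rms": float(np.sqrt(np.mean(env**2))),
        "env_max": float(env.max()),
    }


# ---------------------------------------------------------------------------
# power spectrum

def power_spectrum_summary(recording: CryRecording) -> dict[str, float]:
    """Moments, entropy and energy quartiles of the power spectral density
    treated as a probability distribution over frequency (Hz)."""
    x = np.asarray(recording.waveform, dtype=float)
    if len(x) < int(0.1 * recording.sample_rate):
        raise FeatureError("recording shorter than 0.1 s")
    if np.all(x == 0):
        raise FeatureError("silent recording has no power spectrum")
    freqs, psd = signal.periodogram(x, fs=recording.sample_rate, window="hann")
    total = psd.sum()
    p = psd / total
    mean = float((freqs * p).sum())
    var = float(((freqs - mean) ** 2 * p).sum())
    sd = np.sqrt(var)
    if sd > 0:
        skew = float((((freqs - mean) / sd) ** 3 * p).sum())
        kurt = float((((freqs - mean) / sd) ** 4 * p).sum() - 3.0)
    else:
        skew, kurt = 0.0, 0.0
    cdf = np.cumsum(p)
    quartiles = np.interp([0.25, 0.5, 0.75], cdf, freqs)
    return {
        "spec_mean": mean,
        "spec_sd": float(sd),
        "spec_skew": skew,
        "spec_kurtosis": kurt,
        "spec_entropy": _normalized_entropy(psd),
        "Q1": float(quartiles[0]),
        "Q2": float(quartiles[1]),
        "Q3": float(quartiles[2]),
    }


# ---------------------------------------------------------------------------
# pitch and saliency

@dataclass
class PitchTrack:
    """Framewise fundamental and pitch saliency.

    ``f0`` is NaN on unvoiced frames (saliency below the voicing threshold) and
    on frames too quiet to analyze; ``saliency`` is NaN only on quiet frames.
    """

    frame_times: np.ndarray
    f0: np.ndarray
    saliency: np.ndarray
    frame_length: float

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.f0)


def track_pitch(
    recording: CryRecording,
    f0_min: float = 150.0,
    f0_max: float = 1200.0,
    frame_s: float = 0.033,
    hop_s: float = 0.010,
    voicing_threshold: float = 0.5,
    silence_rel_rms: float = 0.05,
) -> PitchTrack:
    """Autocorrelation pitch tracking in 33 ms running windows.

    Per frame the normalized autocorrelation (with the N/(N-lag) bias
    correction) is searched for peaks at lags inside [1/f0_max, 1/f0_min]; the
    strongest peak gives the fundamental (with parabolic lag interpolation) and
    its height relative to lag zero gives the saliency, clipped to [0, 1].
    """
    sr = recording.sample_rate
    if not 0 < f0_min < f0_max:
        raise FeatureError("need 0 < f0_min < f0_max")
    if f0_max >= sr / 2:
        raise FeatureError("f0_max must be below the Nyquist frequency")
    x = np.asarray(recording.waveform, dtype=float)
    n_frame = int(round(frame_s * sr))
    hop = max(1, int(round(hop_s * sr)))
    lag_min = max(2, int(np.floor(sr / f0_max)))
    lag_max = int(np.ceil(sr / f0_min))
    if lag_max >= n_frame - 1:
        raise FeatureError("frame too short for the requested f0_min")

    starts = np.arange(0, max(1, len(x) - n_frame + 1), hop)
    frames = np.stack([x[s : s + n_frame] for s in starts])
    frames = frames - frames.mean(axis=1, keepdims=True)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    quiet = rms < silence_rel_rms * (rms.max() if rms.max() > 0 else 1.0)

    nfft = int(2 ** np.ceil(np.log2(2 * n_frame)))
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, axis=1)[:, : lag_max + 2]
    r0 = ac[:, 0].copy()
    r0[r0 == 0] = 1.0
    lags = np.arange(lag_max + 2)
    unbias = n_frame / np.maximum(n_frame - lags, 1)
    acn = ac / r0[:, None] * unbias[None, :]

    f0 = np.full(len(frames), np.nan)
    sal = np.full(len(frames), np.nan)
    for i in range(len(frames)):
        if quiet[i]:
            continue
        r = acn[i]
        seg = r[lag_min : lag_max + 1]
        # local maxima within the band
        idx = np.where((seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:]))[0] + 1
        if len(idx) == 0:
            best = int(np.argmax(seg))
        else:
            # the first peak: earliest local maximum comparable to the
            # strongest one (avoids octave-down errors at multiples of the lag)
            tall = idx[seg[idx] >= 0.9 * seg[idx].max()]
            best = int(tall[0])
        lag = lag_min + best
        # parabolic interpolation around the peak
        if 1 <= lag < len(r) - 1:
            y0, y1, y2 = r[lag - 1], r[lag], r[lag + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            peak_val = y1 - 0.25 * (y0 - y2) * delta
            lag_f = lag + delta
        else:
            peak_val, lag_f = r[lag], float(lag)
        s = float(np.clip(peak_val, 0.0, 1.0))
        sal[i] = s
        if s >= voicing_threshold:
            f0[i] = sr / lag_f
    times = (starts + n_frame / 2) / sr
    return PitchTrack(frame_times=times, f0=f0, saliency=sal, frame_length=frame_s)


def _f0_summary(track: PitchTrack) -> dict[str, float]:
    voiced_f0 = track.f0[track.voiced]
    if len(voiced_f0) == 0:
        raise FeatureError("no voiced frames: cannot summarize the fundamental")
    sal = track.saliency[~np.isnan(track.saliency)]
    mean_f0 = float(voiced_f0.mean())
    return {
        "meanF0": mean_f0,
        "MaxF0": float(voiced_f0.max()),
        "MinF0": float(voiced_f0.min()),
        "cvF0": float(voiced_f0.std(ddof=0) / mean_f0),
        "mean_saliency": float(sal.mean()),
    }


# ---------------------------------------------------------------------------
# formants

@dataclass(frozen=True)
class FormantEstimate:
    F1: float
    F2: float
    confident: bool


def estimate_formants(
    recording: CryRecording,
    track: PitchTrack | None = None,
    lpc_order: int = 10,
    max_bandwidth_hz: float = 500.0,
    band_hz: tuple[float, float] = (750.0, 4500.0),
) -> FormantEstimate:
    """Average frequencies of the two lowest vocal-tract resonances.

    Linear-prediction analysis (autocorrelation method) after resampling to
    10 kHz and pre-emphasis; LPC roots with bandwidth below
    ``max_bandwidth_hz`` inside ``band_hz`` are taken as resonance candidates.
    Infant formant estimation is fragile; when fewer than two stable candidates
    emerge the estimate is returned with ``confident=False`` and frequencies
    from the relaxed candidate set, or an error is raised if none exist.
    """
    target_sr = 10000
    x = np.asarray(recording.waveform, dtype=float)
    if track is None:
        track = track_pitch(recording)
    if not np.any(track.voiced):
        raise FeatureError("no voiced frames: cannot estimate formants")
    g = np.gcd(target_sr, recording.sample_rate)
    y = signal.resample_poly(x, target_sr // g, recording.sample_rate // g)
    y = np.append(y[0], y[1:] - 0.97 * y[:-1])  # pre-emphasis
    # keep only energetic samples (the expiratory bursts)
    env = np.abs(y)
    k = int(0.02 * target_sr)
    smooth = signal.fftconvolve(env, np.ones(k) / k, mode="same")
    mask = smooth > 0.1 * smooth.max()
    y = y[mask] if mask.sum() > target_sr // 10 else y
    y = y * np.hamming(len(y))

    r = np.correlate(y, y, mode="full")[len(y) - 1 : len(y) + lpc_order]
    if r[0] <= 0:
        raise FeatureError("degenerate signal for LPC analysis")
    from scipy.linalg import solve_toeplitz

    a = solve_toeplitz((r[:-1], r[:-1]), r[1:])
    poly = np.concatenate([[1.0], -a])
    roots = np.roots(poly)
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * target_sr / (2 * np.pi)
    bws = -np.log(np.abs(roots)) * target_sr / np.pi

    lo, hi = band_hz
    strict = np.sort(freqs[(bws < max_bandwidth_hz) & (freqs > lo) & (freqs < hi)])
    if len(strict) >= 2:
        return FormantEstimate(float(strict[0]), float(strict[1]), True)
    relaxed = np.sort(freqs[(freqs > lo) & (freqs < hi)])
    if len(relaxed) >= 2:
        return FormantEstimate(float(relaxed[0]), float(relaxed[1]), False)
    raise FeatureError("no resonance structure found (e.g. pure tone input)")


# ---------------------------------------------------------------------------
# the 22-feature vector

@dataclass(frozen=True)
class PAFVector:
    """The 22 predefined acoustic features of one cry."""

    env_mean: float
    env_sd: float
    env_skew: float
    env_kurtosis: float
    env_entropy: float
    env_rms: float
    env_max: float
    spec_mean: float
    spec_sd: float
    spec_skew: float
    spec_kurtosis: float
    spec_entropy: float
    Q1: float
    Q2: float
    Q3: float
    meanF0: float
    MaxF0: float
    MinF0: float
    cvF0: float
    mean_saliency: float
    F1: float
    F2: float
    formants_confident: bool = True

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PAF_NAMES}

    def spectral_subset(self) -> dict[str, float]:
        """The 10-feature spectral/pitch subset."""
        return {name: getattr(self, name) for name in SPECTRAL_SUBSET}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PAF_NAMES])


def paf_vector(recording: CryRecording, **pitch_kwargs) -> PAFVector:
    """Extract the complete 22-feature vector from one cry."""
    try:
        env, _ = amplitude_envelope(recording)
        env_stats = summarize_envelope(env)
    except FeatureError as e:
        raise FeatureError(f"envelope features failed: {e}") from e
    try:
        spec_stats = power_spectrum_summary(recording)
    except FeatureError as e:
        raise FeatureError(f"spectral features failed: {e}") from e
    try:
        track = track_pitch(recording, **pitch_kwargs)
        f0_stats = _f0_summary(track)
    except FeatureError as e:
        raise FeatureError(f"fundamental features failed: {e}") from e
    try:
        form = estimate_formants(recording, track)
    except FeatureError as e:
        raise FeatureError(f"formant features failed: {e}") from e
    return PAFVector(
        **env_stats,
        **spec_stats,
        **f0_stats,
        F1=form.F1,
        F2=form.F2,
        formants_confident=form.confident,
    )


def feature_table(recordings, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per cry: metadata labels plus the 22 PAF columns."""
    rows = []
    for rec in recordings:
        paf = paf_vector(rec)
        row = {
            "baby_id": rec.baby_id,
            "sex": rec.sex,
            "condition": rec.condition,
            "sequence_id": rec.sequence_id,
        }
        row.update(paf.to_dict())
        rows.append(row)
    table = pd.DataFrame(rows)
    if metadata is not None and "duration_s" in metadata.columns:
        table = table.merge(
            metadata[["sequence_id", "duration_s"]], on="sequence_id", how="left"
        )
    return table


# ---------------------------------------------------------------------------
# condition contrast

@dataclass
class FeatureContrastResult:
    """Mixed-effects linear contrast of one feature across sex x condition,
    with a per-baby random intercept, tested with Wald z statistics."""

    feature_name: str
    coefficients: dict[str, float]
    wald_z: dict[str, float]
    p_values: dict[str, float]
    random_intercept_var: float
    condition_effect: float
    condition_effect_2se: float


def feature_condition_contrast(
    table: pd.DataFrame, feature_name: str
) -> FeatureContrastResult:
    """Fit ``feature ~ sex * condition`` with a per-baby random intercept (REML)
    and report Wald z tests on the fixed coefficients."""
    import statsmodels.formula.api as smf

    if feature_name not in table.columns:
        raise FeatureError(f"unknown feature {feature_name!r}")
    conditions = set(table["condition"].unique())
    if len(conditions) < 2:
        raise FeatureError("contrast requires both conditions to be present")
    both = table.groupby("baby_id")["condition"].nunique()
    if (both >= 2).sum() < 2:
        raise FeatureError("need at least 2 babies recorded in both conditions")

    df = table[["baby_id", "sex", "condition", feature_name]].rename(
        columns={feature_name: "value"}
    )
    model = smf.mixedlm("value ~ C(sex) * C(condition)", df, groups=df["baby_id"])
    fit = model.fit(reml=True)
    coefs, zs, ps = {}, {}, {}
    for name in fit.fe_params.index:
        coefs[name] = float(fit.fe_params[name])
        zs[name] = float(fit.fe_params[name] / fit.bse[name])
        ps[name] = float(fit.pvalues[name])
    cond_term = next(n for n in coefs if "condition" in n and ":" not in n)
    return FeatureContrastResult(
        feature_name=feature_name,
        coefficients=coefs,
        wald_z=zs,
        p_values=ps,
        random_intercept_var=float(fit.cov_re.iloc[0, 0]),
        condition_effect=coefs[cond_term],
        condition_effect_2se=2 * float(fit.bse[cond_term]),
    )
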