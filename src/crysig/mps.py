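"""Modulation power spectrum (MPS) of cry sequences.

The MPS is the amplitude of the 2D Fourier transform of the log spectrogram,
averaged over 1 s Gaussian-weighted windows.  Its axes are temporal modulation
(Hz, signed) and spectral modulation (cycles/kHz, non-negative).  A harmonic
sound with fundamental f0 concentrates spectral-modulation energy near
1/f0 cyc/kHz (e.g. ~3 cyc/kHz for a 330 Hz pitch), so pitch structure, pitch
stability and amplitude modulation are all directly legible in the map.

Because the log spectrogram is normalized to a 0 dB maximum and floored at
-50 dB before the transform, the MPS is exactly invariant to the overall level
of the recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .synth import CryRecording

__all__ = [
    "MPSError",
    "Spectrogram",
    "MPS",
    "MPSDiff",
    "narrowband_spectrogram",
    "compute_mps",
    "mps_from_recording",
    "average_mps",
    "mps_difference",
    "to_db",
    "spectral_profile",
    "peak_spectral_modulation",
]


class MPSError(ValueError):
    """Input unsuitable for modulation-spectrum analysis."""


@dataclass
class Spectrogram:
    """Narrow-band log-power spectrogram (time x frequency), normalized to a
    0 dB maximum and floored at -50 dB."""

    times: np.ndarray
    frequencies: np.ndarray
    log_power: np.ndarray  # shape (n_times, n_freqs), dB
    window_sd_hz: float


@dataclass
class MPS:
    """Averaged 2D modulation amplitude with labeled axes."""

    temporal_modulations: np.ndarray  # Hz, signed, symmetric about 0
    spectral_modulations: np.ndarray  # cyc/kHz, non-negative
    amplitude: np.ndarray  # shape (n_temporal, n_spectral), >= 0
    provenance: dict = field(default_factory=dict)


@dataclass
class MPSDiff:
    """dB difference map between two averaged MPS (A minus B)."""

    temporal_modulations: np.ndarray
    spectral_modulations: np.ndarray
    values_db: np.ndarray


def narrowband_spectrogram(
    recording: CryRecording,
    freq_width_hz: float = 50.0,
    hop_s: float = 0.001,
    max_freq_hz: float = 11025.0,
    target_freq_step_hz: float = 25.0,
    floor_db: float = -50.0,
) -> Spectrogram:
    """Gaussian-window short-time analysis with a 50 Hz (= 6 sd) width in the
    frequency dimension; log power normalized to max 0 dB and floored.

    The frequency axis is subsampled to roughly ``target_freq_step_hz`` so the
    spectral-modulation Nyquist of the downstream MPS is ~20 cyc/kHz.
    """
    sr = recording.sample_rate
    x = np.asarray(recording.waveform, dtype=float)
    if len(x) < sr:
        raise MPSError(
            f"recording is {len(x) / sr:.2f} s; at least 1 s (one MPS window) required"
        )
    sigma_f = freq_width_hz / 6.0
    sigma_t = 1.0 / (2 * np.pi * sigma_f)  # time-frequency Gaussian duality
    win_len = int(round(6 * sigma_t * sr)) | 1
    win = signal.windows.gaussian(win_len, std=sigma_t * sr)
    hop = max(1, int(round(hop_s * sr)))
    from scipy.fft import next_fast_len

    stft = signal.ShortTimeFFT(
        win, hop=hop, fs=sr, mfft=next_fast_len(win_len), scale_to="magnitude"
    )
    S = stft.stft(x)  # (n_freq, n_times)
    mag = np.abs(S)
    freqs = stft.f
    times = stft.t(len(x))
    # subsample the frequency axis first so the stored grid contains the 0 dB
    # maximum after normalization
    step = max(1, int(round(target_freq_step_hz / (freqs[1] - freqs[0]))))
    keep = freqs <= min(max_freq_hz, sr / 2)
    mag = mag[keep][::step]
    freqs = freqs[keep][::step]
    log_power = 20 * np.log10(mag + 1e-12)
    log_power -= log_power.max()
    log_power = np.maximum(log_power, floor_db)
    return Spectrogram(
        times=np.asarray(times),
        frequencies=freqs,
        log_power=log_power.T.copy(),
        window_sd_hz=sigma_f,
    )


def compute_mps(
    spectrogram: Spectrogram,
    window_s: float = 1.0,
    overlap: float = 0.5,
    temporal_crop_hz: float = 100.0,
    spectral_crop_cpk: float = 10.0,
    taper: str = "gaussian",
    provenance_id: str | None = None,
) -> MPS:
    """Amplitude of the 2D Fourier transform of the log spectrogram, averaged
    over ``window_s`` Gaussian-weighted windows advanced with ``overlap``.

    ``taper="none"`` uses rectangular windows (useful for validating against a
    direct 2D DFT).  The result is cropped to |temporal modulation| <=
    ``temporal_crop_hz`` and spectral modulation <= ``spectral_crop_cpk``.
    """
    t = spectrogram.times
    f = spectrogram.frequencies
    M = spectrogram.log_power  # (n_t, n_f)
    dt = float(t[1] - t[0])
    df_khz = float(f[1] - f[0]) / 1000.0
    L = int(round(window_s / dt))
    n_t, n_f = M.shape
    if n_t < L:
        raise MPSError(
            f"spectrogram spans {n_t * dt:.2f} s; at least {window_s} s required"
        )
    if taper == "gaussian":
        w = signal.windows.gaussian(L, std=L / 6.0)
    elif taper == "none":
        w = np.ones(L)
    else:
        raise MPSError(f"unknown taper {taper!r}")

    step = max(1, int(round(L * (1 - overlap))))
    starts = list(range(0, n_t - L + 1, step))
    if not starts:
        starts = [0]

    tmod = np.fft.fftshift(np.fft.fftfreq(L, d=dt))
    smod = np.fft.rfftfreq(n_f, d=df_khz)
    acc = np.zeros((L, len(smod)))
    for s in starts:
        seg = M[s : s + L] * w[:, None]
        F = np.fft.fft2(seg)[:, : len(smod)]  # non-negative spectral half
        acc += np.abs(np.fft.fftshift(F, axes=0))
    amp = acc / len(starts)

    tkeep = np.abs(tmod) <= temporal_crop_hz
    skeep = smod <= spectral_crop_cpk
    mps = MPS(
        temporal_modulations=tmod[tkeep],
        spectral_modulations=smod[skeep],
        amplitude=amp[np.ix_(tkeep, skeep)],
        provenance={
            "recording_ids": [provenance_id] if provenance_id else [],
            "n_windows": len(starts),
        },
    )
    return mps


def mps_from_recording(recording: CryRecording, **kwargs) -> MPS:
    """Convenience: narrow-band spectrogram followed by the windowed 2D FT."""
    spec_kwargs = {
        k: kwargs.pop(k)
        for k in ("freq_width_hz", "hop_s", "max_freq_hz", "target_freq_step_hz", "floor_db")
        if k in kwargs
    }
    spec = narrowband_spectrogram(recording, **spec_kwargs)
    return compute_mps(spec, provenance_id=recording.sequence_id or None, **kwargs)


def _check_axes(a: MPS, b: MPS) -> None:
    if a.amplitude.shape != b.amplitude.shape or not (
        np.allclose(a.temporal_modulations, b.temporal_modulations)
        and np.allclose(a.spectral_modulations, b.spectral_modulations)
    ):
        raise MPSError("MPS axes do not match")


def average_mps(mps_list: list[MPS]) -> MPS:
    """Element-wise mean of MPS sharing identical axes; provenance concatenated."""
    if not mps_list:
        raise MPSError("cannot average an empty list")
    first = mps_list[0]
    for other in mps_list[1:]:
        _check_axes(first, other)
    amp = np.mean([m.amplitude for m in mps_list], axis=0)
    ids: list = []
    n_windows = 0
    for m in mps_list:
        ids.extend(m.provenance.get("recording_ids", []))
        n_windows += m.provenance.get("n_windows", 0)
    return MPS(
        temporal_modulations=first.temporal_modulations.copy(),
        spectral_modulations=first.spectral_modulations.copy(),
        amplitude=amp,
        provenance={"recording_ids": ids, "n_windows": n_windows},
    )


def to_db(mps: MPS, floor_db: float = -100.0) -> np.ndarray:
    """Log power of an MPS relative to its own maximum, floored."""
    amp = mps.amplitude
    peak = amp.max()
    if peak <= 0:
        raise MPSError("MPS has no energy")
    db = 20 * np.log10(np.maximum(amp / peak, 10 ** (floor_db / 20)))
    return db


def mps_difference(a: MPS, b: MPS) -> MPSDiff:
    """dB difference map: log power of A minus log power of B (antisymmetric
    under operand swap)."""
    _check_axes(a, b)
    return MPSDiff(
        temporal_modulations=a.temporal_modulations.copy(),
        spectral_modulations=a.spectral_modulations.copy(),
        values_db=to_db(a) - to_db(b),
    )


def spectral_profile(mps: MPS, tmod_max_hz: float = 20.0) -> np.ndarray:
    """Mean amplitude over slow temporal modulations, per spectral modulation."""
    mask = np.abs(mps.temporal_modulations) <= tmod_max_hz
    return mps.amplitude[mask].mean(axis=0)


def peak_spectral_modulation(
    mps: MPS, min_cpk: float = 0.5, prominence_frac: float = 0.8
) -> float:
    """Spectral modulation (cyc/kHz) of the pitch ridge: for a harmonic sound
    with fundamental f0 this sits at 1/f0 (f0 in kHz).

    Like a comb or autocorrelation, the profile of a harmonic sound repeats at
    k/f0; the ridge reported is the *first* local maximum above ``min_cpk``
    whose height reaches ``prominence_frac`` of the strongest one, which picks
    the comb fundamental rather than one of its multiples.
    """
    prof = spectral_profile(mps)
    sm = mps.spectral_modulations
    mask = sm >= min_cpk
    if not mask.any():
        raise MPSError("no spectral modulations above min_cpk")
    p = prof[mask]
    peaks = np.where((p[1:-1] >= p[:-2]) & (p[1:-1] >= p[2:]))[0] + 1
    if len(peaks) == 0:
        idx = int(np.argmax(p))
    else:
        tall = peaks[p[peaks] >= prominence_frac * p[peaks].max()]
        idx = int(tall[0])
    return float(sm[mask][idx])


def save_mps(path: str, mps: MPS) -> None:
    """Persist an MPS (axes + matrix + provenance) as a .npz archive."""
    np.savez(
        path,
        temporal_modulations=mps.temporal_modulations,
        spectral_modulations=mps.spectral_modulations,
        amplitude=mps.amplitude,
        recording_ids=np.array(mps.provenance.get("recording_ids", []), dtype=object),
        n_windows=mps.provenance.get("n_windows", 0),
    )


def load_mps(path: str) -> MPS:
    with np.load(path, allow_pickle=True) as z:
        return MPS(
            temporal_modulations=z["temporal_modulations"],
            spectral_modulations=z["spectral_modulations"],
            amplitude=z["amplitude"],
            provenance={
                "recording_ids": list(z["recording_ids"]),
                "n_windows": int(z["n_windows"]),
            },
        )
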