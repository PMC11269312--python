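"""Seeded synthesis of infant-cry corpora with controllable identity and condition effects.

The generator emulates a two-condition cry corpus: each baby has an idiosyncratic
source (mean fundamental, modulation style) and filter (two formants), and cries
are recorded either in a *discomfort* or a *pain* context.  The pain condition
widens the pitch excursion, deepens amplitude modulation, makes the source
noisier (lowering pitch saliency) and pulls each baby's identity parameters
toward the population mean ("shrinkage" of the between-baby acoustic space).

The source model is an additive harmonic stack (20 harmonics, 1/h rolloff) with
sinusoidal pitch modulation and jitter, shaped by two second-order resonances
and mixed with resonance-filtered noise.  Cry sequences are built as 2-6
expiratory bursts separated by short silences.  Nonlinear phenomena of real pain
cries (chaos, biphonation, subharmonics) are emulated only through their
measurable consequence -- reduced tonality -- via the noise mix and jitter.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "ConfigError",
    "SynthesisError",
    "CorpusLoadError",
    "IdentityDispersion",
    "PainEffect",
    "GeneratorConfig",
    "BabyProfile",
    "CryRecording",
    "POPULATION_MEANS",
    "study_profile",
    "sample_baby_profiles",
    "synthesize_cry",
    "generate_corpus",
    "normalize_amplitude",
    "write_corpus",
    "load_corpus",
]

CONDITIONS = ("discomfort", "pain")


class ConfigError(ValueError):
    """Invalid generator configuration."""


class SynthesisError(ValueError):
    """Synthesis cannot proceed (e.g. fundamental too close to Nyquist)."""


class CorpusLoadError(ValueError):
    """A corpus directory is inconsistent with its metadata table."""


# Population means of the identity-bearing parameters.  The fundamental band
# matches the 250-600 Hz pitch range typical of 2-month-old cries; formants
# near 1.1 and 3.3 kHz are representative infant vocal-tract resonances.
POPULATION_MEANS = {
    "f0_mean": 400.0,  # Hz
    "f0_mod_depth": 30.0,  # Hz, half-excursion of slow pitch modulation
    "f0_mod_rate": 4.0,  # Hz
    "F1": 1100.0,  # Hz
    "F2": 3300.0,  # Hz
    "am_rate": 3.5,  # Hz
    "am_depth": 0.35,
    "jitter_sd": 8.0,  # Hz
}

# Hard plausibility bounds used when drawing baby profiles.
_PROFILE_BOUNDS = {
    "f0_mean": (250.0, 600.0),
    "f0_mod_depth": (5.0, 60.0),
    "f0_mod_rate": (1.0, 8.0),
    "F1": (850.0, 1500.0),
    "F2": (2500.0, 4200.0),
    "am_rate": (1.5, 6.0),
    "am_depth": (0.05, 0.8),
    "jitter_sd": (2.0, 20.0),
}

_N_HARMONICS = 20
_BASE_NOISE_FRAC = 0.08  # RMS of noise relative to harmonic part, discomfort


@dataclass(frozen=True)
class IdentityDispersion:
    """Between-baby standard deviations of the identity-bearing parameters (Hz except am_rate in Hz)."""

    f0_mean: float = 70.0
    f0_mod_depth: float = 10.0
    F1: float = 120.0
    F2: float = 250.0
    am_rate: float = 1.0

    def validate(self) -> None:
        for name in ("f0_mean", "f0_mod_depth", "F1", "F2", "am_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"identity dispersion for {name} must be >= 0")


@dataclass(frozen=True)
class PainEffect:
    """Condition effect applied when synthesizing pain cries.

    pitch_range_multiplier scales the pitch-modulation depth (>= 1);
    saliency_drop in [0, 1] raises the noise mix (lowering measured saliency);
    am_depth_increase in [0, 1] deepens amplitude modulation;
    shrinkage in [0, 1] convexly pulls the baby's identity parameters toward
    the population mean before synthesis.
    """

    pitch_range_multiplier: float = 2.0
    saliency_drop: float = 0.4
    am_depth_increase: float = 0.4
    shrinkage: float = 0.6

    def validate(self) -> None:
        if self.pitch_range_multiplier < 1:
            raise ConfigError("pitch_range_multiplier must be >= 1")
        for name in ("saliency_drop", "am_depth_increase", "shrinkage"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")

    @classmethod
    def neutral(cls) -> "PainEffect":
        return cls(1.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-level description of a synthetic cry corpus."""

    n_babies: int = 22
    pain_per_baby: int = 4
    discomfort_count_range: tuple[int, int] = (2, 19)
    duration_mean_s: float = 6.3
    duration_sd_s: float = 1.1
    sample_rate: int = 22050
    identity_dispersion: IdentityDispersion = field(default_factory=IdentityDispersion)
    pain_effect: PainEffect = field(default_factory=PainEffect)
    noise_floor_db: float = -45.0
    seed: int = 0
    # Optional explicit per-baby discomfort counts (overrides the uniform draw).
    discomfort_counts: tuple[int, ...] | None = None

    def validate(self) -> None:
        if self.n_babies < 1 or self.pain_per_baby < 1:
            raise ConfigError("n_babies and pain_per_baby must be >= 1")
        lo, hi = self.discomfort_count_range
        if lo < 1 or hi < lo:
            raise ConfigError("discomfort_count_range must satisfy 1 <= lo <= hi")
        if self.duration_sd_s < 0:
            raise ConfigError("duration_sd_s must be >= 0")
        if self.sample_rate < 8000:
            raise ConfigError("sample_rate must be >= 8000 Hz")
        if self.discomfort_counts is not None and len(self.discomfort_counts) != self.n_babies:
            raise ConfigError("discomfort_counts must have one entry per baby")
        self.identity_dispersion.validate()
        self.pain_effect.validate()


@dataclass(frozen=True)
class BabyProfile:
    """Identity parameters of one baby (source + filter idiosyncrasies)."""

    baby_id: str
    sex: str  # "M" or "F"
    f0_mean: float
    f0_mod_depth: float
    f0_mod_rate: float
    F1: float
    F2: float
    am_rate: float
    am_depth: float
    jitter_sd: float

    def validate(self, sample_rate: int) -> None:
        if not 0 < self.f0_mean < sample_rate / 4:
            raise SynthesisError(
                f"f0_mean {self.f0_mean:.0f} Hz outside (0, fs/4) at fs={sample_rate}"
            )
        if not self.F1 < self.F2:
            raise SynthesisError("F1 must be below F2")
        if not 0 <= self.am_depth <= 1:
            raise SynthesisError("am_depth must lie in [0, 1]")


@dataclass
class CryRecording:
    """One peak-normalized mono cry sequence with its labels."""

    waveform: np.ndarray
    sample_rate: int
    baby_id: str
    sex: str
    condition: str
    sequence_id: str

    @property
    def duration(self) -> float:
        return len(self.waveform) / self.sample_rate


def study_profile(seed: int = 0, **overrides) -> GeneratorConfig:
    """Configuration emulating the study corpus: 22 babies, 4 pain cries each,
    18 babies with >= 6 discomfort sequences (eligible for within-condition
    leave-one-out analyses) and 4 with only 2-5.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x57D1]))
    counts = np.concatenate(
        [rng.integers(6, 17, size=18), rng.integers(2, 6, size=4)]
    )
    rng.shuffle(counts)
    cfg = GeneratorConfig(seed=seed, discomfort_counts=tuple(int(c) for c in counts))
    return replace(cfg, **overrides) if overrides else cfg


def normalize_amplitude(waveform: np.ndarray) -> np.ndarray:
    """Scale a waveform so that max |amplitude| = 1 (peak normalization)."""
    waveform = np.asarray(waveform, dtype=float)
    peak = np.max(np.abs(waveform)) if waveform.size else 0.0
    if peak == 0:
        raise SynthesisError("cannot normalize an all-zero (silent) waveform")
    return waveform / peak


def sample_baby_profiles(config: GeneratorConfig) -> list[BabyProfile]:
    """Draw the per-baby identity parameters.

    Deterministic given ``config.seed``; sexes balanced to within one baby.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xBABE]))
    disp = config.identity_dispersion
    sds = {
        "f0_mean": disp.f0_mean,
        "f0_mod_depth": disp.f0_mod_depth,
        "f0_mod_rate": 1.0,
        "F1": disp.F1,
        "F2": disp.F2,
        "am_rate": disp.am_rate,
        "am_depth": 0.08,
        "jitter_sd": 2.0,
    }
    profiles = []
    n = config.n_babies
    sexes = ["M" if i % 2 == 0 else "F" for i in range(n)]
    for i in range(n):
        params = {}
        for name, mean in POPULATION_MEANS.items():
            lo, hi = _PROFILE_BOUNDS[name]
            v = float(np.clip(rng.normal(mean, sds[name]), lo, hi))
            params[name] = v
        if params["F1"] >= params["F2"]:  # cannot happen with default bounds
            params["F1"], params["F2"] = params["F2"], params["F1"]
        profiles.append(BabyProfile(baby_id=f"B{i:02d}", sex=sexes[i], **params))
    return profiles


def _shrink_profile(profile: BabyProfile, shrinkage: float) -> BabyProfile:
    """Convexly pull the identity-bearing parameters toward the population mean."""
    if shrinkage == 0:
        return profile
    kw = {}
    for name in ("f0_mean", "f0_mod_depth", "F1", "F2", "am_rate"):
        kw[name] = (1 - shrinkage) * getattr(profile, name) + shrinkage * POPULATION_MEANS[name]
    return replace(profile, **kw)


def _resonator_ba(freq: float, bandwidth: float, sr: int) -> tuple[list, list]:
    """Two-pole resonator normalized to unity gain at its resonance."""
    r = np.exp(-np.pi * bandwidth / sr)
    theta = 2 * np.pi * freq / sr
    a = [1.0, -2 * r * np.cos(theta), r * r]
    z = np.exp(-1j * theta)
    b0 = abs(a[0] + a[1] * z + a[2] * z * z)
    return [b0, 0.0, 0.0], a


def _formant_filter(x: np.ndarray, F1: float, F2: float, sr: int) -> np.ndarray:
    """Parallel formant bank: the two resonances sum with a mild high-formant
    de-emphasis, the standard formant-synthesizer topology."""
    out = np.zeros_like(x)
    for freq, bw, gain in ((F1, 150.0, 1.0), (min(F2, 0.45 * sr), 250.0, 0.7)):
        b, a = _resonator_ba(freq, bw, sr)
        out += gain * signal.lfilter(b, a, x)
    return out


def _burst_plan(duration_s: float, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Split a sequence into (burst, following-silence) durations in seconds."""
    n_bursts = int(rng.integers(2, 7))
    gaps = rng.uniform(0.15, 0.40, size=6)  # fixed draw count keeps streams aligned
    # shrink burst count until at least 0.4 s of voicing per burst remains
    while n_bursts > 1 and duration_s - gaps[: n_bursts - 1].sum() < 0.4 * n_bursts:
        n_bursts -= 1
    silence = gaps[: n_bursts - 1].sum() if n_bursts > 1 else 0.0
    weights = rng.uniform(0.6, 1.4, size=6)[:n_bursts]
    burst_total = duration_s - silence
    bursts = burst_total * weights / weights.sum()
    plan = []
    for k in range(n_bursts):
        gap = gaps[k] if k < n_bursts - 1 else 0.0
        plan.append((float(bursts[k]), float(gap)))
    return plan


def synthesize_cry(
    profile: BabyProfile,
    condition: str,
    duration_s: float,
    seed: int,
    *,
    sample_rate: int = 22050,
    pain_effect: PainEffect | None = None,
    noise_floor_db: float = -45.0,
) -> CryRecording:
    """Render one cry sequence for a baby profile under a condition.

    The random stream is consumed identically in both conditions, so a neutral
    ``pain_effect`` yields a waveform identical to the discomfort rendering of
    the same seed.
    """
    if condition not in CONDITIONS:
        raise ConfigError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    if duration_s <= 0.5:
        raise SynthesisError("duration_s must exceed 0.5 s")
    profile.validate(sample_rate)
    effect = pain_effect if pain_effect is not None else PainEffect()
    effect.validate()
    sr = sample_rate
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC47]))

    is_pain = condition == "pain"
    # Condition-dependent effective parameters (identical when effect is neutral).
    shrink = effect.shrinkage if is_pain else 0.0
    p = _shrink_profile(profile, shrink)
    mod_mult = effect.pitch_range_multiplier if is_pain else 1.0
    sal_drop = effect.saliency_drop if is_pain else 0.0
    am_inc = effect.am_depth_increase if is_pain else 0.0

    f0_mod_depth = p.f0_mod_depth * mod_mult
    jitter_sd = p.jitter_sd * (1 + 1.5 * sal_drop)
    am_depth = min(1.0, p.am_depth * (1 + am_inc))
    noise_frac = _BASE_NOISE_FRAC + 0.6 * sal_drop

    n = int(round(duration_s * sr))
    t = np.arange(n) / sr
    # Per-cry idiosyncratic scatter (same draws either condition); scales with
    # the profile's jitter so a noiseless profile has a deterministic f0.
    scatter_sd = 0.03 * p.jitter_sd / POPULATION_MEANS["jitter_sd"]
    f0_cry = p.f0_mean * float(np.exp(rng.normal(0.0, scatter_sd)))
    depth_cry = f0_mod_depth * float(np.exp(rng.normal(0.0, 0.15)))
    mod_phase = float(rng.uniform(0, 2 * np.pi))
    am_phase = float(rng.uniform(0, 2 * np.pi))

    # Time-varying fundamental: slow sinusoidal modulation + smoothed jitter.
    raw_jit = rng.standard_normal(n)
    k = max(3, int(0.005 * sr))
    jitter = signal.fftconvolve(raw_jit, np.ones(k) / k, mode="same") * np.sqrt(k) * jitter_sd
    f0_t = f0_cry + depth_cry * np.sin(2 * np.pi * p.f0_mod_rate * t + mod_phase) + jitter
    f0_t = np.clip(f0_t, 80.0, sr / 4)
    if np.max(f0_t) >= sr / 4:
        raise SynthesisError("fundamental exceeds a quarter of the sample rate")

    phase = 2 * np.pi * np.cumsum(f0_t) / sr
    harm_phases = rng.uniform(0, 2 * np.pi, size=_N_HARMONICS)
    nyq = 0.95 * sr / 2
    f0_max = float(np.max(f0_t))
    source = np.zeros(n)
    for h in range(1, _N_HARMONICS + 1):
        if h * f0_max >= nyq:
            break
        source += np.sin(h * phase + harm_phases[h - 1]) / h

    noise = rng.standard_normal(n)
    voiced = _formant_filter(source, p.F1, p.F2, sr)
    shaped_noise = _formant_filter(noise, p.F1, p.F2, sr)
    v_rms = np.sqrt(np.mean(voiced**2)) or 1.0
    n_rms = np.sqrt(np.mean(shaped_noise**2)) or 1.0
    mix = voiced / v_rms + noise_frac * shaped_noise / n_rms

    # Burst envelope (Tukey windows) and slow amplitude modulation.
    env = np.zeros(n)
    pos = 0
    for burst_s, gap_s in _burst_plan(duration_s, rng):
        nb = int(round(burst_s * sr))
        nb = min(nb, n - pos)
        if nb > 8:
            env[pos : pos + nb] = signal.windows.tukey(nb, alpha=0.4)
        pos += nb + int(round(gap_s * sr))
        if pos >= n:
            break
    if env.max() == 0:  # degenerate plan for very short cries
        env[:] = signal.windows.tukey(n, alpha=0.4)
    am = 1 + am_depth * np.sin(2 * np.pi * p.am_rate * t + am_phase)
    wave = mix * env * am

    floor = 10 ** (noise_floor_db / 20) * np.max(np.abs(wave))
    wave = wave + floor * rng.standard_normal(n)
    wave = normalize_amplitude(wave)
    return CryRecording(
        waveform=wave,
        sample_rate=sr,
        baby_id=profile.baby_id,
        sex=profile.sex,
        condition=condition,
        sequence_id="",
    )


def _truncated_durations(n: int, mean: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Normal(mean, sd) durations truncated below at 2 s (redrawn)."""
    out = np.empty(n)
    for i in range(n):
        d = rng.normal(mean, sd)
        while d < 2.0:
            d = rng.normal(mean, sd)
        out[i] = d
    return out


def generate_corpus(config: GeneratorConfig) -> tuple[list[CryRecording], pd.DataFrame]:
    """Generate the full synthetic corpus and its metadata table.

    Pure function of the configuration (including its seed): two calls with the
    same config give identical recordings and metadata.
    """
    config.validate()
    profiles = sample_baby_profiles(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0D5]))
    lo, hi = config.discomfort_count_range
    recordings: list[CryRecording] = []
    rows = []
    for i, prof in enumerate(profiles):
        if config.discomfort_counts is not None:
            n_disc = int(config.discomfort_counts[i])
        else:
            n_disc = int(rng.integers(lo, hi + 1))
        for condition, count in (("discomfort", n_disc), ("pain", config.pain_per_baby)):
            durations = _truncated_durations(
                count, config.duration_mean_s, config.duration_sd_s, rng
            )
            for k in range(count):
                cry_seed = int(rng.integers(0, 2**31 - 1))
                rec = synthesize_cry(
                    prof,
                    condition,
                    float(durations[k]),
                    cry_seed,
                    sample_rate=config.sample_rate,
                    pain_effect=config.pain_effect,
                    noise_floor_db=config.noise_floor_db,
                )
                rec.sequence_id = f"{prof.baby_id}_{condition}_{k:02d}"
                recordings.append(rec)
                rows.append(
                    {
                        "baby_id": prof.baby_id,
                        "sex": prof.sex,
                        "condition": condition,
                        "sequence_id": rec.sequence_id,
                        "duration_s": rec.duration,
                    }
                )
    metadata = pd.DataFrame(rows)
    return recordings, metadata


def write_corpus(
    recordings: list[CryRecording], metadata: pd.DataFrame, directory: str
) -> pd.DataFrame:
    """Write 16-bit PCM mono WAV files plus a metadata CSV; returns the table with paths."""
    os.makedirs(directory, exist_ok=True)
    meta = metadata.copy()
    paths = []
    by_id = {r.sequence_id: r for r in recordings}
    for seq_id in meta["sequence_id"]:
        rec = by_id[seq_id]
        fname = f"{seq_id}.wav"
        pcm = np.clip(rec.waveform, -1, 1)
        wavfile.write(
            os.path.join(directory, fname), rec.sample_rate, (pcm * 32767).astype(np.int16)
        )
        paths.append(fname)
    meta["wav_path"] = paths
    meta.to_csv(os.path.join(directory, "metadata.csv"), index=False)
    return meta


def load_corpus(directory: str) -> tuple[list[CryRecording], pd.DataFrame]:
    """Load a corpus written by :func:`write_corpus`, validating labels and files."""
    meta_path = os.path.join(directory, "metadata.csv")
    if not os.path.exists(meta_path):
        raise CorpusLoadError(f"no metadata.csv in {directory}")
    metadata = pd.read_csv(meta_path)
    required = {"baby_id", "sex", "condition", "sequence_id", "wav_path"}
    missing = required - set(metadata.columns)
    if missing:
        raise CorpusLoadError(f"metadata.csv lacks columns: {sorted(missing)}")
    bad = set(metadata["condition"]) - set(CONDITIONS)
    if bad:
        raise CorpusLoadError(
            f"unknown condition labels {sorted(bad)}; allowed values are {CONDITIONS}"
        )
    recordings = []
    for row in metadata.itertuples():
        path = os.path.join(directory, row.wav_path)
        if not os.path.exists(path):
            raise CorpusLoadError(f"metadata references missing file: {row.wav_path}")
        sr, data = wavfile.read(path)
        if data.ndim != 1:
            raise CorpusLoadError(f"{row.wav_path} is not mono")
        wave = data.astype(float) / 32767.0
        recordings.append(
            CryRecording(
                waveform=wave,
                sample_rate=sr,
                baby_id=row.baby_id,
                sex=row.sex,
                condition=row.condition,
                sequence_id=row.sequence_id,
            )
        )
    return recordings, metadata
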