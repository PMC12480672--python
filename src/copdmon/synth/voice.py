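"""Source-filter voice synthesis with planted ground truth.

Voiced portions are an impulse-train glottal source passed through a
cascade of second-order resonators at four target formant frequencies.
Glottal periods are mean period × (1 + jitter_pct/100 × z_k) and cycle
amplitudes mean amplitude × (1 + shimmer_pct/100 × w_k), with z_k, w_k
i.i.d. standard normal clipped to ±3 so periods stay positive.  The
realized period and amplitude sequences are recorded per voiced run and
serve as the oracle for the feature extractor.

Impulses are placed with sub-sample (linear-interpolation) precision so
the planted periods are not quantized to the sample grid.  Resonator
bandwidths are deliberately broad (180-300 Hz) so each cycle's response
decays almost completely within one period, keeping the planted cycle
amplitudes cleanly measurable; formant centre frequencies are unaffected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

DEFAULT_FORMANTS = (500.0, 1500.0, 2500.0, 3500.0)
RESONATOR_BANDWIDTHS = (150.0, 180.0, 210.0, 240.0)
VOICED_TARGET_RMS = 0.15
PAUSE_NOISE_DB = -60.0  # re voiced RMS: >= 40 dB below, per contract


@dataclass(frozen=True)
class VoiceSpec:
    """Parameters of one synthetic voiced recording."""

    duration_s: float = 3.0
    f0_hz: float = 140.0
    jitter_pct: float = 1.0
    shimmer_pct: float = 5.0
    formants_hz: tuple[float, float, float, float] = DEFAULT_FORMANTS
    noise_snr_db: float = 25.0
    syllable_pattern: tuple[tuple[float, float], ...] | None = None
    sample_rate_hz: int = 16000
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not (0 <= self.jitter_pct < 20 and 0 <= self.shimmer_pct < 20):
            raise ValueError("jitter_pct and shimmer_pct must be in [0, 20)")
        f = self.formants_hz
        if not (0 < f[0] < f[1] < f[2] < f[3]):
            raise ValueError("formants must be strictly increasing")
        if not (0 < self.f0_hz < f[0]):
            raise ValueError("f0_hz must be positive and below F1")
        if 3.0 * self.jitter_pct / 100.0 >= 1.0:
            raise ValueError("jitter_pct too large: perturbed periods could "
                             "become non-positive")

    @property
    def pattern(self) -> tuple[tuple[float, float], ...]:
        if self.syllable_pattern is not None:
            return tuple(self.syllable_pattern)
        return ((self.duration_s, 0.0),)


@dataclass
class VoiceSample:
    """Synthesized waveform plus its generator-internal ground truth."""

    samples: np.ndarray
    sample_rate_hz: int
    spec: VoiceSpec
    # one entry per voiced run: realized periods (ms) and impulse amplitudes
    true_periods_ms: list[np.ndarray] = field(default_factory=list)
    true_amplitudes: list[np.ndarray] = field(default_factory=list)
    voiced_intervals_s: list[tuple[float, float]] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz


def _resonator_cascade(x: np.ndarray, formants, bandwidths, fs: float) -> np.ndarray:
    y = x
    for f, bw in zip(formants, bandwidths):
        r = math.exp(-math.pi * bw / fs)
        theta = 2.0 * math.pi * f / fs
        a = [1.0, -2.0 * r * math.cos(theta), r * r]
        b = [1.0 - r]  # rough unity-ish gain; overall level is renormalized
        y = sps.lfilter(b, a, y)
    return y


def _place_impulses(n: int, fs: float, times_s: np.ndarray,
                    amps: np.ndarray, half_width: int = 12) -> np.ndarray:
    """Band-limited impulse train with sub-sample placement.

    Each impulse is a Hann-windowed sinc centred at its fractional sample
    position, so realized cycle energies do not depend on where a glottal
    pulse falls relative to the sample grid.
    """
    x = np.zeros(n)
    pos = times_s * fs
    offsets = np.arange(-half_width, half_width + 1)
    for p, a in zip(pos, amps):
        i0 = int(np.floor(p))
        idx = i0 + offsets
        kernel = np.sinc(idx - p) * (0.5 + 0.5 * np.cos(
            np.pi * (idx - p) / (half_width + 1)))
        ok = (idx >= 0) & (idx < n)
        x[idx[ok]] += a * kernel[ok]
    return x


def gen_voice(spec: VoiceSpec) -> VoiceSample:
    """Synthesize one recording according to ``spec``.

    Deterministic for a fixed seed.  Pause portions carry noise at least
    40 dB below the voiced RMS.  Additive broadband noise at
    ``noise_snr_db`` (relative to the voiced signal power) controls the
    achievable HNR; ``noise_snr_db = inf`` means no noise.
    """
    fs = float(spec.sample_rate_hz)
    rng = np.random.default_rng(spec.seed)
    T0 = 1.0 / spec.f0_hz

    runs_samples: list[np.ndarray] = []
    sample = VoiceSample(np.array([]), spec.sample_rate_hz, spec)
    t_cursor = 0.0
    for voiced_s, pause_s in spec.pattern:
        n_v = int(round(voiced_s * fs))
        if n_v > 0:
            # realized glottal timing for this run
            times = []
            periods = []
            amps = []
            t = 0.25 * T0  # first impulse away from the run edge
            while True:
                z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
                w = float(np.clip(rng.standard_normal(), -3.0, 3.0))
                T = T0 * (1.0 + spec.jitter_pct / 100.0 * z)
                if T <= 0:
                    raise ValueError("non-positive perturbed period")
                if t + T >= voiced_s - 0.25 * T0:
                    times.append(t)
                    amps.append(1.0 + spec.shimmer_pct / 100.0 * w)
                    break
                times.append(t)
                amps.append(1.0 + spec.shimmer_pct / 100.0 * w)
                periods.append(T)
                t += T
            times = np.array(times)
            amps = np.array(amps)
            src = _place_impulses(n_v, fs, times, amps)
            voiced = _resonator_cascade(src, spec.formants_hz,
                                        RESONATOR_BANDWIDTHS, fs)
            rms = float(np.sqrt(np.mean(voiced**2)))
            if rms > 0:
                voiced *= VOICED_TARGET_RMS / rms
            if np.isfinite(spec.noise_snr_db):
                p_sig = float(np.mean(voiced**2))
                sigma = math.sqrt(p_sig / (10.0 ** (spec.noise_snr_db / 10.0)))
                voiced = voiced + sigma * rng.standard_normal(n_v)
            runs_samples.append(voiced)
            sample.true_periods_ms.append(np.array(periods) * 1000.0)
            sample.true_amplitudes.append(amps[: len(periods)])
            sample.voiced_intervals_s.append((t_cursor, t_cursor + voiced_s))
            t_cursor += voiced_s
        n_p = int(round(pause_s * fs))
        if n_p > 0:
            sigma = VOICED_TARGET_RMS * 10.0 ** (PAUSE_NOISE_DB / 20.0)
            runs_samples.append(sigma * rng.standard_normal(n_p))
            t_cursor += pause_s
    sample.samples = (np.concatenate(runs_samples)
                      if runs_samples else np.zeros(0))
    return sample


def write_wav(path, samples: np.ndarray, sample_rate_hz: int) -> None:
    """Write PCM 16-bit WAV (clipping at full scale)."""
    from scipy.io import wavfile

    x = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    wavfile.write(path, sample_rate_hz, (x * 32767.0).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a WAV file to float samples in [-1, 1]."""
    from scipy.io import wavfile

    fs, x = wavfile.read(path)
    if x.dtype == np.int16:
        x = x.astype(float) / 32768.0
    elif x.dtype == np.int32:
        x = x.astype(float) / 2147483648.0
    elif x.dtype == np.uint8:
        x = (x.astype(float) - 128.0) / 128.0
    else:
        x = x.astype(float)
    if x.ndim > 1:
        x = x.mean(axis=1)
    return x, int(fs)
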