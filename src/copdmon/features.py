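"""Acoustic voice features from retained speech audio.

Three families, matching the usual voice-quality toolbox:

* phonation — HNR and the jitter/shimmer perturbation suites, computed from
  a cycle-by-cycle track of glottal periods and peak amplitudes;
* prosodic — F0 statistics, the four lowest formants from linear-prediction
  analysis, and formant-derived quantities (dispersion, spacing, vocal tract
  length estimates, formant position);
* syllabic nuclei — speaking-rate measures from intensity peaks coincident
  with voiced frames.

Perturbation definitions follow the standard voice-analysis conventions:
local jitter = mean |T_i − T_{i−1}| / mean(T); absolute jitter in ms;
rap / ppq5 compare each period against a 3- / 5-point moving average;
ddp = 3 × rap exactly.  The shimmer family applies the same formulas to
cycle peak amplitudes, with dda = 3 × apq3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

SPEED_OF_SOUND_CM_S = 35000.0
F0_MIN_HZ = 60.0
F0_MAX_HZ = 400.0
VOICING_THRESHOLD = 0.45
HNR_CEILING_DB = 60.0


@dataclass
class PeriodTrack:
    """Consecutive glottal cycle durations (ms) and peak amplitudes."""

    periods_ms: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self):
        self.periods_ms = np.asarray(self.periods_ms, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.periods_ms.size and np.any(self.periods_ms <= 0):
            raise ValueError("periods must be positive")

    def __len__(self) -> int:
        return self.periods_ms.size


@dataclass(frozen=True)
class FormantSet:
    f1_hz: float
    f2_hz: float
    f3_hz: float
    f4_hz: float
    speed_of_sound_cm_s: float = SPEED_OF_SOUND_CM_S

    def __post_init__(self):
        f = self.as_array()
        if not (0 < f[0] < f[1] < f[2] < f[3]):
            raise ValueError("formants must be strictly increasing and positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.f1_hz, self.f2_hz, self.f3_hz, self.f4_hz])


# ---------------------------------------------------------------------------
# F0 / voicing analysis
# ---------------------------------------------------------------------------


def _norm_autocorr(x: np.ndarray, lag_min: int, lag_max: int):
    """Normalized autocorrelation r(tau) over a lag range.

    r(tau) is the correlation of x[:-tau] with x[tau:], each term normalized
    by the energies of the two overlapping chunks, so a perfectly periodic
    frame scores 1 at its period regardless of frame length.
    """
    x = x - x.mean()
    n = x.size
    if lag_max >= n:
        lag_max = n - 1
    if lag_max <= lag_min:
        return None
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[: lag_max + 1]
    csum = np.cumsum(x * x)
    total = csum[-1]
    if total <= 0:
        return None
    lags = np.arange(lag_min, lag_max + 1)
    e_head = csum[n - lags - 1]
    e_tail = total - csum[lags - 1]
    denom = np.sqrt(e_head * e_tail)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, ac[lag_min:] / denom, 0.0)
    return lags, r


def _best_lag(x: np.ndarray, fs: float, f0_min: float, f0_max: float):
    """(lag_samples, r) of the strongest autocorrelation peak in the pitch
    range, with parabolic interpolation of the lag; None when degenerate."""
    lag_min = max(2, int(fs / f0_max))
    lag_max = int(np.ceil(fs / f0_min))
    res = _norm_autocorr(np.asarray(x, dtype=float), lag_min, lag_max)
    if res is None:
        return None
    lags, r = res
    i = int(np.argmax(r))
    # subharmonic (octave) guard: among local maxima nearly as strong as the
    # global one, prefer the smallest lag (the true period, not a multiple)
    if r[i] > 0:
        interior = np.nonzero(
            (r[1:-1] >= r[:-2]) & (r[1:-1] >= r[2:])
            & (r[1:-1] >= r[i] - max(0.04, 0.04 * r[i]))
        )[0] + 1
        if interior.size:
            i = int(interior[0])
    lag, rbest = float(lags[i]), float(r[i])
    if 0 < i < r.size - 1:
        denom = r[i - 1] - 2 * r[i] + r[i + 1]
        if denom < 0:
            delta = 0.5 * (r[i - 1] - r[i + 1]) / denom
            if abs(delta) < 1:
                lag += delta
                rbest = r[i] - 0.25 * (r[i - 1] - r[i + 1]) * delta
    return lag, min(rbest, 1.0)


def frame_f0(
    x: np.ndarray,
    fs: float,
    frame_s: float = 0.040,
    hop_s: float = 0.010,
    f0_min: float = F0_MIN_HZ,
    f0_max: float = F0_MAX_HZ,
    voicing_threshold: float = VOICING_THRESHOLD,
):
    """Frame-wise F0 track.

    Returns (times_s, f0_hz, r) arrays; unvoiced frames (autocorrelation
    peak below the voicing threshold) have f0 = NaN.
    """
    x = np.asarray(x, dtype=float)
    n = int(round(frame_s * fs))
    hop = int(round(hop_s * fs))
    starts = np.arange(0, max(x.size - n + 1, 0), hop)
    times = (starts + n / 2) / fs
    f0 = np.full(starts.size, np.nan)
    r = np.zeros(starts.size)
    for j, s in enumerate(starts):
        res = _best_lag(x[s : s + n], fs, f0_min, f0_max)
        if res is None:
            continue
        lag, rbest = res
        r[j] = rbest
        if rbest >= voicing_threshold and lag > 0:
            f0[j] = fs / lag
    # sub/superharmonic correction against the track median: isolated
    # halvings, thirds or doublings of an otherwise steady pitch are
    # tracking faults, not pitch changes
    voiced = np.isfinite(f0)
    if voiced.sum() >= 3:
        med = np.median(f0[voiced])
        for k in (2.0, 3.0, 0.5, 1.0 / 3.0):
            fix = voiced & (np.abs(k * f0 - med) < 0.25 * med) \
                & (np.abs(f0 - med) > 0.25 * med)
            f0[fix] *= k
    return times, f0, r


# ---------------------------------------------------------------------------
# Cycle tracking
# ---------------------------------------------------------------------------


def _refine_peak(s: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample peak location/height by parabolic interpolation."""
    if 0 < i < s.size - 1:
        denom = s[i - 1] - 2 * s[i] + s[i + 1]
        if denom < 0:
            delta = 0.5 * (s[i - 1] - s[i + 1]) / denom
            if abs(delta) <= 1:
                height = s[i] - 0.25 * (s[i - 1] - s[i + 1]) * delta
                return i + delta, float(height)
    return float(i), float(s[i])


def track_periods(
    x: np.ndarray,
    fs: float,
    f0_min: float = F0_MIN_HZ,
    f0_max: float = F0_MAX_HZ,
    voicing_threshold: float = VOICING_THRESHOLD,
) -> PeriodTrack:
    """Cycle-by-cycle glottal periods and peak amplitudes.

    A frame-wise autocorrelation F0 track guides peak picking: starting
    from the strongest waveform peak, successive cycle peaks are located
    within ±30% of the locally expected period, with parabolic sub-sample
    refinement.  Unvoiced or aperiodic input yields an empty track.
    """
    x = np.asarray(x, dtype=float)
    times, f0, r = frame_f0(x, fs, f0_min=f0_min, f0_max=f0_max,
                            voicing_threshold=voicing_threshold)
    voiced = np.isfinite(f0)
    if voiced.sum() < 3:
        return PeriodTrack(np.array([]), np.array([]))

    # orient so cycle peaks are positive
    s = x if abs(x.max()) >= abs(x.min()) else -x

    med_T = fs / float(np.median(f0[voiced]))

    def local_period(t_samp: float) -> float:
        t = t_samp / fs
        idx = np.searchsorted(times, t)
        T = med_T
        for j in (idx - 1, idx, idx - 2, idx + 1):
            if 0 <= j < f0.size and voiced[j]:
                T = fs / f0[j]
                break
        # the frame estimate guides the peak search; keep it near the
        # track median so one bad frame cannot derail the walk
        return float(np.clip(T, 0.75 * med_T, 1.35 * med_T))

    # voiced region bounds (samples)
    vtimes = times[voiced]
    t_lo = max(0.0, (vtimes[0] - 0.03) * fs)
    t_hi = min(s.size - 1.0, (vtimes[-1] + 0.03) * fs)
    seg = s[int(t_lo) : int(t_hi) + 1]
    if seg.size < 3:
        return PeriodTrack(np.array([]), np.array([]))
    i0 = int(t_lo) + int(np.argmax(seg))
    floor = 0.15 * s[i0]

    def walk(start: float, direction: int) -> list[tuple[float, float]]:
        out = []
        t = start
        while True:
            T = local_period(t)
            a = t + direction * 0.70 * T
            b = t + direction * 1.35 * T
            lo, hi = (a, b) if direction > 0 else (b, a)
            lo_i, hi_i = int(np.floor(lo)), int(np.ceil(hi))
            if lo_i < t_lo or hi_i > t_hi or hi_i - lo_i < 2:
                break
            chunk = s[lo_i : hi_i + 1]
            j = int(np.argmax(chunk))
            pos, height = _refine_peak(s, lo_i + j)
            if height < floor:
                break
            out.append((pos, height))
            t = pos
        return out

    p0, h0 = _refine_peak(s, i0)
    back = walk(p0, -1)[::-1]
    fwd = walk(p0, +1)
    peaks = back + [(p0, h0)] + fwd
    if len(peaks) < 4:
        return PeriodTrack(np.array([]), np.array([]))
    pos = np.array([p for p, _ in peaks])
    periods_ms = np.diff(pos) / fs * 1000.0
    # cycle amplitude: RMS over one period starting just before each peak,
    # with fractional-sample window edges (cumulative-energy interpolation)
    # so the measure is independent of where the cycle falls on the grid
    cs = np.concatenate([[0.0], np.cumsum(s * s)])
    idx = np.arange(cs.size, dtype=float)
    amps = np.empty(periods_ms.size)
    for k in range(periods_ms.size):
        T = pos[k + 1] - pos[k]
        a = max(pos[k] - 0.1 * T, 0.0)
        b = min(pos[k] + 0.9 * T, cs.size - 1.0)
        e = np.interp(b, idx, cs) - np.interp(a, idx, cs)
        amps[k] = np.sqrt(max(e, 0.0) / max(b - a, 1.0))
    return PeriodTrack(periods_ms, amps)


# ---------------------------------------------------------------------------
# Perturbation features
# ---------------------------------------------------------------------------


def _local_perturbation(v: np.ndarray) -> float:
    return float(np.mean(np.abs(np.diff(v))) / np.mean(v))


def _quotient(v: np.ndarray, k: int) -> float:
    """N-point perturbation quotient: mean deviation from the k-point
    centred moving average, relative to the overall mean."""
    half = k // 2
    kernel = np.ones(k) / k
    smooth = np.convolve(v, kernel, mode="valid")
    centre = v[half : v.size - half]
    return float(np.mean(np.abs(centre - smooth)) / np.mean(v))


def jitter_features(track: PeriodTrack) -> dict[str, float]:
    """Jitter suite on a period track; short tracks give NaNs."""
    T = track.periods_ms
    out = {k: np.nan for k in
           ("jitter", "absolute_jitter", "rap_jitter", "ppq5_jitter", "ddp_jitter")}
    if T.size >= 3:
        out["jitter"] = 100.0 * _local_perturbation(T)
        out["absolute_jitter"] = float(np.mean(np.abs(np.diff(T))))
        out["rap_jitter"] = 100.0 * _quotient(T, 3)
        out["ddp_jitter"] = 3.0 * out["rap_jitter"]
    if T.size >= 5:
        out["ppq5_jitter"] = 100.0 * _quotient(T, 5)
    return out


def shimmer_features(track: PeriodTrack) -> dict[str, float]:
    """Shimmer suite on cycle peak amplitudes; short tracks give NaNs."""
    A = track.amplitudes
    out = {k: np.nan for k in
           ("shimmer", "apq3_shimmer", "apq5_shimmer", "apq11_shimmer", "dda_shimmer")}
    if A.size >= 3:
        out["shimmer"] = 100.0 * _local_perturbation(A)
        out["apq3_shimmer"] = 100.0 * _quotient(A, 3)
        out["dda_shimmer"] = 3.0 * out["apq3_shimmer"]
    if A.size >= 5:
        out["apq5_shimmer"] = 100.0 * _quotient(A, 5)
    if A.size >= 11:
        out["apq11_shimmer"] = 100.0 * _quotient(A, 11)
    return out


# ---------------------------------------------------------------------------
# HNR
# ---------------------------------------------------------------------------


def hnr(
    x: np.ndarray,
    fs: float,
    ceiling_db: float = HNR_CEILING_DB,
    f0_min: float = F0_MIN_HZ,
    f0_max: float = F0_MAX_HZ,
    voicing_threshold: float = VOICING_THRESHOLD,
) -> float:
    """Harmonics-to-noise ratio, dB: 10·log10(r/(1−r)) at the detected
    period, averaged over voiced frames, capped at ``ceiling_db``.

    Unvoiced input returns NaN.
    """
    x = np.asarray(x, dtype=float)
    n = int(round(0.040 * fs))
    hop = int(round(0.010 * fs))
    vals = []
    for s in range(0, max(x.size - n + 1, 1), hop):
        res = _best_lag(x[s : s + n], fs, f0_min, f0_max)
        if res is None:
            continue
        _, r = res
        if r < voicing_threshold:
            continue
        if r <= 0:
            continue
        # periodicity indistinguishable from perfect at the estimator's
        # numerical resolution reports the ceiling
        if 1.0 - r <= 1e-5:
            vals.append(ceiling_db)
        else:
            vals.append(min(10.0 * np.log10(r / (1.0 - r)), ceiling_db))
    return float(np.mean(vals)) if vals else np.nan


def f0_stats(f0_values: np.ndarray) -> tuple[float, float]:
    """(mean F0, std F0) over all voiced-frame estimates of a day."""
    v = np.asarray(f0_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.nan, np.nan
    std = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(np.mean(v)), std


# ---------------------------------------------------------------------------
# Formants
# ---------------------------------------------------------------------------


def _lpc_burg(x: np.ndarray, order: int) -> np.ndarray | None:
    """Burg-method LPC coefficients (no windowing, low bias)."""
    x = np.asarray(x, dtype=float)
    if x.size <= order + 1 or not np.any(x):
        return None
    f = x[1:].copy()
    b = x[:-1].copy()
    a = np.array([1.0])
    for _ in range(order):
        den = float(np.dot(f, f) + np.dot(b, b))
        if den <= 0 or f.size == 0:
            return None
        k = -2.0 * float(np.dot(f, b)) / den
        a = np.concatenate([a, [0.0]]) + k * np.concatenate([[0.0], a[::-1]])
        f, b = f[1:] + k * b[1:], b[:-1] + k * f[:-1]
    return a


def estimate_formants(
    x: np.ndarray,
    fs: float,
    n_formants: int = 4,
    analysis_fs: int = 9000,
    lpc_order: int = 14,
    max_bandwidth_hz: float = 600.0,
    min_freq_hz: float = 90.0,
) -> tuple[FormantSet | None, dict]:
    """Four lowest formants by linear-prediction root solving.

    The segment is resampled to ``analysis_fs`` and fitted with a single
    Burg-method LPC model; polynomial roots give candidate resonances
    (frequency within band, bandwidth below ``max_bandwidth_hz``), of
    which the four lowest are the formants.  Returns (None, meta) when the
    segment is unvoiced or fewer than four resonances are resolvable.
    """
    meta = {
        "analysis_fs": analysis_fs,
        "lpc_order": lpc_order,
        "method": "burg",
        "max_bandwidth_hz": max_bandwidth_hz,
    }
    x = np.asarray(x, dtype=float)
    if fs != analysis_fs:
        g = math.gcd(int(round(fs)), analysis_fs)
        x = sps.resample_poly(x, analysis_fs // g, int(round(fs)) // g)
    fsa = float(analysis_fs)
    _, f0, _ = frame_f0(x, fsa)
    if np.isfinite(f0).sum() < 2:
        return None, meta
    a = _lpc_burg(x, lpc_order)
    if a is None:
        return None, meta
    roots = np.roots(a)
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * fsa / (2 * np.pi)
    bws = -np.log(np.abs(roots)) * fsa / np.pi
    ok = (freqs > min_freq_hz) & (freqs < fsa / 2 - 100) & (bws < max_bandwidth_hz)
    cands = np.sort(freqs[ok])[:n_formants]
    if cands.size < n_formants or not np.all(np.diff(cands) > 0):
        return None, meta
    return FormantSet(*cands), meta


def formant_derived(
    F: FormantSet,
    reference_means: np.ndarray | None = None,
    reference_sds: np.ndarray | None = None,
) -> dict[str, float]:
    """Formant-derived prosodic features.

    * mean formant — arithmetic mean of F1..F4
    * delta_f — least-squares quarter-wave spacing: regression of F_i on
      (2i−1)/2 through the origin
    * fdisp — (F4 − F1)/3, the average adjacent spacing
    * fitch_vtl — mean over i of (2i−1)·c/(4·F_i)
    * mff — geometric mean of F1..F4
    * vtl_delta_f — c/(2·delta_f)
    * pF — mean standardized deviation of F_i from reference means/SDs
      (cohort-derived by default; NaN when no reference is supplied)
    """
    f = F.as_array()
    c = F.speed_of_sound_cm_s
    xi = (2 * np.arange(1, 5) - 1) / 2.0
    delta_f = float(np.sum(f * xi) / np.sum(xi**2))
    out = {
        "mean_formant": float(np.mean(f)),
        "delta_f": delta_f,
        "fdisp": float((f[3] - f[0]) / 3.0),
        "fitch_vtl": float(np.mean((2 * np.arange(1, 5) - 1) * c / (4 * f))),
        "mff": float(np.exp(np.mean(np.log(f)))),
        "vtl_delta_f": float(c / (2 * delta_f)),
    }
    if reference_means is not None and reference_sds is not None:
        mu = np.asarray(reference_means, dtype=float)
        sd = np.asarray(reference_sds, dtype=float)
        out["pF"] = float(np.mean((f - mu) / sd))
    else:
        out["pF"] = np.nan
    return out


# ---------------------------------------------------------------------------
# Syllable nuclei
# ---------------------------------------------------------------------------


def syllable_nuclei_features(
    x: np.ndarray,
    fs: float,
    dip_db: float = 2.0,
    min_pause_s: float = 0.3,
    frame_s: float = 0.030,
    hop_s: float = 0.010,
) -> dict[str, float]:
    """Speaking-rate features from the intensity contour.

    Syllable nuclei are intensity peaks (prominence >= ``dip_db``) above the
    segment's median intensity that fall on voiced frames; a voiced region
    whose contour has no internal dip counts as a single nucleus.  Pauses
    are unvoiced/low-intensity runs of at least ``min_pause_s``.

    Returns speech rate (nuclei/s), pause rate (pauses/s) and phonation
    time (fraction of the segment covered by syllabic regions).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty segment")
    duration = x.size / fs
    n = int(round(frame_s * fs))
    hop = int(round(hop_s * fs))
    starts = np.arange(0, max(x.size - n + 1, 1), hop)
    db = np.array([_safe_db(x[s : s + n]) for s in starts])
    _, f0, _ = frame_f0(x, fs, hop_s=hop_s)
    voiced = np.zeros(starts.size, dtype=bool)
    m = min(voiced.size, f0.size)
    voiced[:m] = np.isfinite(f0[:m])

    finite = db[np.isfinite(db)]
    if finite.size == 0 or not voiced.any():
        return {"speech_rate": 0.0, "pause_rate": _count_runs(
            np.ones(starts.size, dtype=bool), hop_s, min_pause_s) / duration,
            "phonation_time": np.nan}
    threshold = float(np.median(finite))

    # syllabic regions: maximal voiced runs reaching the intensity threshold
    n_nuclei = 0
    syllabic_s = 0.0
    for a, b in _runs(voiced):
        if np.nanmax(db[a:b]) < threshold:
            continue
        syllabic_s += (b - a) * hop_s
        peaks, _ = sps.find_peaks(np.nan_to_num(db[a:b], nan=-120.0),
                                  prominence=dip_db, height=threshold)
        n_nuclei += max(1, peaks.size)

    low = ~voiced | (db < threshold)
    n_pauses = _count_runs(low, hop_s, min_pause_s)
    return {
        "speech_rate": n_nuclei / duration,
        "pause_rate": n_pauses / duration,
        "phonation_time": syllabic_s / duration,
    }


def _safe_db(frame: np.ndarray) -> float:
    rms = float(np.sqrt(np.mean(frame**2)))
    return 20.0 * np.log10(rms) if rms > 0 else -np.inf


def _runs(mask: np.ndarray):
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, mask.size))
    return out


def _count_runs(mask: np.ndarray, hop_s: float, min_s: float) -> int:
    return sum(1 for a, b in _runs(mask) if (b - a) * hop_s >= min_s)


# ---------------------------------------------------------------------------
# Segment-level and daily composition
# ---------------------------------------------------------------------------


def extract_segment_features(x: np.ndarray, fs: float) -> tuple[dict, np.ndarray]:
    """All per-segment features plus the raw voiced-frame F0 values.

    pF is left NaN here; it needs a cohort reference distribution and is
    filled in at table level (see :func:`fill_pF`).
    """
    feats: dict[str, float] = {}
    track = track_periods(x, fs)
    feats.update(jitter_features(track))
    feats.update(shimmer_features(track))
    feats["hnr"] = hnr(x, fs)
    _, f0, _ = frame_f0(x, fs)
    voiced_f0 = f0[np.isfinite(f0)]
    mean_f0, std_f0 = f0_stats(voiced_f0)
    feats["mean_f0"], feats["std_f0"] = mean_f0, std_f0
    formants, _ = estimate_formants(x, fs)
    if formants is not None:
        f = formants.as_array()
        for i in range(4):
            feats[f"mean_f{i + 1}"] = float(f[i])
        feats.update(formant_derived(formants))
    else:
        for k in ("mean_f1", "mean_f2", "mean_f3", "mean_f4", "mean_formant",
                  "delta_f", "fdisp", "fitch_vtl", "mff", "pF", "vtl_delta_f"):
            feats[k] = np.nan
    feats.update(syllable_nuclei_features(x, fs))
    return feats, voiced_f0


def daily_aggregate(
    segment_features: list[dict],
    participant: str,
    date,
    f0_frames: list[np.ndarray] | None = None,
) -> dict:
    """One participant-day feature row: unweighted mean over segments,
    missing segment values excluded pairwise.

    When ``f0_frames`` is given, mean/std F0 are recomputed over the pooled
    voiced-frame F0 estimates of the whole day rather than averaged across
    segment summaries.
    """
    if not segment_features:
        raise ValueError("no segments for this day")
    keys = sorted({k for d in segment_features for k in d})
    row: dict = {"participant": participant, "date": date}
    for k in keys:
        vals = np.array([d[k] for d in segment_features if k in d], dtype=float)
        vals = vals[np.isfinite(vals)]
        row[k] = float(np.mean(vals)) if vals.size else np.nan
    if f0_frames is not None:
        pooled = np.concatenate([np.asarray(a, dtype=float) for a in f0_frames]) \
            if f0_frames else np.array([])
        row["mean_f0"], row["std_f0"] = f0_stats(pooled)
    row["n_segments"] = len(segment_features)
    return row


def fill_pF(table, formant_cols=("mean_f1", "mean_f2", "mean_f3", "mean_f4"),
            reference_means=None, reference_sds=None):
    """Fill the pF column of a daily feature table.

    The reference means/SDs default to the table's own formant
    distribution (cohort-derived normalization); external norms can be
    supplied instead.
    """
    import pandas as pd  # local import keeps numpy-only callers light

    df = table.copy()
    F = df[list(formant_cols)].to_numpy(dtype=float)
    mu = (np.asarray(reference_means, dtype=float)
          if reference_means is not None else np.nanmean(F, axis=0))
    sd = (np.asarray(reference_sds, dtype=float)
          if reference_sds is not None else np.nanstd(F, axis=0, ddof=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        df["pF"] = np.nanmean((F - mu) / sd, axis=1)
    return df
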