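"""Speech segmentation cascade for free-living smartwatch audio.

Stages, in order: silence removal (50-ms sliding frames, -20 dBFS
intensity floor), 2-s windowing with a 1-s step, frame-level voice-activity
scoring on 20-ms frames, binarisation at probability 0.7, merging of
above-threshold frames into utterances with a 250-ms minimum, and retention
of windows whose combined utterance time exceeds 75% of the window (strictly
more than 1.5 s of a 2-s window).  Daily usable-speech duration is the union
of retained-window intervals on the recording timeline, so the 50% window
overlap is never double counted.

The voice-activity detector is pluggable: anything that maps a 20-ms frame
to a probability in [0, 1] conforms.  The bundled
:class:`EnergyPeriodicityVAD` is a deterministic energy + autocorrelation
scorer adequate for synthetic and clean audio; a pretrained neural detector
can be plugged in through the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

SILENCE_FRAME_S = 0.050
SILENCE_THRESHOLD_DB = -20.0
WINDOW_S = 2.0
STEP_S = 1.0
VAD_FRAME_S = 0.020
VAD_THRESHOLD = 0.7
MIN_UTTERANCE_S = 0.250
COVERAGE_FRACTION = 0.75


@dataclass(frozen=True)
class AudioWindow:
    """A 2-s analysis window in original-recording coordinates."""

    start_s: float
    end_s: float
    samples: np.ndarray
    sample_rate_hz: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class UtteranceSpan:
    """A contiguous detected-speech interval, seconds."""

    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


class FrameScorer(Protocol):
    """VAD contract: one 20-ms frame in, one probability in [0, 1] out."""

    def __call__(self, frame: np.ndarray, sample_rate_hz: int) -> float: ...


def _frame_rms_db(frame: np.ndarray) -> float:
    rms = float(np.sqrt(np.mean(np.square(frame, dtype=float))))
    if rms <= 0:
        return -np.inf
    return 20.0 * np.log10(rms)


class EnergyPeriodicityVAD:
    """Deterministic frame scorer combining intensity and periodicity.

    The score is a logistic function of frame intensity (dBFS) scaled by the
    normalized autocorrelation peak in the pitch search range, so silence
    scores near 0, aperiodic noise stays below the 0.7 decision threshold,
    and voiced speech scores high.
    """

    def __init__(
        self,
        energy_floor_db: float = -30.0,
        energy_scale_db: float = 5.0,
        f0_min_hz: float = 60.0,
        f0_max_hz: float = 400.0,
    ):
        self.energy_floor_db = energy_floor_db
        self.energy_scale_db = energy_scale_db
        self.f0_min_hz = f0_min_hz
        self.f0_max_hz = f0_max_hz

    def __call__(self, frame: np.ndarray, sample_rate_hz: int) -> float:
        db = _frame_rms_db(frame)
        if not np.isfinite(db):
            return 0.0
        energy = 1.0 / (1.0 + np.exp(-(db - self.energy_floor_db) / self.energy_scale_db))
        from copdmon.features import _norm_autocorr

        lag_min = max(2, int(sample_rate_hz / self.f0_max_hz))
        lag_max = min(len(frame) - 2, int(sample_rate_hz / self.f0_min_hz))
        peak = 0.0
        res = _norm_autocorr(np.asarray(frame, dtype=float), lag_min, lag_max)
        if res is not None:
            peak = float(np.max(res[1]))
        periodicity = min(max(peak, 0.0), 1.0)
        return float(np.clip(energy * (0.25 + 0.75 * periodicity), 0.0, 1.0))


def remove_silence(
    waveform: np.ndarray,
    sample_rate_hz: int,
    frame_s: float = SILENCE_FRAME_S,
    intensity_threshold_db: float = SILENCE_THRESHOLD_DB,
) -> list[tuple[float, float]]:
    """Non-silent intervals (seconds) of a recording.

    Slides non-overlapping ``frame_s`` frames, computes RMS intensity in dB
    relative to full scale (amplitude 1.0), keeps frames at or above the
    threshold, and merges consecutive kept frames into maximal intervals.
    The trailing partial frame is dropped.
    """
    x = np.asarray(waveform, dtype=float)
    if x.size == 0:
        raise ValueError("empty waveform")
    if frame_s <= 0:
        raise ValueError("frame_s must be positive")
    n = int(round(frame_s * sample_rate_hz))
    n_frames = x.size // n
    if n_frames == 0:
        return []
    frames = x[: n_frames * n].reshape(n_frames, n)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(rms)
    keep = db >= intensity_threshold_db
    intervals: list[tuple[float, float]] = []
    start = None
    for i, k in enumerate(keep):
        if k and start is None:
            start = i
        elif not k and start is not None:
            intervals.append((start * frame_s, i * frame_s))
            start = None
    if start is not None:
        intervals.append((start * frame_s, n_frames * frame_s))
    return intervals


def window_signal(
    waveform: np.ndarray,
    sample_rate_hz: int,
    intervals: Sequence[tuple[float, float]],
    window_s: float = WINDOW_S,
    step_s: float = STEP_S,
) -> list[AudioWindow]:
    """Tile each non-silent interval with fixed windows at a fixed step.

    Windows lie in original-recording coordinates; the trailing remainder
    shorter than ``window_s`` is dropped.
    """
    x = np.asarray(waveform, dtype=float)
    windows: list[AudioWindow] = []
    n_win = int(round(window_s * sample_rate_hz))
    for start, end in intervals:
        t = start
        while t + window_s <= end + 1e-9:
            i0 = int(round(t * sample_rate_hz))
            windows.append(
                AudioWindow(t, t + window_s, x[i0 : i0 + n_win], sample_rate_hz)
            )
            t += step_s
    return windows


def vad_probabilities(
    window: AudioWindow,
    detector: FrameScorer,
    frame_s: float = VAD_FRAME_S,
) -> np.ndarray:
    """Per-frame speech probabilities for one window (20-ms frames).

    A 2-s window yields 100 probabilities; a trailing partial frame is
    dropped.  Detector outputs outside [0, 1] raise.
    """
    n = int(round(frame_s * window.sample_rate_hz))
    n_frames = len(window.samples) // n
    probs = np.empty(n_frames)
    for i in range(n_frames):
        p = float(detector(window.samples[i * n : (i + 1) * n], window.sample_rate_hz))
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"detector probability {p} outside [0, 1]")
        probs[i] = p
    return probs


def frames_to_utterances(
    probabilities: np.ndarray,
    threshold: float = VAD_THRESHOLD,
    min_utterance_s: float = MIN_UTTERANCE_S,
    frame_s: float = VAD_FRAME_S,
    offset_s: float = 0.0,
) -> list[UtteranceSpan]:
    """Merge consecutive above-threshold frames into utterance spans.

    Spans shorter than ``min_utterance_s`` are discarded.  ``offset_s``
    places spans in original-recording coordinates.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilities outside [0, 1]")
    speech = p >= threshold
    spans: list[UtteranceSpan] = []
    start = None
    for i, s in enumerate(speech):
        if s and start is None:
            start = i
        elif not s and start is not None:
            spans.append(
                UtteranceSpan(offset_s + start * frame_s, offset_s + i * frame_s)
            )
            start = None
    if start is not None:
        spans.append(
            UtteranceSpan(offset_s + start * frame_s, offset_s + speech.size * frame_s)
        )
    return [s for s in spans if s.duration_s >= min_utterance_s - 1e-9]


def classify_window(
    utterances: Sequence[UtteranceSpan],
    window_s: float = WINDOW_S,
    coverage_fraction: float = COVERAGE_FRACTION,
) -> str:
    """Label a window ``"speech"`` iff combined utterance time strictly
    exceeds ``coverage_fraction * window_s`` (1.5 s of a 2-s window)."""
    total = sum(u.duration_s for u in utterances)
    return "speech" if total > coverage_fraction * window_s else "non-speech"


def union_intervals(
    intervals: Sequence[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Union of possibly overlapping [start, end) intervals."""
    merged: list[list[float]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(a, b) for a, b in merged]


def daily_speech_duration(
    retained_windows: Sequence[tuple[float, float]],
) -> float:
    """Minutes of usable speech: union of retained-window intervals.

    ``retained_windows`` carries absolute (start, end) timestamps in
    seconds; overlapping windows from the 50% step are counted once.
    """
    return sum(b - a for a, b in union_intervals(retained_windows)) / 60.0


@dataclass
class RecordingResult:
    """Retained windows and unioned utterance spans for one recording."""

    retained_windows: list[AudioWindow]
    window_utterances: list[list[UtteranceSpan]]
    speech_spans: list[tuple[float, float]]  # unioned, recording timeline


def process_recording(
    waveform: np.ndarray,
    sample_rate_hz: int,
    detector: FrameScorer | None = None,
    silence_frame_s: float = SILENCE_FRAME_S,
    silence_threshold_db: float = SILENCE_THRESHOLD_DB,
    window_s: float = WINDOW_S,
    step_s: float = STEP_S,
    vad_threshold: float = VAD_THRESHOLD,
    min_utterance_s: float = MIN_UTTERANCE_S,
    coverage_fraction: float = COVERAGE_FRACTION,
) -> RecordingResult:
    """Run the full cascade on one recording.

    Utterance spans detected inside overlapping retained windows are
    unioned on the recording timeline before any duration bookkeeping.
    """
    detector = detector or EnergyPeriodicityVAD()
    intervals = remove_silence(
        waveform, sample_rate_hz, silence_frame_s, silence_threshold_db
    )
    windows = window_signal(waveform, sample_rate_hz, intervals, window_s, step_s)
    retained, per_window = [], []
    for w in windows:
        probs = vad_probabilities(w, detector)
        spans = frames_to_utterances(
            probs, vad_threshold, min_utterance_s, offset_s=w.start_s
        )
        if classify_window(spans, window_s, coverage_fraction) == "speech":
            retained.append(w)
            per_window.append(spans)
    speech_spans = union_intervals(
        [(s.start_s, s.end_s) for spans in per_window for s in spans]
    )
    return RecordingResult(retained, per_window, speech_spans)
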