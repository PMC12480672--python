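"""Daily HRV metrics from 1-Hz wearable heart rate, and daily step counts.

The heart-rate stream is segmented into contiguous runs (a gap of more than
half a sample period splits a run), runs shorter than 45 s are dropped so
the low-frequency HRV band (0.04-0.15 Hz) remains observable, each sample is
converted to an RR interval via HR x RR = 60,000 ms, and RR values outside
the physiological range [350, 1200] ms are removed.  Time-domain metrics
(mean NN, SDNN, pNN20) are computed per segment and averaged, unweighted,
over the segments of a day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RR_MIN_MS = 350.0
RR_MAX_MS = 1200.0
MIN_SEGMENT_S = 45.0
NN_DIFF_THRESHOLD_MS = 20.0


@dataclass
class RRSeries:
    """Gap-segmented RR intervals (ms) for one participant-day.

    ``segments`` holds one entry per retained heart-rate run; each entry is a
    list of sub-arrays split wherever a range-filtered sample was removed, so
    successive-difference statistics never bridge a removal.
    """

    segments: list[list[np.ndarray]] = field(default_factory=list)
    participant: str | None = None
    source_day: object | None = None


@dataclass(frozen=True)
class HRVDaily:
    mean_nn_ms: float
    sdnn_ms: float
    pnn20_pct: float
    n_segments: int
    participant: str | None = None
    date: object | None = None


def segment_hr(
    timestamps_s: np.ndarray,
    hr_bpm: np.ndarray,
    sample_period_s: float = 1.0,
    min_segment_s: float = MIN_SEGMENT_S,
    gap_tolerance_s: float = 0.5,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a timestamped 1-Hz stream into contiguous runs >= 45 s.

    A run's duration is ``n_samples * sample_period_s``; any inter-sample
    gap exceeding ``sample_period_s + gap_tolerance_s`` starts a new run.
    """
    t = np.asarray(timestamps_s, dtype=float)
    hr = np.asarray(hr_bpm, dtype=float)
    if t.size == 0:
        return []
    order = np.argsort(t, kind="stable")
    t, hr = t[order], hr[order]
    breaks = np.nonzero(np.diff(t) > sample_period_s + gap_tolerance_s)[0] + 1
    runs = []
    for ts, hs in zip(np.split(t, breaks), np.split(hr, breaks)):
        if ts.size * sample_period_s >= min_segment_s:
            runs.append((ts, hs))
    return runs


def hr_to_rr(hr_bpm):
    """RR interval (ms) from heart rate (bpm): RR = 60000 / HR."""
    hr = np.asarray(hr_bpm, dtype=float)
    if np.any(hr <= 0):
        raise ValueError("heart rate must be positive")
    out = 60000.0 / hr
    return float(out) if out.ndim == 0 else out


def filter_rr(
    rr_ms: np.ndarray,
    lo: float = RR_MIN_MS,
    hi: float = RR_MAX_MS,
    bridge_removals: bool = False,
) -> list[np.ndarray]:
    """Range-filter RR intervals to [lo, hi] inclusive.

    Returns the retained values as sub-arrays split at each removal (the
    default), so successive-difference pairs never span a removed sample;
    with ``bridge_removals`` the retained values form a single run.
    """
    rr = np.asarray(rr_ms, dtype=float)
    keep = (rr >= lo) & (rr <= hi)
    if bridge_removals:
        kept = rr[keep]
        return [kept] if kept.size else []
    out: list[np.ndarray] = []
    start = None
    for i, k in enumerate(keep):
        if k and start is None:
            start = i
        elif not k and start is not None:
            out.append(rr[start:i].copy())
            start = None
    if start is not None:
        out.append(rr[start:].copy())
    return out


def _segment_metrics(runs: list[np.ndarray]) -> tuple[float, float, float] | None:
    """Time-domain metrics for one segment given its removal-split runs."""
    values = np.concatenate(runs) if runs else np.array([])
    if values.size < 2:
        return None
    mean_nn = float(np.mean(values))
    sdnn = float(np.std(values, ddof=1))
    diffs = np.concatenate(
        [np.abs(np.diff(run)) for run in runs if run.size >= 2] or [np.array([])]
    )
    if diffs.size == 0:
        pnn20 = 0.0
    else:
        pnn20 = 100.0 * float(np.mean(diffs > NN_DIFF_THRESHOLD_MS))
    return mean_nn, sdnn, pnn20


def hrv_metrics(rr: RRSeries) -> HRVDaily | None:
    """Daily HRV summary: unweighted mean of per-segment metrics.

    Returns None when no segment holds >= 2 retained intervals (the day is
    reported as missing downstream).
    """
    per_segment = [m for m in (_segment_metrics(runs) for runs in rr.segments) if m]
    if not per_segment:
        return None
    arr = np.array(per_segment)
    return HRVDaily(
        mean_nn_ms=float(arr[:, 0].mean()),
        sdnn_ms=float(arr[:, 1].mean()),
        pnn20_pct=float(arr[:, 2].mean()),
        n_segments=len(per_segment),
        participant=rr.participant,
        date=rr.source_day,
    )


def stream_to_rrseries(
    timestamps_s: np.ndarray,
    hr_bpm: np.ndarray,
    participant: str | None = None,
    date=None,
    **segment_kwargs,
) -> RRSeries:
    """Full chain for one day's stream: segment, convert, range-filter."""
    rr = RRSeries(participant=participant, source_day=date)
    for _, hr in segment_hr(timestamps_s, hr_bpm, **segment_kwargs):
        runs = filter_rr(hr_to_rr(hr))
        if runs:
            rr.segments.append(runs)
    return rr


def daily_hrv(hr_stream: pd.DataFrame) -> pd.DataFrame:
    """HRV per participant-day from a (participant, timestamp, hr_bpm) table.

    ``timestamp`` may be epoch seconds or datetimes; days are calendar days.
    """
    df = hr_stream.copy()
    ts = df["timestamp"]
    if not np.issubdtype(ts.dtype, np.number):
        ts = pd.to_datetime(ts).astype("int64") / 1e9
    df["_t"] = ts.astype(float)
    df["_date"] = pd.to_datetime(df["_t"], unit="s").dt.normalize()
    rows = []
    for (participant, date), grp in df.groupby(["participant", "_date"]):
        series = stream_to_rrseries(
            grp["_t"].to_numpy(), grp["hr_bpm"].to_numpy(), participant, date
        )
        daily = hrv_metrics(series)
        if daily is not None:
            rows.append(
                {
                    "participant": participant,
                    "date": date,
                    "hrv_mean_nn": daily.mean_nn_ms,
                    "hrv_sdnn": daily.sdnn_ms,
                    "hrv_pnn20": daily.pnn20_pct,
                    "n_segments": daily.n_segments,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "date",
            "hrv_mean_nn",
            "hrv_sdnn",
            "hrv_pnn20",
            "n_segments",
        ],
    )


def daily_steps(step_records: pd.DataFrame) -> pd.DataFrame:
    """Daily step totals from (participant, date, steps) records.

    Multiple records for the same day are summed; negative counts are
    rejected.  Days with no record are simply absent.
    """
    if (step_records["steps"] < 0).any():
        raise ValueError("negative step counts")
    out = (
        step_records.assign(date=pd.to_datetime(step_records["date"]))
        .groupby(["participant", "date"], as_index=False)["steps"]
        .sum()
        .rename(columns={"steps": "pa_steps"})
    )
    return out
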