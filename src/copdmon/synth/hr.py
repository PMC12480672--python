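"""Synthetic 1-Hz heart-rate streams with known RR ground truth.

The underlying RR process is AR(1) Gaussian with a stationary mean and SD
(the planted SDNN); a configurable fraction of successive steps is forced
to exceed 20 ms in magnitude so pNN20 is controllable.  RR is converted to
heart rate through HR × RR = 60,000 and emitted as timestamped 1-Hz
samples.  To mimic the watch's 2-min-on / 8-min-off duty cycle, samples
arrive in 120-s recording bursts; dropout removes contiguous gaps inside
bursts.  The generator records its retained RR list per contiguous run as
ground truth for the HRV pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BURST_S = 120  # 2-min recording burst
IDLE_S = 480  # 8-min idle between bursts (20% duty cycle)


@dataclass
class HRStream:
    """Timestamped 1-Hz heart-rate samples plus ground truth."""

    timestamps_s: np.ndarray
    hr_bpm: np.ndarray
    # ground truth: RR (ms) per contiguous retained run, aligned with the
    # timestamp runs the pipeline will recover
    true_rr_runs: list[np.ndarray] = field(default_factory=list)

    def to_frame(self, participant: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"timestamp": self.timestamps_s, "hr_bpm": self.hr_bpm})
        if participant is not None:
            df.insert(0, "participant", participant)
        return df


def _ar1_rr(n: int, mean_rr_ms: float, sdnn_ms: float, phi: float,
            prob_large_delta: float, rng: np.random.Generator) -> np.ndarray:
    rr = np.empty(n)
    innov_sd = sdnn_ms * np.sqrt(max(1.0 - phi * phi, 0.0))
    rr[0] = mean_rr_ms + sdnn_ms * rng.standard_normal()
    forced = rng.random(n) < prob_large_delta
    for t in range(1, n):
        if forced[t] and sdnn_ms > 0:
            step = (21.0 + abs(rng.standard_normal()) * 10.0) * rng.choice((-1.0, 1.0))
            rr[t] = rr[t - 1] + step
        else:
            rr[t] = mean_rr_ms + phi * (rr[t - 1] - mean_rr_ms) \
                + innov_sd * rng.standard_normal()
    return rr


def gen_hr_stream(
    n_days: int,
    mean_rr_ms: float = 700.0,
    sdnn_ms: float = 40.0,
    prob_large_delta: float = 0.1,
    dropout_rate: float = 0.0,
    seed: int = 0,
    bursts_per_day: int = 8,
    burst_s: int = BURST_S,
    start_s: float = 0.0,
    ar_phi: float = 0.9,
) -> HRStream:
    """Generate a duty-cycled 1-Hz heart-rate stream over ``n_days``.

    ``dropout_rate`` is the fraction of samples removed, taken out in
    contiguous gaps (one gap per burst when nonzero).  Deterministic for a
    fixed seed.
    """
    if not (350.0 < mean_rr_ms < 1200.0):
        raise ValueError("mean_rr_ms must lie in (350, 1200)")
    if not (0.0 <= dropout_rate < 1.0):
        raise ValueError("dropout_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ts_all: list[np.ndarray] = []
    hr_all: list[np.ndarray] = []
    truth: list[np.ndarray] = []
    for day in range(n_days):
        day_start = start_s + day * 86400.0
        for b in range(bursts_per_day):
            t0 = day_start + b * (burst_s + IDLE_S)
            rr = _ar1_rr(burst_s, mean_rr_ms, sdnn_ms, ar_phi,
                         prob_large_delta, rng)
            t = t0 + np.arange(burst_s, dtype=float)
            keep = np.ones(burst_s, dtype=bool)
            n_drop = int(round(dropout_rate * burst_s))
            if n_drop > 0:
                g0 = int(rng.integers(0, burst_s - n_drop + 1))
                keep[g0 : g0 + n_drop] = False
            # split retained samples into contiguous runs for the truth record
            idx = np.nonzero(keep)[0]
            if idx.size:
                breaks = np.nonzero(np.diff(idx) > 1)[0] + 1
                for run in np.split(idx, breaks):
                    truth.append(rr[run].copy())
            ts_all.append(t[keep])
            hr_all.append(60000.0 / rr[keep])
    return HRStream(
        np.concatenate(ts_all) if ts_all else np.zeros(0),
        np.concatenate(hr_all) if hr_all else np.zeros(0),
        truth,
    )
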