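"""Write a full-fidelity synthetic study directory.

Materializes a (small) cohort as the raw streams the pipeline ingests:
per participant-day WAV recordings whose planted voice parameters are
driven by the cohort table's z-scored feature values, 1-Hz heart-rate CSVs,
a daily step-count CSV, a symptom-diary CSV, and a JSON ground-truth
sidecar holding the seed and every planted parameter.

Mapping from z-scores to physical voice/HRV parameters uses realistic
centres and spreads (e.g. jitter 1.0 ± 0.3 %, SDNN 40 ± 10 ms, steps
1609 ± 2069 per day as in elderly COPD cohorts), clipped to valid ranges.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from copdmon.outcomes import ALL_SYMPTOMS
from copdmon.synth.cohort import CohortSpec, gen_cohort
from copdmon.synth.hr import gen_hr_stream
from copdmon.synth.voice import VoiceSpec, gen_voice, write_wav


def _clip(x, lo, hi):
    return float(np.clip(x, lo, hi))


def write_cohort_streams(
    spec: CohortSpec,
    out_dir: Path,
    recordings_per_day: int = 2,
    recording_s: float = 6.0,
    sample_rate_hz: int = 16000,
) -> dict:
    """Generate and write every raw input stream for a cohort.

    Returns the ground-truth record (also written to ``truth.json``).
    Audio volume scales with cohort size; keep cohorts small when calling
    this full-fidelity writer.
    """
    out_dir = Path(out_dir)
    (out_dir / "audio").mkdir(parents=True, exist_ok=True)
    (out_dir / "hr").mkdir(exist_ok=True)

    table, truth = gen_cohort(spec)
    ss = np.random.SeedSequence(spec.seed)
    audio_seed, hr_seed = (int(s.generate_state(1)[0] % (2**31))
                           for s in ss.spawn(2))

    # --- audio: one or more short recordings per day with speech data -----
    voice_truth = {}
    k = 0
    for _, row in table.iterrows():
        if not np.isfinite(row["jitter"]):
            continue  # speech stream missing that day
        day = pd.Timestamp(row["date"]).strftime("%Y%m%d")
        for rec in range(recordings_per_day):
            spec_v = VoiceSpec(
                duration_s=recording_s,
                f0_hz=_clip(140 + 15 * row["mean_f0"], 80, 300),
                jitter_pct=_clip(1.0 + 0.3 * row["jitter"], 0.1, 5.0),
                shimmer_pct=_clip(5.0 + 1.5 * row["shimmer"], 0.5, 15.0),
                noise_snr_db=25.0,
                syllable_pattern=((2.0, 0.4), (1.6, 0.4), (1.6, 0.0)),
                sample_rate_hz=sample_rate_hz,
                seed=audio_seed + k,
            )
            k += 1
            sample = gen_voice(spec_v)
            name = f"{row['participant']}_{day}_r{rec:02d}.wav"
            write_wav(out_dir / "audio" / name, sample.samples, sample_rate_hz)
            voice_truth[name] = {
                "f0_hz": spec_v.f0_hz,
                "jitter_pct": spec_v.jitter_pct,
                "shimmer_pct": spec_v.shimmer_pct,
            }

    # --- heart rate: one CSV per participant ------------------------------
    epoch = pd.Timestamp("2024-01-01").timestamp()
    for i, (participant, grp) in enumerate(table.groupby("participant")):
        frames = []
        for j, (_, row) in enumerate(grp.iterrows()):
            if not np.isfinite(row["hrv_mean_nn"]):
                continue
            day_offset = (pd.Timestamp(row["date"])
                          - pd.Timestamp("2024-01-01")).days
            stream = gen_hr_stream(
                n_days=1,
                mean_rr_ms=_clip(700 + 60 * row["hrv_mean_nn"], 400, 1100),
                sdnn_ms=_clip(40 + 10 * row["hrv_sdnn"], 5, 120),
                prob_large_delta=_clip(0.10 + 0.04 * row["hrv_pnn20"], 0.0, 0.5),
                dropout_rate=0.05,
                seed=hr_seed + i * 1000 + j,
                bursts_per_day=4,
                start_s=epoch + day_offset * 86400.0 + 8 * 3600.0,
            )
            frames.append(stream.to_frame(participant))
        if frames:
            pd.concat(frames).to_csv(out_dir / "hr" / f"{participant}.csv",
                                     index=False)

    # --- steps and diary ---------------------------------------------------
    steps = table.loc[np.isfinite(table["pa_steps"]),
                      ["participant", "date"]].copy()
    steps["steps"] = np.clip(
        np.round(1609 + 2069 * table.loc[steps.index, "pa_steps"]), 0, None
    ).astype(int)
    steps.to_csv(out_dir / "steps.csv", index=False)

    diary = table.loc[table["daily_score"].notna(),
                      ["participant", "date", *ALL_SYMPTOMS]]
    diary.to_csv(out_dir / "diary.csv", index=False)

    table.to_csv(out_dir / "cohort_table.csv", index=False)
    truth = {**truth, "voice_parameters": voice_truth,
             "streams": {"recordings_per_day": recordings_per_day,
                         "recording_s": recording_s,
                         "sample_rate_hz": sample_rate_hz}}
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
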