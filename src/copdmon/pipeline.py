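"""End-to-end orchestration: raw streams to fitted reports.

Stage order: audio segmentation -> speech features -> HRV & activity ->
symptom outcomes -> merged analysis table -> two-step statistics.  Every
stage writes its table to the run directory and the manifest records a
SHA-256 of each output, so identical config + seed reproduce
hash-identical artifacts.  A stage failure halts the run with the failing
stage named; earlier outputs are preserved.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from copdmon import audio as audio_mod
from copdmon import features as feat_mod
from copdmon import outcomes as out_mod
from copdmon import physio as physio_mod
from copdmon import stats as stats_mod
from copdmon._naming import SPEECH_FEATURES
from copdmon.config import RunConfig
from copdmon.synth.cohort import CohortSpec
from copdmon.synth.streams import write_cohort_streams
from copdmon.synth.voice import read_wav

_WAV_RE = re.compile(r"(?P<participant>[^_]+)_(?P<date>\d{8})_r\d+\.wav$")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False)
    manifest["outputs"][path.name] = _sha256(path)


def stage_simulate(cfg: RunConfig, run_dir: Path, manifest: dict) -> Path:
    spec = CohortSpec(
        n_participants=cfg.n_participants,
        n_days=cfg.n_days,
        fixed_effects={"jitter": -0.3},
        interaction_effects={("jitter", "hrv_pnn20"): 0.5},
        missingness_rates={"speech": 0.1, "hrv": 0.1, "steps": 0.1,
                           "diary": 0.05},
        seed=cfg.stage_seeds()[0],
    )
    data_dir = run_dir / "synthetic_inputs"
    write_cohort_streams(spec, data_dir)
    manifest["synthetic"] = True
    return data_dir


def stage_audio(cfg: RunConfig, audio_dir: Path, run_dir: Path,
                manifest: dict) -> pd.DataFrame:
    """Segment every recording; emit retained windows and daily durations."""
    detector = audio_mod.EnergyPeriodicityVAD()
    window_rows, span_rows = [], []
    for wav in sorted(Path(audio_dir).glob("*.wav")):
        m = _WAV_RE.search(wav.name)
        if not m:
            continue
        participant = m["participant"]
        date = pd.Timestamp(m["date"])
        x, fs = read_wav(wav)
        res = audio_mod.process_recording(
            x, fs, detector,
            silence_frame_s=cfg.silence_frame_s,
            silence_threshold_db=cfg.silence_threshold_db,
            window_s=cfg.window_s, step_s=cfg.step_s,
            vad_threshold=cfg.vad_threshold,
            min_utterance_s=cfg.min_utterance_s,
            coverage_fraction=cfg.window_coverage)
        for w, spans in zip(res.retained_windows, res.window_utterances):
            window_rows.append({
                "participant": participant, "date": date,
                "recording": wav.name, "start_s": w.start_s,
                "end_s": w.end_s,
                "total_utterance_s": sum(s.duration_s for s in spans)})
        for a, b in res.speech_spans:
            span_rows.append({"participant": participant, "date": date,
                              "recording": wav.name, "start_s": a, "end_s": b})
    windows = pd.DataFrame(window_rows, columns=[
        "participant", "date", "recording", "start_s", "end_s",
        "total_utterance_s"])
    spans = pd.DataFrame(span_rows, columns=[
        "participant", "date", "recording", "start_s", "end_s"])
    daily = (windows.groupby(["participant", "date"])
             .apply(lambda g: audio_mod.daily_speech_duration(
                 list(zip(g["start_s"], g["end_s"]))),
                 include_groups=False)
             .rename("speech_minutes").reset_index()
             if len(windows) else
             pd.DataFrame(columns=["participant", "date", "speech_minutes"]))
    _write(windows, run_dir / "retained_windows.csv", manifest)
    _write(spans, run_dir / "speech_spans.csv", manifest)
    _write(daily, run_dir / "daily_speech_duration.csv", manifest)
    return spans


def stage_features(cfg: RunConfig, audio_dir: Path, spans: pd.DataFrame,
                   run_dir: Path, manifest: dict,
                   min_span_s: float = 0.5) -> pd.DataFrame:
    """Per-utterance feature extraction, aggregated to participant-days."""
    rows = []
    for (participant, date), grp in spans.groupby(["participant", "date"]):
        seg_feats, f0_frames = [], []
        for rec, rgrp in grp.groupby("recording"):
            x, fs = read_wav(Path(audio_dir) / rec)
            for _, r in rgrp.iterrows():
                if r["end_s"] - r["start_s"] < min_span_s:
                    continue
                seg = x[int(r["start_s"] * fs): int(r["end_s"] * fs)]
                feats, f0 = feat_mod.extract_segment_features(seg, fs)
                seg_feats.append(feats)
                f0_frames.append(f0)
        if seg_feats:
            rows.append(feat_mod.daily_aggregate(seg_feats, participant,
                                                 pd.Timestamp(date), f0_frames))
    daily = pd.DataFrame(rows)
    if len(daily):
        daily = feat_mod.fill_pF(daily)
        order = ["participant", "date", *SPEECH_FEATURES, "n_segments"]
        daily = daily[[c for c in order if c in daily.columns]]
    _write(daily, run_dir / "daily_speech_features.csv", manifest)
    return daily


def stage_hrv(cfg: RunConfig, hr_dir: Path, steps_csv: Path, run_dir: Path,
              manifest: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    frames = [pd.read_csv(f) for f in sorted(Path(hr_dir).glob("*.csv"))]
    hrv = (physio_mod.daily_hrv(pd.concat(frames, ignore_index=True))
           if frames else pd.DataFrame(columns=[
               "participant", "date", "hrv_mean_nn", "hrv_sdnn",
               "hrv_pnn20", "n_segments"]))
    steps = physio_mod.daily_steps(pd.read_csv(steps_csv))
    _write(hrv, run_dir / "daily_hrv.csv", manifest)
    _write(steps, run_dir / "daily_steps.csv", manifest)
    return hrv, steps


def stage_outcomes(cfg: RunConfig, diary_csv: Path, run_dir: Path,
                   manifest: dict) -> pd.DataFrame:
    diary = pd.read_csv(diary_csv)
    scores = out_mod.score_diary(diary)
    flagged, _ = out_mod.detect_exacerbations(
        scores, threshold=cfg.exacerbation_threshold,
        strict=cfg.strict_exacerbation)
    _write(flagged, run_dir / "daily_outcomes.csv", manifest)
    return flagged


def merge_analysis_table(speech: pd.DataFrame, hrv: pd.DataFrame,
                         steps: pd.DataFrame, outcomes_df: pd.DataFrame,
                         demographics: pd.DataFrame | None = None
                         ) -> pd.DataFrame:
    """Join daily streams into the long-format analysis table."""
    for df in (speech, hrv, steps, outcomes_df):
        if len(df):
            df["date"] = pd.to_datetime(df["date"])
    table = outcomes_df.copy()
    for df in (speech, hrv.drop(columns=["n_segments"], errors="ignore"),
               steps):
        if len(df):
            table = table.merge(df, on=["participant", "date"], how="left")
    if demographics is not None:
        table = table.merge(demographics, on="participant", how="left")
    return table


def stage_stats(cfg: RunConfig, table: pd.DataFrame, run_dir: Path,
                manifest: dict) -> dict:
    """Two-step procedure: screen, prune, interact, moderate, report."""
    from copdmon.plots import interaction_plot

    present = [f for f in SPEECH_FEATURES
               if f in table and table[f].notna().sum() >= 3
               and table[f].std() > 0]
    covs = [c for c in stats_mod.PHYSIO_COVARIATES
            if c in table and table[c].notna().sum() >= 3
            and table[c].std() > 0]
    ztable = stats_mod.zscore(table, present + covs)
    out: dict = {}
    screens = {}
    for outcome in ("score", "exacerbation"):
        if outcome == "exacerbation" and \
                table["exacerbation_day"].dropna().nunique() < 2:
            continue
        screen = stats_mod.univariate_screen(
            ztable, present, outcome, alpha=cfg.alpha,
            bh_correct=cfg.bh_correct)
        screens[outcome] = screen
        _write(screen, run_dir / f"screen_{outcome}.csv", manifest)
        sig = list(screen.loc[screen["significant"] & screen["converged"],
                              "term"])
        terms = stats_mod.build_interaction_design(sig, covs)
        kept, removal_log = stats_mod.vif_prune(ztable, terms,
                                                cfg.vif_cutoff)
        _write(removal_log, run_dir / f"vif_removals_{outcome}.csv", manifest)
        if kept:
            try:
                multi = stats_mod.fit_multivariate(ztable, kept, outcome)
                _write(multi.to_frame(),
                       run_dir / f"multivariate_{outcome}.csv", manifest)
                out[f"multivariate_{outcome}"] = multi
                mod_feature, moderator = _notable_interaction(multi)
                if moderator is not None:
                    strata = stats_mod.moderation_stratify(
                        ztable, mod_feature, moderator, outcome)
                    sdf = _strata_frame(strata)
                    _write(sdf, run_dir / f"moderation_{outcome}.csv",
                           manifest)
                    interaction_plot(
                        strata, mod_feature, moderator,
                        run_dir / f"moderation_{outcome}.svg")
            except ValueError:
                pass
    out["screens"] = screens
    return out


def _notable_interaction(multi) -> tuple[str | None, str | None]:
    """Pick the feature/moderator of the most significant 2-way term."""
    best_p, pick = np.inf, (None, None)
    for r in multi.term_results:
        parts = r.term.split(":")
        if len(parts) == 2 and parts[1] in stats_mod.PHYSIO_COVARIATES \
                and parts[0] not in stats_mod.PHYSIO_COVARIATES \
                and np.isfinite(r.p_value) and r.p_value < best_p:
            best_p, pick = r.p_value, (parts[0], parts[1])
    return pick


def _strata_frame(strata) -> pd.DataFrame:
    rows = []
    for s in strata:
        rows.append({
            "stratum": s.label, "n_rows": s.n_rows,
            "n_participants": s.n_participants,
            "estimate": np.nan if s.empty else s.result.estimate,
            "ci_low": np.nan if s.empty else s.result.ci_low,
            "ci_high": np.nan if s.empty else s.result.ci_high,
            "p_value": np.nan if s.empty else s.result.p_value,
            "stars": "" if s.empty else s.result.stars,
            "note": "empty due to a lack of data" if s.empty else ""})
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig, run_dir=None) -> Path:
    """Execute every stage; returns the run directory."""
    cfg.validate()
    run_dir = Path(run_dir or cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: getattr(cfg, k)
                                 for k in cfg.__dataclass_fields__},
                      "protocol_defaults": cfg.protocol_defaults(),
                      "outputs": {}}
    stage = "simulate"
    try:
        if cfg.synthetic:
            data_dir = stage_simulate(cfg, run_dir, manifest)
            audio_dir, hr_dir = data_dir / "audio", data_dir / "hr"
            steps_csv, diary_csv = data_dir / "steps.csv", data_dir / "diary.csv"
            demographics = (pd.read_csv(data_dir / "cohort_table.csv")
                            [["participant", "age", "sex", "smoking"]]
                            .drop_duplicates())
        else:
            audio_dir, hr_dir = Path(cfg.audio_dir), Path(cfg.hr_dir)
            steps_csv, diary_csv = Path(cfg.steps_csv), Path(cfg.diary_csv)
            demographics = None
        stage = "audio"
        spans = stage_audio(cfg, audio_dir, run_dir, manifest)
        stage = "features"
        speech = stage_features(cfg, audio_dir, spans, run_dir, manifest)
        stage = "hrv"
        hrv, steps = stage_hrv(cfg, hr_dir, steps_csv, run_dir, manifest)
        stage = "outcomes"
        outcomes_df = stage_outcomes(cfg, diary_csv, run_dir, manifest)
        stage = "merge"
        table = merge_analysis_table(speech, hrv, steps, outcomes_df,
                                     demographics)
        _write(table, run_dir / "analysis_table.csv", manifest)
        stage = "stats"
        stage_stats(cfg, table, run_dir, manifest)
    except Exception as exc:  # noqa: BLE001 - named-stage halt per contract
        (run_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str))
        raise StageError(stage, exc) from exc
    import copdmon

    manifest["versions"] = {"copdmon": copdmon.__version__,
                            "numpy": np.__version__,
                            "pandas": pd.__version__}
    (run_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return run_dir
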