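"""Daily symptom scoring and exacerbation labelling.

Implements the London COPD cohort daily symptom questionnaire rule: three
major symptoms (change in sputum colour, increased breathlessness, increased
sputum amount) score 5 points each, five minor symptoms (cold, fever,
increased wheezing, sore throat, worsening cough) score 1 point each.  An
exacerbation is two or more consecutive calendar days with a daily score of
6 or above (one major plus one minor symptom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MAJOR_SYMPTOMS = ("sputum_color", "breathlessness", "sputum_amount")
MINOR_SYMPTOMS = ("cold", "fever", "wheezing", "sore_throat", "cough")
ALL_SYMPTOMS = MAJOR_SYMPTOMS + MINOR_SYMPTOMS

MAJOR_WEIGHT = 5
MINOR_WEIGHT = 1
EXACERBATION_THRESHOLD = 6


@dataclass(frozen=True)
class Episode:
    """One exacerbation episode: a maximal qualifying run of days."""

    participant: str
    start: pd.Timestamp
    end: pd.Timestamp

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


def daily_score(flags) -> int:
    """Score one diary day.

    Parameters
    ----------
    flags : mapping or iterable
        Either a mapping symptom-name -> bool covering all eight symptoms,
        or an iterable of the symptom names reported worse than usual.

    Returns
    -------
    int in [0, 20]
    """
    if hasattr(flags, "keys"):
        missing = [s for s in ALL_SYMPTOMS if s not in flags.keys()]
        if missing:
            raise ValueError(f"diary day is missing symptom flags: {missing}")
        present = {s for s in ALL_SYMPTOMS if bool(flags[s])}
    else:
        present = set(flags)
        unknown = present - set(ALL_SYMPTOMS)
        if unknown:
            raise ValueError(f"unknown symptom names: {sorted(unknown)}")
    n_major = sum(1 for s in MAJOR_SYMPTOMS if s in present)
    n_minor = sum(1 for s in MINOR_SYMPTOMS if s in present)
    return MAJOR_WEIGHT * n_major + MINOR_WEIGHT * n_minor


def score_diary(diary: pd.DataFrame) -> pd.DataFrame:
    """Score a diary table with one row per participant-day.

    Expects columns ``participant``, ``date`` and the eight symptom flags.
    Rows where any flag is missing get a missing score (no imputation).
    """
    out = diary[["participant", "date"]].copy()
    flags = diary[list(ALL_SYMPTOMS)]
    complete = flags.notna().all(axis=1)
    majors = flags[list(MAJOR_SYMPTOMS)].astype(float).sum(axis=1)
    minors = flags[list(MINOR_SYMPTOMS)].astype(float).sum(axis=1)
    score = MAJOR_WEIGHT * majors + MINOR_WEIGHT * minors
    out["daily_score"] = np.where(complete, score, np.nan)
    return out


def detect_exacerbations(
    scores: pd.DataFrame,
    threshold: int = EXACERBATION_THRESHOLD,
    strict: bool = False,
) -> tuple[pd.DataFrame, list[Episode]]:
    """Label exacerbation days from a calendar-ordered score series.

    A maximal run of >= 2 consecutive calendar days whose score meets the
    threshold (``score >= threshold`` by default; ``score > threshold`` when
    ``strict``) forms one episode; every day in the run is flagged.  A
    missing day (absent row or missing score) breaks consecutiveness.

    Parameters
    ----------
    scores : DataFrame with columns participant, date, daily_score.

    Returns
    -------
    (per-day table with ``exacerbation_day`` flag and optional
    ``exacerbation_episode_id``, list of Episode records)
    """
    df = scores.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values(["participant", "date"]).reset_index(drop=True)
    df["exacerbation_day"] = False
    df["exacerbation_episode_id"] = pd.array([pd.NA] * len(df), dtype="Int64")

    episodes: list[Episode] = []
    episode_id = 0
    for participant, grp in df.groupby("participant", sort=False):
        grp = grp.dropna(subset=["daily_score"])
        if grp.empty:
            continue
        qualifies = (
            grp["daily_score"] > threshold
            if strict
            else grp["daily_score"] >= threshold
        )
        run: list[int] = []  # row indices of the current consecutive run
        prev_date = None

        def close_run(run: list[int]) -> None:
            nonlocal episode_id
            if len(run) >= 2:
                start = df.loc[run[0], "date"]
                end = df.loc[run[-1], "date"]
                episodes.append(Episode(participant, start, end))
                df.loc[run, "exacerbation_day"] = True
                df.loc[run, "exacerbation_episode_id"] = episode_id
                episode_id += 1

        for idx, ok in zip(grp.index, qualifies):
            date = df.loc[idx, "date"]
            consecutive = prev_date is not None and (date - prev_date).days == 1
            if ok:
                if run and not consecutive:
                    close_run(run)
                    run = []
                run.append(idx)
            else:
                close_run(run)
                run = []
            prev_date = date
        close_run(run)

    return df, episodes
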