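"""Longitudinal synthetic cohort with planted statistical structure.

Each participant-day draws z-scored feature values (speech, HRV, steps); a
latent daily severity combines planted fixed effects, feature×moderator
interaction effects, demographic confounder effects, a per-participant
random intercept and Gaussian noise.  Severity maps to the eight diary
symptoms through per-symptom logistic links — major symptoms get steeper,
higher-threshold links — so the daily score rises stochastically with
severity and score-≥6 days concentrate at high severity, exercising
exacerbation detection.  Per-stream missingness is independent.

Demographics mirror a realistic elderly COPD cohort: age uniform on
55–93 years, one third female, smoking history {current 22%, never 11%,
ex-smoker 67%}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from copdmon import outcomes
from copdmon._naming import ALL_FEATURES

SMOKING_LEVELS = ("current", "never", "ex-smoker")
SMOKING_PROBS = (0.222, 0.111, 0.667)

# per-symptom logistic links on latent severity: P = sigmoid(slope*(sev-offset))
MAJOR_LINKS = {  # steeper and higher-threshold
    "sputum_color": (2.0, 1.5),
    "breathlessness": (2.0, 1.7),
    "sputum_amount": (2.0, 1.9),
}
MINOR_LINKS = {
    "cold": (1.5, 1.0),
    "fever": (1.5, 1.2),
    "wheezing": (1.5, 1.4),
    "sore_throat": (1.5, 1.6),
    "cough": (1.5, 1.8),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of one synthetic cohort."""

    n_participants: int = 20
    n_days: int = 100
    fixed_effects: dict = field(default_factory=dict)
    interaction_effects: dict = field(default_factory=dict)  # (feature, moderator) -> coef
    random_intercept_sd: float = 0.5
    residual_sd: float = 1.0
    confounder_effects: dict = field(
        default_factory=lambda: {"age": 0.1, "sex_female": -0.1, "smoking_current": 0.2}
    )
    missingness_rates: dict = field(
        default_factory=lambda: {"speech": 0.0, "hrv": 0.0, "steps": 0.0, "diary": 0.0}
    )
    exacerbation_threshold: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.n_days < 3:
            raise ValueError("need at least 3 days")
        for k, v in self.missingness_rates.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"missingness rate {k}={v} outside [0, 1]")
        unknown = (set(self.fixed_effects)
                   | {f for f, _ in self.interaction_effects}
                   | {m for _, m in self.interaction_effects}) - set(ALL_FEATURES)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def gen_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Generate the long analysis table and its ground-truth record.

    Returns one row per participant-day with feature values, confounders,
    symptom flags, daily score, exacerbation flag and the (hidden in real
    data) latent severity.  Missing streams are NaN.  Raises when the
    implied score distribution is degenerate (all zero or all maximal).
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_participants, spec.n_days
    rows = n * d

    participants = np.array([f"P{i + 1:02d}" for i in range(n)])
    age = rng.integers(55, 94, size=n)
    sex = np.where(rng.random(n) < 0.33, "female", "male")
    smoking = rng.choice(SMOKING_LEVELS, size=n, p=SMOKING_PROBS)
    intercepts = spec.random_intercept_sd * rng.standard_normal(n)

    feats = {f: rng.standard_normal(rows) for f in ALL_FEATURES}

    severity = np.zeros(rows)
    for f, beta in spec.fixed_effects.items():
        severity += beta * feats[f]
    for (f, m), gamma in spec.interaction_effects.items():
        severity += gamma * feats[f] * feats[m]
    p_idx = np.repeat(np.arange(n), d)
    age_z = (age - 74.0) / 11.0  # approx standardization of U(55, 93)
    conf = spec.confounder_effects
    severity += conf.get("age", 0.0) * age_z[p_idx]
    severity += conf.get("sex_female", 0.0) * (sex[p_idx] == "female")
    severity += conf.get("smoking_current", 0.0) * (smoking[p_idx] == "current")
    severity += intercepts[p_idx]
    severity += spec.residual_sd * rng.standard_normal(rows)

    table = pd.DataFrame(
        {
            "participant": participants[p_idx],
            "date": np.tile(
                pd.date_range("2024-01-01", periods=d, freq="D"), n
            ),
            **feats,
            "age": age[p_idx],
            "sex": sex[p_idx],
            "smoking": smoking[p_idx],
            "latent_severity": severity,
        }
    )

    for symptom, (slope, offset) in {**MAJOR_LINKS, **MINOR_LINKS}.items():
        p = _sigmoid(slope * (severity - offset))
        table[symptom] = rng.random(rows) < p

    scored = outcomes.score_diary(table)
    table["daily_score"] = scored["daily_score"]
    flagged, episodes = outcomes.detect_exacerbations(
        table[["participant", "date", "daily_score"]],
        threshold=spec.exacerbation_threshold,
    )
    table = table.merge(
        flagged[["participant", "date", "exacerbation_day",
                 "exacerbation_episode_id"]],
        on=["participant", "date"],
        how="left",
    )

    scores = table["daily_score"].dropna()
    if scores.empty or (scores == 0).all() or (scores == 20).all():
        raise ValueError("degenerate symptom score distribution")

    # independent per-stream missingness
    m = spec.missingness_rates
    from copdmon._naming import SPEECH_FEATURES, HRV_FEATURES

    speech_gone = rng.random(rows) < m.get("speech", 0.0)
    hrv_gone = rng.random(rows) < m.get("hrv", 0.0)
    steps_gone = rng.random(rows) < m.get("steps", 0.0)
    diary_gone = rng.random(rows) < m.get("diary", 0.0)
    table.loc[speech_gone, list(SPEECH_FEATURES)] = np.nan
    table.loc[hrv_gone, list(HRV_FEATURES)] = np.nan
    table.loc[steps_gone, "pa_steps"] = np.nan
    table["exacerbation_day"] = table["exacerbation_day"].astype("boolean")
    table.loc[diary_gone, "daily_score"] = np.nan
    table.loc[diary_gone, "exacerbation_day"] = pd.NA

    truth = {
        "seed": spec.seed,
        "n_participants": n,
        "n_days": d,
        "fixed_effects": dict(spec.fixed_effects),
        "interaction_effects": {
            f"{f}*{m_}": g for (f, m_), g in spec.interaction_effects.items()
        },
        "random_intercept_sd": spec.random_intercept_sd,
        "residual_sd": spec.residual_sd,
        "confounder_effects": dict(spec.confounder_effects),
        "missingness_rates": dict(spec.missingness_rates),
        "exacerbation_threshold": spec.exacerbation_threshold,
        "random_intercepts": {p: float(b) for p, b in zip(participants, intercepts)},
        "n_exacerbation_episodes": len(episodes),
    }
    return table, truth
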