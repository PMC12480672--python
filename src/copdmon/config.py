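"""Run configuration: one flat, human-editable mapping of every tunable.

Defaults reproduce the study protocol's printed processing constants
(silence gate −20 dB over 50-ms frames, 2-s windows with 1-s step, VAD
threshold 0.7, 250-ms utterance minimum, 75% window coverage, RR range
350–1200 ms, 45-s segment minimum, exacerbation threshold 6, VIF cutoff
20).  All randomness flows from the single top-level seed; stages derive
their own streams via ``numpy.random.SeedSequence(seed).spawn``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml


@dataclass
class RunConfig:
    # input streams (unused when running synthetically)
    audio_dir: str | None = None
    hr_dir: str | None = None
    steps_csv: str | None = None
    diary_csv: str | None = None
    out_dir: str = "copdmon_run"

    # audio cascade
    silence_frame_s: float = 0.050
    silence_threshold_db: float = -20.0
    window_s: float = 2.0
    step_s: float = 1.0
    vad_threshold: float = 0.7
    min_utterance_s: float = 0.250
    window_coverage: float = 0.75

    # HRV
    rr_min_ms: float = 350.0
    rr_max_ms: float = 1200.0
    min_segment_s: float = 45.0

    # outcomes & stats
    exacerbation_threshold: int = 6
    strict_exacerbation: bool = False
    vif_cutoff: float = 20.0
    alpha: float = 0.05
    bh_correct: bool = False

    # synthetic smoke cohort
    synthetic: bool = False
    n_participants: int = 3
    n_days: int = 8

    seed: int = 0

    def validate(self) -> "RunConfig":
        checks = [
            (0 < self.silence_frame_s, "silence_frame_s must be positive"),
            (0 <= self.vad_threshold <= 1, "vad_threshold must be in [0, 1]"),
            (0 < self.window_coverage <= 1, "window_coverage must be in (0, 1]"),
            (self.min_utterance_s > 0, "min_utterance_s must be positive"),
            (0 < self.step_s <= self.window_s, "step_s must be in (0, window_s]"),
            (0 < self.rr_min_ms < self.rr_max_ms, "RR bounds must be ordered"),
            (self.min_segment_s > 0, "min_segment_s must be positive"),
            (self.exacerbation_threshold >= 0, "exacerbation_threshold >= 0"),
            (self.vif_cutoff > 1, "vif_cutoff must exceed 1"),
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid configuration: {msg}")
        return self

    # --- serialization ----------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw).validate()

    def stage_seeds(self, n: int = 8) -> list[int]:
        """Deterministic per-stage seeds derived from the top-level seed."""
        return [int(s.generate_state(1)[0] % (2**31))
                for s in np.random.SeedSequence(self.seed).spawn(n)]

    def protocol_defaults(self) -> list[dict]:
        """Audit record of processing constants and what each one gates."""
        return [
            {"name": "silence_frame_s", "value": self.silence_frame_s,
             "role": "sliding intensity frame for silence removal (50 ms)"},
            {"name": "silence_threshold_db", "value": self.silence_threshold_db,
             "role": "intensity floor, dB re full scale (-20 dB)"},
            {"name": "window_s / step_s", "value": (self.window_s, self.step_s),
             "role": "2-s analysis windows with 1-s step (50% overlap)"},
            {"name": "vad_threshold", "value": self.vad_threshold,
             "role": "speech-probability binarization threshold (0.7)"},
            {"name": "min_utterance_s", "value": self.min_utterance_s,
             "role": "minimum utterance duration (250 ms)"},
            {"name": "window_coverage", "value": self.window_coverage,
             "role": "window retained when utterances exceed 75% (1.5 s of 2 s)"},
            {"name": "rr range", "value": (self.rr_min_ms, self.rr_max_ms),
             "role": "physiological RR interval range, ms (350-1200)"},
            {"name": "min_segment_s", "value": self.min_segment_s,
             "role": "minimum heart-rate run for HRV (45 s)"},
            {"name": "exacerbation_threshold", "value": self.exacerbation_threshold,
             "role": "daily symptom score threshold (6), two consecutive days"},
            {"name": "vif_cutoff", "value": self.vif_cutoff,
             "role": "variance inflation factor pruning cutoff (20)"},
        ]


def load_or_default(path=None, **overrides) -> RunConfig:
    cfg = RunConfig.from_yaml(path) if path else RunConfig()
    for k, v in overrides.items():
        if v is not None:
            setattr(cfg, k, v)
    return cfg.validate()
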