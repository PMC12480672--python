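"""Canonical feature names and their display forms.

Column names in every table produced by this package are valid Python
identifiers (usable in model formulas); reports translate them to the
conventional display names used in the voice/HRV literature, e.g.
``absolute_jitter`` -> ``absolute jitter``, ``hrv_pnn20`` -> ``HRV(pNN20)``.
"""

from __future__ import annotations

PHONATION_FEATURES = (
    "hnr",
    "jitter",
    "absolute_jitter",
    "ddp_jitter",
    "ppq5_jitter",
    "rap_jitter",
    "shimmer",
    "apq3_shimmer",
    "apq5_shimmer",
    "apq11_shimmer",
    "dda_shimmer",
)

PROSODIC_FEATURES = (
    "mean_f0",
    "std_f0",
    "mean_f1",
    "mean_f2",
    "mean_f3",
    "mean_f4",
    "mean_formant",
    "delta_f",
    "fdisp",
    "fitch_vtl",
    "mff",
    "pF",
    "vtl_delta_f",
)

SYLLABIC_FEATURES = ("pause_rate", "phonation_time", "speech_rate")

SPEECH_FEATURES = PHONATION_FEATURES + PROSODIC_FEATURES + SYLLABIC_FEATURES

HRV_FEATURES = ("hrv_mean_nn", "hrv_sdnn", "hrv_pnn20")
PHYSIO_FEATURES = HRV_FEATURES + ("pa_steps",)

ALL_FEATURES = SPEECH_FEATURES + PHYSIO_FEATURES

CONFOUNDERS = ("age", "sex", "smoking")

_DISPLAY = {
    "hnr": "HNR",
    "jitter": "jitter",
    "absolute_jitter": "absolute jitter",
    "ddp_jitter": "ddp jitter",
    "ppq5_jitter": "ppq5 jitter",
    "rap_jitter": "rap jitter",
    "shimmer": "shimmer",
    "apq3_shimmer": "apq3 shimmer",
    "apq5_shimmer": "apq5 shimmer",
    "apq11_shimmer": "apq11 shimmer",
    "dda_shimmer": "dda shimmer",
    "mean_f0": "mean F0",
    "std_f0": "std F0",
    "mean_f1": "mean F1",
    "mean_f2": "mean F2",
    "mean_f3": "mean F3",
    "mean_f4": "mean F4",
    "mean_formant": "mean formant",
    "delta_f": "delta_f",
    "fdisp": "fdisp",
    "fitch_vtl": "fitch_vtl",
    "mff": "mff",
    "pF": "pF",
    "vtl_delta_f": "vtl_delta_f",
    "pause_rate": "pause rate",
    "phonation_time": "phonation time",
    "speech_rate": "speech rate",
    "hrv_mean_nn": "HRV(mean NN)",
    "hrv_sdnn": "HRV(SDNN)",
    "hrv_pnn20": "HRV(pNN20)",
    "pa_steps": "PA(steps)",
}


def display_name(term: str) -> str:
    """Display form of a single column or a colon-joined interaction term."""
    return ":".join(_DISPLAY.get(p, p) for p in term.split(":"))
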