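"""Daily self-assessment questionnaire schema.

The questionnaire has ten items answered once per day on a smartphone.
Mood is the forecast target and is recorded on a 9-level ordinal scale
{-3, -2, -1, -0.5, 0, 0.5, 1, 2, 3}: negative values grade depression,
positive values grade mania, and the scale is denser around zero where
patients spend most of their time (euthymia).
"""

from __future__ import annotations

import numpy as np

#: The nine allowed mood levels, in increasing order.
MOOD_LEVELS = np.array([-3.0, -2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0])

#: Number of ordinal mood categories.
N_MOOD_LEVELS = len(MOOD_LEVELS)

#: Medicine adherence is categorical by design.
MEDICINE_CATEGORIES = ("taken", "not_taken", "taken_with_changes")

#: Raw questionnaire items in questionnaire order, and their allowed
#: (min, max) ranges.  ``medicine`` is categorical and handled separately.
ITEM_RANGES = {
    "activity": (-3, 3),
    "alcohol": (0, 10),  # open-ended "10+" capped at 10
    "anxiety": (0, 2),
    "irritable": (0, 2),
    "cognitive_difficulty": (0, 2),
    "mixed_mood": (0, 1),
    "mood": (-3, 3),
    "sleep": (0, 24),
    "stress": (0, 2),
}

#: Column order for the long-format CSV dialect: one row per patient-day.
ITEM_COLUMNS = [
    "activity",
    "alcohol",
    "anxiety",
    "irritable",
    "cognitive_difficulty",
    "medicine",
    "mixed_mood",
    "mood",
    "sleep",
    "stress",
]
CSV_COLUMNS = ["patient_id", "date"] + ITEM_COLUMNS

#: Preprocessed predictors per day, in the fixed model feature order.
#: ``medicine`` is expanded to two exclusive binaries and ``sleep`` to a
#: negative/positive deviation pair around the patient's own mean.
PREDICTORS = [
    "mood",
    "activity",
    "alcohol",
    "anxiety",
    "irritable",
    "cognitive_difficulty",
    "medicine_omitted",
    "medicine_changed",
    "mixed_mood",
    "sleep_negative",
    "sleep_positive",
    "stress",
]

#: Ranges used to min-max normalise each predictor to [0, 1].  The split
#: sleep components use a fixed symmetric +/-12 h range around the patient
#: mean so the transform is data-independent.
PREDICTOR_RANGES = {
    "mood": (-3.0, 3.0),
    "activity": (-3.0, 3.0),
    "alcohol": (0.0, 10.0),
    "anxiety": (0.0, 2.0),
    "irritable": (0.0, 2.0),
    "cognitive_difficulty": (0.0, 2.0),
    "medicine_omitted": (0.0, 1.0),
    "medicine_changed": (0.0, 1.0),
    "mixed_mood": (0.0, 1.0),
    "sleep_negative": (-12.0, 0.0),
    "sleep_positive": (0.0, 12.0),
    "stress": (0.0, 2.0),
}

N_PREDICTORS = len(PREDICTORS)


def mood_level_set() -> set[float]:
    """Return the allowed mood levels as a set of floats."""
    return set(MOOD_LEVELS.tolist())


def is_valid_mood(values) -> np.ndarray:
    """Elementwise check that values sit exactly on the 9-level mood scale."""
    arr = np.asarray(values, dtype=float)
    return np.isin(arr, MOOD_LEVELS)
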