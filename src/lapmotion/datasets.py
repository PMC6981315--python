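"""Published reference data shipped with the package.

Two small tables from the original clinical validation of the scoring
algorithm, transcribed for use as worked-example inputs and regression
anchors:

* the twelve blinded validation videos — composite score, blinded expert
  CAT rating and the operator's actual role;
* the seven benchmark weight sets with the number of correctly
  identified performances each achieved on the (unpublished)
  29-participant reference dataset.
"""

from __future__ import annotations

import pandas as pd

from .validation import AssessmentRecord
from .weights import canonical_weight_sets

__all__ = [
    "published_validation_records",
    "published_validation_table",
    "published_weight_search_table",
]

# (video, composite score rho, CAT score, actual operator role)
_VALIDATION_ROWS = [
    ("1", 1.00, 21, "surgeon"),
    ("2", 1.00, 22, "surgeon"),
    ("3", 1.00, 20, "surgeon"),
    ("4", 0.86, 19, "surgeon"),
    ("5", 0.67, 20, "surgeon"),
    ("6", 0.63, 19, "surgeon"),
    ("7", 0.54, 17, "resident"),
    ("8", 0.41, 14, "resident"),
    ("9", 0.36, 14, "resident"),
    ("10", 0.35, 13, "resident"),
    ("11", 0.09, 14, "resident"),
    ("12", 0.00, 13, "resident"),
]

# correctly identified performances (out of 24) per canonical weight set
_WEIGHT_SEARCH_CORRECT = [20, 18, 19, 15, 23, 18, 21]


def published_validation_records() -> list[AssessmentRecord]:
    """The twelve clinical validation videos as assessment records."""
    return [
        AssessmentRecord(video_id=v, rho=rho, cat_score=cat, true_role=role)
        for v, rho, cat, role in _VALIDATION_ROWS
    ]


def published_validation_table() -> pd.DataFrame:
    """The validation videos as a DataFrame (video_id, rho, cat_score, true_role)."""
    return pd.DataFrame(
        _VALIDATION_ROWS, columns=["video_id", "rho", "cat_score", "true_role"]
    )


def published_weight_search_table() -> pd.DataFrame:
    """The seven benchmark weight sets and their published identification counts.

    The counts are historical results on a dataset that was never
    released; they are reference values for comparison, not something the
    package can recompute.
    """
    rows = [
        {
            "set": i + 1,
            "w_l": w.w_l,
            "w_a": w.w_a,
            "w_j": w.w_j,
            "correctly_identified": c,
            "n_total": 24,
        }
        for i, (w, c) in enumerate(zip(canonical_weight_sets(), _WEIGHT_SEARCH_CORRECT))
    ]
    return pd.DataFrame(rows)
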