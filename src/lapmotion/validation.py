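"""Validate composite scores against an external assessor's ratings.

The external criterion is a Competency Assessment Tool (CAT) rating
assigned per video by a blinded expert.  Validation is an ordinary
least-squares fit of CAT score on the algorithm's composite score rho,
summarised by the coefficient of determination R², plus the band
counts (how many videos the algorithm calls expert / intermediate /
novice).  R² is symmetric in x and y for simple OLS, so the axis choice
does not affect the headline number.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateRegressorError, InsufficientDataError
from .scoring import TABLE1_BANDS, CategoryBands, classify

__all__ = [
    "AssessmentRecord",
    "RegressionResult",
    "fit_linear_regression",
    "categorize_batch",
    "validation_report",
    "read_records_csv",
]


@dataclass(frozen=True)
class AssessmentRecord:
    """One video: its composite score, optional CAT rating and metadata."""

    video_id: str
    rho: float
    cat_score: float | None = None
    true_role: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        if self.cat_score is not None and self.cat_score < 0:
            raise ValueError("cat_score must be >= 0")


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS fit y = slope * x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    p_value: float

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
            "p_value": self.p_value,
        }


def fit_linear_regression(pairs: Iterable[tuple[float, float]]) -> RegressionResult:
    """Ordinary least squares over (x, y) pairs.

    R² is 1 − SS_res / SS_tot.  A constant y is fitted with zero slope
    and, by convention, R² = 0 (no variance to explain).  A constant x
    raises :class:`DegenerateRegressorError`; fewer than two pairs raise
    :class:`InsufficientDataError`.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (x, y) tuples")
    n = arr.shape[0]
    if n < 2:
        raise InsufficientDataError(f"need >= 2 pairs for a regression, got {n}")
    x, y = arr[:, 0], arr[:, 1]
    if np.all(x == x[0]):
        raise DegenerateRegressorError("predictor x is constant; slope undefined")
    if np.all(y == y[0]):
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0, n=n, p_value=1.0)
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=n,
        p_value=float(fit.pvalue),
    )


def categorize_batch(
    records: Sequence[AssessmentRecord],
    bands: CategoryBands = TABLE1_BANDS,
) -> dict[str, int]:
    """Count records per skill band; counts always sum to len(records)."""
    if not records:
        raise ValueError("no records to categorize")
    counts = Counter(classify(r.rho, bands) for r in records)
    return {cat: counts.get(cat, 0) for cat in ("expert", "intermediate", "novice")}


def validation_report(
    records: Sequence[AssessmentRecord],
    bands: CategoryBands = TABLE1_BANDS,
    plot_path: str | Path | None = None,
) -> dict:
    """Full validation summary: band counts, regression, per-record table.

    The regression section is present only when every record carries a
    CAT score and there are at least two records.  ``plot_path``, if
    given, receives a scatter of (rho, CAT) with the fitted line.
    """
    if not records:
        raise ValueError("no records to report on")
    counts = categorize_batch(records, bands)
    table = [
        {
            "video_id": r.video_id,
            "rho": r.rho,
            "category": classify(r.rho, bands),
            "cat_score": r.cat_score,
            "true_role": r.true_role,
        }
        for r in records
    ]
    report: dict = {
        "n": len(records),
        "bands": {"expert_min": bands.expert_min, "novice_max": bands.novice_max},
        "counts": counts,
        "records": table,
        "regression": None,
    }
    have_cat = [r for r in records if r.cat_score is not None]
    if len(have_cat) == len(records) and len(records) >= 2:
        pairs = [(r.rho, float(r.cat_score)) for r in records]
        try:
            reg = fit_linear_regression(pairs)
        except DegenerateRegressorError:
            reg = None
        if reg is not None:
            report["regression"] = reg.as_dict()
            if plot_path is not None:
                _scatter_plot(pairs, reg, Path(plot_path))
    return report


def _scatter_plot(pairs: list[tuple[float, float]], reg: RegressionResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, color="tab:blue", zorder=3)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, reg.slope * xs + reg.intercept, color="tab:red",
            label=f"$R^2$ = {reg.r_squared:.3f}")
    ax.set_xlabel("weighted performance score $\\rho$")
    ax.set_ylabel("expert-assessed CAT score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def read_records_csv(path: str | Path) -> list[AssessmentRecord]:
    """Read assessment records from CSV: ``video_id,rho,cat_score[,true_role]``."""
    df = pd.read_csv(path)
    required = {"video_id", "rho"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        cat = row["cat_score"] if "cat_score" in df.columns and pd.notna(row["cat_score"]) else None
        role = str(row["true_role"]) if "true_role" in df.columns and pd.notna(row["true_role"]) else None
        out.append(
            AssessmentRecord(
                video_id=str(row["video_id"]),
                rho=float(row["rho"]),
                cat_score=float(cat) if cat is not None else None,
                true_role=role,
            )
        )
    return out
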