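"""Pointwise ordinary-linear-regression baseline.

The conventional comparator for visual-field forecasting: at each of
the 52 analysed points, fit an ordinary least-squares line of total
deviation (dB) against time (days, same signed displacement convention
as the encoder: 0 = most recent exam) and extrapolate it to the
requested prediction date.  Regression is on raw dB, one point at a
time, independently of all other points.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np

from . import encoder
from .vf_core import N_POINTS, VFExam


@dataclass(frozen=True)
class PointTrend:
    """Fitted line for one test point: TDV(td) = intercept + slope * td."""

    slope: float        # dB / day
    intercept: float    # dB at td = 0 (the most recent exam)
    index: int = -1

    def predict(self, td: float) -> float:
        return self.intercept + self.slope * td


def fit_point(tds: np.ndarray, tdvs: np.ndarray, index: int = -1) -> PointTrend:
    """Least-squares trend of one point's TDV against time displacement."""
    tds = np.asarray(tds, dtype=float)
    tdvs = np.asarray(tdvs, dtype=float)
    if tds.shape != tdvs.shape or tds.ndim != 1 or tds.size < 2:
        raise ValueError("need matched 1-d arrays of at least 2 samples")
    if np.ptp(tds) == 0:
        raise ValueError("all time displacements identical; trend undefined")
    slope, intercept = np.polyfit(tds, tdvs, 1)
    return PointTrend(slope=float(slope), intercept=float(intercept),
                      index=index)


def olr_predict(exams: list[VFExam], prediction_date: date) -> np.ndarray:
    """Extrapolate all 52 pointwise trends to the prediction date (dB).

    Shares the encoder's time-displacement convention so the baseline
    and the network answer the identical question; permutation-invariant
    in the exam list (sorted by date internally).
    """
    if len(exams) != encoder.N_INPUT_EXAMS:
        raise ValueError(
            f"expected {encoder.N_INPUT_EXAMS} exams, got {len(exams)}")
    exams = sorted(exams, key=lambda e: e.exam_date)
    td = encoder.time_displacements(
        [e.exam_date for e in exams], prediction_date)
    query_td, exam_tds = td[0], td[:0:-1]       # oldest..most recent
    Y = np.stack([e.tdv for e in exams])        # (5, 52), oldest first
    # One shared design matrix across the 52 points.
    A = np.column_stack([exam_tds, np.ones_like(exam_tds)])
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
    return coef[0] * query_td + coef[1]


def fit_trends(exams: list[VFExam]) -> list[PointTrend]:
    """Per-point fitted trends for the sorted exam series."""
    exams = sorted(exams, key=lambda e: e.exam_date)
    last = exams[-1].exam_date
    tds = np.array([-(last - e.exam_date).days for e in exams], dtype=float)
    Y = np.stack([e.tdv for e in exams])
    return [fit_point(tds, Y[:, j], index=j) for j in range(N_POINTS)]
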