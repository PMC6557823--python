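"""Input encoding for the visual-field forecaster.

Five exams plus a requested prediction date become a 6 x 108 matrix.
Each row is [time-displacement, FP, FN, FL, 52 PDV, 52 TDV]; the time
displacement is the signed day count relative to the most recent exam
(0 = most recent, negative = past, positive = forecast horizon).  Row 0
is the query: it carries only the positive horizon, all other 107
features zero, telling the network which future date to predict.  The
remaining rows are the five exams ordered by decreasing time
displacement (most recent first).

Normalization: TDV and PDV are divided by 50, time displacements by
10000; reliability rates by 100 (keeping every feature in [-1, 1]).
"""

from __future__ import annotations

from datetime import date

import numpy as np

from .vf_core import N_POINTS, VFExam

N_FEATURES = 108
N_ROWS = 6
N_INPUT_EXAMS = 5

TD_DIVISOR = 10000.0     # days
DB_DIVISOR = 50.0        # dB, for both TDV and PDV
RATE_DIVISOR = 100.0     # percent -> fraction

# Frozen feature layout (start, stop) slices.
SLICE_TD = slice(0, 1)
SLICE_RELIABILITY = slice(1, 4)       # fpr, fnr, flr
SLICE_PDV = slice(4, 4 + N_POINTS)
SLICE_TDV = slice(4 + N_POINTS, 4 + 2 * N_POINTS)

SEQUENCE_ORDERS = ("decreasing", "chronological")


class EncodedSequence:
    """The 6 x 108 normalized input matrix plus raw day displacements.

    ``rows[0]`` is the query vector; ``td_raw`` holds the six
    unnormalized displacements (strictly decreasing, ``td_raw[1] == 0``).
    """

    __slots__ = ("rows", "td_raw")

    def __init__(self, rows: np.ndarray, td_raw: np.ndarray):
        rows = np.asarray(rows, dtype=float)
        td_raw = np.asarray(td_raw, dtype=float)
        if rows.shape != (N_ROWS, N_FEATURES):
            raise ValueError(f"expected {N_ROWS}x{N_FEATURES} rows, got "
                             f"{rows.shape}")
        if td_raw.shape != (N_ROWS,):
            raise ValueError("td_raw must have 6 entries")
        if td_raw[0] <= 0:
            raise ValueError("query time displacement must be positive")
        if np.any(np.diff(td_raw) >= 0):
            raise ValueError("time displacements must be strictly "
                             "decreasing")
        if np.any(rows[0, 1:] != 0.0):
            raise ValueError("query row must be zero except the time "
                             "displacement")
        self.rows = rows
        self.td_raw = td_raw

    def ordered_rows(self, sequence_order: str = "decreasing") -> np.ndarray:
        """Rows in the order fed to the recurrent network.

        ``decreasing``: by decreasing time displacement — query first,
        then most recent to oldest (the default).  ``chronological``:
        oldest to most recent with the query last, the conventional
        direction for an RNN.
        """
        if sequence_order == "decreasing":
            return self.rows
        if sequence_order == "chronological":
            return self.rows[::-1]
        raise ValueError(f"unknown sequence order {sequence_order!r}")


def time_displacements(exam_dates: list[date],
                       prediction_date: date) -> np.ndarray:
    """Signed day counts [query, 0, -d2, ..., -d5], strictly decreasing.

    The most recent exam defines displacement 0; earlier exams are
    negative (an exam 31 days before the most recent has displacement
    -31) and the forecast horizon is positive.
    """
    if len(exam_dates) != N_INPUT_EXAMS:
        raise ValueError(f"expected {N_INPUT_EXAMS} exam dates, got "
                         f"{len(exam_dates)}")
    if any(b <= a for a, b in zip(exam_dates, exam_dates[1:])):
        raise ValueError("exam dates must be strictly increasing")
    last = exam_dates[-1]
    if prediction_date <= last:
        raise ValueError("prediction date must be after the last exam")
    query_td = (prediction_date - last).days
    exam_tds = [-(last - d).days for d in reversed(exam_dates)]
    return np.array([query_td] + exam_tds, dtype=float)


def encode_exam(exam: VFExam, td: float) -> np.ndarray:
    """One exam as a 108-vector: [td/10000, rates/100, PDV/50, TDV/50]."""
    v = np.empty(N_FEATURES)
    v[SLICE_TD] = td / TD_DIVISOR
    v[SLICE_RELIABILITY] = np.array([exam.fpr, exam.fnr, exam.flr]) \
        / RATE_DIVISOR
    v[SLICE_PDV] = exam.pdv / DB_DIVISOR
    v[SLICE_TDV] = exam.tdv / DB_DIVISOR
    return v


def query_vector(query_td: float) -> np.ndarray:
    """The future-date query row: a lone positive displacement."""
    if query_td <= 0:
        raise ValueError("query time displacement must be positive")
    v = np.zeros(N_FEATURES)
    v[0] = query_td / TD_DIVISOR
    return v


def build_sequence(exams: list[VFExam],
                   prediction_date: date) -> EncodedSequence:
    """Assemble the 6 x 108 input from 5 exams and a prediction date.

    Exams are ordered by date internally, so the caller's list order is
    irrelevant.
    """
    if len(exams) != N_INPUT_EXAMS:
        raise ValueError(f"expected {N_INPUT_EXAMS} exams, got {len(exams)}")
    exams = sorted(exams, key=lambda e: e.exam_date)
    td = time_displacements([e.exam_date for e in exams], prediction_date)
    rows = np.empty((N_ROWS, N_FEATURES))
    rows[0] = query_vector(td[0])
    for i, exam in enumerate(reversed(exams)):      # most recent first
        rows[1 + i] = encode_exam(exam, td[1 + i])
    return EncodedSequence(rows, td)


def sequences_from_series(series_list) -> list[tuple["EncodedSequence",
                                                     np.ndarray]]:
    """Training pairs from per-eye series: first 5 exams encode the
    input, the 6th exam supplies the prediction date and the normalized
    TDV target.  Series with fewer than 6 exams are skipped."""
    pairs = []
    for s in series_list:
        if len(s.exams) < N_INPUT_EXAMS + 1:
            continue
        inputs = s.exams[:N_INPUT_EXAMS]
        target = s.exams[N_INPUT_EXAMS]
        seq = build_sequence(inputs, target.exam_date)
        pairs.append((seq, target.tdv / DB_DIVISOR))
    return pairs


def decode_row(row: np.ndarray) -> dict:
    """Invert ``encode_exam``: recover td (days), rates (%), PDV/TDV (dB)."""
    row = np.asarray(row, dtype=float)
    if row.shape != (N_FEATURES,):
        raise ValueError(f"expected a {N_FEATURES}-vector")
    fpr, fnr, flr = row[SLICE_RELIABILITY] * RATE_DIVISOR
    return {
        "td": float(row[0] * TD_DIVISOR),
        "fpr": float(fpr), "fnr": float(fnr), "flr": float(flr),
        "pdv": row[SLICE_PDV] * DB_DIVISOR,
        "tdv": row[SLICE_TDV] * DB_DIVISOR,
    }


def save_sequence(seq: EncodedSequence, path: str) -> None:
    """Write a sequence to a portable array container (bit-exact)."""
    np.savez(path, rows=seq.rows, td_raw=seq.td_raw)


def load_sequence(path: str) -> EncodedSequence:
    with np.load(path) as data:
        return EncodedSequence(data["rows"], data["td_raw"])
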