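"""Humphrey perimetry data model.

24-2 / 30-2 test-point geometry, blind-spot exclusion, 30-2 to 24-2
conversion by overlapped points, left-eye mirroring into right-eye
convention, reliability screening, and the canonical exam CSV format.

Coordinates are degrees of eccentricity in right-eye convention:
temporal = positive x, superior = positive y.  The physiologic scotoma
(blind spot) sits 15 degrees temporal at (15, +-3); those two 24-2
locations carry no visual information and are excluded, leaving the 52
analysed points used everywhere downstream (encoder, model head,
metrics).  The canonical ordering of those 52 points is row-major:
superior to inferior (y descending), then nasal to temporal
(x ascending) — a frozen total order shared by every module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd

N_POINTS = 52          # analysed 24-2 locations after blind-spot exclusion
N_POINTS_RAW = 54      # full 24-2 pattern
N_POINTS_30_2 = 76     # full 30-2 pattern
BLIND_SPOT = ((15, 3), (15, -3))
RELIABILITY_CUTOFF = 33.0      # percent; strict "<" on all three indices
DB_MIN, DB_MAX = -40.0, 15.0   # plausible instrument range for deviation values

# Row layout of the standard patterns: y -> tuple of x values present.
# 24-2 spans 24 degrees plus the two nasal points at x = -27.
_ROWS_24_2 = {
    21: (-9, -3, 3, 9),
    15: (-15, -9, -3, 3, 9, 15),
    9: (-21, -15, -9, -3, 3, 9, 15, 21),
    3: (-27, -21, -15, -9, -3, 3, 9, 15, 21),
    -3: (-27, -21, -15, -9, -3, 3, 9, 15, 21),
    -9: (-21, -15, -9, -3, 3, 9, 15, 21),
    -15: (-15, -9, -3, 3, 9, 15),
    -21: (-9, -3, 3, 9),
}
_ROWS_30_2 = {
    27: (-9, -3, 3, 9),
    21: (-15, -9, -3, 3, 9, 15),
    15: (-21, -15, -9, -3, 3, 9, 15, 21),
    9: (-27, -21, -15, -9, -3, 3, 9, 15, 21, 27),
    3: (-27, -21, -15, -9, -3, 3, 9, 15, 21, 27),
    -3: (-27, -21, -15, -9, -3, 3, 9, 15, 21, 27),
    -9: (-27, -21, -15, -9, -3, 3, 9, 15, 21, 27),
    -15: (-21, -15, -9, -3, 3, 9, 15, 21),
    -21: (-15, -9, -3, 3, 9, 15),
    -27: (-9, -3, 3, 9),
}


@dataclass(frozen=True)
class VFPoint:
    """One test location; ``index`` is None for the two blind-spot points."""

    x: int
    y: int
    index: int | None = None
    blind_spot: bool = False


def grid_24_2() -> list[VFPoint]:
    """The 54 standard 24-2 locations in right-eye convention.

    52 points carry canonical indices 0..51 (y descending, x ascending);
    the two blind-spot points (15, +-3) are flagged and index-free.
    """
    points: list[VFPoint] = []
    idx = 0
    for y in sorted(_ROWS_24_2, reverse=True):
        for x in sorted(_ROWS_24_2[y]):
            if (x, y) in BLIND_SPOT:
                points.append(VFPoint(x, y, index=None, blind_spot=True))
            else:
                points.append(VFPoint(x, y, index=idx))
                idx += 1
    return points


def grid_30_2() -> list[tuple[int, int]]:
    """The 76 standard 30-2 locations (coordinates only)."""
    return [
        (x, y)
        for y in sorted(_ROWS_30_2, reverse=True)
        for x in sorted(_ROWS_30_2[y])
    ]


#: Canonical (x, y) of the 52 analysed points, position = canonical index.
CANONICAL_COORDS: tuple[tuple[int, int], ...] = tuple(
    (p.x, p.y) for p in grid_24_2() if not p.blind_spot
)
_COORD_TO_INDEX = {xy: i for i, xy in enumerate(CANONICAL_COORDS)}


def to_24_2(raw_values: dict[tuple[int, int], float],
            pattern: str = "24-2") -> np.ndarray:
    """Select the 52 canonical values from a coordinate->dB map.

    Accepts a full 24-2 map (54 locations) or a full 30-2 map (76
    locations); the 24-2 lattice is a subset of the 30-2 lattice, so
    conversion is pure selection of overlapped points — no interpolation.
    Blind-spot values are dropped.  A missing canonical coordinate is a
    hard error naming the coordinate.
    """
    if pattern not in ("24-2", "30-2"):
        raise ValueError(f"unknown test pattern {pattern!r}")
    out = np.empty(N_POINTS)
    for i, xy in enumerate(CANONICAL_COORDS):
        if xy not in raw_values:
            raise KeyError(f"missing canonical 24-2 coordinate {xy}")
        out[i] = raw_values[xy]
    return out


def _select(raw_values: dict[tuple[int, int], float],
            coords) -> np.ndarray:
    out = np.empty(len(coords))
    for i, xy in enumerate(coords):
        if xy not in raw_values:
            raise KeyError(f"missing coordinate {xy}")
        out[i] = raw_values[xy]
    return out


@dataclass
class VFExam:
    """One automated-perimetry test in canonical form.

    ``tdv``/``pdv`` are the 52 total/pattern deviation values (dB) in
    canonical point order; ``fpr``/``fnr``/``flr`` are false-positive,
    false-negative and fixation-loss rates in percent.
    """

    exam_date: date
    tdv: np.ndarray
    pdv: np.ndarray
    fpr: float
    fnr: float
    flr: float
    laterality: str = "right"
    pattern: str = "24-2"
    md: float | None = None

    def __post_init__(self) -> None:
        self.tdv = np.asarray(self.tdv, dtype=float)
        self.pdv = np.asarray(self.pdv, dtype=float)
        if self.tdv.shape != (N_POINTS,) or self.pdv.shape != (N_POINTS,):
            raise ValueError(
                f"tdv/pdv must have exactly {N_POINTS} entries, got "
                f"{self.tdv.shape}/{self.pdv.shape}")
        for name in ("fpr", "fnr", "flr"):
            r = getattr(self, name)
            if not 0.0 <= r <= 100.0:
                raise ValueError(f"{name}={r} outside [0, 100]")
        if self.laterality not in ("left", "right"):
            raise ValueError(f"unknown laterality {self.laterality!r}")
        if self.md is None:
            # Unweighted mean of the 52 TDVs; the instrument's
            # eccentricity weighting is proprietary and MD is only used
            # for binning, never for prediction.
            self.md = float(np.mean(self.tdv))


# Field-chart coordinates of a left eye are the mirror image (x -> -x) of
# the canonical right-eye lattice.  Sorting that mirrored lattice with the
# same rule (y descending, x ascending) and mapping each location back to
# the canonical index of its mirror reverses each y-row block, so the
# permutation is its own inverse.
_LEFT_COORDS: tuple[tuple[int, int], ...] = tuple(sorted(
    ((-x, y) for x, y in CANONICAL_COORDS), key=lambda c: (-c[1], c[0])))
_MIRROR_PERM = np.array(
    [_COORD_TO_INDEX[(-x, y)] for x, y in _LEFT_COORDS])


def canonicalize_laterality(exam: VFExam) -> VFExam:
    """Mirror a left eye's values (x -> -x) into right-eye convention.

    Left-eye exams read from field-chart coordinates carry their values in
    the mirrored-lattice ordering; this permutes them onto the canonical
    right-eye ordering, pooling anatomically homologous locations across
    eyes.  Right eyes pass through unchanged.  The coordinate mirror is an
    involution: applying it twice restores the original exam.
    """
    if exam.laterality == "right":
        return exam
    if exam.laterality != "left":
        raise ValueError(f"unknown laterality {exam.laterality!r}")
    out = replace(exam)
    out.tdv = np.empty_like(exam.tdv)
    out.pdv = np.empty_like(exam.pdv)
    out.tdv[_MIRROR_PERM] = exam.tdv
    out.pdv[_MIRROR_PERM] = exam.pdv
    return out


def reliability_pass(exam: VFExam,
                     max_fp: float = RELIABILITY_CUTOFF,
                     max_fn: float = RELIABILITY_CUTOFF,
                     max_fl: float = RELIABILITY_CUTOFF) -> bool:
    """True iff all three reliability indices are strictly below cutoff."""
    return exam.fpr < max_fp and exam.fnr < max_fn and exam.flr < max_fl


@dataclass
class VFSeries:
    """Longitudinal exam series of one eye, sorted by ascending date.

    At least 6 exams make one forecasting sample (5 inputs + 1 target).
    """

    eye_id: str
    exams: list[VFExam] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exams = sorted(self.exams, key=lambda e: e.exam_date)
        dates = [e.exam_date for e in self.exams]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"eye {self.eye_id}: exam dates not strictly "
                             "increasing")

    def __len__(self) -> int:
        return len(self.exams)


# ---------------------------------------------------------------------------
# Exam CSV I/O
#
# One row per exam: eye_id, exam_date (ISO-8601), laterality, pattern,
# fpr, fnr, flr, md, td_001..td_052, pd_001..pd_052 in canonical order.
# dB values are written at 0.01 precision.  A sidecar JSON documents the
# canonical coordinate table.  The "wide-raw" dialect instead carries
# coordinate-labelled columns (td_x-27_y3, ...) for pre-conversion input.
# ---------------------------------------------------------------------------

_TD_COLS = [f"td_{i + 1:03d}" for i in range(N_POINTS)]
_PD_COLS = [f"pd_{i + 1:03d}" for i in range(N_POINTS)]
_META_COLS = ["eye_id", "exam_date", "laterality", "pattern",
              "fpr", "fnr", "flr", "md"]


def series_to_frame(series_list: list[VFSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for e in s.exams:
            row = {
                "eye_id": s.eye_id,
                "exam_date": e.exam_date.isoformat(),
                "laterality": e.laterality,
                "pattern": e.pattern,
                "fpr": round(e.fpr, 2),
                "fnr": round(e.fnr, 2),
                "flr": round(e.flr, 2),
                "md": round(float(e.md), 2),
            }
            row.update({c: round(float(v), 2)
                        for c, v in zip(_TD_COLS, e.tdv)})
            row.update({c: round(float(v), 2)
                        for c, v in zip(_PD_COLS, e.pdv)})
            rows.append(row)
    return pd.DataFrame(rows, columns=_META_COLS + _TD_COLS + _PD_COLS)


def write_exams(series_list: list[VFSeries], path: str,
                sidecar: bool = True) -> None:
    """Write series to the canonical exam CSV (+ coordinate-table JSON)."""
    df = series_to_frame(series_list)
    df.to_csv(path, index=False, float_format="%.2f")
    if sidecar:
        meta = {
            "format": "vfforecast-exam-csv/1",
            "n_points": N_POINTS,
            "ordering": "y descending, then x ascending; right-eye "
                        "convention (temporal positive)",
            "coordinates": [list(xy) for xy in CANONICAL_COORDS],
            "blind_spot": [list(xy) for xy in BLIND_SPOT],
        }
        with open(path + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


def read_exams(path: str) -> list[VFSeries]:
    """Read the canonical exam CSV back into per-eye series."""
    df = pd.read_csv(path)
    missing = [c for c in _META_COLS + _TD_COLS + _PD_COLS
               if c not in df.columns]
    if missing:
        raise ValueError(f"exam CSV missing columns: {missing[:4]}...")
    out = []
    for eye_id, g in df.groupby("eye_id", sort=False):
        exams = [
            VFExam(
                exam_date=date.fromisoformat(str(r["exam_date"])),
                tdv=r[_TD_COLS].to_numpy(dtype=float),
                pdv=r[_PD_COLS].to_numpy(dtype=float),
                fpr=float(r["fpr"]), fnr=float(r["fnr"]), flr=float(r["flr"]),
                laterality=str(r["laterality"]), pattern=str(r["pattern"]),
                md=float(r["md"]),
            )
            for _, r in g.iterrows()
        ]
        out.append(VFSeries(eye_id=str(eye_id), exams=exams))
    return out


def read_wide_raw(path: str) -> list[VFSeries]:
    """Read the coordinate-labelled "wide-raw" CSV dialect.

    Columns td_x{X}_y{Y} / pd_x{X}_y{Y} carry the full 54 (24-2) or 76
    (30-2) locations; rows are converted to canonical 52-point form via
    ``to_24_2`` and left eyes are mirrored.
    """
    df = pd.read_csv(path)
    out = []
    for eye_id, g in df.groupby("eye_id", sort=False):
        exams = []
        for _, r in g.iterrows():
            td_map, pd_map = {}, {}
            for col in df.columns:
                if col.startswith(("td_x", "pd_x")):
                    xs, ys = col[4:].split("_y")
                    xy = (int(xs), int(ys))
                    if pd.notna(r[col]):
                        (td_map if col.startswith("td") else pd_map)[xy] = \
                            float(r[col])
            pattern = str(r.get("pattern", "24-2"))
            laterality = str(r["laterality"])
            if laterality == "left":
                # left field charts use the mirrored lattice; index over it
                tdv = _select(td_map, _LEFT_COORDS)
                pdv = _select(pd_map, _LEFT_COORDS)
            else:
                tdv = to_24_2(td_map, pattern)
                pdv = to_24_2(pd_map, pattern)
            exam = VFExam(
                exam_date=date.fromisoformat(str(r["exam_date"])),
                tdv=tdv, pdv=pdv,
                fpr=float(r["fpr"]), fnr=float(r["fnr"]), flr=float(r["flr"]),
                laterality=laterality, pattern=pattern,
            )
            exams.append(canonicalize_laterality(exam))
        out.append(VFSeries(eye_id=str(eye_id), exams=exams))
    return out
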