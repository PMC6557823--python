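"""Seeded simulator of longitudinal 24-2 visual-field series.

Emulates the statistical structure a pointwise forecaster assumes of
real perimetry: per-eye series of 6 exams at 0.5-1.5-year intervals;
baseline fields built from a diffuse component plus 0-2 cluster-shaped
defects; pointwise linear progression concentrated in anatomically
plausible clusters (arcuate bundles, nasal step, paracentral); test-
retest noise whose standard deviation grows with defect depth;
reliability indices with the false-negative rate coupled to damage; and
occasional "outlier" exams with tripled noise and inflated FNR — the
long-tailed fluctuations that make trend extrapolation fragile.

Ground-truth trends are retained beside each generated series so tests
can compare any forecaster against the noise-free trajectory.

It does not emulate threshold-staircase psychophysics, learning or
fatigue effects, cataract-induced diffuse change over time, or
diagnosis-specific subtypes; passing tests on this simulator show the
pipeline recovers the generating linear-trend-plus-noise structure, not
clinical performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta

import numpy as np
import yaml
from scipy import stats

from .vf_core import (CANONICAL_COORDS, N_POINTS, VFExam, VFSeries,
                      write_exams)

DAYS_PER_YEAR = 365.25

#: Frozen defect/progression cluster menu: coordinate sets over the
#: canonical grid following the arcuate course of retinal nerve-fibre
#: bundles, the nasal step, and the paracentral region.
CLUSTERS: dict[str, tuple[tuple[int, int], ...]] = {
    "superior_arcuate": (
        (-9, 21), (-3, 21), (3, 21), (9, 21),
        (-15, 15), (-9, 15), (-3, 15), (3, 15), (9, 15), (15, 15),
        (9, 9), (15, 9), (21, 9),
    ),
    "inferior_arcuate": (
        (-9, -21), (-3, -21), (3, -21), (9, -21),
        (-15, -15), (-9, -15), (-3, -15), (3, -15), (9, -15), (15, -15),
        (9, -9), (15, -9), (21, -9),
    ),
    "nasal_step": (
        (-27, 3), (-21, 3), (-15, 3), (-27, -3), (-21, -3), (-15, -3),
    ),
    "paracentral": (
        (-9, 3), (-3, 3), (3, 3), (-9, -3), (-3, -3), (3, -3),
    ),
}

_COORD_INDEX = {xy: i for i, xy in enumerate(CANONICAL_COORDS)}
CLUSTER_INDICES = {name: np.array([_COORD_INDEX[xy] for xy in coords])
                   for name, coords in CLUSTERS.items()}


@dataclass
class SimParams:
    """Generator settings; the same seed always yields the same cohort.

    Defaults target a mixed glaucoma-clinic population: initial mean
    deviation drawn from a normal with mean -7.0 dB and SD 6.1
    truncated to [-30, 2]; progressing points lose 0.6 +- 0.3 dB/year;
    observation noise sigma(point) = sigma0 + kappa * defect depth,
    capped at 6 dB.
    """

    n_eyes: int = 100
    visits: int = 6
    interval_years: tuple[float, float] = (0.5, 1.5)
    md_mean: float = -7.0
    md_sd: float = 6.1
    md_bounds: tuple[float, float] = (-30.0, 2.0)
    progress_fraction: float = 0.6
    slope_mean: float = -0.6          # dB / year at progressing points
    slope_sd: float = 0.3
    sigma0: float = 1.0               # dB floor of test-retest noise
    kappa: float = 0.12               # noise growth per dB of defect depth
    sigma_cap: float = 6.0
    outlier_prob: float = 0.08        # per-exam; noise x3, FNR inflated
    outlier_sigma_factor: float = 3.0
    outlier_fnr_boost: float = 10.0   # percentage points
    start_date: date = date(2012, 1, 1)
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        doc = asdict(self)
        doc["interval_years"] = list(self.interval_years)
        doc["md_bounds"] = list(self.md_bounds)
        doc["start_date"] = self.start_date.isoformat()
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimParams":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["interval_years"] = tuple(doc["interval_years"])
        doc["md_bounds"] = tuple(doc["md_bounds"])
        doc["start_date"] = date.fromisoformat(doc["start_date"])
        return cls(**doc)


def noiseless_params(n_eyes: int, seed: int = 0, **overrides) -> SimParams:
    """A noise-free, outlier-free cohort: exams follow the true linear
    trajectories exactly (up to 1-dB instrument rounding)."""
    return SimParams(n_eyes=n_eyes, sigma0=0.0, kappa=0.0,
                     outlier_prob=0.0, seed=seed, **overrides)


@dataclass
class EyeTruth:
    """Hidden generating process of one simulated eye."""

    base: np.ndarray                    # true TDV at the first exam (dB)
    slope: np.ndarray                   # true dB/year per point
    exam_years: np.ndarray              # years since first exam, per exam
    true_tdv: np.ndarray                # (visits, 52) noise-free values
    outlier: np.ndarray                 # per-exam outlier flags
    progressing: bool
    clusters: tuple[str, ...] = ()
    md_target: float = np.nan           # sampled initial mean deviation

    def tdv_at(self, years: float) -> np.ndarray:
        return self.base + self.slope * years


def general_height(tdv: np.ndarray) -> float:
    """General-height estimate: the 7th-highest total-deviation value.

    Standard perimetry convention for separating diffuse depression
    from localized loss (the instrument's exact algorithm is
    proprietary; the 7th-best-point rule is its published surrogate).
    """
    tdv = np.asarray(tdv, dtype=float)
    return float(np.sort(tdv)[-7])


def derive_pdv(tdv: np.ndarray) -> np.ndarray:
    """Pattern deviation: TDV minus the general height."""
    tdv = np.asarray(tdv, dtype=float)
    return tdv - general_height(tdv)


def _baseline_field(md_target: float, rng: np.random.Generator) -> np.ndarray:
    """True TDV field at the first exam with mean equal to md_target."""
    fld = rng.normal(0.0, 1.0, N_POINTS)
    if md_target < -2.0:
        n_defects = rng.integers(1, 3)
        names = rng.choice(list(CLUSTERS), size=n_defects, replace=False)
        for name in names:
            idx = CLUSTER_INDICES[name]
            depth = rng.uniform(4.0, 18.0)
            fld[idx] -= depth * rng.uniform(0.5, 1.0, idx.size)
    # diffuse shift to the target mean, then keep values in instrument
    # range; re-center a few times because clipping drags the mean
    for _ in range(3):
        fld += md_target - fld.mean()
        fld = np.clip(fld, -38.0, 5.0)
    return fld


def _sample_md(params: SimParams, rng: np.random.Generator) -> float:
    a = (params.md_bounds[0] - params.md_mean) / params.md_sd
    b = (params.md_bounds[1] - params.md_mean) / params.md_sd
    return float(stats.truncnorm.rvs(a, b, loc=params.md_mean,
                                     scale=params.md_sd, random_state=rng))


def simulate_eye(params: SimParams, rng: np.random.Generator,
                 eye_id: str = "eye") -> VFSeries:
    """One simulated series; the hidden truth rides on ``series.truth``."""
    md0 = _sample_md(params, rng)
    base = _baseline_field(md0, rng)

    slope = np.zeros(N_POINTS)
    progressing = rng.random() < params.progress_fraction
    names: tuple[str, ...] = ()
    if progressing:
        k = rng.integers(1, 3)
        names = tuple(rng.choice(list(CLUSTERS), size=k, replace=False))
        for name in names:
            idx = CLUSTER_INDICES[name]
            slope[idx] += rng.normal(params.slope_mean, params.slope_sd,
                                     idx.size)

    lo, hi = params.interval_years
    intervals = rng.uniform(lo, hi, params.visits - 1)
    years = np.concatenate([[0.0], np.cumsum(intervals)])
    day0 = params.start_date + timedelta(days=int(rng.integers(0, 366)))
    dates = [day0 + timedelta(days=round(y * DAYS_PER_YEAR)) for y in years]

    outlier = rng.random(params.visits) < params.outlier_prob
    true_tdv = np.empty((params.visits, N_POINTS))
    exams = []
    for v in range(params.visits):
        truth = base + slope * years[v]
        true_tdv[v] = truth
        sigma = np.minimum(
            params.sigma0 + params.kappa * np.maximum(0.0, -truth),
            params.sigma_cap)
        if outlier[v]:
            sigma = sigma * params.outlier_sigma_factor
        obs = truth + rng.normal(0.0, 1.0, N_POINTS) * sigma
        obs = np.clip(np.round(obs), -40.0, 15.0)    # 1-dB instrument steps

        md_true = float(truth.mean())
        fpr = 33.0 * rng.beta(1.5, 12.0)
        flr = 33.0 * rng.beta(1.5, 8.0)
        fnr = (33.0 * rng.beta(1.5, 12.0)
               + 0.35 * max(0.0, -md_true)
               + (params.outlier_fnr_boost if outlier[v] else 0.0))
        fnr = float(np.clip(fnr, 0.0, 32.9))
        exams.append(VFExam(
            exam_date=dates[v], tdv=obs, pdv=derive_pdv(obs),
            fpr=round(fpr, 2), fnr=round(fnr, 2), flr=round(flr, 2),
            laterality="right", pattern="24-2",
        ))
    series = VFSeries(eye_id=eye_id, exams=exams)
    series.truth = EyeTruth(base=base, slope=slope, exam_years=years,
                            true_tdv=true_tdv, outlier=outlier,
                            progressing=progressing, clusters=names,
                            md_target=md0)
    return series


def simulate_cohort(params: SimParams) -> list[VFSeries]:
    """n_eyes independent series; deterministic under ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    return [simulate_eye(params, rng, eye_id=f"sim{i:05d}")
            for i in range(params.n_eyes)]


def write_cohort(series_list: list[VFSeries], path: str,
                 truth_path: str | None = None) -> None:
    """Write the canonical exam CSV plus a hidden-truth sidecar CSV."""
    write_exams(series_list, path)
    if truth_path is None:
        return
    import pandas as pd
    rows = []
    for s in series_list:
        t: EyeTruth = s.truth
        for v in range(t.true_tdv.shape[0]):
            row = {"eye_id": s.eye_id, "visit": v,
                   "years": round(float(t.exam_years[v]), 6),
                   "outlier": bool(t.outlier[v]),
                   "progressing": t.progressing,
                   "clusters": "|".join(t.clusters)}
            row.update({f"true_td_{i + 1:03d}": round(float(x), 4)
                        for i, x in enumerate(t.true_tdv[v])})
            rows.append(row)
    pd.DataFrame(rows).to_csv(truth_path, index=False)
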