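"""Accuracy metrics and method-comparison analyses.

Two accuracy metrics: root-mean-square error per eye over the 52
points, and mean absolute error per point across eyes.  Method
comparison is paired (each eye yields one RNN and one OLR error):
Shapiro-Wilk decides normality of the paired differences, then a paired
t-test (normal) or Wilcoxon signed-rank test is applied, two-sided at
alpha 0.05.  Errors are additionally binned by reliability indices and
mean deviation, and correlated with those factors via Spearman's rho
and simple linear regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .vf_core import N_POINTS

SHAPIRO_ALPHA = 0.05

#: Default bin edges replicating the published reliability / MD tables.
RELIABILITY_EDGES = (2.5, 5.0, 7.5, 10.0)   # percent; <=2.5 ... >10
MD_EDGES = (-12.0, -9.0, -6.0, -3.0)        # dB; <-12 ... >=-3


def rmse_eye(true: np.ndarray, pred: np.ndarray) -> float:
    """Root-mean-square error over the 52 points of one eye (dB)."""
    true = np.asarray(true, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if true.shape != (N_POINTS,) or pred.shape != (N_POINTS,):
        raise ValueError(f"expected aligned {N_POINTS}-vectors")
    return float(np.sqrt(np.mean((true - pred) ** 2)))


def mae_points(truths, preds) -> np.ndarray:
    """Mean absolute error at each point across eyes (52-vector, dB)."""
    truths = np.asarray(truths, dtype=float)
    preds = np.asarray(preds, dtype=float)
    if truths.size == 0:
        raise ValueError("no eyes supplied")
    if truths.shape != preds.shape or truths.shape[1] != N_POINTS:
        raise ValueError("truths and preds must be aligned (n_eyes, 52)")
    return np.mean(np.abs(truths - preds), axis=0)


@dataclass
class EvalRecord:
    """Per-eye paired forecast: truth, both predictions, errors, covariates.

    ``fpr``/``fnr``/``flr``/``md`` are the binning covariates aggregated
    from the input series (see ``aggregate_covariates``).
    """

    eye_id: str
    true_tdv: np.ndarray
    rnn_pred: np.ndarray
    olr_pred: np.ndarray
    fpr: float = np.nan
    fnr: float = np.nan
    flr: float = np.nan
    md: float = np.nan
    rmse_rnn: float = field(init=False)
    rmse_olr: float = field(init=False)

    def __post_init__(self) -> None:
        self.true_tdv = np.asarray(self.true_tdv, dtype=float)
        self.rnn_pred = np.asarray(self.rnn_pred, dtype=float)
        self.olr_pred = np.asarray(self.olr_pred, dtype=float)
        self.rmse_rnn = rmse_eye(self.true_tdv, self.rnn_pred)
        self.rmse_olr = rmse_eye(self.true_tdv, self.olr_pred)


def aggregate_covariates(exams, rule: str = "mean") -> dict:
    """Reliability/MD covariates of one input series.

    ``mean``: average over the 5 input exams (default — a series-level
    summary); ``last``: the most recent input exam alone.
    """
    if rule == "mean":
        agg = lambda vals: float(np.mean(vals))      # noqa: E731
    elif rule == "last":
        exams = [sorted(exams, key=lambda e: e.exam_date)[-1]]
        agg = lambda vals: float(vals[0])            # noqa: E731
    else:
        raise ValueError(f"unknown covariate rule {rule!r}")
    return {
        "fpr": agg([e.fpr for e in exams]),
        "fnr": agg([e.fnr for e in exams]),
        "flr": agg([e.flr for e in exams]),
        "md": agg([e.md for e in exams]),
    }


def _paired_test(a: np.ndarray, b: np.ndarray) -> tuple[str, float]:
    """Paired comparison: Shapiro-Wilk gates t-test vs Wilcoxon."""
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.allclose(diff, 0.0):
        return "degenerate", 1.0
    if np.ptp(diff) == 0.0:
        # constant nonzero difference: normality is undefined and the
        # t statistic degenerates; the sign test inside Wilcoxon applies
        return "wilcoxon signed-rank", float(stats.wilcoxon(a, b).pvalue)
    normal = stats.shapiro(diff).pvalue >= SHAPIRO_ALPHA
    if normal:
        return "paired t-test", float(stats.ttest_rel(a, b).pvalue)
    return "wilcoxon signed-rank", float(stats.wilcoxon(a, b).pvalue)


def compare_methods(records: list[EvalRecord]) -> dict:
    """Cohort summary: mean +- SD per method, delta, paired test, p."""
    if len(records) < 3:
        raise ValueError("need at least 3 records for a paired comparison")
    rnn = np.array([r.rmse_rnn for r in records])
    olr = np.array([r.rmse_olr for r in records])
    test, p = _paired_test(rnn, olr)
    return {
        "n": len(records),
        "rmse_rnn_mean": float(rnn.mean()),
        "rmse_rnn_sd": float(rnn.std(ddof=1)),
        "rmse_olr_mean": float(olr.mean()),
        "rmse_olr_sd": float(olr.std(ddof=1)),
        "delta_olr_minus_rnn": float(olr.mean() - rnn.mean()),
        "test": test,
        "p_value": p,
        "significant": p < 0.05,
    }


def _bin_labels_edges(factor: str, edges):
    if edges is not None:
        return list(edges)
    return list(MD_EDGES) if factor == "md" else list(RELIABILITY_EDGES)


def _assign_bin(value: float, edges: list[float], factor: str) -> int:
    # Reliability factors bin as (lo, hi]; MD bins as [lo, hi).
    if factor == "md":
        return int(np.searchsorted(edges, value, side="right"))
    return int(np.searchsorted(edges, value, side="left"))


def _bin_name(k: int, edges: list[float], factor: str) -> str:
    if factor == "md":
        if k == 0:
            return f"< {edges[0]:g}"
        if k == len(edges):
            return f">= {edges[-1]:g}"
        return f"[{edges[k - 1]:g}, {edges[k]:g})"
    if k == 0:
        return f"<= {edges[0]:g}"
    if k == len(edges):
        return f"> {edges[-1]:g}"
    return f"({edges[k - 1]:g}, {edges[k]:g}]"


def bin_rmse(records: list[EvalRecord], factor: str,
             edges=None) -> pd.DataFrame:
    """Per-bin mean +- SD RMSE for each method, with paired tests.

    Default edges reproduce the published table layout: reliability
    rates at {<=2.5, 2.5-5, 5-7.5, 7.5-10, >10} percent and mean
    deviation at {<-12, -12..-9, -9..-6, -6..-3, >=-3} dB.  Bins
    partition the cohort; an empty bin yields an n=0 row with no test.
    """
    if factor not in ("fpr", "fnr", "flr", "md"):
        raise ValueError(f"unknown binning factor {factor!r}")
    edges = _bin_labels_edges(factor, edges)
    values = np.array([getattr(r, factor) for r in records], dtype=float)
    if np.any(np.isnan(values)):
        raise ValueError(f"factor {factor!r} not populated on all records")
    assignment = np.array([_assign_bin(v, edges, factor) for v in values])
    rows = []
    for k in range(len(edges) + 1):
        members = [r for r, a in zip(records, assignment) if a == k]
        row = {"factor": factor, "bin": _bin_name(k, edges, factor),
               "n": len(members)}
        if members:
            rnn = np.array([r.rmse_rnn for r in members])
            olr = np.array([r.rmse_olr for r in members])
            row.update(
                rmse_rnn_mean=rnn.mean(),
                rmse_rnn_sd=rnn.std(ddof=1) if len(members) > 1 else 0.0,
                rmse_olr_mean=olr.mean(),
                rmse_olr_sd=olr.std(ddof=1) if len(members) > 1 else 0.0,
            )
            if len(members) >= 3:
                test, p = _paired_test(rnn, olr)
                row.update(test=test, p_value=p)
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_error(records: list[EvalRecord], factor: str) -> dict:
    """Spearman rho and simple OLS of per-eye RMSE on a factor.

    Returns per-method dicts with (rho, rho_p, slope, intercept, r2,
    ols_p).  The factor must vary across the cohort.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    x = np.array([getattr(r, factor) for r in records], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"factor {factor!r} has zero variance")
    out = {"factor": factor, "n": len(records)}
    for method in ("rnn", "olr"):
        y = np.array([getattr(r, f"rmse_{method}") for r in records])
        rho, rho_p = stats.spearmanr(x, y)
        fit = stats.linregress(x, y)
        out[method] = {
            "rho": float(rho), "rho_p": float(rho_p),
            "slope": float(fit.slope), "intercept": float(fit.intercept),
            "r2": float(fit.rvalue ** 2), "ols_p": float(fit.pvalue),
        }
    return out


def evaluate_cohort(model, series_list,
                    covariate_rule: str = "mean") -> list[EvalRecord]:
    """Paired per-eye evaluation of the network against the OLR baseline.

    For every series with at least 6 exams, the first five are the
    inputs, the sixth is the truth; both methods forecast its date.
    """
    from . import olr                       # local import, avoids cycle
    from .encoder import N_INPUT_EXAMS
    records = []
    for s in series_list:
        if len(s.exams) < N_INPUT_EXAMS + 1:
            continue
        inputs = s.exams[:N_INPUT_EXAMS]
        target = s.exams[N_INPUT_EXAMS]
        cov = aggregate_covariates(inputs, covariate_rule)
        records.append(EvalRecord(
            eye_id=s.eye_id,
            true_tdv=target.tdv,
            rnn_pred=model.predict_tdv(inputs, target.exam_date),
            olr_pred=olr.olr_predict(inputs, target.exam_date),
            **cov,
        ))
    return records


def records_to_frame(records: list[EvalRecord]) -> pd.DataFrame:
    """Flat per-eye table of errors and covariates (for report CSVs)."""
    return pd.DataFrame([
        {"eye_id": r.eye_id, "rmse_rnn": r.rmse_rnn, "rmse_olr": r.rmse_olr,
         "fpr": r.fpr, "fnr": r.fnr, "flr": r.flr, "md": r.md}
        for r in records
    ])
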