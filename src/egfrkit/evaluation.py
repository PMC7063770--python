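"""Model-evaluation protocol for GFR estimation.

Performance of an estimator is summarised by the standard triad on the
per-subject error ``d_i = eGFR_i - mGFR_i``:

* **bias** — median of d (mL/min/1.73 m^2),
* **precision** — interquartile range of d (smaller is better),
* **P30** — percentage of subjects with eGFR within ±30% of mGFR.

95% confidence intervals come from a subject-level percentile bootstrap
(2000 resamples by default).  Paired model comparisons use the tests
conventional for each metric: Wilcoxon signed-rank on the per-subject
difference of differences for bias (exact null for n <= 25, handling
ties via midranks; normal approximation above), a paired sign-swap
permutation test for the IQR, and McNemar's test on the discordant
within-30% indicators for P30.  Reports are produced overall and within
measured-GFR strata (< 60 / >= 60, and the finer < 30 / 30–59 / 60–89 /
>= 90 split; boundaries left-closed).

Quantiles use linear interpolation between order statistics throughout
(the ``numpy`` default); the convention is a parameter of
:func:`metrics` for sensitivity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "PairedDifferences",
    "EvaluationResult",
    "ComparisonResult",
    "EvaluationError",
    "metrics",
    "bootstrap_ci",
    "compare_bias",
    "compare_precision",
    "compare_p30",
    "stratified_report",
    "COARSE_STRATA",
    "FINE_STRATA",
]

#: stratum label -> (low, high) bounds on mGFR, left-closed [low, high)
COARSE_STRATA = {"overall": (0.0, np.inf),
                 "mGFR<60": (0.0, 60.0),
                 "mGFR>=60": (60.0, np.inf)}
FINE_STRATA = {"mGFR<30": (0.0, 30.0),
               "mGFR30-59": (30.0, 60.0),
               "mGFR60-89": (60.0, 90.0),
               "mGFR>=90": (90.0, np.inf)}


class EvaluationError(Exception):
    pass


def _iqr(x: np.ndarray, method: str = "linear") -> float:
    q1, q3 = np.quantile(x, [0.25, 0.75], method=method)
    return float(q3 - q1)


def within_30pct(e: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Indicator a_i = 1 iff |e_i - m_i| <= 0.3 * m_i."""
    e = np.asarray(e, dtype=float)
    m = np.asarray(m, dtype=float)
    return (np.abs(e - m) <= 0.3 * m).astype(int)


@dataclass(frozen=True)
class PairedDifferences:
    """Per-subject errors of one model, aligned by subject."""
    subject_ids: tuple[str, ...]
    d: np.ndarray        # eGFR - mGFR
    a: np.ndarray        # within-30% indicator

    @classmethod
    def from_predictions(cls, subject_ids: Sequence[str],
                         e: np.ndarray, m: np.ndarray) -> "PairedDifferences":
        e = np.asarray(e, dtype=float)
        m = np.asarray(m, dtype=float)
        if len(e) != len(m) or len(e) != len(subject_ids):
            raise EvaluationError("e, m and subject_ids must be aligned")
        if np.any(m <= 0):
            raise EvaluationError("mGFR must be positive")
        return cls(tuple(subject_ids), e - m, within_30pct(e, m))


@dataclass(frozen=True)
class EvaluationResult:
    stratum: str
    n: int
    bias: float
    precision: float
    p30: float
    bias_ci: tuple[float, float] | None = None
    precision_ci: tuple[float, float] | None = None
    p30_ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class ComparisonResult:
    stratum: str
    p_bias: float
    p_precision: float
    p_p30: float


def metrics(e: Sequence[float], m: Sequence[float], stratum: str = "overall",
            quantile_method: str = "linear") -> EvaluationResult:
    """Point estimates of bias, precision and P30 for one model."""
    e = np.asarray(e, dtype=float)
    m = np.asarray(m, dtype=float)
    if e.shape != m.shape:
        raise EvaluationError(f"length mismatch: {e.shape} vs {m.shape}")
    if e.size < 1:
        raise EvaluationError("need at least one subject")
    if np.any(m <= 0):
        raise EvaluationError("mGFR must be positive")
    d = e - m
    return EvaluationResult(
        stratum=stratum, n=int(e.size),
        bias=float(np.median(d)),
        precision=_iqr(d, quantile_method),
        p30=float(100.0 * within_30pct(e, m).mean()))


_STATISTICS = ("bias", "precision", "p30")


def _stat_rows(statistic: str, e_rows: np.ndarray, m_rows: np.ndarray,
               quantile_method: str) -> np.ndarray:
    d = e_rows - m_rows
    if statistic == "bias":
        return np.median(d, axis=1)
    if statistic == "precision":
        q1, q3 = np.quantile(d, [0.25, 0.75], axis=1, method=quantile_method)
        return q3 - q1
    if statistic == "p30":
        return 100.0 * (np.abs(d) <= 0.3 * m_rows).mean(axis=1)
    raise EvaluationError(f"unknown statistic {statistic!r}; "
                          f"expected one of {_STATISTICS}")


def bootstrap_ci(statistic: str, e: Sequence[float], m: Sequence[float],
                 B: int = 2000, seed: int = 0,
                 quantile_method: str = "linear") -> tuple[float, float]:
    """Subject-level percentile bootstrap 95% CI for a named metric.

    Subjects are resampled with replacement ``B`` times; the interval is
    the (2.5th, 97.5th) percentile of the replicate statistics.
    Deterministic given ``seed``.
    """
    e = np.asarray(e, dtype=float)
    m = np.asarray(m, dtype=float)
    if B < 1:
        raise EvaluationError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n = e.size
    idx = rng.integers(0, n, size=(B, n))
    reps = _stat_rows(statistic, e[idx], m[idx], quantile_method)
    lo, hi = np.quantile(reps, [0.025, 0.975])
    return float(lo), float(hi)


# ---- paired comparison tests -----------------------------------------


def _exact_signed_rank_p(x: np.ndarray) -> float:
    """Two-sided exact Wilcoxon signed-rank p-value.

    Zeros are dropped; ties are handled with midranks, whose doubled
    values are integers, so the null distribution of W+ (sum of ranks of
    positive values) is computed exactly by dynamic programming over all
    2^n sign assignments.
    """
    x = x[x != 0]
    n = x.size
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(x))           # midranks
    r2 = np.rint(2 * ranks).astype(int)       # doubled midranks: integers
    w_obs = int(np.rint(2 * ranks[x > 0].sum()))
    total = int(r2.sum())
    # dist[s] = #assignments with doubled W+ == s
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    p_le = dist[:w_obs + 1].sum()
    p_ge = dist[w_obs:].sum()
    return float(min(1.0, 2 * min(p_le, p_ge)))


def compare_bias(d1: PairedDifferences, d2: PairedDifferences,
                 exact_max_n: int = 25, on_absolute: bool = False) -> float:
    """Wilcoxon signed-rank test comparing the bias of two models.

    Tests median(d1 - d2) = 0 on the per-subject paired values (or
    median(|d1| - |d2|) with ``on_absolute=True``).  Exact null for
    n <= ``exact_max_n`` non-zero pairs; normal approximation with tie
    correction above.
    """
    if d1.subject_ids != d2.subject_ids:
        raise EvaluationError("paired differences are not subject-aligned")
    x = (np.abs(d1.d) - np.abs(d2.d)) if on_absolute else (d1.d - d2.d)
    if np.all(x == 0):
        warnings.warn("models are identical on every subject; p = 1")
        return 1.0
    n_nonzero = int((x != 0).sum())
    if n_nonzero <= exact_max_n:
        return _exact_signed_rank_p(x)
    res = sps.wilcoxon(x, zero_method="wilcox", correction=True,
                       method="approx")
    return float(res.pvalue)


def compare_precision(d1: PairedDifferences, d2: PairedDifferences,
                      n_perm: int = 2000, seed: int = 0,
                      quantile_method: str = "linear") -> float:
    """Paired sign-swap permutation test comparing IQRs.

    Observed statistic T = IQR(d1) - IQR(d2).  Under the null the model
    labels are exchangeable within subject, so each permutation swaps
    (d1_i, d2_i) independently with probability 1/2.  Two-sided p with
    the add-one correction ``(1 + #{|T*| >= |T|}) / (n_perm + 1)``.
    """
    if d1.subject_ids != d2.subject_ids:
        raise EvaluationError("paired differences are not subject-aligned")
    if n_perm < 1:
        raise EvaluationError("n_perm must be >= 1")
    a, b = d1.d, d2.d
    t_obs = _iqr(a, quantile_method) - _iqr(b, quantile_method)
    rng = np.random.default_rng(seed)
    swap = rng.random((n_perm, a.size)) < 0.5
    a_star = np.where(swap, b, a)
    b_star = np.where(swap, a, b)
    q = np.quantile(a_star, [0.25, 0.75], axis=1, method=quantile_method)
    t_star = (q[1] - q[0])
    q = np.quantile(b_star, [0.25, 0.75], axis=1, method=quantile_method)
    t_star = t_star - (q[1] - q[0])
    exceed = int((np.abs(t_star) >= abs(t_obs) - 1e-12).sum())
    return float((1 + exceed) / (n_perm + 1))


def compare_p30(a1: Sequence[int], a2: Sequence[int],
                exact_max_discordant: int = 25) -> float:
    """McNemar test comparing two models' P30.

    Builds the 2x2 discordance table of the within-30% indicators
    (b = model-1 hit & model-2 miss, c = the reverse); exact binomial
    test when b + c < ``exact_max_discordant``, chi-square with
    continuity correction otherwise.  Two-sided.
    """
    a1 = np.asarray(a1, dtype=int)
    a2 = np.asarray(a2, dtype=int)
    if a1.shape != a2.shape:
        raise EvaluationError("indicator vectors are not aligned")
    if not (np.isin(a1, (0, 1)).all() and np.isin(a2, (0, 1)).all()):
        raise EvaluationError("indicators must be binary")
    b = int(((a1 == 1) & (a2 == 0)).sum())
    c = int(((a1 == 0) & (a2 == 1)).sum())
    if b + c == 0:
        warnings.warn("no discordant pairs; p = 1")
        return 1.0
    n11 = int(((a1 == 1) & (a2 == 1)).sum())
    n00 = int(((a1 == 0) & (a2 == 0)).sum())
    table = [[n11, b], [c, n00]]
    res = _sm_mcnemar(table, exact=(b + c) < exact_max_discordant,
                      correction=True)
    return float(min(1.0, res.pvalue))


# ---- stratified report ------------------------------------------------


def _strata_map(strata: str) -> dict[str, tuple[float, float]]:
    if strata == "coarse":
        return dict(COARSE_STRATA)
    if strata == "fine":
        return {"overall": (0.0, np.inf)} | dict(FINE_STRATA)
    if strata == "both":
        return dict(COARSE_STRATA) | dict(FINE_STRATA)
    raise EvaluationError(f"unknown strata scheme {strata!r}")


def stratified_report(models: Sequence[np.ndarray], m: Sequence[float],
                      reference_index: int = 0,
                      model_names: Sequence[str] | None = None,
                      subject_ids: Sequence[str] | None = None,
                      strata: str = "coarse", bootstrap_B: int = 2000,
                      n_perm: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Evaluation table for several models, overall and by mGFR stratum.

    Each non-reference model is compared against the reference model
    within every stratum.  Returns a tidy DataFrame with one row per
    (stratum, model) and columns for each metric, its bootstrap CI, and
    the comparison p-value (NaN for the reference row).  Empty strata
    yield rows with NaN metrics.
    """
    m = np.asarray(m, dtype=float)
    models = [np.asarray(e, dtype=float) for e in models]
    for e in models:
        if e.shape != m.shape:
            raise EvaluationError("all model vectors must align with mGFR")
    if model_names is None:
        model_names = [f"model{i}" for i in range(len(models))]
    if subject_ids is None:
        subject_ids = [f"s{i}" for i in range(m.size)]
    subject_ids = list(subject_ids)

    rows = []
    for stratum, (lo, hi) in _strata_map(strata).items():
        mask = (m >= lo) & (m < hi)
        ids = tuple(s for s, k in zip(subject_ids, mask) if k)
        ms = m[mask]
        if ms.size == 0:
            for name in model_names:
                rows.append({"stratum": stratum, "model": name, "n": 0})
            continue
        pd_by_model = [PairedDifferences.from_predictions(ids, e[mask], ms)
                       for e in models]
        ref = pd_by_model[reference_index]
        for j, (name, e) in enumerate(zip(model_names, models)):
            es = e[mask]
            res = metrics(es, ms, stratum=stratum)
            row = {
                "stratum": stratum, "model": name, "n": res.n,
                "bias": res.bias, "precision": res.precision, "p30": res.p30,
            }
            for stat in _STATISTICS:
                lo_ci, hi_ci = bootstrap_ci(stat, es, ms, B=bootstrap_B,
                                            seed=seed)
                row[f"{stat}_ci_low"], row[f"{stat}_ci_high"] = lo_ci, hi_ci
            if j != reference_index:
                dj = pd_by_model[j]
                row["p_bias"] = compare_bias(dj, ref)
                row["p_precision"] = compare_precision(dj, ref, n_perm=n_perm,
                                                       seed=seed)
                row["p_p30"] = compare_p30(dj.a, ref.a)
            rows.append(row)
    return pd.DataFrame(rows)
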