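"""Development of piecewise multiplicative eGFR equations by OLS.

The estimation problem is linear after a log transform: with measured
GFR as the response,

    ln(mGFR) = b0 + a_lo*min(ln(scr/k_scr), 0) + a_hi*max(ln(scr/k_scr), 0)
                  + c_lo*min(ln(scys/k_scys), 0) + c_hi*max(ln(scys/k_scys), 0)
                  + b_age*age [+ b_bmi*BMI + b_bun*ln(BUN) + b_alb*ALB
                               + b_ua*UA + b_hgb*HGB]  + error,

a two-segment linear spline in each log marker with a single knot ``k``
per marker.  Exponentiating the fit gives a
:class:`~egfrkit.equations.MultiplicativeEquation`:
intercept ``exp(b0)``, marker exponents equal to the spline slopes,
age factor ``exp(b_age)``, per-unit auxiliary factors ``exp(b_x)`` and
BUN entering as a power ``BUN**b_bun``.

Fits are fully stratified by sex (separate coefficient sets, including
the age and auxiliary factors).  Knots are chosen by exhaustive grid
search minimising the pooled log-scale residual sum of squares, with a
sex-specific creatinine knot and a single cystatin C knot shared by both
sexes; ties break toward the smallest candidate knots.  The nine-variable
fit inherits the knots selected under the four-variable design (override
via the ``knots`` argument of :func:`develop_equation`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .cohort import Cohort, PatientRecord, Sex
from .equations import AuxTerm, MultiplicativeEquation, SexBlock

__all__ = [
    "FitSpec",
    "KnotSet",
    "LogCoefficients",
    "FitResult",
    "FitError",
    "default_scr_grid",
    "default_scys_grid",
    "build_design",
    "fit_at_knots",
    "select_knots",
    "develop_equation",
]

FOUR_VARIABLE = "four_variable"
NINE_VARIABLE = "nine_variable"

#: auxiliary variables of the nine-variable equation, in design order
AUX_VARIABLES = ("bmi", "bun", "alb", "ua", "hgb")


class FitError(Exception):
    pass


def default_scr_grid() -> tuple[float, ...]:
    """Candidate creatinine knots: 0.5 to 1.5 mg/dL in steps of 0.1."""
    return tuple(round(0.5 + 0.1 * i, 1) for i in range(11))


def default_scys_grid() -> tuple[float, ...]:
    """Candidate cystatin C knots: 0.6 to 1.4 mg/L in steps of 0.1."""
    return tuple(round(0.6 + 0.1 * i, 1) for i in range(9))


@dataclass(frozen=True)
class FitSpec:
    variable_set: str = FOUR_VARIABLE
    knot_grid_scr: tuple[float, ...] = field(default_factory=default_scr_grid)
    knot_grid_scys: tuple[float, ...] = field(default_factory=default_scys_grid)
    stratify_by_sex: bool = True

    def __post_init__(self):
        if self.variable_set not in (FOUR_VARIABLE, NINE_VARIABLE):
            raise FitError(f"unknown variable_set {self.variable_set!r}")
        for grid, name in ((self.knot_grid_scr, "knot_grid_scr"),
                           (self.knot_grid_scys, "knot_grid_scys")):
            if len(grid) == 0 or any(g <= 0 for g in grid) or \
                    list(grid) != sorted(grid):
                raise FitError(f"{name} must be non-empty, positive, sorted")

    @property
    def required_vars(self) -> tuple[str, ...]:
        base = ("age", "scr", "scys", "mgfr")
        if self.variable_set == NINE_VARIABLE:
            return base + AUX_VARIABLES
        return base

    def design_columns(self) -> list[str]:
        cols = ["const", "scr_low", "scr_high", "scys_low", "scys_high", "age"]
        if self.variable_set == NINE_VARIABLE:
            cols += ["bmi", "ln_bun", "alb", "ua", "hgb"]
        return cols


@dataclass(frozen=True)
class KnotSet:
    """Selected spline knots: creatinine per sex, cystatin C shared."""
    scr_female: float
    scr_male: float
    scys: float


@dataclass(frozen=True)
class LogCoefficients:
    """OLS coefficients on the log scale for one sex stratum."""
    b0: float
    b_scr_low: float
    b_scr_high: float
    b_scys_low: float
    b_scys_high: float
    b_age: float
    b_bmi: float | None = None
    b_lnbun: float | None = None
    b_alb: float | None = None
    b_ua: float | None = None
    b_hgb: float | None = None

    @classmethod
    def from_params(cls, params: np.ndarray, nine: bool) -> "LogCoefficients":
        base = dict(b0=params[0], b_scr_low=params[1], b_scr_high=params[2],
                    b_scys_low=params[3], b_scys_high=params[4], b_age=params[5])
        if nine:
            base.update(b_bmi=params[6], b_lnbun=params[7], b_alb=params[8],
                        b_ua=params[9], b_hgb=params[10])
        return cls(**base)

    def to_params(self) -> np.ndarray:
        vals = [self.b0, self.b_scr_low, self.b_scr_high,
                self.b_scys_low, self.b_scys_high, self.b_age]
        if self.b_bmi is not None:
            vals += [self.b_bmi, self.b_lnbun, self.b_alb, self.b_ua, self.b_hgb]
        return np.array(vals)


@dataclass(frozen=True)
class FitResult:
    """A fitted equation with its log-scale coefficients and diagnostics.

    For a single-stratum fit (``fit_at_knots``) only one sex key is
    present in ``log_scale_coefficients``/``residual_sd``/``n_used``.
    """
    equation: MultiplicativeEquation | None
    log_scale_coefficients: dict[Sex, LogCoefficients]
    residual_sd: dict[Sex, float]
    n_used: dict[Sex, int]
    knots: KnotSet
    spec: FitSpec

    @property
    def total_n(self) -> int:
        return sum(self.n_used.values())

    def report(self) -> str:
        """Plain-text fit report: knots, coefficients, residual SD, n."""
        lines = [f"variable set: {self.spec.variable_set}",
                 f"knots: scr F={self.knots.scr_female:g} mg/dL, "
                 f"M={self.knots.scr_male:g} mg/dL, scys={self.knots.scys:g} mg/L"]
        for sex, co in self.log_scale_coefficients.items():
            lines.append(f"[{sex.name.lower()}] n={self.n_used[sex]}, "
                         f"residual SD (log scale)={self.residual_sd[sex]:.4f}")
            for name, v in vars(co).items():
                if v is not None:
                    lines.append(f"  {name} = {v:+.6f}")
        return "\n".join(lines)


def _records_for(cohort: Cohort, sex: Sex | None) -> list[PatientRecord]:
    if sex is None:
        return list(cohort)
    return [r for r in cohort if r.sex is sex]


def build_design(records: Sequence[PatientRecord], spec: FitSpec,
                 scr_knot: float, scys_knot: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and response ``ln(mGFR)`` for a set of records.

    Columns follow :meth:`FitSpec.design_columns`; row order is
    preserved.  Raises :class:`FitError` naming the subject if any
    log-transformed quantity is non-positive or missing.
    """
    nine = spec.variable_set == NINE_VARIABLE
    rows, y = [], []
    for r in records:
        needed = ["mgfr", "scr", "scys"] + (["bun"] if nine else [])
        for name in needed:
            v = r.get(name)
            if v is None or not v > 0:
                raise FitError(f"subject {r.subject_id!r}: {name} must be "
                               f"positive and present, got {v!r}")
        if nine:
            for name in ("bmi", "alb", "ua", "hgb"):
                if r.get(name) is None:
                    raise FitError(f"subject {r.subject_id!r}: {name} missing")
        ls = math.log(r.scr / scr_knot)
        lc = math.log(r.scys / scys_knot)
        row = [1.0, min(ls, 0.0), max(ls, 0.0), min(lc, 0.0), max(lc, 0.0),
               float(r.age)]
        if nine:
            row += [float(r.bmi), math.log(r.bun), float(r.alb),
                    float(r.ua), float(r.hgb)]
        rows.append(row)
        y.append(math.log(r.mgfr))
    X = np.asarray(rows, dtype=float).reshape(len(rows), len(spec.design_columns()))
    return X, np.asarray(y, dtype=float)


def _coefficients_to_block(co: LogCoefficients, scr_knot: float,
                           scys_knot: float) -> SexBlock:
    aux: tuple[AuxTerm, ...] = ()
    if co.b_bmi is not None:
        aux = (AuxTerm("bmi", "factor", math.exp(co.b_bmi)),
               AuxTerm("bun", "power", co.b_lnbun),
               AuxTerm("alb", "factor", math.exp(co.b_alb)),
               AuxTerm("ua", "factor", math.exp(co.b_ua)),
               AuxTerm("hgb", "factor", math.exp(co.b_hgb)))
    return SexBlock(
        intercept=math.exp(co.b0),
        scr_knot=scr_knot, scys_knot=scys_knot,
        scr_exp_low=co.b_scr_low, scr_exp_high=co.b_scr_high,
        scys_exp_low=co.b_scys_low, scys_exp_high=co.b_scys_high,
        age_factor=math.exp(co.b_age), aux_terms=aux)


def block_to_coefficients(block: SexBlock) -> LogCoefficients:
    """Inverse of the exp transform: log-scale coefficients of a SexBlock."""
    kw = dict(b0=math.log(block.intercept),
              b_scr_low=block.scr_exp_low, b_scr_high=block.scr_exp_high,
              b_scys_low=block.scys_exp_low, b_scys_high=block.scys_exp_high,
              b_age=math.log(block.age_factor))
    if block.aux_terms:
        by_var = {t.variable: t for t in block.aux_terms}
        kw.update(b_bmi=math.log(by_var["bmi"].value),
                  b_lnbun=by_var["bun"].value,
                  b_alb=math.log(by_var["alb"].value),
                  b_ua=math.log(by_var["ua"].value),
                  b_hgb=math.log(by_var["hgb"].value))
    return LogCoefficients(**kw)


def fit_at_knots(cohort: Cohort, spec: FitSpec, scr_knot: float,
                 scys_knot: float, sex: Sex | None = None) -> FitResult:
    """OLS fit on the log scale for one sex stratum at fixed knots.

    ``sex=None`` uses all records (for unstratified use on pre-filtered
    cohorts).  The residual SD uses the ``n - p`` denominator.
    """
    records = _records_for(cohort, sex)
    X, y = build_design(records, spec, scr_knot, scys_knot)
    n, p = X.shape
    if n <= p:
        raise FitError(f"need more than {p} records to fit, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise FitError("design matrix is rank deficient (singular fit)")
    res = sm.OLS(y, X).fit()
    co = LogCoefficients.from_params(res.params,
                                     spec.variable_set == NINE_VARIABLE)
    resid_sd = float(np.sqrt(res.ssr / (n - p)))
    sex_key = sex if sex is not None else Sex.FEMALE
    # single-stratum result: the equation is assembled by develop_equation
    knots = KnotSet(scr_female=scr_knot, scr_male=scr_knot, scys=scys_knot)
    return FitResult(equation=None, log_scale_coefficients={sex_key: co},
                     residual_sd={sex_key: resid_sd}, n_used={sex_key: n},
                     knots=knots, spec=spec)


def _sse_at(records: Sequence[PatientRecord], spec: FitSpec,
            scr_knot: float, scys_knot: float) -> float:
    X, y = build_design(records, spec, scr_knot, scys_knot)
    n, p = X.shape
    if n <= p or np.linalg.matrix_rank(X) < p:
        raise FitError("singular or underdetermined candidate fit")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def select_knots(cohort: Cohort, spec: FitSpec) -> KnotSet:
    """Exhaustive grid search for the spline knots.

    For every candidate cystatin C knot (shared across sexes) the best
    sex-specific creatinine knot is found per sex; the cystatin knot
    minimising the pooled residual sum of squares is selected.
    Deterministic; ties break toward the smallest knot values.
    Candidates producing singular fits are skipped with a warning.
    """
    strata = [Sex.FEMALE, Sex.MALE] if spec.stratify_by_sex else [None]
    per_sex = {s: _records_for(cohort, s) for s in strata}
    best_total, best = math.inf, None
    any_ok = False
    for scys_knot in spec.knot_grid_scys:
        total = 0.0
        chosen: dict = {}
        ok = True
        for s in strata:
            best_sse, best_scr = math.inf, None
            for scr_knot in spec.knot_grid_scr:
                try:
                    sse = _sse_at(per_sex[s], spec, scr_knot, scys_knot)
                except FitError as exc:
                    warnings.warn(f"skipping knot candidate (scr={scr_knot}, "
                                  f"scys={scys_knot}, sex={s}): {exc}")
                    continue
                if sse < best_sse:  # strict: ties keep the smaller knot
                    best_sse, best_scr = sse, scr_knot
            if best_scr is None:
                ok = False
                break
            total += best_sse
            chosen[s] = best_scr
        if not ok:
            continue
        any_ok = True
        if total < best_total:
            best_total, best = total, chosen | {"scys": scys_knot}
    if not any_ok or best is None:
        raise FitError("every knot candidate produced a singular fit")
    if spec.stratify_by_sex:
        return KnotSet(scr_female=best[Sex.FEMALE], scr_male=best[Sex.MALE],
                       scys=best["scys"])
    return KnotSet(scr_female=best[None], scr_male=best[None], scys=best["scys"])


def develop_equation(dev: Cohort, spec: FitSpec,
                     knots: KnotSet | None = None) -> FitResult:
    """Full equation development on a development cohort.

    Selects knots by grid search (always under the four-variable design,
    so the nine-variable equation inherits the four-variable knots —
    pass ``knots`` to override), then fits each sex stratum by OLS and
    assembles the resulting :class:`MultiplicativeEquation`.
    """
    if knots is None:
        knot_spec = replace(spec, variable_set=FOUR_VARIABLE)
        knots = select_knots(dev, knot_spec)
    blocks: dict[Sex, SexBlock] = {}
    coefs: dict[Sex, LogCoefficients] = {}
    resid: dict[Sex, float] = {}
    n_used: dict[Sex, int] = {}
    for sex, scr_knot in ((Sex.FEMALE, knots.scr_female),
                          (Sex.MALE, knots.scr_male)):
        part = fit_at_knots(dev, spec, scr_knot, knots.scys, sex=sex)
        co = part.log_scale_coefficients[sex]
        coefs[sex] = co
        resid[sex] = part.residual_sd[sex]
        n_used[sex] = part.n_used[sex]
        blocks[sex] = _coefficients_to_block(co, scr_knot, knots.scys)
    eq = MultiplicativeEquation(
        female=blocks[Sex.FEMALE], male=blocks[Sex.MALE],
        name=f"fitted_{spec.variable_set}",
        description=f"OLS-developed {spec.variable_set} equation "
                    f"(n={sum(n_used.values())})")
    return FitResult(equation=eq, log_scale_coefficients=coefs,
                     residual_sd=resid, n_used=n_used, knots=knots, spec=spec)


def rounded_equation(eq: MultiplicativeEquation) -> MultiplicativeEquation:
    """Display-rounded copy: intercepts to integers, other constants to
    three decimals (the conventional presentation of these equations)."""
    def round_block(b: SexBlock) -> SexBlock:
        return SexBlock(
            intercept=float(round(b.intercept)),
            scr_knot=round(b.scr_knot, 3), scys_knot=round(b.scys_knot, 3),
            scr_exp_low=round(b.scr_exp_low, 3),
            scr_exp_high=round(b.scr_exp_high, 3),
            scys_exp_low=round(b.scys_exp_low, 3),
            scys_exp_high=round(b.scys_exp_high, 3),
            age_factor=round(b.age_factor, 3),
            aux_terms=tuple(AuxTerm(t.variable, t.kind, round(t.value, 3))
                            for t in b.aux_terms))
    return MultiplicativeEquation(female=round_block(eq.female),
                                  male=round_block(eq.male),
                                  name=eq.name + "_rounded",
                                  description=eq.description)
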