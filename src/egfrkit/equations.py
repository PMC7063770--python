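"""Piecewise multiplicative eGFR equations.

The equation family estimated here is the CKD-EPI style: per sex,

    eGFR = I * min(scr/k_scr, 1)^a_lo * max(scr/k_scr, 1)^a_hi
             * min(scys/k_scys, 1)^b_lo * max(scys/k_scys, 1)^b_hi
             * f_age^age * PRODUCT(aux terms)

where ``k`` are the spline knots of the two filtration markers, the
exponents are the log-log slopes below/above each knot, ``f_age`` is a
per-year multiplier, and each auxiliary term is either a per-unit factor
``c^x`` (BMI, ALB, UA, HGB) or a power ``x^e`` (BUN).  The min/max form
is algebraically identical to enumerating the four branch combinations
and is continuous at the knots by construction: at ``x == k`` both
branches contribute a factor of exactly 1, so the <=/> convention at the
boundary is immaterial.

Two fixed constant sets ship with the package as JSON fixtures —
:func:`revised_ckdepi_4var` (age, sex, creatinine, cystatin C) and
:func:`revised_ckdepi_9var` (plus BMI, BUN, albumin, uric acid,
hemoglobin) — and the fitting pipeline in
:mod:`egfrkit.development` emits equations in the same format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import Cohort, PatientRecord, Sex

__all__ = [
    "AuxTerm",
    "SexBlock",
    "MultiplicativeEquation",
    "EquationError",
    "InsufficientVariablesError",
    "revised_ckdepi_4var",
    "revised_ckdepi_9var",
    "load_equation",
    "evaluate",
    "evaluate_batch",
]


class EquationError(Exception):
    pass


class InsufficientVariablesError(EquationError):
    """The record lacks a variable this equation references."""


@dataclass(frozen=True)
class AuxTerm:
    """One auxiliary multiplicative term.

    ``kind == "factor"``: contributes ``value ** x`` (per-unit multiplier).
    ``kind == "power"``:  contributes ``x ** value`` (power of the variable).
    """

    variable: str
    kind: str
    value: float

    def __post_init__(self):
        if self.kind not in ("factor", "power"):
            raise EquationError(f"unknown aux term kind {self.kind!r}")
        if self.kind == "factor" and not self.value > 0:
            raise EquationError(f"aux factor for {self.variable!r} must be > 0")

    def contribution(self, x: float) -> float:
        if self.kind == "factor":
            return self.value ** x
        return x ** self.value


@dataclass(frozen=True)
class SexBlock:
    """Constants of the equation for one sex."""

    intercept: float
    scr_knot: float
    scys_knot: float
    scr_exp_low: float
    scr_exp_high: float
    scys_exp_low: float
    scys_exp_high: float
    age_factor: float
    aux_terms: tuple[AuxTerm, ...] = ()

    def __post_init__(self):
        if not self.intercept > 0:
            raise EquationError("intercept must be > 0")
        if not (self.scr_knot > 0 and self.scys_knot > 0):
            raise EquationError("knots must be > 0")
        for name in ("scr_exp_low", "scr_exp_high", "scys_exp_low", "scys_exp_high"):
            if getattr(self, name) > 0:
                raise EquationError(f"{name} must be <= 0")
        if not self.age_factor > 0:
            raise EquationError("age_factor must be > 0")


@dataclass(frozen=True)
class MultiplicativeEquation:
    """Sex-stratified piecewise multiplicative eGFR equation."""

    female: SexBlock
    male: SexBlock
    name: str = ""
    description: str = ""

    def block(self, sex: Sex) -> SexBlock:
        return self.male if sex is Sex.MALE else self.female

    def variables(self) -> list[str]:
        """Variables referenced besides age and sex, in evaluation order."""
        out = ["scr", "scys"]
        for t in self.female.aux_terms:
            out.append(t.variable)
        return out

    # ---- serialization ----------------------------------------------

    def to_dict(self) -> dict:
        def block_dict(b: SexBlock) -> dict:
            d = {k: getattr(b, k) for k in (
                "intercept", "scr_knot", "scys_knot", "scr_exp_low",
                "scr_exp_high", "scys_exp_low", "scys_exp_high", "age_factor")}
            d["aux_terms"] = [
                {"variable": t.variable, "kind": t.kind, "value": t.value}
                for t in b.aux_terms]
            return d
        return {"name": self.name, "description": self.description,
                "female": block_dict(self.female), "male": block_dict(self.male)}

    @classmethod
    def from_dict(cls, d: dict) -> "MultiplicativeEquation":
        def block(bd: dict) -> SexBlock:
            try:
                aux = tuple(AuxTerm(t["variable"], t["kind"], float(t["value"]))
                            for t in bd.get("aux_terms", []))
                return SexBlock(
                    intercept=float(bd["intercept"]),
                    scr_knot=float(bd["scr_knot"]),
                    scys_knot=float(bd["scys_knot"]),
                    scr_exp_low=float(bd["scr_exp_low"]),
                    scr_exp_high=float(bd["scr_exp_high"]),
                    scys_exp_low=float(bd["scys_exp_low"]),
                    scys_exp_high=float(bd["scys_exp_high"]),
                    age_factor=float(bd["age_factor"]),
                    aux_terms=aux)
            except KeyError as exc:
                raise EquationError(f"equation fixture missing field {exc}")
        return cls(female=block(d["female"]), male=block(d["male"]),
                   name=d.get("name", ""), description=d.get("description", ""))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _load_fixture(fname: str) -> MultiplicativeEquation:
    text = resources.files("egfrkit.data").joinpath(fname).read_text()
    return MultiplicativeEquation.from_dict(json.loads(text))


def revised_ckdepi_4var() -> MultiplicativeEquation:
    """The revised 4-variable equation constant set (packaged fixture)."""
    return _load_fixture("revised_ckdepi_4var.json")


def revised_ckdepi_9var() -> MultiplicativeEquation:
    """The revised 9-variable equation constant set (packaged fixture)."""
    return _load_fixture("revised_ckdepi_9var.json")


def load_equation(source: str | Path) -> MultiplicativeEquation:
    """Load an equation by shorthand (``"4var"``/``"9var"``) or JSON path."""
    if str(source) in ("4var", "4-var", "four_variable"):
        return revised_ckdepi_4var()
    if str(source) in ("9var", "9-var", "nine_variable"):
        return revised_ckdepi_9var()
    return MultiplicativeEquation.from_dict(json.loads(Path(source).read_text()))


def _spline_factor(x: float, knot: float, exp_low: float, exp_high: float) -> float:
    r = x / knot
    return min(r, 1.0) ** exp_low * max(r, 1.0) ** exp_high


def evaluate(eq: MultiplicativeEquation, rec: PatientRecord) -> float:
    """Evaluate the equation for one record; returns eGFR in mL/min/1.73 m^2.

    Raises :class:`InsufficientVariablesError` if any variable the
    equation references is missing from the record — there is no
    fallback to a reduced equation.
    """
    b = eq.block(rec.sex)
    needed = ["scr", "scys"] + [t.variable for t in b.aux_terms]
    missing = [v for v in needed if rec.get(v) is None]
    if missing:
        raise InsufficientVariablesError(
            f"insufficient variables for this equation: subject "
            f"{rec.subject_id!r} missing {missing}")
    out = b.intercept
    out *= _spline_factor(rec.scr, b.scr_knot, b.scr_exp_low, b.scr_exp_high)
    out *= _spline_factor(rec.scys, b.scys_knot, b.scys_exp_low, b.scys_exp_high)
    out *= b.age_factor ** rec.age
    for t in b.aux_terms:
        out *= t.contribution(rec.get(t.variable))
    return out


def evaluate_batch(eq: MultiplicativeEquation, cohort: Cohort
                   ) -> tuple[list[str], np.ndarray]:
    """Evaluate the equation over a cohort.

    Returns ``(subject_ids, egfr)`` with order preserved; element-wise
    identical to :func:`evaluate` per record.
    """
    ids, vals = [], []
    for rec in cohort:
        vals.append(evaluate(eq, rec))
        ids.append(rec.subject_id)
    return ids, np.asarray(vals, dtype=float)
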