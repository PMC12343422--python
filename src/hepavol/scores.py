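"""Serum-based liver scores: FIB-4, ALBI, and MELD-Na.

Units follow the package's cohort convention: albumin in g/L, bilirubin in
mg/dL (converted internally to umol/L for ALBI, x 17.1), platelets in
Giga/L, AST/ALT in U/L, sodium in mmol/L, creatinine in mg/dL.

Formulas:

* FIB-4  = age * AST / (platelets * sqrt(ALT))
* ALBI   = 0.66 * log10(bilirubin [umol/L]) - 0.085 * albumin [g/L]
* MELD   = 9.57 ln(creatinine) + 3.78 ln(bilirubin) + 11.2 ln(INR) + 6.43,
  with creatinine clamped to [1.0, 4.0], bilirubin and INR floored at 1.0;
  MELD-Na = MELD + 1.32 (137 - Na) - 0.033 MELD (137 - Na) with sodium
  clamped to [125, 137]; the final score is clamped to [6, 40].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

MG_DL_TO_UMOL_L_BILIRUBIN = 17.1


class MissingLabError(ValueError):
    """A score's required laboratory value is absent or non-positive."""


@dataclass(frozen=True)
class ScorePanel:
    """Derived scores for one subject; a score is None when a required
    lab is missing (never silently zero)."""

    fib4: float | None
    albi: float | None
    meld_na: float | None


def _require_positive(name: str, value: float | None) -> float:
    if value is None or not math.isfinite(value):
        raise MissingLabError(f"missing laboratory value: {name}")
    if value <= 0:
        raise MissingLabError(f"non-positive laboratory value: {name}={value}")
    return float(value)


def fib4_score(age_years: float, ast_u_l: float, alt_u_l: float, platelets_g_l: float) -> float:
    age = _require_positive("age", age_years)
    ast = _require_positive("ast", ast_u_l)
    alt = _require_positive("alt", alt_u_l)
    plt = _require_positive("platelets", platelets_g_l)
    return age * ast / (plt * math.sqrt(alt))


def albi_score(bilirubin_mg_dl: float, albumin_g_l: float) -> float:
    bili = _require_positive("bilirubin", bilirubin_mg_dl)
    alb = _require_positive("albumin", albumin_g_l)
    bili_umol = bili * MG_DL_TO_UMOL_L_BILIRUBIN
    return 0.66 * math.log10(bili_umol) - 0.085 * alb


def meld_na_score(
    bilirubin_mg_dl: float,
    inr: float,
    creatinine_mg_dl: float,
    sodium_mmol_l: float,
) -> float:
    bili = max(_require_positive("bilirubin", bilirubin_mg_dl), 1.0)
    inr_v = max(_require_positive("inr", inr), 1.0)
    creat = min(max(_require_positive("creatinine", creatinine_mg_dl), 1.0), 4.0)
    na = min(max(_require_positive("sodium", sodium_mmol_l), 125.0), 137.0)
    meld = 9.57 * math.log(creat) + 3.78 * math.log(bili) + 11.2 * math.log(inr_v) + 6.43
    meld_na = meld + 1.32 * (137.0 - na) - 0.033 * meld * (137.0 - na)
    return min(max(meld_na, 6.0), 40.0)


def compute_scores(record) -> ScorePanel:
    """Score panel for one subject record (any object or mapping with the
    lab fields). A missing lab marks that score as None rather than
    raising, so partially-characterised subjects keep their other scores.
    """

    def get(name):
        if isinstance(record, dict):
            return record.get(name)
        return getattr(record, name, None)

    def attempt(fn, *args):
        try:
            return fn(*args)
        except MissingLabError:
            return None

    fib4 = attempt(fib4_score, get("age"), get("ast"), get("alt"), get("platelets"))
    albi = attempt(albi_score, get("bilirubin"), get("albumin"))
    meld = attempt(meld_na_score, get("bilirubin"), get("inr"), get("creatinine"), get("sodium"))
    return ScorePanel(fib4=fib4, albi=albi, meld_na=meld)
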