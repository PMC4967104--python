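"""Rival accounts of compound probability judgment.

Four competitors to the equate-to-differentiate heuristic are represented:

* **CWA** (configural weighted average): the compound estimate is a weighted
  average β·P(smaller) + (1−β)·P(larger), with β in (0.5, 1) for
  conjunctions (the smaller constituent dominates) and in (0, 0.5) for
  disjunctions (the larger dominates). Tested by the direction of
  standardized regression weights; the potential-surprise framework makes
  the same directional prediction and is represented only by that check.
* **Signed sum**: a qualitative rule predicting which fallacy class peaks
  in each likelihood-type stratum — zero in UU, single in LU, double in LL.
* **Misinterpretation**: reading A ∧ B as ¬A ∧ B, which under independence
  has probability (1−t)·f and exceeds t exactly when t < (1−t)·f; or
  reading ∧ as ∨.
* **Venn coding**: the forced-choice Venn-diagram option maps to an
  intersection (C), disjunction (B), or other interpretation, with option D
  depicting the complement-conjunction ¬A ∧ B; ``venn_consistency``
  cross-tabulates interpretation against actual judgment behavior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from etdfallacy.io import ResponseTable, VENN_OPTIONS
from etdfallacy.stats import FitResult, ols_two
from etdfallacy.taxonomy import CONNECTIVES, classify_compound

__all__ = [
    "CwaParams", "VennInterpretation", "MisreadResult",
    "cwa_predict", "fit_cwa", "signed_sum_check", "neg_base_misread",
    "code_venn", "venn_consistency",
]


@dataclass(frozen=True)
class CwaParams:
    """CWA weight β on the smaller constituent, bound to a connective.

    β must lie strictly inside (0.5, 1) for 'and' and (0, 0.5) for 'or'.
    """

    beta: float
    connective: str

    def __post_init__(self) -> None:
        if self.connective not in CONNECTIVES:
            raise ValueError(f"invalid connective {self.connective!r}")
        lo, hi = (0.5, 1.0) if self.connective == "and" else (0.0, 0.5)
        if not (lo < self.beta < hi):
            raise ValueError(
                f"beta={self.beta} outside open interval ({lo}, {hi}) "
                f"for connective {self.connective!r}"
            )


@dataclass(frozen=True)
class VennInterpretation:
    """Coding of one Venn-diagram choice."""

    option: str
    coding: str  # intersection | disjunction | other
    complement_conjunction_candidate: bool


@dataclass(frozen=True)
class MisreadResult:
    """The ¬T∧F misreading evaluated at one participant's (t, f).

    Under independence Prob(¬T ∧ F) = (1−t)·f; the misreading inflates the
    apparent compound above the base statement exactly when t < (1−t)·f.
    """

    t: float
    f: float
    prob_neg_base_and_added: float
    condition_met: bool


def cwa_predict(p_small: float, p_large: float, params: CwaParams) -> float:
    """CWA point prediction β·p_small + (1−β)·p_large."""
    if not (0.0 <= p_small <= p_large <= 1.0):
        raise ValueError("need 0 <= p_small <= p_large <= 1")
    return params.beta * p_small + (1.0 - params.beta) * p_large


def fit_cwa(
    table: ResponseTable, connective: str
) -> tuple[dict[str, FitResult], dict[str, str]]:
    """Regress compound estimates on larger/smaller constituents, per compound and pooled.

    Returns FitResults keyed by compound id plus 'total', and a verdict per
    key stating whether the dominant standardized coefficient has the
    CWA / potential-surprise direction: the larger constituent dominates
    disjunctions, the smaller dominates conjunctions.
    """
    if connective not in CONNECTIVES:
        raise ValueError(f"invalid connective {connective!r}")
    per_compound: dict[str, list[tuple[float, float, float]]] = {}
    for rec in table.records:
        group = table.design.group(rec.group_id)
        for comp in group.compounds:
            if comp.connective != connective or comp.id not in rec.estimates:
                continue
            a, b = (rec.estimates[c] for c in comp.constituents)
            lo, hi = min(a, b), max(a, b)
            per_compound.setdefault(f"{rec.group_id}/{comp.id}", []).append(
                (rec.estimates[comp.id], hi, lo)
            )
    if not per_compound:
        raise ValueError(f"no {connective!r} compounds in table")

    fits: dict[str, FitResult] = {}
    verdicts: dict[str, str] = {}
    pooled: list[tuple[float, float, float]] = []
    for key, rows in per_compound.items():
        pooled.extend(rows)
        fits[key] = _fit_rows(rows)
    fits["total"] = _fit_rows(pooled)
    dominant_ok = (lambda f: abs(f.beta_small) > abs(f.beta_large)) if (
        connective == "and"
    ) else (lambda f: abs(f.beta_large) > abs(f.beta_small))
    for key, fit in fits.items():
        verdicts[key] = "consistent" if dominant_ok(fit) else "inconsistent"
    return fits, verdicts


def _fit_rows(rows: list[tuple[float, float, float]]) -> FitResult:
    if len(rows) < 3:
        raise ValueError("need at least 3 responses per compound")
    y, hi, lo = (np.array(col) for col in zip(*rows))
    return ols_two(y, hi, lo)


def signed_sum_check(counts) -> dict[str, dict]:
    """Check the signed-sum peak pattern on type-stratified conjunction counts.

    The rule predicts, across the UU / LU / LL strata, that the zero-fallacy
    share peaks in UU, the single share in LU, and the double share in LL.
    Shares are within-stratum proportions (strata differ in size); each
    verdict requires a strict maximum, and ties fail. ``counts`` is a
    FallacyCounts or a DataFrame indexed by likelihood type with
    zero/single/double columns.
    """
    df = counts.by_type("and") if hasattr(counts, "by_type") else counts
    needed = {"UU", "LU", "LL"}
    if not needed.issubset(set(df.index)):
        raise ValueError(f"missing likelihood strata: {needed - set(df.index)}")
    df = df.loc[["UU", "LU", "LL"], ["zero", "single", "double"]]
    shares = df.div(df.sum(axis=1), axis=0)
    expected_peak = {"zero": "UU", "single": "LU", "double": "LL"}
    report = {}
    for cls, stratum in expected_peak.items():
        col = shares[cls]
        strict_peak = all(col[stratum] > col[other] for other in col.index
                          if other != stratum)
        report[cls] = {
            "expected_peak": stratum,
            "verdict": bool(strict_peak),
            "shares": {k: float(v) for k, v in col.items()},
            "counts": {k: int(v) for k, v in df[cls].items()},
        }
    return report


def neg_base_misread(t: float, f: float) -> MisreadResult:
    """Evaluate the ¬base ∧ added misreading at estimates (t, f).

    Assumes independence of the two statements, so the misread compound has
    probability (1−t)·f; the condition is the strict inequality t < (1−t)·f.
    """
    for name, p in (("t", t), ("f", f)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name}={p} outside [0, 1]")
    prob = (1.0 - t) * f
    return MisreadResult(t=t, f=f, prob_neg_base_and_added=prob,
                         condition_met=t < prob)


def code_venn(option: str) -> VennInterpretation:
    """Map a Venn option letter to its interpretation coding.

    C → intersection, B → disjunction, anything else → other; D is
    additionally flagged as depicting the complement-conjunction ¬A ∧ B.
    """
    if option not in VENN_OPTIONS:
        raise ValueError(f"unknown Venn option {option!r}")
    coding = {"C": "intersection", "B": "disjunction"}.get(option, "other")
    return VennInterpretation(option=option, coding=coding,
                              complement_conjunction_candidate=option == "D")


def venn_consistency(table: ResponseTable, tie_policy: str = "strict") -> dict:
    """Cross-tabulate Venn interpretation against judgment behavior.

    For each interpretation group, counts participants who obey the
    conjunction rule on both compounds, on exactly one, or commit fallacies
    on both. Disjunction-choosers are additionally checked for full
    behavioral accordance with their reading (both compounds estimated above
    both constituents); option-D choosers for whether their own (base,
    added) estimates on the Venn-referenced compound satisfy the ¬base ∧
    added inequality.
    """
    with_venn = [r for r in table.records if r.venn_option is not None]
    if not with_venn:
        raise ValueError("no Venn data in table")

    crosstab = {
        coding: {"both_rule": 0, "one_rule": 0, "both_fallacy": 0, "n": 0}
        for coding in ("intersection", "disjunction", "other")
    }
    disj_full_accord = 0
    d_total = d_condition_met = 0
    for rec in with_venn:
        group = table.design.group(rec.group_id)
        interp = code_venn(rec.venn_option)
        classes = []
        above_both = []
        for comp in group.compounds:
            a, b = (rec.estimates[c] for c in comp.constituents)
            p_c = rec.estimates[comp.id]
            cls = classify_compound(p_c, a, b, comp.connective, tie_policy)
            classes.append(cls.value)
            above_both.append(p_c > max(a, b))
        n_rule = sum(cls == "zero" for cls in classes)
        bucket = crosstab[interp.coding]
        bucket["n"] += 1
        if n_rule == len(classes):
            bucket["both_rule"] += 1
        elif n_rule > 0:
            bucket["one_rule"] += 1
        else:
            bucket["both_fallacy"] += 1
        if interp.coding == "disjunction" and all(above_both):
            disj_full_accord += 1
        if interp.complement_conjunction_candidate:
            d_total += 1
            venn_comp = group.statement(group.venn_statement or group.compounds[0].id)
            base_id, added_id = venn_comp.constituents
            res = neg_base_misread(rec.estimates[base_id], rec.estimates[added_id])
            d_condition_met += res.condition_met

    return {
        "crosstab": crosstab,
        "disjunction_full_accord": disj_full_accord,
        "option_d": {
            "n": d_total,
            "condition_met": d_condition_met,
            "fraction": (d_condition_met / d_total) if d_total else float("nan"),
        },
        "n_with_venn": len(with_venn),
    }
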