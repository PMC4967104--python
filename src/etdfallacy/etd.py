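"""The equate-to-differentiate (ETD) heuristic predictor.

ETD holds that when comparing two alternatives people decompose them into
paired dimensions, subjectively *equate* every pair except the most
distinct one — the pair with the largest absolute outcome difference — and
decide on that single remaining dimension. Applied to probability
judgment of Linda-style statements, a dimension's outcome is the
probability estimate of the corresponding component statement, so the
model reduces to arithmetic on the participant's own component estimates.

Two scoring modes are provided. *Between* mode predicts the preference
between two compounds of the same connective (e.g. T ∧ F vs Y ∧ P) from
the four component estimates and checks it against the observed compound
estimates. *Within* mode predicts, for a single compound, the weak
ordering larger-component ≽ compound ≽ smaller-component — the ordering
that makes a single (but never a double) fallacy the model-consistent
response.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from etdfallacy.io import ResponseRecord, ResponseTable, TaskDesign

__all__ = [
    "DimensionOutcome", "EtdPrediction", "most_distinct_pair",
    "predict_within", "score_consistency", "consistency_rate",
]


@dataclass(frozen=True)
class DimensionOutcome:
    """A named dimension and its outcome — here a component's probability estimate."""

    dimension: str
    value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"outcome {self.value} for {self.dimension!r} outside [0, 1]")


@dataclass(frozen=True)
class EtdPrediction:
    """Outcome of applying the ETD rule to a pair of alternatives.

    ``pairing`` matches each dimension of the first alternative to one of
    the second; ``most_distinct`` is the pair with maximal absolute outcome
    difference, all other pairs being treated as equated. ``preference`` is
    'first', 'second', or 'indifferent' according to the sign of the
    difference on the most distinct pair. ``tie`` flags an argmax tie that
    was broken lexicographically by dimension id.
    """

    pairing: tuple[tuple[DimensionOutcome, DimensionOutcome], ...]
    most_distinct: tuple[DimensionOutcome, DimensionOutcome]
    equated: tuple[tuple[DimensionOutcome, DimensionOutcome], ...]
    preference: str
    tie: bool = False


def most_distinct_pair(
    a: list[DimensionOutcome] | tuple[DimensionOutcome, ...],
    b: list[DimensionOutcome] | tuple[DimensionOutcome, ...],
) -> EtdPrediction:
    """Select the dimension pairing and most distinct pair across two alternatives.

    Dimensions are matched one-to-one; among all admissible matchings the one
    containing the globally largest absolute outcome difference is chosen,
    its argmax pair is most distinct, and the rest are equated. Argmax ties
    are broken by lexicographic dimension id and flagged.
    """
    a, b = tuple(a), tuple(b)
    if not a or not b:
        raise ValueError("empty dimension list")
    if len(a) != len(b):
        raise ValueError("alternatives must expose the same number of dimensions")

    best: tuple | None = None
    for perm in permutations(b):
        pairs = tuple(zip(a, perm))
        # sort candidate argmax pairs: largest |diff| first, ids for tie-break
        ranked = sorted(
            pairs,
            key=lambda pr: (-abs(pr[0].value - pr[1].value),
                            pr[0].dimension, pr[1].dimension),
        )
        top = ranked[0]
        gap = abs(top[0].value - top[1].value)
        tied = sum(1 for pr in pairs if abs(pr[0].value - pr[1].value) == gap) > 1
        key = (gap, top[0].dimension, top[1].dimension)
        if best is None or (key[0], ) > (best[0][0], ) or (
            key[0] == best[0][0] and key[1:] < best[0][1:]
        ):
            best = (key, pairs, top, tied)
    _, pairs, top, tied = best
    diff = top[0].value - top[1].value
    gap = abs(diff)
    # argmax ties whose differences point in opposite directions give the
    # model no discriminating dimension: the prediction is indifference
    signs = {np.sign(pr[0].value - pr[1].value)
             for pr in pairs if abs(pr[0].value - pr[1].value) == gap}
    if len(signs) > 1 or diff == 0:
        preference = "indifferent"
    else:
        preference = "first" if diff > 0 else "second"
    equated = tuple(pr for pr in pairs if pr is not top)
    return EtdPrediction(pairing=pairs, most_distinct=top, equated=equated,
                         preference=preference, tie=tied)


def predict_within(p_small: float, p_large: float, connective: str = "and") -> str:
    """Predicted weak ordering of (larger component, compound, smaller component).

    The ETD rule places the compound weakly between its constituents for
    both connectives: the comparison with either constituent is decided on
    the dimension carrying the other constituent's estimate. Returns
    'larger>=compound>=smaller', or 'indifferent' when the constituents are
    judged equal.
    """
    for p in (p_small, p_large):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability {p} outside [0, 1]")
    if p_small == p_large:
        return "indifferent"
    return "larger>=compound>=smaller"


def _observed_matches(pred: str, first: float, second: float, match: str) -> bool:
    if pred == "indifferent":
        return True if match == "weak" else first == second
    if pred == "first":
        return first >= second if match == "weak" else first > second
    return second >= first if match == "weak" else second > first


def score_consistency(
    record: ResponseRecord,
    design: TaskDesign,
    mode: str = "between",
    match: str = "weak",
) -> tuple[bool, EtdPrediction | None]:
    """Score one participant's responses against the ETD prediction.

    ``between`` mode requires the participant's group to contain two
    compounds of the same connective; the predicted preference between them
    (from the four component estimates) is compared with the observed
    compound estimates. ``within`` mode checks each compound estimate
    against the predicted weak ordering and requires all to hold.
    ``match`` selects weak (≥, the model's ≽) or strict observed-preference
    matching.
    """
    if mode not in ("between", "within"):
        raise ValueError(f"unknown mode {mode!r}")
    if match not in ("weak", "strict"):
        raise ValueError(f"unknown match {match!r}")
    group = design.group(record.group_id)
    compounds = group.compounds
    if mode == "between":
        if len(compounds) != 2 or compounds[0].connective != compounds[1].connective:
            raise ValueError(
                f"between mode needs two same-connective compounds in group {group.id!r}"
            )
        c1, c2 = compounds
        for sid in (*c1.constituents, *c2.constituents, c1.id, c2.id):
            if sid not in record.estimates:
                raise ValueError(
                    f"participant {record.participant_id!r} missing estimate for {sid!r}"
                )
        alt1 = [DimensionOutcome(s, record.estimates[s]) for s in c1.constituents]
        alt2 = [DimensionOutcome(s, record.estimates[s]) for s in c2.constituents]
        pred = most_distinct_pair(alt1, alt2)
        ok = _observed_matches(pred.preference, record.estimates[c1.id],
                               record.estimates[c2.id], match)
        return ok, pred
    # within mode: every compound must satisfy the predicted ordering
    ok = True
    for comp in compounds:
        a_id, b_id = comp.constituents
        for sid in (a_id, b_id, comp.id):
            if sid not in record.estimates:
                raise ValueError(
                    f"participant {record.participant_id!r} missing estimate for {sid!r}"
                )
        p_a, p_b = record.estimates[a_id], record.estimates[b_id]
        p_c = record.estimates[comp.id]
        lo, hi = min(p_a, p_b), max(p_a, p_b)
        ordering = predict_within(lo, hi, comp.connective)
        if ordering == "indifferent":
            sat = True if match == "weak" else (p_c == lo == hi)
        elif match == "weak":
            sat = hi >= p_c >= lo
        else:
            sat = hi > p_c > lo
        ok = ok and sat
    return ok, None


def consistency_rate(
    table: ResponseTable,
    mode: str = "between",
    match: str = "weak",
) -> tuple[float, pd.DataFrame]:
    """Fraction of retained participants whose responses fit the ETD prediction.

    Returns the rate together with a per-participant audit frame holding
    the predicted preference, most distinct pair, and consistency flag.
    """
    if not table.records:
        raise ValueError("empty response table")
    rows = []
    for rec in table.records:
        ok, pred = score_consistency(rec, table.design, mode=mode, match=match)
        rows.append({
            "participant_id": rec.participant_id,
            "group": rec.group_id,
            "consistent": ok,
            "predicted_preference": pred.preference if pred else "",
            "most_distinct": (
                f"{pred.most_distinct[0].dimension}|{pred.most_distinct[1].dimension}"
                if pred else ""
            ),
            "argmax_tie": pred.tie if pred else False,
        })
    audit = pd.DataFrame(rows)
    return float(audit["consistent"].mean()), audit
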