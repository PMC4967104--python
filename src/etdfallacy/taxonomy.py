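"""Fallacy taxonomy: classify compound judgments and stratify by likelihood.

A conjunction estimate above the smaller constituent violates
P(A ∧ B) ≤ min(P(A), P(B)); above both constituents it violates the rule
doubly. Disjunctions mirror this against P(A ∨ B) ≥ max(P(A), P(B)). Each
(compound, constituent-pair) triple therefore falls into exactly one of
zero / single / double fallacy classes. Constituent pairs are further
stratified by likelihood type — Unlikely ∧ Unlikely (UU), Likely ∧ Unlikely
(LU), Likely ∧ Likely (LL), or intermediate when a constituent sits exactly
at 0.5 — because fallacy rates differ sharply across these strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from etdfallacy.io import ResponseTable

__all__ = [
    "FallacyClass", "LikelihoodType", "FallacyCounts",
    "likelihood_class", "pair_likelihood_type", "classify_compound", "tally",
    "CONNECTIVES",
]

CONNECTIVES = ("and", "or")


class FallacyClass(str, Enum):
    ZERO = "zero"
    SINGLE = "single"
    DOUBLE = "double"
    TIE = "tie"


class LikelihoodType(str, Enum):
    UU = "UU"
    LU = "LU"
    LL = "LL"
    INTERMEDIATE = "intermediate"


def _check_prob(p: float, name: str = "p") -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name}={p} outside [0, 1]")


def likelihood_class(p: float) -> str:
    """'unlikely' for p in [0, 0.5), 'likely' for (0.5, 1], 'no_difference' at 0.5."""
    _check_prob(p)
    if p < 0.5:
        return "unlikely"
    if p > 0.5:
        return "likely"
    return "no_difference"


def pair_likelihood_type(p_a: float, p_b: float) -> LikelihoodType:
    """Likelihood type of a constituent pair; intermediate if either is exactly 0.5."""
    a, b = likelihood_class(p_a), likelihood_class(p_b)
    if "no_difference" in (a, b):
        return LikelihoodType.INTERMEDIATE
    if a == b == "unlikely":
        return LikelihoodType.UU
    if a == b == "likely":
        return LikelihoodType.LL
    return LikelihoodType.LU


def classify_compound(
    p_c: float,
    p_a: float,
    p_b: float,
    connective: str,
    tie_policy: str = "strict",
) -> FallacyClass:
    """Classify one compound estimate against its constituents.

    For conjunctions: p_c ≤ min → zero; min < p_c ≤ max → single;
    p_c > max → double. Disjunctions mirror: p_c ≥ max → zero;
    min ≤ p_c < max → single; p_c < min → double. Under the default
    ``strict`` tie policy exact equality with a constituent resolves toward
    the less fallacious class; under ``tie_class`` it returns TIE.
    """
    _check_prob(p_c, "p_c")
    _check_prob(p_a, "p_a")
    _check_prob(p_b, "p_b")
    if connective not in CONNECTIVES:
        raise ValueError(f"invalid connective {connective!r}")
    if tie_policy not in ("strict", "tie_class"):
        raise ValueError(f"invalid tie policy {tie_policy!r}")
    lo, hi = min(p_a, p_b), max(p_a, p_b)
    if tie_policy == "tie_class" and (p_c == lo or p_c == hi):
        return FallacyClass.TIE
    if connective == "and":
        if p_c <= lo:
            return FallacyClass.ZERO
        if p_c <= hi:
            return FallacyClass.SINGLE
        return FallacyClass.DOUBLE
    if p_c >= hi:
        return FallacyClass.ZERO
    if p_c >= lo:
        return FallacyClass.SINGLE
    return FallacyClass.DOUBLE


@dataclass
class FallacyCounts:
    """Aggregated fallacy classifications over a response table.

    ``responses`` holds one row per (participant, compound) with the class
    and likelihood type. Counts are exposed as pivot tables; type-stratified
    counts exclude intermediate-type responses, whose constituent pair gives
    the compound no discriminable likelihood structure.
    """

    responses: pd.DataFrame
    tie_policy: str = "strict"

    @property
    def total(self) -> int:
        return len(self.responses)

    def by_compound(self) -> pd.DataFrame:
        """Counts indexed by (group, compound), one column per class."""
        return self._pivot(["group", "compound"])

    def by_connective(self) -> pd.DataFrame:
        """Counts pooled across compounds sharing a connective."""
        return self._pivot(["connective"])

    def by_type(self, connective: str | None = None) -> pd.DataFrame:
        """Counts per likelihood type (UU/LU/LL); intermediate excluded."""
        df = self.responses[self.responses["likelihood_type"] != "intermediate"]
        if connective is not None:
            df = df[df["connective"] == connective]
        return self._pivot(["likelihood_type"], df)

    def fallacious_by_type(self, connective: str | None = None) -> pd.DataFrame:
        """Fallacious (single ∪ double) vs non-fallacious counts per type."""
        df = self.responses[self.responses["likelihood_type"] != "intermediate"].copy()
        if connective is not None:
            df = df[df["connective"] == connective]
        df["fallacious"] = df["fallacy_class"].isin(["single", "double"])
        out = (
            df.groupby(["likelihood_type", "fallacious"]).size().unstack(fill_value=0)
        )
        return out.reindex(columns=[True, False], fill_value=0)

    def _pivot(self, index: list[str], df: pd.DataFrame | None = None) -> pd.DataFrame:
        df = self.responses if df is None else df
        classes = ["zero", "single", "double"] + (
            ["tie"] if self.tie_policy == "tie_class" else []
        )
        if df.empty:
            return pd.DataFrame(columns=classes)
        out = df.groupby(index + ["fallacy_class"]).size().unstack(fill_value=0)
        return out.reindex(columns=classes, fill_value=0)


def tally(table: ResponseTable, tie_policy: str = "strict") -> FallacyCounts:
    """Classify every compound response in a table and aggregate.

    Produces one row per (participant, compound) — two per participant in
    the built-in designs — carrying the fallacy class and the likelihood
    type of the constituent pair.
    """
    rows = []
    for rec in table.records:
        group = table.design.group(rec.group_id)
        for comp in group.compounds:
            a_id, b_id = comp.constituents
            if comp.id not in rec.estimates:
                continue
            p_c = rec.estimates[comp.id]
            p_a, p_b = rec.estimates[a_id], rec.estimates[b_id]
            rows.append({
                "participant_id": rec.participant_id,
                "group": rec.group_id,
                "compound": comp.id,
                "connective": comp.connective,
                "p_compound": p_c,
                "p_a": p_a,
                "p_b": p_b,
                "fallacy_class": classify_compound(p_c, p_a, p_b, comp.connective,
                                                   tie_policy).value,
                "likelihood_type": pair_likelihood_type(p_a, p_b).value,
            })
    columns = ["participant_id", "group", "compound", "connective",
               "p_compound", "p_a", "p_b", "fallacy_class", "likelihood_type"]
    df = pd.DataFrame(rows, columns=columns)
    return FallacyCounts(df, tie_policy)
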