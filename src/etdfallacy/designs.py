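"""Built-in task designs for the two Linda-problem studies the package models.

``disjunction_study()`` is a single-group within-subjects design with two
disjunctions (T ∨ F, Y ∨ P) and their four components. ``conjunction_study()``
has four groups, each with two conjunctions and four components plus a
Venn-diagram task on one conjunction per group. ``INTENDED_CLASS`` records
the likelihood class (unlikely/likely) each component statement was written
to evoke, taken from the published group-mean estimates; the synthetic
cohort generator uses it to pick sampling intervals.
"""

from __future__ import annotations

from etdfallacy.io import GroupSpec, StatementSpec, TaskDesign

__all__ = [
    "disjunction_study", "conjunction_study",
    "INTENDED_CLASS", "DISJUNCTION_N", "CONJUNCTION_GROUP_SIZES",
    "VENN_MIXTURE",
]


def _comp(sid: str, text: str) -> StatementSpec:
    return StatementSpec(sid, text, "component")


def disjunction_study() -> TaskDesign:
    """One group: components T, F, Y, P; disjunctions T∨F and Y∨P; a filler."""
    g = GroupSpec(
        id="g1",
        statements=(
            _comp("T", "Linda will be a bank teller"),
            _comp("F", "Linda will be active in the feminist movement"),
            _comp("Y", "Linda will take Yoga classes"),
            _comp("P", "Linda will be a teacher in elementary school"),
            StatementSpec("TvF", "bank teller or feminist", "disjunction", ("T", "F")),
            StatementSpec("YvP", "yoga classes or teacher", "disjunction", ("Y", "P")),
            StatementSpec("X", "unrelated statement", "filler"),
        ),
    )
    return TaskDesign(experiment="disjunction", groups=(g,))


def conjunction_study() -> TaskDesign:
    """Four groups of two conjunctions each, spanning UU / LU / LL component mixes."""
    g1 = GroupSpec(
        id="g1",
        statements=(
            _comp("T", "Linda is a bank teller"),
            _comp("F", "Linda is active in the feminist movement"),
            _comp("Y", "Linda takes Yoga classes"),
            _comp("P", "Linda is a teacher in elementary school"),
            StatementSpec("TaF", "bank teller and feminist", "conjunction", ("T", "F")),
            StatementSpec("YaP", "yoga classes and teacher", "conjunction", ("Y", "P")),
            StatementSpec("X", "unrelated statement", "filler"),
        ),
        venn_task=True, venn_statement="TaF",
    )
    g2 = GroupSpec(
        id="g2",
        statements=(
            _comp("T", "Linda is a bank teller"),
            _comp("F", "Linda is active in the feminist movement"),
            _comp("D", "Linda is an executive"),
            _comp("M", "Linda subscribes to a popular liberal magazine"),
            StatementSpec("TaF", "bank teller and feminist", "conjunction", ("T", "F")),
            StatementSpec("DaM", "executive and magazine subscriber", "conjunction", ("D", "M")),
            StatementSpec("X", "unrelated statement", "filler"),
        ),
        venn_task=True, venn_statement="TaF",
    )
    g3 = GroupSpec(
        id="g3",
        statements=(
            _comp("R", "Linda is an avid reader"),
            _comp("F", "Linda is active in the feminist movement"),
            _comp("D", "Linda is an executive"),
            _comp("M", "Linda subscribes to a popular liberal magazine"),
            StatementSpec("RaF", "avid reader and feminist", "conjunction", ("R", "F")),
            StatementSpec("DaM", "executive and magazine subscriber", "conjunction", ("D", "M")),
            StatementSpec("X", "unrelated statement", "filler"),
        ),
        venn_task=True, venn_statement="RaF",
    )
    g4 = GroupSpec(
        id="g4",
        statements=(
            _comp("T", "Linda is a bank teller"),
            _comp("S", "Linda is very shy"),
            _comp("P", "Linda is a teacher in elementary school"),
            _comp("C", "Linda is active in crafts like needlepoint"),
            StatementSpec("TaS", "bank teller and very shy", "conjunction", ("T", "S")),
            StatementSpec("PaC", "teacher and crafts", "conjunction", ("P", "C")),
            StatementSpec("X", "unrelated statement", "filler"),
        ),
        venn_task=True, venn_statement="TaS",
    )
    return TaskDesign(experiment="conjunction", groups=(g1, g2, g3, g4))


# Likelihood class each component was written to evoke, per study and group,
# inferred from the direction of the published group means (< or > 50 %).
INTENDED_CLASS: dict[str, dict[str, dict[str, str]]] = {
    "disjunction": {
        "g1": {"T": "unlikely", "F": "likely", "Y": "unlikely", "P": "unlikely"},
    },
    "conjunction": {
        "g1": {"T": "unlikely", "F": "likely", "Y": "unlikely", "P": "unlikely"},
        "g2": {"T": "unlikely", "F": "likely", "D": "unlikely", "M": "likely"},
        "g3": {"R": "likely", "F": "likely", "D": "unlikely", "M": "likely"},
        "g4": {"T": "unlikely", "S": "unlikely", "P": "unlikely", "C": "unlikely"},
    },
}

# Retained sample sizes of the two studies (after exclusions).
DISJUNCTION_N = 41
CONJUNCTION_GROUP_SIZES = {"g1": 104, "g2": 37, "g3": 41, "g4": 42}

# Default Venn-option mixture: intersection (C) 57.8 %, disjunction (B) and
# complement-conjunction (D) 14.7 % each, the remainder spread over A, E, F.
_rest = (1.0 - 0.578 - 0.147 - 0.147) / 3.0
VENN_MIXTURE = {"A": _rest, "B": 0.147, "C": 0.578, "D": 0.147, "E": _rest, "F": _rest}
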