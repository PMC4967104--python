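"""Data model and I/O for probability-judgment task designs and responses.

A *design* lists, per experimental group, the statements shown to
participants: single components, compound statements (conjunctions A ∧ B or
disjunctions A ∨ B) built from two components, and unrelated filler items.
A *response table* holds one record per participant with a probability
estimate in [0, 1] for each statement, plus an optional Venn-diagram option
(A–F) coding how the participant interpreted the connective "and".

Responses travel as long-format CSV (one row per participant × statement);
designs as YAML or JSON. Estimates may be entered as decimals ("0.8"),
percentages ("80%"), or fractions ("4/5") and are normalized on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "StatementSpec", "GroupSpec", "TaskDesign", "ResponseRecord",
    "ResponseTable", "EstimateFormatError", "parse_estimate",
    "load_responses", "write_responses", "apply_exclusions",
    "load_design", "write_design",
]

ROLES = ("component", "conjunction", "disjunction", "filler")
VENN_OPTIONS = ("A", "B", "C", "D", "E", "F")

RESPONSE_COLUMNS = ["participant_id", "group", "statement_id", "estimate", "venn_option"]


class EstimateFormatError(ValueError):
    """Raised when a raw estimate cannot be parsed into a probability."""


@dataclass(frozen=True)
class StatementSpec:
    """One statement in a group.

    ``role`` is one of component / conjunction / disjunction / filler.
    Compound roles carry exactly two distinct constituent component ids;
    components and fillers carry none.
    """

    id: str
    text: str
    role: str
    constituents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for statement {self.id!r}")
        if self.is_compound:
            if len(self.constituents) != 2 or self.constituents[0] == self.constituents[1]:
                raise ValueError(
                    f"compound statement {self.id!r} needs exactly 2 distinct constituents"
                )
        elif self.constituents:
            raise ValueError(f"statement {self.id!r} with role {self.role} has constituents")

    @property
    def is_compound(self) -> bool:
        return self.role in ("conjunction", "disjunction")

    @property
    def connective(self) -> str | None:
        """'and' for conjunctions, 'or' for disjunctions, None otherwise."""
        if self.role == "conjunction":
            return "and"
        if self.role == "disjunction":
            return "or"
        return None


@dataclass(frozen=True)
class GroupSpec:
    """Statement set shown to one group of participants.

    ``venn_statement`` names the compound the Venn-diagram task refers to,
    when the group includes that task.
    """

    id: str
    statements: tuple[StatementSpec, ...]
    venn_task: bool = False
    venn_statement: str | None = None

    def __post_init__(self) -> None:
        ids = [s.id for s in self.statements]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate statement ids in group {self.id!r}")
        known = set(ids)
        for s in self.statements:
            for c in s.constituents:
                if c not in known:
                    raise ValueError(
                        f"compound {s.id!r} references {c!r} absent from group {self.id!r}"
                    )
        if self.venn_task and self.venn_statement is not None:
            if self.venn_statement not in known:
                raise ValueError(
                    f"venn_statement {self.venn_statement!r} not in group {self.id!r}"
                )

    def statement(self, sid: str) -> StatementSpec:
        for s in self.statements:
            if s.id == sid:
                return s
        raise KeyError(sid)

    @property
    def compounds(self) -> tuple[StatementSpec, ...]:
        return tuple(s for s in self.statements if s.is_compound)

    @property
    def components(self) -> tuple[StatementSpec, ...]:
        return tuple(s for s in self.statements if s.role == "component")

    @property
    def required_ids(self) -> tuple[str, ...]:
        """Ids a record must estimate to count as complete (fillers excluded)."""
        return tuple(s.id for s in self.statements if s.role != "filler")


@dataclass(frozen=True)
class TaskDesign:
    """A full experiment: one or more groups of statements."""

    experiment: str
    groups: tuple[GroupSpec, ...]

    def group(self, gid: str) -> GroupSpec:
        for g in self.groups:
            if g.id == gid:
                return g
        raise KeyError(gid)

    @property
    def group_ids(self) -> tuple[str, ...]:
        return tuple(g.id for g in self.groups)


@dataclass
class ResponseRecord:
    """One participant's estimates plus optional Venn choice."""

    participant_id: str
    group_id: str
    estimates: dict[str, float]
    venn_option: str | None = None
    complete: bool = False

    def __post_init__(self) -> None:
        for sid, p in self.estimates.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(
                    f"estimate {p} for statement {sid!r} of participant "
                    f"{self.participant_id!r} outside [0, 1]"
                )
        if self.venn_option is not None and self.venn_option not in VENN_OPTIONS:
            raise ValueError(f"unknown Venn option {self.venn_option!r}")


@dataclass
class ResponseTable:
    """Responses bound to their design, with an exclusion report."""

    design: TaskDesign
    records: list[ResponseRecord]
    exclusions: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_retained(self) -> int:
        return len(self.records)

    @property
    def n_excluded(self) -> int:
        return sum(self.exclusions.values())


def parse_estimate(raw: str, *, context: str = "") -> float:
    """Normalize a raw textual estimate to a probability in [0, 1].

    Accepts decimal ("0.8"), percent ("80%"), and fraction ("4/5") formats.
    Bare numbers above 1 are rejected rather than auto-interpreted as
    percentages, so "80" is an error while "80%" is 0.8.
    """
    text = str(raw).strip()
    where = f" ({context})" if context else ""
    if not text:
        raise EstimateFormatError(f"empty estimate{where}")
    try:
        if text.endswith("%"):
            value = float(Fraction(text[:-1].strip())) / 100.0
        elif "/" in text:
            value = float(Fraction(text))
        else:
            value = float(text)
    except (ValueError, ZeroDivisionError) as exc:
        raise EstimateFormatError(f"cannot parse estimate {raw!r}{where}") from exc
    if not (0.0 <= value <= 1.0):
        raise EstimateFormatError(
            f"estimate {raw!r} normalizes to {value}, outside [0, 1]{where}"
        )
    return value


def _mark_complete(rec: ResponseRecord, design: TaskDesign) -> ResponseRecord:
    required = design.group(rec.group_id).required_ids
    rec.complete = all(sid in rec.estimates for sid in required)
    return rec


def load_responses(path: str | Path, design: TaskDesign) -> ResponseTable:
    """Read a long-format responses CSV into a ResponseTable.

    Expected columns: participant_id, group, statement_id, estimate,
    venn_option (the last may be empty everywhere but one row per
    participant). Raises on unknown statement ids and duplicate
    (participant, statement) rows; rows with an empty estimate cell are
    treated as omitted answers (the record becomes incomplete).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RESPONSE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"responses file missing columns: {missing}")
    if "venn_option" not in df.columns:
        df["venn_option"] = ""

    records: dict[str, ResponseRecord] = {}
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        pid, gid, sid = row.participant_id, row.group, row.statement_id
        group = design.group(gid)  # KeyError on unknown group
        try:
            group.statement(sid)
        except KeyError:
            raise ValueError(f"unknown statement id {sid!r} for group {gid!r}") from None
        if (pid, sid) in seen:
            raise ValueError(f"duplicate row for participant {pid!r}, statement {sid!r}")
        seen.add((pid, sid))
        rec = records.get(pid)
        if rec is None:
            rec = records[pid] = ResponseRecord(pid, gid, {})
        elif rec.group_id != gid:
            raise ValueError(f"participant {pid!r} appears in two groups")
        raw = str(row.estimate).strip()
        if raw:
            rec.estimates[sid] = parse_estimate(raw, context=f"participant {pid}, {sid}")
        venn = str(row.venn_option).strip()
        if venn:
            rec.venn_option = venn
            if venn not in VENN_OPTIONS:
                raise ValueError(f"unknown Venn option {venn!r} for participant {pid!r}")
    for rec in records.values():
        _mark_complete(rec, design)
    return ResponseTable(design, list(records.values()))


def write_responses(table: ResponseTable, path: str | Path) -> None:
    """Write a ResponseTable as long-format CSV (estimates as repr floats)."""
    rows = []
    for rec in table.records:
        venn_done = False
        for sid in sorted(rec.estimates):
            venn = rec.venn_option if (rec.venn_option and not venn_done) else ""
            venn_done = venn_done or bool(venn)
            rows.append((rec.participant_id, rec.group_id, sid,
                         repr(rec.estimates[sid]), venn))
    pd.DataFrame(rows, columns=RESPONSE_COLUMNS).to_csv(path, index=False)


def apply_exclusions(table: ResponseTable) -> ResponseTable:
    """Drop incomplete records, keeping an exclusion report.

    A record missing only filler estimates is retained: fillers are
    unrelated items and do not enter any analysis. Idempotent.
    """
    retained, n_incomplete = [], 0
    for rec in table.records:
        if rec.complete:
            retained.append(rec)
        else:
            n_incomplete += 1
    exclusions = dict(table.exclusions)
    exclusions["incomplete"] = exclusions.get("incomplete", 0) + n_incomplete
    return ResponseTable(table.design, retained, exclusions)


# ---------------------------------------------------------------------------
# Design serialization (YAML / JSON share one dict schema)

def _design_to_dict(design: TaskDesign) -> dict:
    return {
        "experiment": design.experiment,
        "groups": [
            {
                "id": g.id,
                "venn_task": g.venn_task,
                **({"venn_statement": g.venn_statement} if g.venn_statement else {}),
                "statements": [
                    {
                        "id": s.id,
                        "text": s.text,
                        "role": s.role,
                        **({"constituents": list(s.constituents)} if s.constituents else {}),
                    }
                    for s in g.statements
                ],
            }
            for g in design.groups
        ],
    }


def _design_from_dict(data: Mapping) -> TaskDesign:
    groups = []
    for g in data["groups"]:
        statements = tuple(
            StatementSpec(
                id=s["id"], text=s.get("text", s["id"]), role=s["role"],
                constituents=tuple(s.get("constituents", ())),
            )
            for s in g["statements"]
        )
        groups.append(GroupSpec(
            id=g["id"], statements=statements,
            venn_task=bool(g.get("venn_task", False)),
            venn_statement=g.get("venn_statement"),
        ))
    return TaskDesign(experiment=data["experiment"], groups=tuple(groups))


def load_design(path: str | Path) -> TaskDesign:
    """Load a TaskDesign from YAML (.yaml/.yml) or JSON (.json)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _design_from_dict(data)


def write_design(design: TaskDesign, path: str | Path) -> None:
    path = Path(path)
    data = _design_to_dict(design)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
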