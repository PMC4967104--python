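"""Synthetic participant cohorts for Linda-style probability-judgment tasks.

Raw participant data for these studies was never deposited, so the
generator produces cohorts with the statistical structure the analyses
assume: component estimates drawn from likelihood-class intervals
(unlikely below 0.5, likely above), compound estimates produced by a
selectable response model, and Venn-diagram choices drawn from a
configurable mixture with optional linkage between interpretation and
judgment behavior.

Response models:

* ``probability_rule`` — normative: P(A∧B) = ab, P(A∨B) = a + b − ab
  (independence), which never commits a fallacy;
* ``cwa`` — configural weighted average β·min + (1−β)·max plus truncated
  Gaussian noise of sd σ, a strict convex combination when σ = 0;
* ``averaging`` — the unweighted midpoint;
* ``signed_sum`` — qualitative placement by likelihood type: below both
  constituents for UU pairs, between for LU, above both for LL;
* ``random_error`` — the normative value plus symmetric uniform error of
  configurable half-width, clipped to [0, 1];
* ``etd_ordinal`` — placement strictly between the constituents at a
  random fraction γ of the gap, the ordinal pattern the
  equate-to-differentiate model predicts;
* ``reversed`` — compound preferences deliberately contradicting the
  equate-to-differentiate prediction (a negative control).

Randomness uses one substream per participant derived from the master
seed, so enlarging a cohort never perturbs earlier records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from etdfallacy.etd import DimensionOutcome, most_distinct_pair
from etdfallacy.io import ResponseRecord, ResponseTable, TaskDesign
from etdfallacy.rivals import CwaParams, cwa_predict
from etdfallacy.taxonomy import classify_compound, pair_likelihood_type

__all__ = [
    "RESPONSE_MODELS", "DEFAULT_INTERVALS", "CohortConfig",
    "draw_components", "respond_compound", "generate_cohort", "analytic_rates",
]

RESPONSE_MODELS = (
    "probability_rule", "cwa", "averaging", "signed_sum",
    "random_error", "etd_ordinal", "reversed",
)

# Sampling intervals per likelihood class. They stay clear of 0.5 so the
# intended class of every draw is unambiguous; the degenerate
# "intermediate" interval pins mass at exactly 0.5 to exercise the
# intermediate-type exclusion path.
DEFAULT_INTERVALS: dict[str, tuple[float, float]] = {
    "unlikely": (0.05, 0.45),
    "likely": (0.55, 0.95),
    "intermediate": (0.5, 0.5),
}


@dataclass
class CohortConfig:
    """Specification of one synthetic cohort.

    ``component_classes`` maps group id → statement id → likelihood class
    (or an explicit (lo, hi) interval); statements not mentioned default to
    'unlikely'. ``group_sizes`` fixes how many participants fall in each
    group; without it participants are dealt round-robin.
    ``venn_mixture`` gives option weights A–F for groups with a Venn task;
    with ``venn_linkage`` the drawn option overrides the response model
    (C → probability_rule, B → disjunctive reading, D → ¬base ∧ added).
    """

    design: TaskDesign
    n_participants: int
    seed: int
    response_model: str = "cwa"
    component_classes: dict[str, dict[str, object]] = field(default_factory=dict)
    beta: float = 0.7
    sigma: float = 0.0
    error_half_width: float = 0.3
    group_sizes: dict[str, int] | None = None
    venn_mixture: dict[str, float] | None = None
    venn_linkage: bool = False

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.response_model not in RESPONSE_MODELS:
            raise ValueError(f"unknown response model {self.response_model!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.error_half_width < 0:
            raise ValueError("error_half_width must be >= 0")
        if self.group_sizes is not None:
            if sum(self.group_sizes.values()) != self.n_participants:
                raise ValueError("group_sizes must sum to n_participants")
            if set(self.group_sizes) != set(self.design.group_ids):
                raise ValueError("group_sizes keys must match design groups")
        if self.venn_mixture is not None:
            w = np.array(list(self.venn_mixture.values()), dtype=float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("venn_mixture weights must be non-negative and sum to 1")

    def interval_for(self, group_id: str, statement_id: str) -> tuple[float, float]:
        spec = self.component_classes.get(group_id, {}).get(statement_id, "unlikely")
        if isinstance(spec, str):
            try:
                lo, hi = DEFAULT_INTERVALS[spec]
            except KeyError:
                raise ValueError(f"unknown likelihood class {spec!r}") from None
        else:
            lo, hi = spec  # explicit interval
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"empty or invalid interval ({lo}, {hi})")
        return float(lo), float(hi)

    def group_of(self, index: int) -> str:
        gids = self.design.group_ids
        if self.group_sizes is None:
            return gids[index % len(gids)]
        cum = 0
        for gid in gids:
            cum += self.group_sizes[gid]
            if index < cum:
                return gid
        raise IndexError(index)


def _participant_rng(config: CohortConfig, index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, index])


def draw_components(
    config: CohortConfig, group_id: str, rng: np.random.Generator
) -> dict[str, float]:
    """Draw one participant's component estimates from their class intervals."""
    group = config.design.group(group_id)
    out = {}
    for stmt in group.components:
        lo, hi = config.interval_for(group_id, stmt.id)
        out[stmt.id] = lo if lo == hi else float(rng.uniform(lo, hi))
    return out


def respond_compound(
    model: str,
    params: dict,
    p_a: float,
    p_b: float,
    connective: str,
    rng: np.random.Generator,
) -> float:
    """Generate one compound estimate under a response model.

    The result is always clipped to [0, 1]. The ``reversed`` model here
    places the estimate strictly outside the constituent interval,
    contradicting the within-compound ordering the equate-to-differentiate
    model predicts; cohort-level preference reversal is applied by
    ``generate_cohort``.
    """
    lo, hi = min(p_a, p_b), max(p_a, p_b)
    if model == "probability_rule":
        value = p_a * p_b if connective == "and" else p_a + p_b - p_a * p_b
    elif model == "cwa":
        beta = params.get("beta", 0.7)
        base = cwa_predict(lo, hi, CwaParams(beta, connective))
        sigma = params.get("sigma", 0.0)
        value = base + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
    elif model == "averaging":
        value = 0.5 * (p_a + p_b)
    elif model == "signed_sum":
        ltype = pair_likelihood_type(p_a, p_b).value
        gamma = _open_unit(rng)
        if ltype == "LL":
            value = hi + gamma * (1.0 - hi) if hi < 1.0 else 1.0
        elif ltype == "UU":
            value = lo * gamma
        else:  # LU or intermediate: between the constituents
            value = lo + gamma * (hi - lo)
    elif model == "random_error":
        norm = p_a * p_b if connective == "and" else p_a + p_b - p_a * p_b
        h = params.get("error_half_width", 0.3)
        value = norm + float(rng.uniform(-h, h))
    elif model == "etd_ordinal":
        value = lo + _open_unit(rng) * (hi - lo)
    elif model == "reversed":
        gamma = _open_unit(rng)
        if hi < 1.0:
            value = hi + gamma * (1.0 - hi)
        else:
            value = lo * gamma
    else:
        raise ValueError(f"unknown response model {model!r}")
    return float(np.clip(value, 0.0, 1.0))


def _open_unit(rng: np.random.Generator) -> float:
    """Uniform draw on the open interval, bounded away from 0 and 1."""
    return float(rng.uniform(0.02, 0.98))


def generate_cohort(config: CohortConfig) -> tuple[ResponseTable, pd.DataFrame]:
    """Generate a complete cohort and its ground-truth frame.

    Every record is complete (filler included) and reproducible given the
    seed. The ground truth records, per (participant, compound), the
    generating model and the realized fallacy class of the emitted
    estimate under the strict tie policy.
    """
    records: list[ResponseRecord] = []
    truth_rows = []
    params = {"beta": config.beta, "sigma": config.sigma,
              "error_half_width": config.error_half_width}
    venn_opts = list(config.venn_mixture) if config.venn_mixture else None
    venn_w = (np.array([config.venn_mixture[o] for o in venn_opts])
              if venn_opts else None)

    for i in range(config.n_participants):
        rng = _participant_rng(config, i)
        gid = config.group_of(i)
        group = config.design.group(gid)
        estimates = draw_components(config, gid, rng)
        for stmt in group.statements:
            if stmt.role == "filler":
                estimates[stmt.id] = float(rng.uniform(0.0, 1.0))

        venn_option = None
        if group.venn_task and venn_opts is not None:
            venn_option = str(rng.choice(venn_opts, p=venn_w))

        model = config.response_model
        if config.venn_linkage and venn_option in ("B", "C", "D"):
            model = {"C": "probability_rule", "B": "_disjunctive",
                     "D": "_neg_base"}[venn_option]

        for comp in group.compounds:
            a_id, b_id = comp.constituents
            p_a, p_b = estimates[a_id], estimates[b_id]
            if model == "_disjunctive":
                value = p_a + p_b - p_a * p_b
            elif model == "_neg_base":
                value = (1.0 - p_a) * p_b
            else:
                value = respond_compound(model, params, p_a, p_b,
                                         comp.connective, rng)
            estimates[comp.id] = value

        if model == "reversed":
            _reverse_preference(estimates, group, rng)

        for comp in group.compounds:
            p_a, p_b = (estimates[c] for c in comp.constituents)
            truth_rows.append({
                "participant_id": f"p{i:04d}", "group": gid, "compound": comp.id,
                "model": model.lstrip("_"),
                "realized_class": classify_compound(
                    estimates[comp.id], p_a, p_b, comp.connective, "strict").value,
            })

        records.append(ResponseRecord(
            participant_id=f"p{i:04d}", group_id=gid,
            estimates=estimates, venn_option=venn_option, complete=True,
        ))
    table = ResponseTable(config.design, records)
    return table, pd.DataFrame(truth_rows)


def _reverse_preference(estimates: dict, group, rng: np.random.Generator) -> None:
    """Force the compound pair's observed preference against the ETD prediction."""
    compounds = group.compounds
    if len(compounds) != 2 or compounds[0].connective != compounds[1].connective:
        return
    c1, c2 = compounds
    alt1 = [DimensionOutcome(s, estimates[s]) for s in c1.constituents]
    alt2 = [DimensionOutcome(s, estimates[s]) for s in c2.constituents]
    pred = most_distinct_pair(alt1, alt2)
    v1, v2 = estimates[c1.id], estimates[c2.id]
    lo, hi = min(v1, v2), max(v1, v2)
    if lo == hi:  # split so a strict observed preference exists
        lo = max(0.0, lo - 0.05)
        hi = min(1.0, hi + 0.05)
    if pred.preference == "first":
        estimates[c1.id], estimates[c2.id] = lo, hi
    else:  # 'second' or (measure-zero) indifference
        estimates[c1.id], estimates[c2.id] = hi, lo


def analytic_rates(
    model: str,
    params: dict | None = None,
    component_intervals: tuple[tuple[float, float], tuple[float, float]] = (
        (0.05, 0.45), (0.55, 0.95)),
    connective: str = "and",
    n_mc: int = 100_000,
    seed: int = 0,
) -> dict:
    """Expected fallacy-class distribution under a response model.

    Closed forms are returned where the model's structure fixes the class
    outright (probability_rule → all zero; noiseless cwa, averaging, and
    etd_ordinal → all single, given strictly distinct components).
    Otherwise a Monte-Carlo estimate over ``n_mc`` draws is returned along
    with binomial standard errors per class.
    """
    params = params or {}
    if model == "probability_rule":
        return {"zero": 1.0, "single": 0.0, "double": 0.0, "se": 0.0}
    if model in ("averaging", "etd_ordinal") or (
        model == "cwa" and params.get("sigma", 0.0) == 0.0
    ):
        return {"zero": 0.0, "single": 1.0, "double": 0.0, "se": 0.0}

    rng = np.random.default_rng(seed)
    (lo1, hi1), (lo2, hi2) = component_intervals
    p_a = rng.uniform(lo1, hi1, n_mc) if lo1 < hi1 else np.full(n_mc, lo1)
    p_b = rng.uniform(lo2, hi2, n_mc) if lo2 < hi2 else np.full(n_mc, lo2)
    counts = {"zero": 0, "single": 0, "double": 0}
    for a, b in zip(p_a, p_b):
        v = respond_compound(model, params, float(a), float(b), connective, rng)
        cls = classify_compound(v, float(a), float(b), connective, "strict")
        counts[cls.value] += 1
    out = {k: v / n_mc for k, v in counts.items()}
    out["se"] = {k: float(np.sqrt(p * (1 - p) / n_mc)) for k, p in out.items()}
    return out
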