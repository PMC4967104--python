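"""Trace the equate-to-differentiate rule on one participant's estimates.

A participant judges T = 0.1, F = 0.8, Y = 0.5, P = 0.2 and gives the
disjunctions T∨F = 0.7, Y∨P = 0.4. The rule pairs the four component
dimensions across the two compounds, treats every pair except the most
discrepant one as equal, and predicts the compound preference from that
single pair — here (F, P), difference 0.6, so T∨F should be preferred,
which matches the observed 0.7 > 0.4.
"""

from etdfallacy import DimensionOutcome, designs, most_distinct_pair, score_consistency
from etdfallacy.io import ResponseRecord

pred = most_distinct_pair(
    [DimensionOutcome("T", 0.1), DimensionOutcome("F", 0.8)],
    [DimensionOutcome("Y", 0.5), DimensionOutcome("P", 0.2)],
)
md = pred.most_distinct
print(f"most distinct pair: ({md[0].dimension}, {md[1].dimension}), "
      f"gap = {abs(md[0].value - md[1].value):.2f}")
print(f"equated pair(s): "
      + ", ".join(f"({a.dimension}, {b.dimension})" for a, b in pred.equated))
print(f"predicted preference: {pred.preference} compound")

design = designs.disjunction_study()
record = ResponseRecord("p0", "g1", {
    "T": 0.1, "F": 0.8, "Y": 0.5, "P": 0.2, "TvF": 0.7, "YvP": 0.4,
}, complete=True)
ok, _ = score_consistency(record, design, mode="between")
print(f"observed 0.7 vs 0.4 -> consistent with the prediction: {ok}")
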