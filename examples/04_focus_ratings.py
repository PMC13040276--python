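"""Aggregate expert spatial-focus ratings of heatmap explanations.

Simulates a "good/intermediate/poor" rating per frame for two models with
different rating mixes, compares the models on the share of "good"
ratings, and crosses ratings with classification correctness.
"""

from embryoeval import (
    accuracy_by_focus,
    compare_models_on_rating,
    rating_proportions,
    simulate_rating_table,
    uniform_profile,
)
from embryoeval.agreement import format_p
from embryoeval.fixtures import DEFAULT_FOCUS_MIX, simulate_focus_ratings

table = simulate_rating_table(
    31, 35,
    [uniform_profile("resnet_like", 0.79), uniform_profile("vgg_like", 0.74)],
    seed=3,
)
frames = table["frame_id"].tolist()
stages = dict(zip(table["frame_id"], table["reference"]))
# NB: a distinct seed — sharing one seed across two generators would couple
# their uniform streams and silently correlate ratings with correctness
ratings = simulate_focus_ratings(
    frames, ["resnet_like", "vgg_like"], DEFAULT_FOCUS_MIX, seed=301
)

props = rating_proportions(ratings, stages)
overall = props[props["stage"] == 0]
print("overall rating proportions:")
for _, row in overall.iterrows():
    print(f"  {row['model_id']:12s} {row['rating']:12s} "
          f"{100 * row['proportion']:.0f}% (n={row['count']})")

res = compare_models_on_rating(ratings, "resnet_like", "vgg_like", "good")
print(f"\n'good' share, resnet_like vs vgg_like: p = {format_p(res.p_value)}")

correctness = {
    (f, m): bool(lbl == stages[f])
    for m in ("resnet_like", "vgg_like")
    for f, lbl in zip(table["frame_id"], table[m])
}
cells, tests = accuracy_by_focus(ratings, correctness, stages)
testable = [c for c in cells if not c.too_few]
print(f"\n{len(cells)} stage x model x rating cells "
      f"({len(cells) - len(testable)} too small to test)")
for t in tests[:3]:
    a, b = t.extras["ratings"]
    print(f"  stage {t.extras['stage']} {t.extras['model_id']}: "
          f"{a} vs {b} accuracy, p = {format_p(t.p_value)}")
# ratings were drawn independently of correctness, so these stay null
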