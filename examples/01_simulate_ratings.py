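"""Simulate a multi-rater embryo-staging table and score accuracy.

Builds a study-scale table (245 frames over the 7 merged stages, three
human-like raters and two model-like raters whose errors concentrate on
adjacent stages), then prints pooled accuracy and one confusion matrix.
"""

from embryoeval import accuracy, confusion, simulate_rating_table, uniform_profile

profiles = [
    uniform_profile("E1", 0.91),
    uniform_profile("E2", 0.90),
    uniform_profile("E3", 0.89),
    uniform_profile("resnet_like", 0.79),
    uniform_profile("vgg_like", 0.74),
]
table = simulate_rating_table(
    n_embryos=31, frames_per_stage=35, profiles=profiles, seed=7
)
print(f"{len(table)} frames, raters: {[p.rater_id for p in profiles]}")

pooled = accuracy(table, ["E1", "E2", "E3"])
print(
    f"embryologists pooled: {pooled.correct}/{pooled.total} "
    f"= {100 * pooled.proportion:.1f}% correct"
)
for model in ("resnet_like", "vgg_like"):
    res = accuracy(table, model)
    print(f"{model}: {res.correct}/{res.total} = {100 * res.proportion:.1f}%")

cm = confusion(table, "vgg_like")
print("\nvgg_like confusion (% of each true stage, rows=truth):")
print(cm.display_percent)
# off-diagonal mass sits next to the diagonal: errors are adjacent-stage
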