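"""End-to-end run: simulate the default study, write report.json/report.md.

Equivalent to `embryoeval analyze --out report_dir`; identical config and
seed always reproduce a byte-identical report.json.
"""

from embryoeval import FixtureConfig, RunConfig, run, write_report

config = RunConfig(simulate=FixtureConfig(), seed=2026)
bundle = run(config)
paths = write_report(bundle, "scratch/example_report")

print(f"report written: {paths['json']}")
acc = bundle["accuracy"]
print(f"pooled embryologist accuracy: "
      f"{100 * acc['embryologists_pooled']['proportion']:.1f}%")
for model in ("resnet_like", "vgg_like"):
    k = bundle["kappa_vs_reference"][model]
    print(f"{model}: accuracy {100 * acc[model]['proportion']:.1f}%, "
          f"kappa vs reference {k['estimate']:.3f}")
q = bundle["cochran_q"]
print(f"Cochran's Q({q['df']}) = {q['statistic']:.2f}, p = {q['p_value']:.2g}")
print("median IoU by model:", bundle["iou"]["overall_median_percent"])
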