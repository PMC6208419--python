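"""The full study pipeline: fits, PK tables, bioavailability, statistics.

Generates a three-particle study dosed by both routes (with one excluded
subject, as happens in practice), writes it to CSV, reads it back, and runs
the complete analysis: variant selection and fitting for every subject x
ROI, group summaries, i.p. bioavailability fractions, and an ANOVA on the
uptake rate across i.p. arms.
"""

import tempfile
from pathlib import Path

from nanopk import PipelineConfig, read_study, run_pipeline, write_study
from nanopk.io import series_to_table
from nanopk.synthetic import (
    DEFAULT_PANEL,
    SyntheticStudyConfig,
    generate_study,
)

particles = tuple(p for p in DEFAULT_PANEL
                  if p.particle_id in ("TMS25", "TMS50", "TMS150"))
cfg = SyntheticStudyConfig(
    seed=42, particles=particles,
    routes={p.particle_id: ("iv", "ip") for p in particles},
    exclusions=(("TMS25_ip", "TMS25_ip_r1", "subject motion"),))
study = generate_study(cfg)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "study.csv"
    write_study(series_to_table(study.series), path)
    table = read_study(path)

pipe_cfg = PipelineConfig(seed=42, stats_requests=[
    {"name": "kin_across_ip_arms", "parameter": "k_in", "roi": "heart",
     "routes": ["ip"]}])
report = run_pipeline(table, pipe_cfg, design=study.design)

print("row disposition:", report.records.groupby("status").size().to_dict())
print("\nbioavailability (dose-normalised i.p./i.v. AUC ratio):")
for _, row in report.bioavailability.iterrows():
    print("  %s: F = %.1f%%" % (row["particle_id"], row["F_percent"]))

heart = report.group_summaries.query("roi == 'heart' and parameter == 'k_out'")
print("\nheart k_out by arm (mean +/- sd, 1/h):")
for _, row in heart.iterrows():
    print("  %-10s %.4f +/- %.4f (n=%d)"
          % (row["group_id"], row["mean"], row["sd"], row["n"]))

anova = report.stats["kin_across_ip_arms"]["anova"]
print("\nANOVA, uptake rate k_in across i.p. arms: F = %.2f, p = %.3f"
      % (anova["F"], anova["p"]))
if anova["p"] >= 0.05:
    print("(no detectable size dependence of the peritoneal absorption rate)")
else:
    print("(nominally significant here: with only three imaging times the "
          "absorption-phase fits interpolate, so arm-level k_in estimates "
          "carry no within-subject error bar and small spreads can reach "
          "significance)")
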