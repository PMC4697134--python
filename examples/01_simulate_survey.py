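"""Generate a synthetic two-stage cluster nutrition survey.

The default configuration emulates biannual cluster surveys (two rainy
seasons per year over four years): ~1064 community clusters, 30 households
per cluster, children aged 6-59 months, with calibrated marginal
prevalences of wasting / stunting / low MUAC near 21 / 31 / 36%.  Here we
generate a reduced survey so the script runs in seconds.
"""

import nutsurv as ns

cfg = ns.default_config(n_clusters=120, households_per_cluster=10, seed=42)
survey = ns.generate_survey(cfg)

print(f"children: {survey.n_children}, clusters: {survey.n_clusters}, "
      f"districts: {len(survey.districts)}")
print(survey.records[["age_months", "sex", "whz", "haz", "muac_mm",
                      "wasted", "stunted", "low_muac"]].head())

table = ns.descriptive_table(survey)
for indicator, p in table.prevalence.items():
    print(f"{indicator}: {100 * p:.1f}%")
# The three percentages are the marginal indicator prevalences; at the
# full default size they concentrate near the calibrated 21/31/36%.

survey.write("example_survey")
print("wrote records.csv / clusters.csv / edges.txt / config.json to example_survey/")
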