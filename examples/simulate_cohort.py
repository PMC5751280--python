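"""Simulate a case-control cohort with a carrier-enriched causal region.

Generates 500 cases and 500 controls over ten 4-variant gene regions with
rare heterozygous carriers (1/500 to 10/500 per variant), enriching the
causal region's carrier probability in cases through an odds ratio of 3.4,
then counts carriers per cohort.
"""

from poolburden import carriers, default_config, region_variant_map, simulate_cohort

cfg = default_config(seed=42, causal_region="R00", carrier_or=3.4)
genotypes, truth = simulate_cohort(cfg)

print(f"samples: {len(genotypes.samples)}, variants: {len(genotypes.variant_ids)}")
print(f"comorbid (excluded in subset re-analysis): {int(genotypes.samples.comorbid.sum())}")
print()
print("region  ctrl_carriers  case_carriers")
for region, vids in region_variant_map(cfg).items():
    c = carriers(genotypes, vids, "control")
    a = carriers(genotypes, vids, "case")
    mark = "  <- causal" if region == cfg.causal_region else ""
    print(f"{region:6s}  {c:13d}  {a:13d}{mark}")
print()
print("The causal region shows more case than control carriers; the other")
print("regions fluctuate around equality, as expected under the null.")
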