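"""Simulate a calibrated cohort and recover its editability model.

Generates a synthetic genic-Alu cohort (layout, true editability, site-level
read counts), aggregates the read counts into per-element editability,
extracts genomic-architecture covariates, and fits the exponential distance
model plus the residual neighbor-count regression.
"""

from alueditability import (
    CoverageFilter,
    GeneratorConfig,
    aggregate_site_counts,
    apply_coverage_filters,
    editability_frame,
    fit_all,
    merge_tables,
    simulate_cohort,
)

config = GeneratorConfig(seed=42, n_alus=10_000)
cohort = simulate_cohort(config)
print(f"simulated {len(cohort.repeats)} repeats "
      f"({len(cohort.genic_alus)} genic) in {len(cohort.genes)} genes, "
      f"{len(cohort.site_counts)} site-count rows")

records = apply_coverage_filters(
    aggregate_site_counts(cohort.site_counts, cohort.genic_alus),
    CoverageFilter())
merged = merge_tables(editability_frame(records, cohort.genic_alus),
                      cohort.features_df, cohort.genic_alus)
report = fit_all(merged)

exp = report["exponential"]
nbr = report["neighbor_model"]
print(f"\nE(d) = {exp['amplitude']:.2f} * exp(-d/{exp['decay_bp']:.0f}) "
      f"+ {exp['baseline']:.2f}   (generated from 2.90, 800, 0.25)")
print(f"distance explains {100 * exp['variance_explained_per_element']:.1f}% "
      f"of per-element variance (generator target 28%)")
print(f"residual OLS: beta_ss = {nbr['beta_ss']:.4f} (true -0.022), "
      f"beta_rs = {nbr['beta_rs']:.4f} (true +0.015)")
print(f"cohort mean editability {report['mean_editability_pct']:.2f}% "
      f"over {report['n_records']} elements passing coverage filters")
print("\nThe fitted curve says how fast editing decays as an element's "
      "nearest reversely oriented partner moves away; the two OLS "
      "coefficients say how same- and opposite-strand neighbor counts "
      "shift editability once that distance is controlled for.")
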