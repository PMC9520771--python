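"""Run the two-statistic specificity screen on a planted cohort.

A triplet is a druggable cancer-specific pathway (DCSP) when its one-sided
robust t clears FDR < 0.01, its rest-of-cancers homogeneity statistic T2 is
within the first quartile of the FDR survivors, and the sample-size rules
hold.
"""

from dcsp import (PASConfig, PlantedTriplet, ScreenConfig, SimConfig,
                  pas_matrix, screen, simulate_cohort)

sim = simulate_cohort(SimConfig(planted=(PlantedTriplet("D1", "PW1", "C1", 3.0),),
                                seed=7))
pas = pas_matrix(sim.cohort, sim.pathways, sim.drug_targets, sim.drivers,
                 sim.directed, sim.functional, PASConfig())
result = screen(pas, ScreenConfig())

print(f"{len(result)} candidate triplets "
      f"({result['drug'].nunique()} drugs x {result['pathway'].nunique()} "
      f"pathways x {result['cancer'].nunique()} cancers)")
top = result.sort_values("T1", ascending=False).head(3)
print("\ntop 3 by T1:")
print(top[["drug", "pathway", "cancer", "T1", "fdr", "T2", "is_dcsp"]]
      .to_string(index=False))
print("\nonly the planted triplet combines a large T1 (specific overactivation)")
print("with a small T2 (the remaining cancers are mutually homogeneous).")
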