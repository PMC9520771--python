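"""Simulate a planted cohort and compute the pathway activation scores.

One (drug, pathway, cancer) triplet is planted: drug D1's pathway PW1 is
upshifted by 3 within-cancer SDs in cancer C1, with matching functional
network links and drug-response coupling.  The PAS table has one row per
(sample, drug, pathway).
"""

from dcsp import (PASConfig, PlantedTriplet, SimConfig, pas_matrix,
                  simulate_cohort)

sim = simulate_cohort(SimConfig(planted=(PlantedTriplet("D1", "PW1", "C1", 3.0),),
                                seed=7))
print(f"cohort: {sim.cohort.expression.shape[0]} genes x "
      f"{sim.cohort.n_samples} samples, cancers {sim.cohort.cancers}")
print("ground truth:")
print(sim.truth[["drug", "pathway", "cancer", "effect_size"]].to_string(index=False))

pas = pas_matrix(sim.cohort, sim.pathways, sim.drug_targets, sim.drivers,
                 sim.directed, sim.functional, PASConfig())
print(f"\nPAS table: {len(pas)} records")

by_cancer = (pas[(pas.drug == "D1") & (pas.pathway == "PW1")]
             .groupby("cancer")["PAS"].mean().round(1))
print("\nmean PAS of the planted (D1, PW1) pair per cancer:")
print(by_cancer.to_string())
print("\nC1 stands far above the other cancers: the upstream half of PW1 is")
print("overexpressed there and the connectivity weights amplify the score.")
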