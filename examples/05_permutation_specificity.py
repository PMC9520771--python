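"""Permutation specificity test of one (drug, pathway) PAS group.

Compares the PAS of the planted (D1, PW1) group within its cancer against
(i) the same pathway under other drugs, (ii) the same drug on other
pathways, and (iii) other drugs on other pathways, using a 10,000-fold
label-permutation null of the two-sample t statistic.
"""

from dcsp import (PASConfig, PlantedTriplet, SimConfig, pas_matrix,
                  permutation_specificity_test, simulate_cohort)

sim = simulate_cohort(SimConfig(planted=(PlantedTriplet("D1", "PW1", "C1", 3.0),),
                                seed=7))
pas = pas_matrix(sim.cohort, sim.pathways, sim.drug_targets, sim.drivers,
                 sim.directed, sim.functional, PASConfig())
in_cancer = pas[pas["cancer"] == "C1"]

for comparison in ("Dbar_P", "D_Pbar", "Dbar_Pbar"):
    res = permutation_specificity_test(in_cancer, "D1", "PW1",
                                       comparison=comparison,
                                       n_perm=10_000, seed=7)
    print(f"{comparison:>9}: t = {res.observed_t:6.2f}, "
          f"empirical p = {res.p_empirical:.2e} "
          f"(groups {res.n_group} vs {res.n_comparison})")

print("\nsmall p for every comparison = the planted group's activation is")
print("specific to this drug-pathway combination, not shared by its pathway")
print("under other drugs or by the drug on other pathways; p can never fall")
print("below 1/(n_perm + 1) = 1e-4.")
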