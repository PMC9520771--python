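"""Relate activation to drug response and compute a rediscovery-rate curve.

Eight druggable pathways of one cancer are planted with AUC coupling in both
a discovery and an independent validation cohort.  Triplet-level
cor(PAS, AUC) is computed on normal scores (positive activation only), the
discovery records are ranked, and RDR(f) measures how many of the top f
validate at alpha = 0.05.
"""

from dcsp import (PASConfig, PlantedTriplet, SimConfig, correlate_table,
                  pas_matrix, rdr_curve, simulate_cohort)

planted = tuple(PlantedTriplet(f"D{i+1}", f"PW{i+1}", "C1", 3.0) for i in range(8))
cfg = dict(n_drugs=8, n_pathways=8, n_genes=360, samples_per_cancer=20,
           planted=planted)


def correlations(seed):
    sim = simulate_cohort(SimConfig(seed=seed, **cfg))
    pas = pas_matrix(sim.cohort, sim.pathways, sim.drug_targets, sim.drivers,
                     sim.directed, sim.functional, PASConfig())
    cor = correlate_table(pas, sim.response)
    return cor[cor["cancer"] == "C1"].dropna(subset=["r"])


discovery = correlations(seed=7)
validation = correlations(seed=1007)
planted_rows = discovery[discovery.drug.str.replace("D", "PW") == discovery.pathway]
print("discovery cor(PAS, AUC) of the planted pairs:")
print(planted_rows[["drug", "pathway", "r", "p"]].round(3).to_string(index=False))

curve = rdr_curve(discovery, validation, alpha=0.05, sign="negative")
print(f"\nRDR over {curve.n_records} matched records (alpha = {curve.alpha}):")
for f, r in zip(curve.fractions, curve.rdr):
    print(f"  top {f:>5.0%}: RDR = {r:.2f}")
print("\nhigh RDR at top fractions = the strongest discovery correlations")
print("replicate in the independent cohort; with no true coupling the curve")
print("would sit on the alpha target line instead.")
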