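"""Pathway partitioning and the activation-score algebra."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dcsp.errors import DisconnectedPathwayError, ValidationError
from dcsp.nea import ConnectivityWeights, nea_z, weights_from_z
from dcsp.pas import (PASConfig, compute_pas, expression_sum, partition_pathway,
                      pas_matrix)
from dcsp.screen import robust_t_one_vs_rest


def _weights(w1, w2, w3):
    return ConnectivityWeights(0, 0, 0, w1, w2, w3)


class TestPartitionPathway:
    def test_chain_reachability(self):
        directed = nx.DiGraph([("A", "B"), ("B", "C"), ("C", "D")])
        part = partition_pathway({"A", "B", "C", "D"}, {"C"}, directed)
        assert part.g_u == {"A", "B", "C"}
        assert part.g_d == {"D"}

    def test_target_gene_inside_pathway_always_upstream(self):
        # a drug hitting a chaperone that is itself a pathway member
        directed = nx.DiGraph([("HSP90", "AKT1"), ("AKT1", "MTOR")])
        part = partition_pathway({"HSP90", "AKT1", "MTOR"}, {"HSP90"}, directed)
        assert "HSP90" in part.g_u
        assert part.g_d == {"AKT1", "MTOR"}

    def test_unreached_policy(self):
        directed = nx.DiGraph([("A", "T"), ("T", "B")])
        down = partition_pathway({"A", "B", "Z"}, {"T"}, directed,
                                 unreached_policy="downstream")
        assert "Z" in down.g_d
        excl = partition_pathway({"A", "B", "Z"}, {"T"}, directed,
                                 unreached_policy="exclude")
        assert "Z" not in excl.g_u | excl.g_d

    def test_cycle_gives_target_side_precedence(self):
        directed = nx.DiGraph([("A", "T"), ("T", "A")])
        part = partition_pathway({"A"}, {"T"}, directed)
        assert part.g_u == {"A"}  # upstream wins even though A is also downstream

    def test_disconnected_pathway_is_an_error(self):
        directed = nx.DiGraph([("X", "Y")])
        with pytest.raises(DisconnectedPathwayError):
            partition_pathway({"A", "B"}, {"T"}, directed)

    def test_matches_transitive_closure_oracle_on_random_dags(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = 15
            order = rng.permutation(n)
            adj = np.zeros((n, n), dtype=bool)
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.15:
                        adj[order[i], order[j]] = True
            directed = nx.DiGraph(zip(*np.nonzero(adj)))
            directed.add_nodes_from(range(n))
            targets = set(rng.choice(n, 2, replace=False))
            pathway = set(range(n))
            # oracle: boolean matrix closure by repeated squaring
            reach = adj.copy()
            for _ in range(int(np.ceil(np.log2(n))) + 1):
                reach = reach | (reach @ reach)
            g_u = targets | {g for g in pathway
                             if any(reach[g, t] for t in targets)}
            g_d = {g for g in pathway
                   if any(reach[t, g] for t in targets)} - g_u
            g_d |= pathway - g_u - g_d  # unreached default downstream
            part = partition_pathway(pathway, targets, directed)
            assert part.g_u == g_u
            assert part.g_d == g_d


class TestExpressionSum:
    def test_plain_sum(self, tiny_cohort):
        assert expression_sum(tiny_cohort, "s1", {"A", "B"}) == 5.0

    def test_empty_set_sums_to_zero(self, tiny_cohort):
        assert expression_sum(tiny_cohort, "s1", set()) == 0.0

    def test_missing_genes_dropped(self, tiny_cohort):
        assert expression_sum(tiny_cohort, "s2", {"A", "NOT_A_GENE"}) == 1.0

    def test_unknown_sample_is_an_error(self, tiny_cohort):
        with pytest.raises(ValidationError, match="unknown sample"):
            expression_sum(tiny_cohort, "s99", {"A"})

    def test_random_subset_matches_resummation_oracle(self):
        rng = np.random.default_rng(13)
        expr = pd.DataFrame(rng.lognormal(0, 1, (80, 6)),
                            index=[f"g{i}" for i in range(80)],
                            columns=[f"s{i}" for i in range(6)])
        from dcsp.data import Cohort
        cohort = Cohort(expr, pd.Series("X", index=expr.columns))
        genes = set(rng.choice(expr.index, 50, replace=False))
        got = expression_sum(cohort, "s3", genes)
        assert got == pytest.approx(expr.loc[sorted(genes), "s3"].sum())


class TestComputePAS:
    @pytest.fixture()
    def partition(self):
        from dcsp.pas import PathwayPartition
        return PathwayPartition("drug", "pw", frozenset({"A", "B"}),
                                frozenset({"C", "D"}))

    def test_weight_free_case(self, tiny_cohort, partition):
        out = compute_pas(tiny_cohort, partition, _weights(0, 0, 0)).set_index("sample")
        assert out.loc["s1", "PAS_u"] == 5.0   # A+B
        assert out.loc["s1", "PAS_d"] == 6.0   # C+D
        assert out.loc["s1", "PAS"] == -1.0

    def test_saturated_weights_quadruple_the_sums(self, tiny_cohort, partition):
        out = compute_pas(tiny_cohort, partition, _weights(1, 1, 1)).set_index("sample")
        assert out.loc["s1", "PAS_u"] == 20.0

    def test_swap_of_gu_gd_negates_pas(self, tiny_cohort, partition):
        from dcsp.pas import PathwayPartition
        swapped = PathwayPartition("drug", "pw", partition.g_d, partition.g_u)
        w = _weights(0.3, 0.6, 0.9)
        a = compute_pas(tiny_cohort, partition, w)["PAS"].to_numpy()
        b = compute_pas(tiny_cohort, swapped, w)["PAS"].to_numpy()
        assert np.array_equal(a, -b)

    def test_pas_u_bounded_by_weight_range(self, tiny_cohort, partition):
        rng = np.random.default_rng(14)
        for _ in range(10):
            w = _weights(*rng.random(3))
            out = compute_pas(tiny_cohort, partition, w)
            assert ((out["PAS_u"] >= out["S_u"] - 1e-12)
                    & (out["PAS_u"] <= 4 * out["S_u"] + 1e-12)).all()

    def test_larger_weights_amplify_but_never_flip(self, tiny_cohort, partition):
        lo = compute_pas(tiny_cohort, partition, _weights(0.2, 0.2, 0.2))["PAS"]
        hi = compute_pas(tiny_cohort, partition, _weights(0.9, 0.2, 0.2))["PAS"]
        nonzero = lo != 0
        assert (np.abs(hi[nonzero]) >= np.abs(lo[nonzero])).all()
        assert (np.sign(hi[nonzero]) == np.sign(lo[nonzero])).all()


class TestPASMatrix:
    def test_record_cardinality(self, planted_sim, planted_pas):
        n_samples = planted_sim.cohort.n_samples
        n_pairs = len(planted_sim.drug_targets) * len(planted_sim.pathways)
        assert len(planted_pas) == n_pairs * n_samples

    def test_zero_expression_gives_zero_pas(self, planted_sim):
        from dcsp.data import Cohort
        cohort = planted_sim.cohort
        zero = Cohort(cohort.expression * 0.0, cohort.labels, name="zero")
        out = pas_matrix(zero, planted_sim.pathways, planted_sim.drug_targets,
                         planted_sim.drivers, planted_sim.directed,
                         planted_sim.functional, PASConfig())
        assert (out["PAS"] == 0).all()

    def test_linearity_in_expression(self, planted_sim, planted_pas):
        from dcsp.data import Cohort
        cohort = planted_sim.cohort
        scaled = Cohort(cohort.expression * 3.7, cohort.labels, name="scaled")
        out = pas_matrix(scaled, planted_sim.pathways, planted_sim.drug_targets,
                         planted_sim.drivers, planted_sim.directed,
                         planted_sim.functional, PASConfig())
        np.testing.assert_allclose(out["PAS"].to_numpy(),
                                   3.7 * planted_pas["PAS"].to_numpy(), rtol=1e-12)

    def test_weight_factor_constant_within_triplet(self, planted_pas):
        # PAS_u / S_u is the same for every sample of a (drug, pathway, cancer)
        sub = planted_pas[planted_pas["S_u"] > 0]
        ratios = sub["PAS_u"] / sub["S_u"]
        spread = ratios.groupby([sub["drug"], sub["pathway"], sub["cancer"]]).agg(np.ptp)
        assert (spread < 1e-9).all()

    def test_matches_stepwise_composition_oracle(self, planted_sim, planted_pas):
        sim = planted_sim
        drug, pathway, cancer = "D2", "PW3", "C4"
        part = partition_pathway(sim.pathways[pathway], sim.drug_targets[drug],
                                 sim.directed, drug=drug, pathway=pathway)
        z1 = nea_z(sim.functional, sim.drivers[cancer], sim.drug_targets[drug]).z
        z2 = nea_z(sim.functional, sim.pathways[pathway], sim.drivers[cancer]).z
        z3 = nea_z(sim.functional, sim.pathways[pathway], sim.drug_targets[drug]).z
        w = weights_from_z(z1, z2, z3)
        manual = compute_pas(sim.cohort, part, w,
                             samples=sim.cohort.samples_of(cancer)).set_index("sample")
        got = planted_pas[(planted_pas["drug"] == drug)
                          & (planted_pas["pathway"] == pathway)
                          & (planted_pas["cancer"] == cancer)].set_index("sample")
        np.testing.assert_allclose(got["PAS"].to_numpy(),
                                   manual.loc[got.index, "PAS"].to_numpy(), rtol=1e-12)
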