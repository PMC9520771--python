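"""Readers, writers and the dataset-level filtering rules."""

import numpy as np
import pandas as pd
import pytest

from dcsp.data import (Cohort, PathwayDB, dedupe_monotherapy, filter_driver_fusions,
                       filter_driver_mutations, filter_unexpressed_genes, read_cohort,
                       read_drug_response, read_gmt, write_cohort, write_drug_response,
                       write_gmt)
from dcsp.errors import ParseError, ValidationError


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

class TestReadGMT:
    def test_duplicate_genes_within_line_are_deduplicated(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("PW1\tdesc\tA\tB\tB\n")
        assert read_gmt(p).pathways == {"PW1": frozenset({"A", "B"})}

    def test_empty_file_gives_empty_db(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("")
        assert len(read_gmt(p)) == 0

    def test_three_line_fixture_matches_hand_parse(self, tmp_path):
        lines = ["PW1\tna\tA\tB", "PW2\tna\tC", "PW3\tna\tA\tC\tD"]
        p = tmp_path / "x.gmt"
        p.write_text("\n".join(lines) + "\n")
        expected = {name: frozenset(rest)
                    for name, _, *rest in (l.split("\t") for l in lines)}
        assert read_gmt(p).pathways == expected

    def test_malformed_line_error_names_line_number(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("PW1\tna\tA\nBADLINE\n")
        with pytest.raises(ParseError, match=":2"):
            read_gmt(p)

    def test_duplicate_pathway_name_rejected(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("PW1\tna\tA\nPW1\tna\tB\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_gmt(p)


# ---------------------------------------------------------------------------
# domain-type invariants and round trips
# ---------------------------------------------------------------------------

class TestCohortInvariants:
    def test_duplicate_genes_rejected(self):
        expr = pd.DataFrame([[1.0], [2.0]], index=["A", "A"], columns=["s1"])
        with pytest.raises(ValidationError, match="duplicate gene"):
            Cohort(expr, pd.Series({"s1": "X"}))

    def test_unlabeled_sample_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["A"], columns=["s1", "s2"])
        with pytest.raises(ValidationError, match="without a cancer label"):
            Cohort(expr, pd.Series({"s1": "X"}))

    def test_negative_expression_rejected(self):
        expr = pd.DataFrame([[-1.0]], index=["A"], columns=["s1"])
        with pytest.raises(ValidationError, match="finite"):
            Cohort(expr, pd.Series({"s1": "X"}))

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            PathwayDB({"PW": frozenset()})


class TestRoundTrips:
    def test_cohort(self, tmp_path, tiny_cohort):
        write_cohort(tiny_cohort, tmp_path / "e.tsv", tmp_path / "l.tsv")
        back = read_cohort(tmp_path / "e.tsv", tmp_path / "l.tsv", name="tiny")
        pd.testing.assert_frame_equal(back.expression, tiny_cohort.expression)
        assert back.labels.to_dict() == tiny_cohort.labels.to_dict()

    def test_pathway_db(self, tmp_path):
        db = PathwayDB({"PW1": frozenset("ABC"), "PW2": frozenset("XY")})
        write_gmt(db, tmp_path / "x.gmt")
        assert read_gmt(tmp_path / "x.gmt") == db

    def test_drug_response(self, tmp_path):
        tab = pd.DataFrame({"sample": ["s1", "s2"], "drug": ["D1", "D1"],
                            "auc": [0.51, 0.73]})
        write_drug_response(tab, tmp_path / "r.tsv")
        pd.testing.assert_frame_equal(read_drug_response(tmp_path / "r.tsv"), tab)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _cohort_from_matrix(values, genes, samples, cancer="X"):
    expr = pd.DataFrame(values, index=genes, columns=samples)
    return Cohort(expr, pd.Series(cancer, index=samples))


class TestFilterUnexpressedGenes:
    def test_all_zero_gene_removed_and_expressed_gene_kept(self):
        values = np.vstack([np.zeros(10), np.full(10, 5.0)])
        cohort = _cohort_from_matrix(values, ["dead", "alive"],
                                     [f"s{i}" for i in range(10)])
        out = filter_unexpressed_genes(cohort)
        assert out.genes == ["alive"]

    def test_synthetic_matrix_count_matches_direct_scan(self):
        rng = np.random.default_rng(0)
        values = rng.lognormal(0, 1, size=(100, 40))
        values[:20, : int(40 * 0.95)] = 0.0  # 20 genes silent in 95% of samples
        cohort = _cohort_from_matrix(values, [f"g{i}" for i in range(100)],
                                     [f"s{i}" for i in range(40)])
        out = filter_unexpressed_genes(cohort, threshold=1e-2, fraction=0.9)
        assert len(out.genes) == 80
        # oracle: direct proportion scan
        keep = ((values <= 1e-2).mean(axis=1) <= 0.9)
        assert out.genes == [f"g{i}" for i in np.flatnonzero(keep)]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(0, 1, size=(30, 10))
        values[:5] = 0.0
        cohort = _cohort_from_matrix(values, [f"g{i}" for i in range(30)],
                                     [f"s{i}" for i in range(10)])
        once = filter_unexpressed_genes(cohort)
        twice = filter_unexpressed_genes(once)
        pd.testing.assert_frame_equal(once.expression, twice.expression)

    def test_removing_everything_is_an_error(self):
        cohort = _cohort_from_matrix(np.zeros((3, 4)), list("abc"), list("wxyz"))
        with pytest.raises(ValidationError, match="all genes"):
            filter_unexpressed_genes(cohort)


class TestFilterDriverMutations:
    @pytest.fixture()
    def cohort100(self):
        return _cohort_from_matrix(np.ones((2, 100)), ["g1", "g2"],
                                   [f"s{i}" for i in range(100)])

    def test_two_percent_boundary_is_inclusive(self, cohort100):
        occ = pd.DataFrame({"gene": ["m"] * 2, "sample": ["s0", "s1"]})
        out = filter_driver_mutations(occ, cohort100, min_fraction=0.02)
        assert "m" in out["X"]

    def test_below_boundary_dropped(self, cohort100):
        occ = pd.DataFrame({"gene": ["m"], "sample": ["s0"]})
        assert filter_driver_mutations(occ, cohort100, min_fraction=0.02) == {}

    def test_binomial_table_matches_threshold_oracle(self, cohort100):
        rng = np.random.default_rng(2)
        rows = [(f"gene{g}", f"s{s}")
                for g in range(50)
                for s in np.flatnonzero(rng.random(100) < 0.03)]
        occ = pd.DataFrame(rows, columns=["gene", "sample"])
        out = filter_driver_mutations(occ, cohort100, min_fraction=0.02)
        kept = out.get("X", frozenset())
        counts = occ.drop_duplicates().groupby("gene")["sample"].nunique()
        oracle = {g for g, c in counts.items() if c / 100 >= 0.02}
        assert set(kept) == oracle

    def test_monotone_in_threshold(self, cohort100):
        rng = np.random.default_rng(3)
        rows = [(f"gene{g}", f"s{s}")
                for g in range(30)
                for s in np.flatnonzero(rng.random(100) < 0.05)]
        occ = pd.DataFrame(rows, columns=["gene", "sample"])
        loose = filter_driver_mutations(occ, cohort100, min_fraction=0.01)
        strict = filter_driver_mutations(occ, cohort100, min_fraction=0.04)
        assert strict.get("X", frozenset()) <= loose.get("X", frozenset())

    def test_unknown_sample_is_an_error(self, cohort100):
        occ = pd.DataFrame({"gene": ["m"], "sample": ["nope"]})
        with pytest.raises(ValidationError, match="unknown sample"):
            filter_driver_mutations(occ, cohort100)


class TestFilterDriverFusions:
    @pytest.fixture()
    def cohort(self):
        return _cohort_from_matrix(np.ones((1, 6)), ["g"],
                                   [f"s{i}" for i in range(6)])

    def test_single_occurrence_dropped(self, cohort):
        tab = pd.DataFrame({"fusion": ["F1"], "genes": ["A,B"], "sample": ["s0"]})
        assert filter_driver_fusions(tab, cohort, min_count=2) == {}

    def test_two_occurrences_with_empty_whitelist_kept(self, cohort):
        tab = pd.DataFrame({"fusion": ["F1", "F1"], "genes": ["A,B", "A,B"],
                            "sample": ["s0", "s1"]})
        out = filter_driver_fusions(tab, cohort, min_count=2)
        assert out["X"] == frozenset({"A", "B"})

    def test_whitelist_intersection_matches_set_algebra(self, cohort):
        tab = pd.DataFrame({
            "fusion": ["F1", "F1", "F2", "F2", "F3", "F3", "F4"],
            "genes": ["A,B", "A,B", "C,D", "C,D", "E,F", "E,F", "G,H"],
            "sample": ["s0", "s1", "s1", "s2", "s3", "s4", "s5"]})
        whitelist = {"F1", "F3", "F9"}
        out = filter_driver_fusions(tab, cohort, min_count=2, whitelist=whitelist)
        # oracle: recurrent fusions {F1,F2,F3} intersected with the whitelist
        assert out["X"] == frozenset({"A", "B", "E", "F"})


class TestDedupeMonotherapy:
    def test_replicated_pair_dropped_entirely(self):
        raw = pd.DataFrame({"sample": ["s1", "s2", "s2"], "drug": ["d1"] * 3,
                            "auc": [0.4, 0.5, 0.6]})
        out = dedupe_monotherapy(raw)
        assert list(out["sample"]) == ["s1"]

    def test_identity_without_duplicates(self):
        raw = pd.DataFrame({"sample": ["s1", "s2"], "drug": ["d1", "d2"],
                            "auc": [0.4, 0.5]})
        pd.testing.assert_frame_equal(dedupe_monotherapy(raw), raw)

    def test_random_fixture_count_matches_multiset_oracle(self):
        rng = np.random.default_rng(4)
        pairs = [(f"s{rng.integers(8)}", f"d{rng.integers(3)}") for _ in range(60)]
        raw = pd.DataFrame(pairs, columns=["sample", "drug"])
        raw["auc"] = rng.random(len(raw))
        out = dedupe_monotherapy(raw)
        from collections import Counter
        counts = Counter(pairs)
        expected = sum(1 for c in counts.values() if c == 1)
        assert len(out) == expected

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        raw = pd.DataFrame({"sample": rng.choice(["a", "b", "c"], 20),
                            "drug": rng.choice(["d1", "d2"], 20),
                            "auc": rng.random(20)})
        once = dedupe_monotherapy(raw)
        pd.testing.assert_frame_equal(dedupe_monotherapy(once), once)
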