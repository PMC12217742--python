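"""The 61-feature pair-characterization engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paretoppi import features as ft
from paretoppi.interactions import EvalueTable, canonical_pair

sequences = st.text(alphabet=ft.AMINO_ACIDS, min_size=2, max_size=80)


class TestRegistry:
    def test_exactly_61_unique_stable_names(self):
        names = ft.feature_registry()
        assert len(names) == 61
        assert len(set(names)) == 61
        assert names == ft.FEATURE_NAMES == ft.feature_registry()

    def test_group_layout(self):
        names = ft.FEATURE_NAMES
        assert names[:3] == ("BP_similarity", "MF_similarity", "CC_similarity")
        assert "Exists in MINT?" in names and "pfam_interaction" in names
        assert sum(n.startswith("Spearman_") for n in names) == 17
        assert sum(n.endswith(" %") for n in names) == 20
        assert names[-1] == "charge_pH7_dif"

    def test_rna_datasets_extend_the_registry(self):
        extended = ft.feature_registry(
            expression_datasets=ft.EXPRESSION_DATASETS + ("RNA1", "RNA2"))
        assert len(extended) == 63
        assert "Spearman_RNA1" in extended


class TestComposition:
    @pytest.mark.parametrize("seq,expected", [
        ("AAAA", {"A": 1.0}),
        ("ACDE", {"A": 0.25, "C": 0.25, "D": 0.25, "E": 0.25}),
        ("AAC", {"A": 2 / 3, "C": 1 / 3}),
    ])
    def test_known_compositions(self, seq, expected):
        comp = ft.aa_composition(seq)
        for aa in ft.AMINO_ACIDS:
            assert comp[aa] == pytest.approx(expected.get(aa, 0.0))

    def test_invalid_residue_names_position(self):
        with pytest.raises(ft.InvalidSequenceError, match="position 2"):
            ft.aa_composition("ACXDE")

    @given(sequences)
    @settings(deadline=None)
    def test_composition_sums_to_one(self, seq):
        assert sum(ft.aa_composition(seq).values()) == pytest.approx(1.0, abs=1e-9)


class TestPhyschem:
    def test_aromaticity(self):
        assert ft.physchem_profile("FWY")["aromaticity"] == 1.0
        assert ft.physchem_profile("AG")["aromaticity"] == 0.0

    def test_extinction_coefficients(self):
        p = ft.physchem_profile("WY")
        assert p["eps_reduced"] == 6990  # 5500 + 1490
        assert p["eps_cystines"] == 6990  # no cystine bond possible

    def test_gravy(self):
        assert ft.physchem_profile("AG")["gravy"] == pytest.approx(0.7)  # (1.8-0.4)/2

    def test_charge_signs_at_ph7(self):
        assert ft.charge_at_pH("DDDDDD", 7.0) < 0
        assert ft.charge_at_pH("KKKKKK", 7.0) > 0

    def test_instability_missing_for_single_residue(self):
        assert ft.physchem_profile("A")["instability"] is None
        assert ft.physchem_profile("GG")["instability"] is not None

    @given(sequences)
    @settings(deadline=None, max_examples=40)
    def test_internal_consistency(self, seq):
        comp = ft.aa_composition(seq)
        p = ft.physchem_profile(seq)
        # aromaticity is the summed F/W/Y composition
        assert p["aromaticity"] == pytest.approx(comp["F"] + comp["W"] + comp["Y"])
        # cystine pairing can only add absorbance
        assert p["eps_cystines"] >= p["eps_reduced"]
        assert (p["eps_cystines"] == p["eps_reduced"]) == (seq.count("C") <= 1)
        helix, turn, sheet = (p["helix_frac"], p["turn_frac"], p["sheet_frac"])
        assert 0 <= min(helix, turn, sheet) and max(helix, turn, sheet) <= 1


class TestPairDifference:
    def test_identity_symmetry_and_example(self):
        comp_a, comp_b = ft.aa_composition("AAAA"), ft.aa_composition("AACC")
        prof_a, prof_b = ft.physchem_profile("AAAA"), ft.physchem_profile("AACC")
        diff = ft.pair_difference(prof_a, prof_b, comp_a, comp_b)
        assert len(diff) == 30
        assert diff["A %"] == pytest.approx(0.5)
        same = ft.pair_difference(prof_a, prof_a, comp_a, comp_a)
        assert all(v == 0 for v in same.values())
        flipped = ft.pair_difference(prof_b, prof_a, comp_b, comp_a)
        assert diff == flipped

    def test_missing_propagates(self):
        prof_a, prof_b = ft.physchem_profile("A"), ft.physchem_profile("GG")
        diff = ft.pair_difference(prof_a, prof_b, ft.aa_composition("A"),
                                  ft.aa_composition("GG"))
        assert diff["instability_dif"] is None


class TestSetFeatures:
    @pytest.mark.parametrize("a,b,expected", [
        ({"g1", "g2"}, {"g2", "g3"}, 1 / 3),
        ({"g1"}, {"g1"}, 1.0),
        ({"g1"}, {"g2"}, 0.0),
    ])
    def test_go_jaccard(self, a, b, expected):
        assert ft.go_similarity(a, b) == pytest.approx(expected)

    def test_go_both_empty_missing_and_pluggable(self):
        assert ft.go_similarity(set(), set()) is None
        assert ft.go_similarity({"a"}, {"b"}, measure=lambda x, y: 0.42) == 0.42

    def test_flags_unordered_and_empty(self):
        tables = {"MINT": {("A1", "B1")}, "APID": set()}
        f1 = ft.lookup_flags(("A1", "B1"), tables, ("MINT", "APID"))
        f2 = ft.lookup_flags(("B1", "A1"), tables, ("MINT", "APID"))
        assert f1 == f2 == {"MINT": 1, "APID": 0}

    def test_pfam_examples_and_brute_force(self):
        assert ft.pfam_interaction({"PF1"}, {"PF2"}, {("PF1", "PF2")}) == 1
        assert ft.pfam_interaction({"PF1"}, {"PF2"}, {("PF3", "PF4")}) == 0
        rng = np.random.default_rng(2)
        pool = [f"PF{i:02d}" for i in range(12)]
        for _ in range(20):
            da = set(rng.choice(pool, 5, replace=False))
            db = set(rng.choice(pool, 5, replace=False))
            ddi = {canonical_pair(*rng.choice(pool, 2, replace=False))
                   for _ in range(6)}
            expected = int(any(canonical_pair(x, y) in ddi
                               for x in da for y in db))
            assert ft.pfam_interaction(da, db, ddi) == expected

    def test_colocalization(self):
        assert ft.colocalization({"nucleus"}, {"nucleus", "cytosol"}) == 1
        assert ft.colocalization({"nucleus"}, {"membrane"}) == 0
        assert ft.colocalization(None, {"membrane"}) is None


class TestExpression:
    def test_identical_reversed_and_monotone(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert ft.expression_correlation(x, x) == pytest.approx(1.0)
        assert ft.expression_correlation(x, x[::-1]) == pytest.approx(-1.0)
        assert ft.expression_correlation(x, 10 * x) == pytest.approx(1.0)

    def test_undefined_cases_are_missing(self):
        x = np.array([1.0, 2.0, 3.0])
        assert ft.expression_correlation(x, np.ones(3)) is None  # constant
        assert ft.expression_correlation(x, None) is None
        assert ft.expression_correlation(x[:2], x[:2]) is None  # < 3 samples

    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=10, unique=True))
    @settings(deadline=None, max_examples=30)
    def test_monotone_transform_invariance(self, vals):
        x = np.array(vals, dtype=float) / 100.0
        y = np.exp(x / 10) + 3  # strictly increasing transform
        assert ft.expression_correlation(x, y) == pytest.approx(1.0)


class TestAssemble:
    def test_full_resources_no_missing(self, small_world):
        rec = small_world.records[0]
        fv = ft.assemble_feature_vector(rec.pair, small_world.resources)
        assert len(fv.values) == len(fv.names)
        assert not fv.missing_mask.any()

    def test_symmetry(self, small_world):
        a, b = small_world.records[3].pair
        fa = ft.assemble_feature_vector((a, b), small_world.resources)
        fb = ft.assemble_feature_vector((b, a), small_world.resources)
        np.testing.assert_array_equal(fa.values, fb.values)

    def test_self_pair_differences_zero_similarities_maximal(self, small_world):
        acc = small_world.accessions[0]
        fv = ft.assemble_feature_vector((acc, acc), small_world.resources)
        s = fv.as_series()
        for name in fv.names:
            if name.endswith(("_dif", " %")):
                assert s[name] == 0.0
        assert s["BP_similarity"] == 1.0
        assert s["co_localization"] == 1.0
        for ds in small_world.resources.expression_datasets:
            assert s[f"Spearman_{ds}"] == pytest.approx(1.0)

    def test_missing_expression_flags_exactly_those_features(self, small_world):
        res = small_world.resources
        a, b = small_world.records[0].pair
        bare_a = ft.ProteinAnnotation(accession=a, sequence=res.annotations[a].sequence,
                                      go_terms=res.annotations[a].go_terms,
                                      pfam_domains=res.annotations[a].pfam_domains,
                                      localizations=res.annotations[a].localizations)
        patched = ft.FeatureResources(
            annotations={**res.annotations, a: bare_a},
            orthology=res.orthology, databases=res.databases, ddi=res.ddi,
            evalues=res.evalues, expression_datasets=res.expression_datasets,
        )
        fv = ft.assemble_feature_vector((a, b), patched)
        missing = {n for n, m in zip(fv.names, fv.missing_mask) if m}
        assert missing == {f"Spearman_{ds}" for ds in res.expression_datasets}

    def test_missing_sequence_is_hard_error(self, small_world):
        with pytest.raises(KeyError):
            ft.assemble_feature_vector(("Z99999", small_world.accessions[0]),
                                       small_world.resources)

    def test_unknown_evalue_is_missing_not_zero(self, small_world):
        res = small_world.resources
        accs = small_world.accessions
        # pick a pair that was never aligned
        pair = None
        for i in range(len(accs)):
            for j in range(i + 1, len(accs)):
                if res.evalues.get(accs[i], accs[j]) is None:
                    pair = (accs[i], accs[j])
                    break
            if pair:
                break
        fv = ft.assemble_feature_vector(pair, res)
        s = fv.as_series()
        assert np.isnan(s["Sequence Similarity"])

    def test_matrix_shape_and_header(self, small_matrix, small_world):
        X, M, y = small_matrix
        names = ft.feature_registry(
            expression_datasets=small_world.resources.expression_datasets)
        assert list(X.columns) == list(names)
        assert X.shape == M.shape == (len(y), len(names))
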