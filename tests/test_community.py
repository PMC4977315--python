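"""PLFA classification, F:B indices, table transforms and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from isotrace import (
    BACTERIAL_PLFA_MARKERS,
    FUNGAL_PLFA_MARKERS,
    PLFAProfile,
    TaxonTable,
    arb_ratio,
    classify_plfa,
    fb_from_taxa,
    fb_percent,
    fold_change,
    hellinger,
    permanova,
    permanova_sequential,
    relative_abundance,
)
from isotrace.community import canonicalize_marker


class TestClassifyPlfa:
    def test_only_fungal_marker(self):
        f, b = classify_plfa(PLFAProfile("s", {"18:2ω6,9": 0.5}))
        assert (f, b) == (0.5, 0.0)

    def test_all_bacterial_markers_at_unit_concentration(self):
        profile = PLFAProfile("s", {m: 1.0 for m in BACTERIAL_PLFA_MARKERS})
        f, b = classify_plfa(profile)
        assert b == pytest.approx(len(BACTERIAL_PLFA_MARKERS)) == pytest.approx(23)
        assert f == 0.0

    def test_unknown_marker_excluded_with_log(self, caplog):
        profile = PLFAProfile("s", {"18:2ω6,9": 0.5, "20:0": 3.0})
        with caplog.at_level("WARNING"):
            f, b = classify_plfa(profile)
        assert (f, b) == (0.5, 0.0)
        assert "20:0" in caplog.text

    def test_ascii_omega_canonicalized(self):
        assert canonicalize_marker("18:2w6,9") == "18:2ω6,9"
        f, _ = classify_plfa(PLFAProfile("s", {"18:2w6,9": 1.5}))
        assert f == pytest.approx(1.5)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            PLFAProfile("s", {})

    def test_marker_totals_are_exact_sums(self):
        rng = np.random.default_rng(5)
        conc = {m: float(rng.uniform(0, 2)) for m in BACTERIAL_PLFA_MARKERS + FUNGAL_PLFA_MARKERS}
        f, b = classify_plfa(PLFAProfile("s", conc))
        assert b == pytest.approx(sum(conc[m] for m in BACTERIAL_PLFA_MARKERS), rel=1e-12)
        assert f == pytest.approx(conc["18:2ω6,9"], rel=1e-12)


class TestFbPercent:
    def test_measured_lipid_pools(self):
        # field-measured PLFA index totals of the two soils
        assert fb_percent(0.52, 18.46, ndigits=1) == 2.8
        assert fb_percent(0.99, 23.55, ndigits=1) == 4.2

    def test_ratio_between_soils(self):
        ratio = fb_percent(0.99, 23.55) / fb_percent(0.52, 18.46)
        assert round(ratio, 1) == 1.5

    def test_zero_fungal(self):
        assert fb_percent(0.0, 5.0) == 0.0

    def test_zero_bacterial_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            fb_percent(1.0, 0.0)

    @pytest.mark.parametrize("scale", [0.1, 3.0, 1e6])
    def test_scale_invariance(self, scale):
        assert fb_percent(0.7 * scale, 21.0 * scale) == pytest.approx(fb_percent(0.7, 21.0))


class TestTaxonIndices:
    def test_fb_from_proportions(self):
        t = TaxonTable(pd.DataFrame({"s": [2.0, 98.0]}, index=["Fungi;Asco", "Bacteria;Actino"]))
        assert fb_from_taxa(t).loc["s", "percent_fb"] == pytest.approx(2.0 / 98.0 * 100)

    def test_archaea_do_not_move_the_index(self, small_taxa):
        base = fb_from_taxa(small_taxa)["percent_fb"]
        with_more_archaea = small_taxa.data.copy()
        with_more_archaea.loc["Archaea;Euryarchaeota"] *= 50
        again = fb_from_taxa(TaxonTable(with_more_archaea))["percent_fb"]
        assert np.allclose(base, again)

    def test_zero_bacteria_rejected(self):
        t = TaxonTable(pd.DataFrame({"s": [2.0]}, index=["Fungi;Asco"]))
        with pytest.raises(ZeroDivisionError):
            fb_from_taxa(t)

    def test_relative_abundance_normalizes_and_is_idempotent(self, small_taxa):
        rel = relative_abundance(small_taxa)
        assert np.allclose(rel.data.sum(axis=0), 1.0)
        twice = relative_abundance(rel)
        assert np.allclose(rel.data, twice.data)
        assert list(rel.data.index) == list(small_taxa.data.index)

    def test_relative_abundance_zero_sum_names_sample(self):
        t = TaxonTable(pd.DataFrame({"good": [1.0], "empty": [0.0]}, index=["Bacteria;X"]))
        with pytest.raises(ValueError, match="empty"):
            relative_abundance(t)

    def test_fold_change_cases(self):
        assert fold_change(0.3, 0.3) == pytest.approx(1.0)
        # shift of the dominant actinobacterial share after litter input
        assert fold_change(39.4, 32.9) == pytest.approx(1.1976, abs=1e-4)
        assert np.isnan(fold_change(0.5, 0.0))
        assert fold_change(0.0, 0.5) == 0.0

    def test_arb_ratio(self, small_taxa):
        # s1: A=30, rest=68 → 0.4412
        assert arb_ratio(small_taxa)["s1"] == pytest.approx(30.0 / 68.0)

    def test_arb_zero_actinobacteria(self):
        t = TaxonTable(pd.DataFrame({"s": [5.0]}, index=["Bacteria;Proteobacteria"]))
        assert arb_ratio(t)["s"] == 0.0

    def test_arb_error_when_only_actinobacteria(self):
        t = TaxonTable(pd.DataFrame({"s": [5.0]}, index=["Bacteria;Actinobacteria"]))
        with pytest.raises(ValueError):
            arb_ratio(t)


class TestHellinger:
    def test_uniform_column(self):
        out = hellinger(np.array([[1.0], [1.0], [1.0], [1.0]]))
        assert np.allclose(out, 0.5)

    def test_concentrated_column(self):
        out = hellinger(np.array([[4.0], [0.0]]))
        assert np.allclose(out[:, 0], [1.0, 0.0])

    def test_unit_sum_of_squares_on_random_tables(self):
        rng = np.random.default_rng(11)
        arr = rng.uniform(0, 5, size=(8, 6))
        out = hellinger(arr)
        assert np.allclose((out**2).sum(axis=0), 1.0)

    def test_composition_with_relative_abundance(self, small_taxa):
        direct = hellinger(small_taxa).data
        composed = hellinger(relative_abundance(small_taxa)).data
        assert np.allclose(direct, composed)

    def test_rejects_negative_cells(self):
        with pytest.raises(ValueError):
            hellinger(np.array([[1.0], [-0.1]]))


class TestPermanova:
    def test_exhaustive_p_on_separated_toy(self, toy_distance):
        # 20 distinct relabelings of 3+3; the observed grouping and its
        # complement both maximize F, so the exact p is 2/20
        d, groups = toy_distance
        res = permanova(d, groups, n_permutations=999)
        assert res.exhaustive
        assert res.n_permutations == 20
        assert res.p_value == pytest.approx(0.1)
        assert np.isinf(res.pseudo_f)  # zero within-group scatter

    def test_exhaustive_matches_manual_enumeration(self):
        # brute-force oracle on a small non-degenerate design
        from itertools import combinations

        rng = np.random.default_rng(3)
        y = rng.normal(size=(6, 2))
        d = squareform(pdist(y))
        d2 = d**2
        labels = np.array([0, 0, 0, 1, 1, 1])

        def f_of(codes):
            n = 6
            sst = d2.sum() / (2 * n)
            ssw = 0.0
            for g in (0, 1):
                idx = np.flatnonzero(np.asarray(codes) == g)
                ssw += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
            return ((sst - ssw) / 1) / (ssw / 4)

        f_obs = f_of(labels)
        fs = []
        for combo in combinations(range(6), 3):
            codes = np.ones(6, dtype=int)
            codes[list(combo)] = 0
            fs.append(f_of(codes))
        expected_p = np.mean(np.asarray(fs) >= f_obs - 1e-12)

        res = permanova(d, labels, n_permutations=999)
        assert res.exhaustive
        assert res.pseudo_f == pytest.approx(f_obs, rel=1e-12)
        assert res.p_value == pytest.approx(expected_p)

    def test_pseudo_f_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(42)
        y = rng.normal(size=(12, 4))
        y[6:] += 0.8
        d = squareform(pdist(y))
        labels = ["a"] * 6 + ["b"] * 6
        mine = permanova(d, labels, n_permutations=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d), grouping=labels, permutations=99
        )
        assert mine.pseudo_f == pytest.approx(float(ref["test statistic"]), rel=1e-10)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(10, 3))
        d = squareform(pdist(y))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        perm = rng.permutation(10)
        a = permanova(d, labels, n_permutations=99, seed=1)
        b = permanova(d[np.ix_(perm, perm)], labels[perm], n_permutations=99, seed=1)
        assert a.pseudo_f == pytest.approx(b.pseudo_f, rel=1e-12)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(14, 3))
        d = squareform(pdist(y))
        labels = ["a"] * 7 + ["b"] * 7
        p1 = permanova(d, labels, n_permutations=199, seed=5).p_value
        p2 = permanova(d, labels, n_permutations=199, seed=5).p_value
        assert p1 == p2

    def test_input_validation(self, toy_distance):
        d, groups = toy_distance
        with pytest.raises(ValueError):
            permanova(d + np.triu(np.ones_like(d)), groups)
        with pytest.raises(ValueError):
            permanova(d, ["A"] * 5 + ["B"])  # singleton group
        with pytest.raises(ValueError):
            permanova(d, ["A"] * 6)  # one group


class TestPermanovaSequential:
    def test_matches_adonis_decomposition(self):
        """Frozen from vegan::adonis2(dist ~ soil_class * treatment, by='terms')."""
        rng = np.random.default_rng(42)
        y = rng.normal(size=(12, 4))
        y[6:] += 0.8
        d = squareform(pdist(y))
        meta = pd.DataFrame(
            {
                "soil_class": ["low"] * 6 + ["high"] * 6,
                "treatment": (["before"] * 3 + ["after"] * 3) * 2,
            }
        )
        seq = permanova_sequential(
            d, meta, ["soil_class", "treatment", "soil_class:treatment"], 199, seed=0
        )
        assert seq.loc["soil_class", "ss"] == pytest.approx(12.896676, abs=1e-5)
        assert seq.loc["treatment", "ss"] == pytest.approx(3.074481, abs=1e-5)
        assert seq.loc["soil_class:treatment", "ss"] == pytest.approx(2.746325, abs=1e-5)
        assert seq.loc["Residual", "ss"] == pytest.approx(15.179289, abs=1e-5)
        assert seq.loc["soil_class", "pseudo_f"] == pytest.approx(6.7970, abs=1e-3)
        assert seq.loc["treatment", "pseudo_f"] == pytest.approx(1.6204, abs=1e-3)
        assert int(seq.loc["Residual", "df"]) == 8

    def test_term_sums_equal_total(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(12, 3))
        d = squareform(pdist(y))
        meta = pd.DataFrame(
            {"a": ["x"] * 6 + ["y"] * 6, "b": (["u"] * 3 + ["v"] * 3) * 2}
        )
        seq = permanova_sequential(d, meta, ["a", "b", "a:b"], 99, seed=0)
        total = (d**2).sum() / (2 * 12)
        assert seq["ss"].sum() == pytest.approx(total, rel=1e-10)
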