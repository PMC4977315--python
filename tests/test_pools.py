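"""CFE biomass, respiration integration, mass balance and replicate aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isotrace import (
    CFEPair,
    IsotopeMeasurement,
    Pool,
    TracerDose,
    aggregate_replicates,
    cfe_biomass_c,
    cfe_biomass_delta,
    cumulative_respired,
    mass_balance,
    nonliving_som_excess,
)
from isotrace.isotope import NegativeExcessWarning
from isotrace.pools import merge_respiration_series


def _pair(c_fum, c_nf, d_fum=-27.0, d_nf=-27.0, kec=0.45):
    return CFEPair(
        IsotopeMeasurement(Pool.FUMIGATED_EXTRACT, 24.0, d_fum, c_fum),
        IsotopeMeasurement(Pool.NONFUMIGATED_EXTRACT, 24.0, d_nf, c_nf),
        kec,
    )


class TestCFE:
    @pytest.mark.parametrize(
        ("c_fum", "c_nf", "kec", "expected"),
        [(10.0, 5.5, 0.45, 10.0), (7.0, 7.0, 0.45, 0.0), (7.0, 3.0, 1.0, 4.0)],
    )
    def test_biomass_c(self, c_fum, c_nf, kec, expected):
        assert cfe_biomass_c(_pair(c_fum, c_nf, kec=kec)) == pytest.approx(expected)

    def test_inverted_extracts_flagged_not_raised(self):
        pair = _pair(4.0, 6.0)
        assert pair.flagged
        assert cfe_biomass_c(pair) < 0

    def test_invalid_kec(self):
        with pytest.raises(ValueError):
            _pair(10.0, 5.0, kec=0.0)

    def test_delta_equal_sources(self):
        assert cfe_biomass_delta(_pair(10.0, 5.0, d_fum=40.0, d_nf=40.0)) == pytest.approx(40.0)

    def test_delta_two_pool_unmixing(self):
        # (100·10 − 0·5)/(10 − 5) = 200‰
        assert cfe_biomass_delta(_pair(10.0, 5.0, d_fum=100.0, d_nf=0.0)) == pytest.approx(200.0)

    def test_delta_undefined_when_no_biomass_carbon(self):
        with pytest.raises(ValueError):
            cfe_biomass_delta(_pair(5.0, 5.0))

    @given(
        st.floats(-27.0, 500.0),
        st.floats(-27.0, 0.0),
        st.floats(1.0, 50.0),
        st.floats(0.1, 40.0),
    )
    @settings(deadline=None)
    def test_delta_inverts_c_weighted_mixing(self, d_bio, d_nf, c_nf, c_bio):
        # mixing then unmixing must return the biomass δ
        c_fum = c_nf + c_bio
        d_fum = (c_nf * d_nf + c_bio * d_bio) / c_fum
        got = cfe_biomass_delta(_pair(c_fum, c_nf, d_fum=d_fum, d_nf=d_nf))
        assert got == pytest.approx(d_bio, rel=1e-9, abs=1e-9)


class TestNonlivingSom:
    def test_subtraction_and_sign(self):
        assert nonliving_som_excess(3.0, 1.0) == pytest.approx(2.0)
        assert nonliving_som_excess(1.2, 1.2) == 0.0
        with pytest.warns(NegativeExcessWarning):
            assert nonliving_som_excess(1.0, 1.5) == pytest.approx(-0.5)


class TestCumulativeRespired:
    def test_constant_rate(self):
        # 2 ng g⁻¹ h⁻¹ over 24 h in 50 g soil = 2400 ng = 2.4 μg
        t = np.array([0.0, 6.0, 12.0, 24.0])
        r = np.full(4, 2.0)
        assert cumulative_respired(t, r, 50.0) == pytest.approx(2.4)

    def test_all_zero_rates(self):
        assert cumulative_respired([0, 10, 20], [0, 0, 0], 50.0) == 0.0

    def test_exponential_rate_against_closed_form(self):
        k = 0.01  # h⁻¹
        r0 = 100.0
        t = np.arange(0.0, 720.0 + 1)
        auc = cumulative_respired(t, r0 * np.exp(-k * t), 1.0) * 1000.0  # back to ng
        exact = r0 * (1 - np.exp(-k * 720.0)) / k
        assert abs(auc / exact - 1) < 5e-4  # within 0.05 %

    def test_piecewise_linear_rate_is_integrated_exactly(self):
        # trapezoid is exact on linear segments: r(t) = 3 + 0.5 t
        t = np.array([0.0, 5.0, 11.0, 30.0])
        r = 3.0 + 0.5 * t
        exact = 3.0 * 30.0 + 0.25 * 30.0**2
        assert cumulative_respired(t, r, 1000.0) == pytest.approx(exact, rel=1e-12)

    def test_zero_at_t0_convention(self):
        # series starting at 6 h: a zero-rate node is prepended at t = 0
        got = cumulative_respired([6.0, 12.0], [2.0, 2.0], 1.0) * 1000.0
        assert got == pytest.approx(0.5 * 6 * 2 + 6 * 2)
        # alternative convention: left-extrapolate the first rate
        got2 = cumulative_respired([6.0, 12.0], [2.0, 2.0], 1.0, assume_zero_at_t0=False) * 1000.0
        assert got2 == pytest.approx(12 * 2)

    @pytest.mark.parametrize(
        ("t", "r"),
        [([5.0], [1.0]), ([0, 10, 5], [1, 1, 1]), ([0, 5, 5], [1, 1, 1])],
    )
    def test_input_errors(self, t, r):
        with pytest.raises(ValueError):
            cumulative_respired(t, r, 50.0)

    @given(st.integers(2, 20), st.integers(0, 10_000))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_horizon_for_nonnegative_rates(self, n, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 720, n))
        t += np.arange(n) * 1e-6  # break ties
        r = rng.uniform(0, 10, n)
        aucs = [
            cumulative_respired(t[: i + 1], r[: i + 1], 50.0) for i in range(1, n)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(aucs, aucs[1:]))

    def test_merge_bins_near_coincident_points(self):
        t, r = merge_respiration_series([6.0, 6.2, 24.0], [1.0, 3.0, 5.0], bin_width_h=0.5)
        assert len(t) == 2
        assert r[0] == pytest.approx(2.0)


class TestMassBalance:
    def test_all_zero_pools(self):
        mb = mass_balance(TracerDose(), 0.0, 0.0, 0.0)
        assert mb.fraction_respired == mb.fraction_biomass == mb.fraction_som == 0.0
        assert mb.fraction_unaccounted == 1.0

    def test_day30_worked_example(self):
        # printed day-30 pool masses of the bacterially dominated soil:
        # 302 μg respired, 10.7 μg biomass, 151.1 μg non-living SOM of a
        # 531.3 μg dose (per-gram excesses back-computed for a 50 g mesocosm)
        dose = TracerDose()
        mb = mass_balance(
            dose,
            respired_ug13c=302.0,
            biomass_excess_ng_g=10.7 * 1000 / 50,
            som_excess_ng_g=151.1 * 1000 / 50,
        )
        assert mb.fraction_respired == pytest.approx(302.0 / 531.3, rel=1e-12)
        assert mb.fraction_respired == pytest.approx(0.568, abs=5e-4)
        assert mb.fraction_biomass == pytest.approx(0.0201, abs=5e-4)
        assert mb.fraction_som == pytest.approx(0.2844, abs=5e-4)
        assert mb.fraction_unaccounted == pytest.approx(0.127, abs=5e-4)

    @given(
        st.floats(0, 400), st.floats(0, 5000), st.floats(0, 8000), st.floats(100.0, 1000.0)
    )
    @settings(deadline=None)
    def test_fractions_always_close_to_one(self, resp, bio, som, dose_ug):
        dose = TracerDose(dose_ug13c=dose_ug)
        mb = mass_balance(dose, resp, bio, som)
        total = (
            mb.fraction_respired + mb.fraction_biomass + mb.fraction_som + mb.fraction_unaccounted
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_dose_must_be_positive(self):
        with pytest.raises(ValueError):
            TracerDose(dose_ug13c=0.0)

    def test_excess_dose_interpretation_is_smaller(self):
        dose = TracerDose()
        assert 0 < dose.dose_excess_ug13c() < dose.dose_ug13c


class TestAggregateReplicates:
    def test_hand_arithmetic(self):
        m, se = aggregate_replicates([1.0, 2.0, 3.0])
        assert m == pytest.approx(2.0)
        assert se == pytest.approx(0.5774, abs=1e-4)

    def test_constant_replicates(self):
        m, se = aggregate_replicates([4.2, 4.2, 4.2])
        assert (m, se) == (pytest.approx(4.2), 0.0)

    def test_matches_textbook_formula_on_random_triples(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            v = rng.normal(size=3)
            m, se = aggregate_replicates(v)
            mean = sum(v) / 3
            sd = (sum((x - mean) ** 2 for x in v) / 2) ** 0.5
            assert m == pytest.approx(mean, rel=1e-12, abs=1e-12)
            assert se == pytest.approx(sd / 3**0.5, rel=1e-12, abs=1e-12)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            aggregate_replicates([1.0])
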