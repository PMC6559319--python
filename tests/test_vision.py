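"""Receptor-noise-limited model: noise scaling, closed forms, invariances."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

from camopipe import (
    DataError,
    ReceptorSet,
    RegionColour,
    achromatic_jnd,
    chromatic_jnd,
    chromatic_jnd_general,
    classify_jnd,
    luminance_from_catches,
    match_trajectory,
    receptor_noise,
)


class TestReceptorNoise:
    def test_most_abundant_cone_gets_reference_weber(self, fish_set):
        e = receptor_noise(fish_set)
        assert fish_set.names == ("lw", "sw")
        assert e[0] == 0.05  # LW is the most abundant class

    def test_abundance_scaling_matches_exact_arithmetic(self, fish_set):
        # independent oracle: 0.05 * sqrt(339/168) in exact arithmetic
        expected = float(sympy.Rational(5, 100) * sympy.sqrt(sympy.Rational(339, 168)))
        e = receptor_noise(fish_set)
        assert abs(e[1] - expected) <= 1e-12

    def test_equal_abundances_give_equal_noise(self):
        rs = ReceptorSet(
            names=("a", "b", "c"), weber_reference=0.1,
            abundances={"a": 2.0, "b": 2.0, "c": 2.0}, luminance_weber=0.1,
        )
        assert np.allclose(receptor_noise(rs), 0.1)

    def test_explicit_webers_override_scaling(self, human_set):
        assert np.allclose(receptor_noise(human_set), [0.020, 0.028, 0.066])


class TestChromaticJnd:
    def test_dichromat_closed_form_matches_symbolic_oracle(self, fish_set):
        # ΔS = ln(1.2) / sqrt(e_LW² + e_SW²) evaluated with sympy
        e_lw = sympy.Rational(5, 100)
        e_sw = e_lw * sympy.sqrt(sympy.Rational(339, 168))
        expected = float(sympy.log(sympy.Rational(6, 5)) / sympy.sqrt(e_lw**2 + e_sw**2))
        got = chromatic_jnd([1.0, 1.0], [1.2, 1.0], fish_set)
        assert got.jnd == pytest.approx(expected, rel=1e-12)
        assert got.band == "uncertain"

    def test_identical_stimuli_are_indistinguishable(self, fish_set, human_set):
        for rs, q in ((fish_set, [0.4, 0.2]), (human_set, [0.5, 0.4, 0.1])):
            band = chromatic_jnd(q, q, rs)
            assert band.jnd == 0.0
            assert band.band == "indistinguishable"

    def test_uniform_intensity_change_is_invisible_to_chromatic_channel(self, fish_set):
        qa = np.array([0.3, 0.12])
        assert chromatic_jnd(qa, 3.7 * qa, fish_set).jnd == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_receptors", [2, 3])
    def test_closed_forms_agree_with_general_quadratic(self, fish_set, human_set, n_receptors):
        rs = {2: fish_set, 3: human_set}[n_receptors]
        rng = np.random.default_rng(99)
        for _ in range(1000):
            qa = rng.uniform(0.01, 2.0, size=n_receptors)
            qb = rng.uniform(0.01, 2.0, size=n_receptors)
            closed = chromatic_jnd(qa, qb, rs).jnd
            general = chromatic_jnd_general(qa, qb, rs)
            assert abs(closed - general) <= 1e-10

    def test_general_form_supports_tetrachromats(self):
        # e.g. an avian-style observer: four receptor classes
        rs = ReceptorSet(
            names=("uvs", "sws", "mws", "lws"), weber_reference=0.1,
            abundances={"uvs": 1, "sws": 2, "mws": 2, "lws": 4}, luminance_weber=0.1,
        )
        ds = chromatic_jnd([0.2, 0.3, 0.4, 0.5], [0.25, 0.28, 0.38, 0.55], rs)
        assert ds.jnd > 0
        assert ds.jnd == pytest.approx(
            chromatic_jnd_general([0.2, 0.3, 0.4, 0.5], [0.25, 0.28, 0.38, 0.55], rs)
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        qa=st.tuples(*[st.floats(0.01, 5.0)] * 2),
        qb=st.tuples(*[st.floats(0.01, 5.0)] * 2),
        c=st.floats(0.01, 100.0),
    )
    def test_symmetry_and_scale_invariance(self, fish_set, qa, qb, c):
        ab = chromatic_jnd(qa, qb, fish_set).jnd
        ba = chromatic_jnd(qb, qa, fish_set).jnd
        scaled = chromatic_jnd(c * np.array(qa), c * np.array(qb), fish_set).jnd
        assert ab == pytest.approx(ba, abs=1e-10)
        assert ab == pytest.approx(scaled, abs=1e-8)

    def test_moving_one_channel_away_from_equality_never_decreases_jnd(self, fish_set):
        qb = np.array([0.5, 0.5])
        jnds = [chromatic_jnd([0.5 + d, 0.5], qb, fish_set).jnd for d in np.linspace(0, 2, 40)]
        assert np.all(np.diff(jnds) >= -1e-12)

    def test_non_positive_catches_rejected(self, fish_set):
        with pytest.raises(DataError):
            chromatic_jnd([0.0, 1.0], [1.0, 1.0], fish_set)
        with pytest.raises(DataError):
            chromatic_jnd([1.0, 1.0], [-0.5, 1.0], fish_set)


class TestAchromaticJnd:
    def test_equal_luminance_is_zero(self, human_set):
        assert achromatic_jnd(0.37, 0.37, human_set).jnd == 0.0

    def test_log_ratio_equal_to_weber_fraction_is_one_jnd(self, human_set):
        lum = 0.5
        got = achromatic_jnd(lum * np.exp(human_set.luminance_weber), lum, human_set)
        assert got.jnd == pytest.approx(1.0, abs=1e-12)

    def test_matches_high_precision_oracle(self):
        rs = ReceptorSet(
            names=("lw", "sw"), weber_reference=0.05,
            abundances={"lw": 1, "sw": 1}, luminance_weber=0.05,
        )
        expected = float(sympy.log(2) / sympy.Rational(5, 100))
        assert achromatic_jnd(2.0, 1.0, rs).jnd == pytest.approx(expected, rel=1e-12)

    def test_non_positive_luminance_rejected(self, human_set):
        with pytest.raises(DataError):
            achromatic_jnd(0.0, 1.0, human_set)


class TestDiscriminabilityBands:
    @pytest.mark.parametrize(
        "jnd,band",
        [
            (0.0, "indistinguishable"),
            (0.999, "indistinguishable"),
            (1.0, "uncertain"),     # boundaries belong to the uncertainty region
            (2.0, "uncertain"),
            (3.0, "uncertain"),
            (3.001, "discriminable"),
        ],
    )
    def test_band_boundaries(self, jnd, band):
        assert classify_jnd(jnd) == band


class TestMatchTrajectory:
    @staticmethod
    def _rc(uv, b, g, r):
        return RegionColour.from_channel_means(r=r, g=g, b=b, uv=uv)

    def test_crab_equal_to_background_gives_zero_jnds(self, fish_set, fish_mapping):
        rc = self._rc(0.06, 0.1, 0.2, 0.2)
        table = match_trajectory(
            [("c1", w, rc, rc) for w in range(5)], fish_set, fish_mapping
        )
        assert (table["chromatic_jnd"] == 0).all()
        assert (table["luminance_jnd"] == 0).all()
        assert list(table["week"]) == list(range(5))

    def test_composition_equals_per_week_calls(self, fish_set, fish_mapping):
        from camopipe import to_cone_catches

        crab0, crab1 = self._rc(0.05, 0.2, 0.3, 0.35), self._rc(0.05, 0.15, 0.28, 0.3)
        bg = self._rc(0.055, 0.09, 0.2, 0.2)
        table = match_trajectory(
            [("c1", 0, crab0, bg), ("c1", 1, crab1, bg)], fish_set, fish_mapping
        )
        for row, crab in zip(table.itertuples(), (crab0, crab1)):
            qc = to_cone_catches(crab, fish_mapping)
            qb = to_cone_catches(bg, fish_mapping)
            expected_chrom = chromatic_jnd(
                [qc[n] for n in fish_set.names], [qb[n] for n in fish_set.names], fish_set
            ).jnd
            expected_lum = achromatic_jnd(
                luminance_from_catches(qc, fish_set),
                luminance_from_catches(qb, fish_set),
                fish_set,
            ).jnd
            assert row.chromatic_jnd == pytest.approx(expected_chrom)
            assert row.luminance_jnd == pytest.approx(expected_lum)

    def test_convergent_series_has_non_increasing_luminance_jnd(self, fish_set, fish_mapping):
        from camopipe import CrabPhenotype, OntogenyParams, extract_region, generate_crab_series

        # dark crab darkening toward the mudflat background, no noise, no crossing
        phenotype = CrabPhenotype(
            base_reflectance=np.array([0.05, 0.22, 0.28, 0.34]),
            pattern_contrast=0.1, marking_size_px=4, shade_class="dark",
            carapace_width_px=40,
        )
        params = OntogenyParams(weeks=10, darkening_rate=0.04)
        series = generate_crab_series(phenotype, params, seed=5)
        bg = self._rc(0.055, 0.09, 0.2, 0.2)  # mudflat palette mean
        records = [
            (("c1"), week, extract_region(img, mask), bg) for week, img, mask in series
        ]
        table = match_trajectory(records, fish_set, fish_mapping)
        assert np.all(np.diff(table["luminance_jnd"]) <= 1e-9)
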