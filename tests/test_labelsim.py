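"""Simulator tests, including a brute-force carbon-fate enumeration oracle.

The oracle enumerates every discrete outcome path (triose-half choice,
tracer-labeled-or-not draws per turn, succinate orientation flips) molecule
by molecule, deriving the condensation fate map from the citrate structure
rather than reusing the engine's index arithmetic.  Engine and oracle must
agree to a total-variation distance below 1e-9.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurotracer.core import LabelPattern
from neurotracer.labelsim import (
    SimulationConfig,
    acetate_to_acetyl,
    aggregate_to_classes,
    bernoulli_pool,
    expected_label_count,
    glu_to_gaba,
    glycolysis_map,
    mix,
    oaa_to_asp,
    og_to_glu,
    pdh_step,
    run_two_compartment,
    simulate_peaks,
    synthetic_calibration,
    tca_turn,
    unlabeled,
)

# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def oracle_condense(acetyl, oaa):
    """Citrate-synthase → aconitase → IDH fate of one (acetyl, OAA) pair,
    derived from the citrate structure.

    Citrate's central carbon is OAA C2; it carries the OAA C1 carboxyl, the
    acetyl-derived arm (CH2 = acetyl methyl, COOH = acetyl carboxyl), and
    the OAA-derived arm (CH2 = OAA C3, COOH = OAA C4).  Aconitase moves the
    hydroxyl onto the OAA-arm CH2; IDH oxidizes that carbon and releases the
    carboxyl on the adjacent central carbon (OAA C1) as CO2.  Reading the
    resulting 2-oxoglutarate from its keto-adjacent carboxyl: C1 = OAA-arm
    COOH, C2 = OAA-arm CH2 (the new keto carbon), C3 = central carbon,
    C4 = acetyl CH2, C5 = acetyl COOH.
    """
    central = oaa[1]
    central_cooh = oaa[0]  # released as CO2 at the IDH step
    arm_ace_ch2, arm_ace_cooh = acetyl[1], acetyl[0]
    arm_oaa_ch2, arm_oaa_cooh = oaa[2], oaa[3]
    og = (arm_oaa_cooh, arm_oaa_ch2, central, arm_ace_ch2, arm_ace_cooh)
    co2 = central_cooh
    return og, co2


def oracle_acetyl_choices_from_glucose(p_labeled):
    """All (acetyl vector, probability) outcomes of one glucose molecule."""
    choices = []
    for labeled, lp in ((True, p_labeled), (False, 1.0 - p_labeled)):
        if lp == 0.0:
            continue
        g = (1, 0, 0, 0, 0, 0) if labeled else (0,) * 6
        for pyr, hp in (((g[2], g[1], g[0]), 0.5), ((g[3], g[4], g[5]), 0.5)):
            acetyl = (pyr[1], pyr[2])  # pyruvate C1 lost as CO2
            choices.append((acetyl, lp * hp))
    return choices


def oracle_acetyl_choices_from_acetate(p_labeled):
    choices = []
    if p_labeled > 0.0:
        choices.append(((1, 1), p_labeled))
    if p_labeled < 1.0:
        choices.append(((0, 0), 1.0 - p_labeled))
    return choices


def oracle_og_distribution(acetyl_choices, turns):
    """Exact final-turn oxoglutarate distribution by path enumeration."""
    results: dict[tuple, float] = {}

    def recurse(turn, oaa, prob):
        for acetyl, ap in acetyl_choices:
            og, _co2 = oracle_condense(acetyl, oaa)
            if turn == turns:
                results[og] = results.get(og, 0.0) + prob * ap
            else:
                succ = og[1:]  # OG C1 lost in the OG→succinate step
                for nxt in (succ, succ[::-1]):
                    recurse(turn + 1, nxt, prob * ap * 0.5)

    recurse(1, (0, 0, 0, 0), 1.0)
    return results


def engine_og_distribution(acetyl, turns):
    oaa = unlabeled(4)
    og = None
    for _ in range(turns):
        og, oaa = tca_turn(acetyl, oaa)
    return og


def total_variation(d1, d2):
    keys = set(d1) | set(d2)
    return 0.5 * sum(abs(d1.get(k, 0.0) - d2.get(k, 0.0)) for k in keys)


# ---------------------------------------------------------------------------
# Hypothesis strategies
# ---------------------------------------------------------------------------


def pool_distributions(n_carbons, max_support=4):
    vectors = st.lists(
        st.tuples(*[st.integers(0, 1)] * n_carbons),
        min_size=1,
        max_size=max_support,
        unique=True,
    )
    weights = st.lists(
        st.floats(min_value=0.01, max_value=1.0), min_size=max_support, max_size=max_support
    )

    def build(vecs, ws):
        ws = ws[: len(vecs)]
        total = sum(ws)
        return {v: w / total for v, w in zip(vecs, ws)}

    return st.builds(build, vectors, weights)


def assert_is_distribution(dist, n):
    assert all(len(v) == n for v in dist)
    assert all(p >= 0 for p in dist.values())
    assert math.isclose(sum(dist.values()), 1.0, abs_tol=1e-9)


# ---------------------------------------------------------------------------
# Single-step fate maps
# ---------------------------------------------------------------------------


class TestGlycolysisMap:
    def test_c1_glucose(self):
        pyr = glycolysis_map(bernoulli_pool(6, (1,), 1.0))
        assert pyr == {(0, 0, 1): 0.5, (0, 0, 0): 0.5}

    def test_unlabeled(self):
        assert glycolysis_map(unlabeled(6)) == {(0, 0, 0): 1.0}

    def test_c6_glucose_symmetry(self):
        pyr = glycolysis_map(bernoulli_pool(6, (6,), 1.0))
        assert pyr[(0, 0, 1)] == pytest.approx(0.5)

    def test_fully_labeled(self):
        assert glycolysis_map(bernoulli_pool(6, (1, 2, 3, 4, 5, 6), 1.0)) == {
            (1, 1, 1): 1.0
        }


class TestPdhStep:
    def test_c3_pyruvate(self):
        assert pdh_step({(0, 0, 1): 1.0}) == {(0, 1): 1.0}

    def test_c1_lost(self):
        assert pdh_step({(1, 0, 0): 1.0}) == {(0, 0): 1.0}

    def test_fully_labeled(self):
        assert pdh_step({(1, 1, 1): 1.0}) == {(1, 1): 1.0}


class TestTcaTurn:
    def test_first_turn_methyl_labeled_acetyl(self):
        og, _ = tca_turn({(0, 1): 1.0}, unlabeled(4))
        assert og == {(0, 0, 0, 1, 0): 1.0}  # label only at OG C4

    def test_first_turn_doubly_labeled_acetyl(self):
        og, _ = tca_turn({(1, 1): 1.0}, unlabeled(4))
        assert og == {(0, 0, 0, 1, 1): 1.0}  # OG C4 + C5

    def test_second_turn_scrambling(self):
        # after a first turn with methyl-labeled acetyl, a second turn with
        # unlabeled acetyl puts the label at OG C2 or C3 with equal mass
        _, oaa = tca_turn({(0, 1): 1.0}, unlabeled(4))
        og2, _ = tca_turn(unlabeled(2), oaa)
        assert og2 == {
            (0, 1, 0, 0, 0): pytest.approx(0.5),
            (0, 0, 1, 0, 0): pytest.approx(0.5),
        }

    def test_og_c1_lost_on_next_turn(self):
        # put label on OAA C4 only -> OG C1; it must not survive to next OAA
        og, oaa_next = tca_turn(unlabeled(2), {(0, 0, 0, 1): 1.0})
        assert og == {(1, 0, 0, 0, 0): 1.0}
        assert oaa_next == {(0, 0, 0, 0): 1.0}

    @given(
        acetyl=pool_distributions(2),
        oaa=pool_distributions(4),
    )
    @settings(max_examples=50)
    def test_probability_and_label_conservation(self, acetyl, oaa):
        og, oaa_next = tca_turn(acetyl, oaa)
        assert_is_distribution(og, 5)
        assert_is_distribution(oaa_next, 4)
        # labels out (OG) = labels in minus the OAA C1 atom lost as CO2
        co2_in = sum(p * v[0] for v, p in oaa.items())
        expected = expected_label_count(acetyl) + expected_label_count(oaa) - co2_in
        assert expected_label_count(og) == pytest.approx(expected, abs=1e-9)
        # next-turn OAA loses exactly the OG C1 mass
        og_c1 = sum(p * v[0] for v, p in og.items())
        assert expected_label_count(oaa_next) == pytest.approx(
            expected_label_count(og) - og_c1, abs=1e-9
        )

    @given(acetyl=pool_distributions(2), oaa=pool_distributions(4))
    @settings(max_examples=50)
    def test_scrambling_symmetry(self, acetyl, oaa):
        _, oaa_next = tca_turn(acetyl, oaa)
        for vec, p in oaa_next.items():
            assert oaa_next.get(vec[::-1], 0.0) == pytest.approx(p, abs=1e-12)


class TestAminoAcidMaps:
    def test_og_to_glu_identity(self):
        assert og_to_glu({(0, 0, 0, 1, 0): 1.0}, 0.0) == {(0, 0, 0, 1, 0): 1.0}

    def test_og_to_glu_full_dilution(self):
        assert og_to_glu({(0, 0, 0, 1, 1): 1.0}, 1.0) == {(0, 0, 0, 0, 0): 1.0}

    def test_og_to_glu_half_dilution(self):
        glu = og_to_glu({(0, 0, 0, 1, 1): 1.0}, 0.5)
        assert glu == {
            (0, 0, 0, 1, 1): pytest.approx(0.5),
            (0, 0, 0, 0, 0): pytest.approx(0.5),
        }

    def test_glu4_to_gaba2(self):
        assert glu_to_gaba({(0, 0, 0, 1, 0): 1.0}) == {(0, 1, 0, 0): 1.0}

    def test_glu45_to_gaba12(self):
        assert glu_to_gaba({(0, 0, 0, 1, 1): 1.0}) == {(1, 1, 0, 0): 1.0}

    def test_glu1_lost(self):
        assert glu_to_gaba({(1, 0, 0, 0, 0): 1.0}) == {(0, 0, 0, 0): 1.0}

    @pytest.mark.parametrize(
        "oaa_vec", [(0, 1, 1, 0), (1, 1, 0, 0), (0, 0, 0, 0)]
    )
    def test_oaa_to_asp_identity(self, oaa_vec):
        assert oaa_to_asp({oaa_vec: 1.0}) == {oaa_vec: 1.0}


# ---------------------------------------------------------------------------
# Oracle equivalence
# ---------------------------------------------------------------------------


class TestOracleEquivalence:
    @pytest.mark.parametrize("turns", [1, 2, 3])
    @pytest.mark.parametrize("p", [1.0, 0.3])
    def test_glucose_route(self, turns, p):
        acetyl = pdh_step(glycolysis_map(bernoulli_pool(6, (1,), p)))
        engine = engine_og_distribution(acetyl, turns)
        oracle = oracle_og_distribution(
            oracle_acetyl_choices_from_glucose(p), turns
        )
        assert total_variation(engine, oracle) < 1e-9

    @pytest.mark.parametrize("turns", [1, 2, 3])
    @pytest.mark.parametrize("p", [1.0, 0.4])
    def test_acetate_route(self, turns, p):
        acetyl = acetate_to_acetyl(bernoulli_pool(2, (1, 2), p))
        engine = engine_og_distribution(acetyl, turns)
        oracle = oracle_og_distribution(
            oracle_acetyl_choices_from_acetate(p), turns
        )
        assert total_variation(engine, oracle) < 1e-9

    def test_third_turn_singles_include_c1_and_c2(self):
        # later turns must generate the C2/C1-labeled glutamate precursors
        oracle = oracle_og_distribution(oracle_acetyl_choices_from_glucose(0.5), 3)
        singles = {
            tuple(i + 1 for i, b in enumerate(v) if b)
            for v in oracle
            if sum(v) == 1
        }
        assert {(1,), (2,), (3,), (4,)} <= singles


# ---------------------------------------------------------------------------
# Whole simulation
# ---------------------------------------------------------------------------


class TestRunTwoCompartment:
    def test_one_turn_pure_tracers_label_classes(self):
        cfg = SimulationConfig(
            glucose_c1_fraction=1.0,
            acetate_c12_fraction=1.0,
            turns=1,
            cv=0.0,
            n_replicates=2,
            glucose_flux_scale={"CTL": 1.0},
            acetate_flux_scale={"CTL": 1.0},
        )
        iso, _ = run_two_compartment(cfg)
        observed = set(iso.df["pattern"])
        assert observed == {
            "[4-13C]Glu",
            "[4,5-13C]Glu",
            "[4,5-13C]Gln",
            "[2-13C]GABA",
            "[1,2-13C]GABA",
            "[3-13C]Ala",
            "[3-13C]Lac",
        }

    def test_identical_group_scales_zero_expected_change(self):
        cfg = SimulationConfig(
            glucose_flux_scale={"A": 1.0, "B": 1.0},
            acetate_flux_scale={"A": 1.0, "B": 1.0},
            cv=0.0,
            n_replicates=2,
        )
        iso, _ = run_two_compartment(cfg)
        means = iso.group_means().pivot(index="pattern", columns="group")
        np.testing.assert_allclose(
            means[("conc_mM", "A")], means[("conc_mM", "B")], rtol=1e-12
        )

    def test_zero_cv_replicates_identical(self, noiseless_config):
        iso, totals = run_two_compartment(noiseless_config)
        spread = iso.df.groupby(["group", "pattern"])["conc_mM"].agg(["min", "max"])
        np.testing.assert_allclose(spread["min"], spread["max"], rtol=0)
        assert noiseless_config.seed == iso.meta["seed"]

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(seed=7)
        iso1, tot1 = run_two_compartment(cfg)
        iso2, tot2 = run_two_compartment(SimulationConfig(seed=7))
        assert iso1.df.equals(iso2.df)
        assert tot1.df.equals(tot2.df)

    def test_other_class_mass_retained(self):
        # turns=3 acetate route makes >2-label patterns; they must appear
        # under the aggregate class instead of vanishing
        cfg = SimulationConfig(
            glucose_c1_fraction=0.0,
            acetate_c12_fraction=1.0,
            turns=3,
            cv=0.0,
            n_replicates=2,
            glucose_flux_scale={"CTL": 1.0},
            acetate_flux_scale={"CTL": 1.0},
        )
        iso, _ = run_two_compartment(cfg)
        assert (iso.df["pattern"] == "[other-13C]Glu").any()

    def test_parameter_recovery_knockout_scale(self):
        cfg = SimulationConfig(cv=0.1, n_replicates=20, seed=123)
        iso, _ = run_two_compartment(cfg)
        from neurotracer.metrics import percent_change

        pc = percent_change(
            iso.mean("CTL", "[4-13C]Glu"), iso.mean("KO", "[4-13C]Glu")
        )
        assert abs(pc - 30.0) <= 10.0

    def test_cycling_ratio_monotone_in_turns(self):
        from neurotracer.metrics import glucose_cycling_ratio

        values = []
        for turns in (1, 2, 3, 4):
            cfg = SimulationConfig(turns=turns, cv=0.0, n_replicates=2)
            iso, _ = run_two_compartment(cfg)
            values.append(glucose_cycling_ratio(iso, "CTL"))
        assert values[0] == 0.0
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(turns=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_replicates=1)
        with pytest.raises(ValueError):
            SimulationConfig(glucose_c1_fraction=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(glucose_flux_scale={"CTL": 1.0})  # group mismatch


class TestAggregation:
    def test_adjacent_double_is_observable(self):
        classes = aggregate_to_classes("Glu", {(0, 0, 0, 1, 1): 1.0})
        assert classes == {LabelPattern("Glu", (4, 5)): 1.0}

    def test_nonadjacent_double_goes_to_other(self):
        classes = aggregate_to_classes("Glu", {(1, 0, 0, 1, 0): 1.0})
        assert classes == {LabelPattern.other("Glu"): 1.0}

    def test_triple_goes_to_other(self):
        classes = aggregate_to_classes("Glu", {(0, 1, 1, 1, 0): 1.0})
        assert classes == {LabelPattern.other("Glu"): 1.0}

    def test_unlabeled_excluded(self):
        assert aggregate_to_classes("Glu", unlabeled(5)) == {}

    def test_mass_conservation(self):
        dist = mix(
            [({(0, 0, 0, 1, 0): 1.0}, 0.3), ({(1, 0, 1, 1, 0): 1.0}, 0.2),
             (unlabeled(5), 0.5)]
        )
        classes = aggregate_to_classes("Glu", dist)
        assert sum(classes.values()) == pytest.approx(0.5)


class TestSimulatePeaks:
    def _tiny_table(self):
        from neurotracer.core import IsotopomerTable

        return IsotopomerTable.from_records(
            [
                ("CTL", "r1", "[4,5-13C]Glu", 0.0),
                ("CTL", "r1", "[4-13C]Gln", 1.0),
            ]
        )

    def test_zero_concentration_gives_intercept(self):
        iso = self._tiny_table()
        cal = synthetic_calibration(
            metabolites=["Glu", "Gln"], intercept_au=5.0
        )
        peaks = simulate_peaks(iso, cal)
        glu = peaks.df[peaks.df.metabolite == "Glu"]
        np.testing.assert_allclose(glu["area"], 5.0)

    def test_multiplet_classes(self):
        iso = self._tiny_table()
        cal = synthetic_calibration(metabolites=["Glu", "Gln"])
        peaks = simulate_peaks(iso, cal)
        glu = peaks.df[peaks.df.pattern == "[4,5-13C]Glu"]
        assert set(glu["multiplet"]) == {"doublet"}
        gln = peaks.df[peaks.df.pattern == "[4-13C]Gln"]
        assert set(gln["multiplet"]) == {"singlet"}

    def test_missing_calibration_pair(self):
        iso = self._tiny_table()
        cal = synthetic_calibration(metabolites=["Glu"])
        with pytest.raises(KeyError, match="no calibration"):
            simulate_peaks(iso, cal)
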