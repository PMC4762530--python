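"""Top-down quantitation: mass grouping, linkage, standardization, the
state-term ANOVA, fold changes and BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import bh_step_up_brute_force
from tdbu import synthetic, td
from tdbu.types import EffectSpec, ProteoformRecord, StudyDesign


def obs_frame(masses, rts, intensities, **kwargs):
    n = len(masses)
    data = {
        "proteoform_id": [None] * n,
        "neutral_mass_da": masses,
        "rt_min": rts,
        "fraction": [1] * n,
        "state": ["A"] * n,
        "gelfree_rep": [1] * n,
        "lcms_rep": list(range(1, n + 1)),
        "intensity": intensities,
    }
    data.update(kwargs)
    return pd.DataFrame(data)


class TestGroupMasses:
    def test_single_observation(self):
        obs = obs_frame([12000.0], [10.0], [5.0])
        groups = td.group_masses(obs)
        assert len(groups) == 1
        assert groups[0].consensus_mass == pytest.approx(12000.0)

    def test_ppm_tolerance_controls_split(self):
        obs = obs_frame([10000.00, 10000.05], [10.0, 10.0], [2.0, 1.0])
        assert len(td.group_masses(obs, mass_tol_ppm=10.0)) == 1
        assert len(td.group_masses(obs, mass_tol_ppm=1.0)) == 2

    def test_rt_tolerance_controls_split(self):
        obs = obs_frame([10000.0, 10000.0], [10.0, 40.0], [1.0, 1.0])
        assert len(td.group_masses(obs, rt_tol_min=5.0)) == 2
        assert len(td.group_masses(obs, rt_tol_min=50.0)) == 1

    def test_members_within_tolerance_of_consensus(self):
        rng = np.random.default_rng(1)
        mass = 15000.0 * (1 + rng.normal(0, 2e-6, 200))
        obs = obs_frame(mass, rng.normal(30.0, 0.5, 200), rng.uniform(1, 10, 200))
        groups = td.group_masses(obs, mass_tol_ppm=10.0, rt_tol_min=5.0)
        m = obs["neutral_mass_da"].to_numpy()
        r = obs["rt_min"].to_numpy()
        seen = []
        for g in groups:
            idx = g.member_index
            seen.extend(idx)
            assert np.all(np.abs(m[idx] - g.consensus_mass)
                          <= 10e-6 * g.consensus_mass)
            assert np.all(np.abs(r[idx] - g.rt_center) <= 5.0)
        # partition: each observation in exactly one group
        assert sorted(seen) == list(range(200))

    def test_empty_and_invalid(self):
        assert td.group_masses(obs_frame([], [], [])) == []
        with pytest.raises(ValueError):
            td.group_masses(obs_frame([1.0], [1.0], [1.0]), mass_tol_ppm=0)


class TestLinkGroups:
    @staticmethod
    def catalog(masses):
        return [
            ProteoformRecord(f"PF{i}", f"NP_{i}", "G", monoisotopic_mass=m)
            for i, m in enumerate(masses)
        ]

    @pytest.mark.parametrize(
        "offset,expect_linked",
        [(0.0, True), (1.0, True), (2.0, True), (3.0, False)],
    )
    def test_precursor_tolerance(self, offset, expect_linked):
        obs = obs_frame([12000.0 + offset], [10.0], [1.0])
        groups = td.group_masses(obs)
        td.link_groups_to_proteoforms(groups, self.catalog([12000.0]))
        assert (groups[0].proteoform_id is not None) == expect_linked
        if offset == 0.0:
            assert groups[0].mass_error_da == pytest.approx(0.0, abs=1e-9)

    def test_nearest_wins_and_lexicographic_tiebreak(self):
        obs = obs_frame([12001.0], [10.0], [1.0])
        groups = td.group_masses(obs)
        td.link_groups_to_proteoforms(groups, self.catalog([12000.0, 12001.5]))
        assert groups[0].proteoform_id == "PF1"  # 0.5 Da beats 1.0 Da
        # exact tie: equidistant -> lexicographically smaller id
        groups = td.group_masses(obs_frame([12000.75], [10.0], [1.0]))
        td.link_groups_to_proteoforms(groups, self.catalog([12000.0, 12001.5]))
        assert groups[0].proteoform_id == "PF0"

    def test_negative_tolerance_rejected(self):
        groups = td.group_masses(obs_frame([1000.0], [1.0], [1.0]))
        with pytest.raises(ValueError):
            td.link_groups_to_proteoforms(groups, self.catalog([1000.0]), -1.0)


class TestStandardize:
    def test_hand_computed_values(self):
        obs = obs_frame([1e4] * 3, [1.0] * 3, [10.0, 20.0, 30.0],
                        proteoform_id=["P"] * 3)
        out, untestable = td.standardize_within_fraction(obs)
        assert untestable.empty
        assert out["z"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_zero_variance_untestable(self):
        obs = obs_frame([1e4] * 3, [1.0] * 3, [5.0, 5.0, 5.0],
                        proteoform_id=["P"] * 3)
        out, untestable = td.standardize_within_fraction(obs)
        assert out.empty
        assert untestable["reason"].tolist() == ["zero_variance"]

    def test_single_observation_untestable(self):
        obs = obs_frame([1e4], [1.0], [5.0], proteoform_id=["P"])
        out, untestable = td.standardize_within_fraction(obs)
        assert out.empty
        assert untestable["reason"].tolist() == ["too_few_obs"]

    @given(st.lists(st.floats(1.0, 1e6), min_size=3, max_size=30, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_centred_and_unit_scaled(self, values):
        obs = obs_frame([1e4] * len(values), [1.0] * len(values), values,
                        proteoform_id=["P"] * len(values))
        out, _ = td.standardize_within_fraction(obs)
        assert abs(out["z"].mean()) < 1e-10
        assert abs(out["z"].std(ddof=1) - 1.0) < 1e-10

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(10, 1, 25)
        obs = obs_frame([1e4] * 25, [1.0] * 25, vals, proteoform_id=["P"] * 25)
        once, _ = td.standardize_within_fraction(obs)
        again, _ = td.standardize_within_fraction(
            once.assign(intensity=once["z"])
        )
        assert np.allclose(again["z"], once["z"], atol=1e-10)


def standardized_frame(z, states, fractions, gelfree=None):
    return pd.DataFrame({
        "proteoform_id": "P",
        "z": z,
        "state": states,
        "fraction": fractions,
        "gelfree_rep": gelfree if gelfree is not None else [1] * len(z),
    })


class TestHierarchicalAnova:
    def test_no_effect_gives_p_near_one(self):
        sub = standardized_frame([-1, 0, 1, -1, 0, 1],
                                 ["A"] * 3 + ["B"] * 3, [1] * 6)
        p, eff = td.fit_hierarchical_anova(sub)
        assert eff == pytest.approx(0.0, abs=1e-12)
        assert p > 0.99

    def test_single_fraction_equals_t_test(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n1, n2 = rng.integers(3, 10, 2)
            z = np.concatenate([rng.normal(0, 1, n1), rng.normal(0.5, 1, n2)])
            z = (z - z.mean()) / z.std(ddof=1)
            states = ["A"] * n1 + ["B"] * n2
            sub = standardized_frame(z, states, [1] * (n1 + n2))
            p, _ = td.fit_hierarchical_anova(sub)
            p_t = stats.ttest_ind(z[:n1], z[n1:], equal_var=True).pvalue
            assert p == pytest.approx(p_t, abs=1e-10)

    def test_matches_statsmodels_two_way_fit(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        rng = np.random.default_rng(11)
        z = rng.normal(0, 1, 40)
        states = np.where(rng.random(40) < 0.5, "A", "B")
        fractions = rng.integers(1, 4, 40)
        if min((states == "A").sum(), (states == "B").sum()) < 2:
            states[:2] = ["A", "B"]
        sub = standardized_frame(z, states, fractions)
        p, _ = td.fit_hierarchical_anova(sub)
        fit = smf.ols("z ~ C(state) + C(fraction)", data=sub).fit()
        expected = anova_lm(fit, typ=2).loc["C(state)", "PR(>F)"]
        assert p == pytest.approx(expected, rel=1e-8)

    def test_detects_large_injected_effect(self, study2):
        cat = synthetic.generate_catalog(1, {1: 1.0}, seed=21)
        eff = [EffectSpec(cat[0].proteoform_id, log2_fold_change=2.0,
                          intensity_cv=0.1)]
        obs = synthetic.simulate_td_observations(cat, study2, eff,
                                                 p_span=0.0, seed=22)
        std, _ = td.standardize_within_fraction(obs)
        p, _ = td.fit_hierarchical_anova(std)
        assert p < 0.001

    def test_insufficient_replication_rejected(self):
        sub = standardized_frame([0.1, -0.1, 0.2], ["A", "A", "B"], [1, 1, 1])
        with pytest.raises(ValueError):
            td.fit_hierarchical_anova(sub)


class TestLog2FC:
    def test_arithmetic(self):
        assert td.estimate_log2fc([2.0, 4.0], [2.0, 4.0]) == pytest.approx(0.0)
        assert td.estimate_log2fc([1.0, 1.0], [4.0, 4.0]) == pytest.approx(2.0)

    def test_empty_state_is_present_absent(self):
        assert td.estimate_log2fc([], [1.0]) is None


class TestBHFDR:
    def test_all_ones(self):
        q, flags = td.bh_fdr([1.0, 1.0, 1.0])
        assert np.all(q == 1.0)
        assert not flags.any()

    def test_step_up_example(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.060, 0.070, 0.080, 0.090, 0.100]
        _q, flags = td.bh_fdr(p, alpha=0.05)
        assert flags.tolist() == [True, True] + [False] * 8

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_step_up(self, p):
        q, flags = td.bh_fdr(p, alpha=0.05)
        q_ref, flags_ref = bh_step_up_brute_force(p, 0.05)
        assert np.allclose(q, q_ref, atol=1e-12)
        assert np.array_equal(flags, flags_ref)

    def test_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(5)
        p = rng.random(50)
        q, _ = td.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            td.bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            td.bh_fdr([np.nan])


class TestQuantifyAndVolcano:
    def test_recovers_planted_effects(self, study2):
        rng_ids = synthetic.generate_catalog(100, {1: 1.0}, seed=31)
        effects = []
        for i, rec in enumerate(rng_ids):
            lfc = 2.0 * (1 if i % 2 else -1) if i < 20 else 0.0
            effects.append(EffectSpec(rec.proteoform_id, lfc,
                                      missing_rate=0.546, intensity_cv=0.25))
        obs = synthetic.simulate_td_observations(rng_ids, study2, effects, seed=32)
        results, _side = td.quantify_td(obs, states=study2.states)
        truth_de = {e.entity_id for e in effects if e.de_flag}
        flagged = set(results.loc[results["de_flag"], "entity_id"])
        assert len(flagged & truth_de) >= 18
        volcano = td.volcano_table(results)
        assert set(volcano.columns) == {"entity_id", "log2_fold_change",
                                        "neg_log10_q", "de_flag"}
        q = results.set_index("entity_id")["q_value"]
        assert q[volcano["entity_id"]].is_monotonic_increasing

    def test_present_absent_reported_not_tested(self, study2):
        cat = synthetic.generate_catalog(2, {1: 1.0}, seed=33)
        eff = [EffectSpec(r.proteoform_id) for r in cat]
        obs = synthetic.simulate_td_observations(cat, study2, eff,
                                                 p_span=0.0, seed=34)
        pid = cat[0].proteoform_id
        obs = obs[~((obs["proteoform_id"] == pid)
                    & (obs["state"] == study2.states[1]))]
        results, side = td.quantify_td(obs, states=study2.states)
        assert pid not in set(results["entity_id"])
        row = side[side["entity_id"] == pid]
        assert row["reason"].tolist() == ["present_absent"]
        assert row["present_in"].tolist() == [study2.states[0]]

    def test_pipeline_determinism_on_fixed_table(self, study2):
        cat = synthetic.generate_catalog(20, seed=35)
        eff = [EffectSpec(r.proteoform_id, missing_rate=0.4) for r in cat]
        obs = synthetic.simulate_td_observations(cat, study2, eff, seed=36)
        r1, s1 = td.quantify_td(obs, states=study2.states)
        r2, s2 = td.quantify_td(obs, states=study2.states)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(s1, s2)
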