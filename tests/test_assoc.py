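import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lambhap import assoc, synthetic
from lambhap.assoc import (ModelSpec, Significance, classify_significance,
                           code_presence, derived_growth_effect,
                           derived_meat_effect, fit_adjusted_model,
                           fit_diplotype_model, fit_presence_model,
                           letter_display, select_structure_term)
from lambhap.genodata import Diplotype, Haplotype

A13 = Haplotype("A1", "A3")
A1C3 = Haplotype("A1", "C3")
B13 = Haplotype("B1", "A3")


def D(text):
    return Diplotype.parse(text)


class TestPresenceCoding:
    @pytest.mark.parametrize("dip,hap,expected", [
        ("A1-A3/A1-A3", A13, 1),      # homozygous carrier
        ("A1-A3/B1-A3", Haplotype("B1", "C3"), 0),
        ("A1-A3/B1-A3", A13, 1),      # heterozygous carrier
    ])
    def test_coding(self, dip, hap, expected):
        assert code_presence(D(dip), hap) == expected

    def test_presence_over_common_diplotype_groups(self):
        groups = ["A1-A3/A1-A3", "A1-A3/A1-C3", "A1-A3/B1-A3",
                  "B1-A3/B1-A3", "B1-A3/B1-C3"]
        present = [g for g in groups if code_presence(D(g), A13)]
        assert present == ["A1-A3/A1-A3", "A1-A3/A1-C3", "A1-A3/B1-A3"]

    def test_n_present_matches_diplotype_counts(self, truth_dataset):
        sub = truth_dataset[truth_dataset["growth_rate"].notna()
                            & truth_dataset["diplotype"].notna()]
        r = fit_presence_model(truth_dataset, "growth_rate", A13)
        carriers = sum(d.contains(A13) for d in sub["diplotype"])
        assert r.n_present == carriers
        assert r.n_absent + r.n_present == len(sub)


class TestSignificanceClassification:
    @pytest.mark.parametrize("p,expected", [
        (0.031, Significance.SIGNIFICANT),
        (0.062, Significance.TREND),
        (0.05, Significance.TREND),        # boundary: strict p < alpha
        (0.5, Significance.NS),
        (0.0, Significance.SIGNIFICANT),
    ])
    def test_thresholds(self, p, expected):
        assert classify_significance(p) is expected

    @pytest.mark.parametrize("p", [-0.1, 1.5])
    def test_domain(self, p):
        with pytest.raises(ValueError):
            classify_significance(p)


class TestDerivedEffects:
    def test_growth_effect_from_marginal_means(self):
        diff, cumulative = derived_growth_effect(275.9, 268.2, 100)
        assert diff == pytest.approx(7.7)
        assert cumulative == pytest.approx(770.0)

    def test_growth_effect_null_and_hand_values(self):
        assert derived_growth_effect(280.0, 280.0, 100) == (0.0, 0.0)
        diff, cum = derived_growth_effect(280.0, 268.5, 90)
        assert (diff, cum) == (pytest.approx(11.5), pytest.approx(1035.0))

    def test_meat_effect_grams(self):
        assert derived_meat_effect(0.71, 18) == 128
        assert derived_meat_effect(0.45, 18) == 81
        assert derived_meat_effect(0.0, 18) == 0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            derived_growth_effect(1, 2, 0)
        with pytest.raises(ValueError):
            derived_meat_effect(0.5, 0)


class TestPresenceModel:
    def test_planted_effect_recovered_within_two_se(self):
        cfg = synthetic.SimConfig(seed=1).with_effects(
            "growth_rate", {"A1-A3": -8.0})
        cohort = synthetic.generate_cohort(cfg)
        truth = {a: t.diplotype for a, t in cohort.truth.items()}
        df = assoc.build_dataset(cohort.records, truth)
        r = fit_presence_model(df, "growth_rate", A13)
        assert r.status == "ok"
        assert abs(r.effect - (-8.0)) <= 2 * r.effect_se
        # estimated marginal means are consistent with the effect
        assert r.emm_present - r.emm_absent == pytest.approx(r.effect)

    def test_effect_estimate_tightens_with_sample_size(self):
        ses = []
        for n_per in (20, 80):
            cfg = synthetic.SimConfig(seed=4, progeny_per_sire=n_per)
            cfg = cfg.with_effects("growth_rate", {"A1-A3": -8.0})
            cohort = synthetic.generate_cohort(cfg)
            truth = {a: t.diplotype for a, t in cohort.truth.items()}
            df = assoc.build_dataset(cohort.records, truth)
            ses.append(fit_presence_model(df, "growth_rate", A13).effect_se)
        assert ses[1] < ses[0]

    def test_constant_trait_degenerates_gracefully(self, truth_dataset):
        df = truth_dataset.copy()
        df["growth_rate"] = 250.0
        r = fit_presence_model(df, "growth_rate", A13)
        assert r.status == "zero variance"
        assert r.emm_absent == r.emm_present == 250.0
        assert r.p_value == 1.0

    def test_absent_group_empty_not_estimable(self, truth_dataset):
        df = truth_dataset.copy()
        everywhere = Haplotype("Z1", "Z3")
        df["diplotype"] = [Diplotype.of(everywhere, everywhere)] * len(df)
        r = fit_presence_model(df, "growth_rate", everywhere)
        assert r.status == "not estimable"
        assert r.p_value is None

    def test_carcass_trait_uses_males_only(self, truth_dataset):
        r = fit_presence_model(truth_dataset, "leg_yield", A13)
        males = truth_dataset[
            (truth_dataset["gender"] == "male")
            & truth_dataset["leg_yield"].notna()
            & truth_dataset["diplotype"].notna()
            & truth_dataset["age_slaughter"].notna()]
        assert r.n_absent + r.n_present == len(males)


class TestAdjustedModel:
    def test_empty_cofit_reduces_to_single_model(self, truth_dataset):
        single = fit_presence_model(truth_dataset, "growth_rate", A13)
        adjusted = fit_adjusted_model(truth_dataset, "growth_rate", A13, [])
        assert adjusted == single

    def test_correlated_haplotypes_deconfounded(self):
        # A1-A3 and B1-A3 presence are negatively correlated; planting an
        # effect on A1-A3 alone induces a ghost signal on B1-A3 that the
        # co-fitted model should absorb
        cfg = synthetic.SimConfig(seed=11).with_effects(
            "growth_rate", {"A1-A3": -20.0})
        cohort = synthetic.generate_cohort(cfg)
        truth = {a: t.diplotype for a, t in cohort.truth.items()}
        df = assoc.build_dataset(cohort.records, truth)
        adj_true = fit_adjusted_model(df, "growth_rate", A13, [B13])
        adj_ghost = fit_adjusted_model(df, "growth_rate", B13, [A13])
        assert adj_true.effect < 0
        assert adj_true.p_value < 0.05
        assert abs(adj_true.effect - (-20.0)) <= 2.5 * adj_true.effect_se
        assert adj_ghost.p_value > 0.05
        assert adj_true.others == (B13,)
        assert adj_true.model_tag == "adjusted(B1–A3)"

    def test_screen_uses_include_p(self, truth_dataset):
        singles = [
            fit_presence_model(truth_dataset, "growth_rate", h)
            for h in (A13, B13, A1C3)]
        out = assoc.run_adjusted_series(truth_dataset, singles,
                                        ModelSpec(include_p=0.9999))
        flagged = {r.haplotype for r in out if r.trait == "growth_rate"}
        assert flagged == {A13, B13, A1C3}
        for r in out:
            assert all(o.display() != r.haplotype.display()
                       for o in r.others)


class TestDiplotypeModel:
    def test_common_diplotypes_pass_frequency_filter(self, truth_dataset):
        r = fit_diplotype_model(truth_dataset, "leg_yield")
        assert r.status == "ok"
        names = {d.display() for d in r.diplotypes}
        assert {"A1–A3/A1–A3", "A1–A3/B1–A3", "B1–A3/B1–A3"} <= names
        sub = truth_dataset[(truth_dataset["gender"] == "male")
                            & truth_dataset["leg_yield"].notna()
                            & truth_dataset["diplotype"].notna()
                            & truth_dataset["age_slaughter"].notna()]
        for d, n in zip(r.diplotypes, r.n):
            count = (sub["diplotype"] == d).sum()
            assert n == count
            assert count / len(sub) > 0.05

    def test_shifted_group_shares_no_letter(self, truth_dataset):
        df = truth_dataset.copy()
        target = D("A1-A3/A1-A3")
        mask = df["diplotype"].apply(lambda d: d == target)
        df.loc[mask, "leg_yield"] += 3 * 1.3   # 3 residual SDs
        r = fit_diplotype_model(df, "leg_yield")
        i = r.diplotypes.index(target)
        for j in range(len(r.n)):
            if j != i:
                assert set(r.letters[i]).isdisjoint(r.letters[j])
        assert r.overall_p < 0.05

    def test_null_groups_all_share_a_letter(self, truth_dataset):
        r = fit_diplotype_model(truth_dataset, "leg_yield")
        assert all(set(a) & set(b) for a, b in
                   itertools.combinations(r.letters, 2))

    def test_letters_reconstruct_pairwise_matrix(self, truth_dataset):
        df = truth_dataset.copy()
        target = D("A1-A3/A1-A3")
        df.loc[df["diplotype"].apply(lambda d: d == target),
               "leg_yield"] += 2.0
        r = fit_diplotype_model(df, "leg_yield", ModelSpec())
        for i, j in itertools.combinations(range(len(r.n)), 2):
            p = r.pairwise_p.iloc[i, j]
            share = bool(set(r.letters[i]) & set(r.letters[j]))
            assert share == (p >= 0.05)

    def test_bonferroni_caps_at_one(self, truth_dataset):
        r = fit_diplotype_model(truth_dataset, "leg_yield")
        vals = r.pairwise_p.to_numpy()
        finite = vals[~np.isnan(vals)]
        assert ((0 <= finite) & (finite <= 1)).all()

    def test_too_few_groups_is_skipped(self, truth_dataset):
        df = truth_dataset.copy()
        df["diplotype"] = [D("A1-A3/A1-A3")] * len(df)
        r = fit_diplotype_model(df, "growth_rate")
        assert r.status != "ok"
        assert r.overall_p is None


class TestLetterDisplay:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(2, 7), st.data())
    def test_round_trip_with_any_significance_pattern(self, k, data):
        pairs = list(itertools.combinations(range(k), 2))
        sig = {p for p in pairs if data.draw(st.booleans())}
        letters = letter_display(k, sig)
        assert all(letters)
        for i, j in pairs:
            share = bool(set(letters[i]) & set(letters[j]))
            assert share == ((i, j) not in sig)


class TestStructureSelection:
    def test_planted_birth_rank_effect_selected(self):
        import dataclasses
        traits = synthetic._traits()
        traits["growth_rate"] = dataclasses.replace(
            traits["growth_rate"], rank_effects=(50.0, 0.0, -50.0))
        traits["birth_weight"] = dataclasses.replace(
            traits["birth_weight"], rank_effects=(0.0, 0.0, 0.0))
        cohort = synthetic.generate_cohort(
            synthetic.SimConfig(seed=7, traits=traits))
        truth = {a: t.diplotype for a, t in cohort.truth.items()}
        df = assoc.build_dataset(cohort.records, truth)
        sel = select_structure_term(df, "growth_rate")
        assert sel.chosen == "birth_rank"
        assert sel.f_values["birth_rank"] > sel.f_values["birth_weight"]

    def test_null_trait_still_selects_deterministically(self, truth_dataset):
        rng = np.random.default_rng(0)
        df = truth_dataset.copy()
        df["growth_rate"] = rng.normal(270, 50, len(df))
        a = select_structure_term(df, "growth_rate")
        b = select_structure_term(df, "growth_rate")
        assert a.chosen == b.chosen is not None

    def test_exact_tie_follows_fixed_priority(self, truth_dataset):
        # make birth weight a numeric recode of a two-level birth rank so
        # both candidates span the identical one-column model space
        df = truth_dataset.copy()
        df = df[df["birth_rank"] != "triplet"].copy()
        df["birth_weight"] = (df["birth_rank"] == "twin").astype(float)
        sel = select_structure_term(df, "growth_rate")
        assert sel.f_values["birth_rank"] == pytest.approx(
            sel.f_values["birth_weight"])
        assert sel.chosen == "birth_rank"
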