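import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famprs import (
    ParameterError,
    RandomEffectStructure,
    SimulationConfig,
    auc,
    kinship_from_pedigree,
    nri_idi,
    optimism_bootstrap,
    quintile_or_test,
    simulate_cohort,
    trend_test,
    variance_explained,
)
from famprs.prs import PRSVector, assign_quintiles

from conftest import simulate_family_outcome


def pair_counting_auc(pred, y):
    wins = ties = 0
    cases = pred[y == 1]
    controls = pred[y == 0]
    for c in cases:
        for d in controls:
            if c > d:
                wins += 1
            elif c == d:
                ties += 1
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


class TestAUC:
    def test_perfect_and_constant(self):
        y = np.array([0, 0, 1, 1])
        assert auc(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0
        assert auc(np.full(4, 0.5), y) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            auc(np.array([0.1, 0.2]), np.array([1, 1]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 50)
        y = np.zeros(n)
        y[: rng.integers(1, n)] = 1
        rng.shuffle(y)
        pred = np.round(rng.random(n), 2)  # coarse grid to exercise ties
        assert auc(pred, y) == pytest.approx(pair_counting_auc(pred, y), abs=1e-12)


class TestNRIIDI:
    def test_identity_is_zero(self):
        y = np.array([1, 1, 0, 0])
        p = np.array([0.7, 0.6, 0.2, 0.3])
        rep = nri_idi(p, p, y, B=0)
        assert rep.nri == 0.0 and rep.idi == 0.0

    def test_enumerated_nri(self):
        """4 events: 3 up, 1 down; 3 nonevents: 2 down, 1 up -> 0.5 + 1/3."""
        y = np.array([1, 1, 1, 1, 0, 0, 0])
        p_old = np.full(7, 0.5)
        p_new = np.array([0.6, 0.6, 0.6, 0.4, 0.4, 0.4, 0.6])
        rep = nri_idi(p_old, p_new, y, B=0)
        assert rep.nri == pytest.approx(0.5 + 1 / 3)
        assert (rep.event_up, rep.event_down) == (0.75, 0.25)

    def test_enumerated_idi(self):
        """Events: mean risk moves 0.5->0.6; nonevents 0.35->0.30 -> IDI 0.15."""
        y = np.array([1, 1, 0, 0])
        p_old = np.array([0.45, 0.55, 0.30, 0.40])
        p_new = np.array([0.55, 0.65, 0.25, 0.35])
        rep = nri_idi(p_old, p_new, y, B=0)
        assert rep.idi == pytest.approx(0.10 + 0.05)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 30)
        y = np.zeros(n)
        y[: rng.integers(1, n)] = 1
        rng.shuffle(y)
        p_old = np.round(rng.random(n), 1)
        p_new = np.round(rng.random(n), 1)
        rep = nri_idi(p_old, p_new, y, B=0)
        ev, ne = y == 1, y == 0
        nri = ((p_new[ev] > p_old[ev]).mean() - (p_new[ev] < p_old[ev]).mean()) + (
            (p_new[ne] < p_old[ne]).mean() - (p_new[ne] > p_old[ne]).mean()
        )
        idi = (p_new[ev].mean() - p_old[ev].mean()) - (p_new[ne].mean() - p_old[ne].mean())
        assert rep.nri == pytest.approx(nri, abs=1e-12)
        assert rep.idi == pytest.approx(idi, abs=1e-12)
        assert -2.0 <= rep.nri <= 2.0 and -1.0 <= rep.idi <= 1.0

    def test_bootstrap_ci_and_p(self):
        rng = np.random.default_rng(0)
        y = (rng.random(200) < 0.3).astype(int)
        p_old = np.clip(rng.random(200), 0, 1)
        p_new = np.clip(p_old + 0.2 * (y - 0.3) + rng.normal(0, 0.05, 200), 0, 1)
        rep = nri_idi(p_old, p_new, y, B=300, seed=1)
        assert rep.nri_ci[0] < rep.nri < rep.nri_ci[1]
        assert rep.idi > 0 and rep.idi_p < 0.05

    def test_risks_outside_unit_interval_rejected(self):
        with pytest.raises(ParameterError):
            nri_idi(np.array([-0.1, 0.5]), np.array([0.2, 0.3]), np.array([0, 1]))


@pytest.fixture(scope="module")
def family_setup():
    cfg = SimulationConfig(n_families=45, n_snps=5, seed=23, missing_rate=0.0)
    co = simulate_cohort(cfg)
    kin = kinship_from_pedigree(co.pedigree)
    a = 2.0 * kin.matrix
    st_ = RandomEffectStructure(a, family_ids=co.pedigree.family_ids)
    return co, a, st_


class TestTrend:
    def test_per_sd_identity(self, family_setup):
        co, _, st_ = family_setup
        sex = co.phenotypes["sex"].to_numpy()
        age = co.phenotypes["age"].to_numpy(float)
        prs = co.true_score + 0.1 * np.arange(co.n_individuals)  # arbitrary score
        unit = trend_test(prs, co.obesity, sex, age, st_)
        per_sd = trend_test(prs, co.obesity, sex, age, st_, per_sd=True)
        sd = prs.std(ddof=1)
        assert per_sd.odds_ratio == pytest.approx(unit.odds_ratio**sd, rel=1e-9)

    def test_null_permutation_coverage(self, family_setup):
        """Permuting the score severs its link with obesity: the 95% CI should
        cover OR = 1 in roughly 95% of replicates."""
        co, a, st_ = family_setup
        sex = co.phenotypes["sex"].to_numpy()
        age = co.phenotypes["age"].to_numpy(float)
        rng = np.random.default_rng(77)
        base_prs = co.bmi + rng.normal(0, 3, co.n_individuals)
        covered = 0
        n_rep = 300
        for _ in range(n_rep):
            prs = rng.permutation(base_prs)
            res = trend_test(prs, co.obesity, sex, age, st_)
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert 0.91 <= covered / n_rep <= 0.985

    def test_positive_effect_detected(self):
        cfg = SimulationConfig(n_families=500, n_snps=10, h2_score=0.2, seed=41, missing_rate=0.0)
        co = simulate_cohort(cfg)
        assert co.n_individuals > 1800
        kin = kinship_from_pedigree(co.pedigree)
        st_ = RandomEffectStructure(2 * kin.matrix, family_ids=co.pedigree.family_ids)
        res = trend_test(
            co.true_score, co.obesity,
            co.phenotypes["sex"].to_numpy(), co.phenotypes["age"].to_numpy(float), st_,
        )
        assert res.odds_ratio > 1.0 and res.ci_low > 1.0


class TestQuintileOR:
    def test_reference_is_one_and_null_is_flat(self):
        cfg = SimulationConfig(n_families=1300, n_snps=2, h2_score=0.0, seed=57, missing_rate=0.0)
        co = simulate_cohort(cfg, ascertain=False)
        assert co.n_individuals >= 4900
        kin = kinship_from_pedigree(co.pedigree)
        st_ = RandomEffectStructure(2 * kin.matrix, family_ids=co.pedigree.family_ids)
        rng = np.random.default_rng(3)
        quint = assign_quintiles(PRSVector(values=rng.normal(size=co.n_individuals))).quintile
        res = quintile_or_test(
            quint, co.obesity,
            co.phenotypes["sex"].to_numpy(), co.phenotypes["age"].to_numpy(float), st_,
        )
        assert res[0].quintile == "Q1" and res[0].odds_ratio == 1.0
        for r in res[1:]:
            assert abs(np.log(r.odds_ratio)) < 0.5
            assert r.ci_low <= 1.0 <= r.ci_high

    def test_degenerate_quintile_flagged(self):
        from conftest import make_unrelated_cohort

        co = make_unrelated_cohort(np.full(100, 25.0), seed=8)
        score = np.arange(100.0)
        quint = assign_quintiles(PRSVector(values=score)).quintile
        y = (quint == "Q5").astype(int)  # only Q5 members obese
        st_ = RandomEffectStructure.identity(100)
        rng = np.random.default_rng(0)
        res = quintile_or_test(quint, y, rng.integers(1, 3, 100), rng.uniform(20, 60, 100), st_)
        q5 = [r for r in res if r.quintile == "Q5"][0]
        assert not q5.estimable

    def test_requires_both_classes(self):
        quint = np.array(["Q1", "Q2", "Q3", "Q4", "Q5"] * 4)
        with pytest.raises(ParameterError):
            quintile_or_test(
                quint, np.ones(20), np.ones(20), np.arange(20.0),
                RandomEffectStructure.identity(20),
            )


class TestOptimismBootstrap:
    def test_b_zero_returns_apparent(self, family_setup):
        co, _, st_ = family_setup
        x = np.column_stack([co.covariate_matrix(), co.true_score])
        rep = optimism_bootstrap(co.obesity.astype(float), x, st_, B=0, seed=1)
        assert rep.optimism == 0.0
        assert rep.auc_adj == rep.apparent

    def test_fixed_seed_reproducible(self, family_setup):
        co, _, st_ = family_setup
        x = np.column_stack([co.covariate_matrix(), co.true_score])
        r1 = optimism_bootstrap(co.obesity.astype(float), x, st_, B=25, seed=5)
        r2 = optimism_bootstrap(co.obesity.astype(float), x, st_, B=25, seed=5)
        assert r1 == r2

    def test_null_predictors_corrected_to_half(self):
        """Pure-noise predictors: apparent AUC exceeds the corrected one and
        AUC_adj lands near 0.5."""
        rng = np.random.default_rng(9)
        n = 400
        y = np.zeros(n)
        y[:120] = 1.0
        rng.shuffle(y)
        x = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        rep = optimism_bootstrap(y, x, RandomEffectStructure.identity(n), B=200, seed=2)
        assert rep.apparent > rep.auc_adj
        assert abs(rep.auc_adj - 0.5) < 0.03

    def test_optimism_nonnegative_in_expectation(self):
        rng = np.random.default_rng(31)
        opts = []
        for _ in range(25):
            n = 150
            y = np.zeros(n)
            y[:45] = 1.0
            rng.shuffle(y)
            x = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            rep = optimism_bootstrap(
                y, x, RandomEffectStructure.identity(n), B=40,
                seed=int(rng.integers(2**31)),
            )
            opts.append(rep.optimism)
        assert np.mean(opts) > -0.005

    def test_added_score_increases_corrected_auc(self):
        """When the simulated score effect is positive, the model with the
        score beats covariates-only on corrected AUC in most replicate
        cohorts (sign test)."""
        wins = 0
        n_rep = 15
        for rep_i in range(n_rep):
            cfg = SimulationConfig(n_families=40, n_snps=5, h2_score=0.25,
                                   seed=900 + rep_i, missing_rate=0.0)
            co = simulate_cohort(cfg)
            kin = kinship_from_pedigree(co.pedigree)
            st_ = RandomEffectStructure(2 * kin.matrix, family_ids=co.pedigree.family_ids)
            base = co.covariate_matrix()
            full = np.column_stack([base, co.true_score])
            rep = optimism_bootstrap(
                co.obesity.astype(float), full, st_, B=30, seed=5000 + rep_i, x_base=base,
            )
            wins += rep.delta_adj > 0
        assert wins >= 12  # one-sided sign test, p < 0.02 under a fair coin


class TestVarianceExplained:
    def test_unrelated_score_explains_nothing(self, family_setup):
        co, _, st_ = family_setup
        rng = np.random.default_rng(2)
        noise_prs = rng.normal(size=co.n_individuals)
        ve = variance_explained(
            co.bmi, noise_prs,
            co.phenotypes["sex"].to_numpy(), co.phenotypes["age"].to_numpy(float), st_,
        )
        assert ve.r2 < 0.02
        assert ve.r2_partial < 0.02

    def test_true_score_explains_its_share(self):
        cfg = SimulationConfig(n_families=700, n_snps=20, h2_score=0.15, seed=13, missing_rate=0.0)
        co = simulate_cohort(cfg, ascertain=False)
        kin = kinship_from_pedigree(co.pedigree)
        st_ = RandomEffectStructure(2 * kin.matrix, family_ids=co.pedigree.family_ids)
        ve = variance_explained(
            co.bmi, co.true_score,
            co.phenotypes["sex"].to_numpy(), co.phenotypes["age"].to_numpy(float), st_,
        )
        assert ve.r2 == pytest.approx(0.15, abs=0.03)
        assert ve.p < 1e-10
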