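import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reachfield.selectivity import (
    amplitude_selectivity_flags,
    anova2_interaction,
    derive_direction_factor,
    directionwise_amplitude_tests,
    epoch_windows,
    is_task_related,
    population_proportion_test,
    screen_neuron,
    screen_population,
    selectivity_table,
    shuffle_null_proportion,
)
from reachfield.synthetic_data import EPOCHS, UNTUNED, rate_column, simulate_session


def balanced_anova_oracle(y, a, b):
    """Brute-force sums-of-squares decomposition for a balanced two-way
    design (type I == II == III when balanced)."""
    y, a, b = np.asarray(y, float), np.asarray(a), np.asarray(b)
    a_levels, b_levels = np.unique(a), np.unique(b)
    grand = y.mean()
    ss_a = sum(
        (y[a == ai].mean() - grand) ** 2 * (a == ai).sum() for ai in a_levels
    )
    ss_b = sum(
        (y[b == bi].mean() - grand) ** 2 * (b == bi).sum() for bi in b_levels
    )
    ss_cells = 0.0
    ss_err = 0.0
    for ai in a_levels:
        for bi in b_levels:
            cell = y[(a == ai) & (b == bi)]
            ss_cells += len(cell) * (cell.mean() - grand) ** 2
            ss_err += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    df_a, df_b = len(a_levels) - 1, len(b_levels) - 1
    df_ab = df_a * df_b
    df_err = len(y) - len(a_levels) * len(b_levels)
    mse = ss_err / df_err
    return {
        "direction": ss_a / df_a / mse,
        "amplitude": ss_b / df_b / mse,
        "interaction": ss_ab / df_ab / mse,
    }


class TestEpochWindows:
    def test_windows(self):
        w = epoch_windows()
        assert w["C"] == ("cue onset", 0, 500)
        assert w["EM"] == ("cue offset", 200, 700)
        assert w["LM"] == ("go signal", -700, -200)
        assert w["RT/MT"] == ("go signal", 0, 500)
        assert w["baseline"] == ("cue onset", -500, 0)

    def test_all_windows_500ms(self):
        for _, start, end in epoch_windows().values():
            assert end - start == 500


class TestIsTaskRelated:
    def test_null_neuron_not_related(self, task1_config, make_neuron):
        trials = simulate_session(
            task1_config, [make_neuron(model_id=UNTUNED, baseline=5.0)], 40, seed=1
        )
        assert not is_task_related(trials).task_related

    def test_strong_epoch_gain_detected(self, task1_config, make_neuron):
        trials = simulate_session(
            task1_config, [make_neuron(model_id=1, params=[0.0], baseline=5.0, gain=20.0)],
            40, seed=0,
        )
        res = is_task_related(trials)
        assert res.task_related
        assert min(res.p_values.values()) < 0.05 / 4

    def test_rate_floor_blocks_low_rates(self, task1_config, make_neuron):
        # clear modulation but every epoch mean below 1 Hz -> not task-related
        trials = simulate_session(
            task1_config, [make_neuron(model_id=UNTUNED, baseline=0.4)], 60, seed=1
        )
        # impose a deterministic sub-1Hz epoch shift
        trials[rate_column("EM")] = 0.9
        trials[rate_column("baseline")] = 0.4
        res = is_task_related(trials)
        assert not res.rate_floor_ok
        assert not res.task_related
        assert res.p_values["EM"] < 0.05 / 4  # significant but floored out

    def test_constant_rates_degenerate(self, task1_config, make_neuron):
        trials = simulate_session(
            task1_config, [make_neuron(model_id=UNTUNED, baseline=0.0)], 10, seed=0
        )
        res = is_task_related(trials)
        assert res.degenerate and not res.task_related


class TestAnova:
    def test_hand_worked_2x2(self):
        # 2x2, 2 trials/cell; worked through the SS decomposition by hand
        y = np.array([1.0, 2.0, 4.0, 5.0, 2.0, 3.0, 8.0, 9.0])
        a = np.array(["d0", "d0", "d0", "d0", "d1", "d1", "d1", "d1"])
        b = np.array(["s", "s", "l", "l", "s", "s", "l", "l"])
        oracle = balanced_anova_oracle(y, a, b)
        res = anova2_interaction(y, a, b)
        for eff in ("direction", "amplitude", "interaction"):
            assert res[eff]["F"] == pytest.approx(oracle[eff], rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_on_random_balanced_designs(self, seed):
        rng = np.random.default_rng(seed)
        n_a = rng.integers(2, 5)
        n_b = rng.integers(2, 4)
        n_rep = rng.integers(2, 6)
        a = np.repeat(np.arange(n_a), n_b * n_rep)
        b = np.tile(np.repeat(np.arange(n_b), n_rep), n_a)
        y = rng.normal(size=n_a * n_b * n_rep) + 0.3 * a + 0.1 * b
        oracle = balanced_anova_oracle(y, a, b)
        res = anova2_interaction(y, a, b)
        for eff in ("direction", "amplitude", "interaction"):
            assert res[eff]["F"] == pytest.approx(oracle[eff], rel=1e-9)

    def test_matches_statsmodels_type2_unbalanced(self):
        # second, independent route on a mildly unbalanced design
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        rows = []
        for ai in range(3):
            for bi in range(2):
                for _ in range(rng.integers(3, 7)):
                    rows.append((ai, bi, rng.normal() + 0.5 * ai - 0.2 * bi * ai))
        df = pd.DataFrame(rows, columns=["a", "b", "y"])
        fit = smf.ols("y ~ C(a) * C(b)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        res = anova2_interaction(df["y"], df["a"], df["b"])
        assert res["direction"]["F"] == pytest.approx(table.loc["C(a)", "F"], rel=1e-8)
        assert res["amplitude"]["F"] == pytest.approx(table.loc["C(b)", "F"], rel=1e-8)
        assert res["interaction"]["F"] == pytest.approx(table.loc["C(a):C(b)", "F"], rel=1e-8)

    def test_pure_amplitude_effect_noiseless(self):
        a = np.repeat([0, 90, 180, 270], 4)
        b = np.tile([1.0, 1.0, 2.0, 2.0], 4)
        y = 3.0 * b
        res = anova2_interaction(y, a, b)
        assert res["amplitude"]["p"] == 0.0
        assert res["direction"]["p"] == 1.0
        assert res["interaction"]["p"] == 1.0

    def test_empty_cell_named(self):
        with pytest.raises(ValueError, match="empty design cell"):
            anova2_interaction([1, 2, 3], ["a", "a", "b"], [1, 2, 1])

    def test_needs_replication(self):
        with pytest.raises(ValueError, match="residual"):
            anova2_interaction([1, 2, 3, 4], ["a", "a", "b", "b"], [1, 2, 1, 2])


class TestFlags:
    def _anova_stub(self, p=0.9):
        return {
            e: {eff: {"F": 1.0, "p": p} for eff in ("direction", "amplitude", "interaction")}
            for e in EPOCHS
        }

    def test_all_high_p_no_flags(self):
        flags = amplitude_selectivity_flags(self._anova_stub(0.9))
        assert not flags["any_epoch"] and not flags["planning"]

    def test_single_interaction_hit(self):
        stub = self._anova_stub(0.9)
        stub["EM"]["interaction"]["p"] = 0.001
        flags = amplitude_selectivity_flags(stub)
        assert flags["any_epoch"]  # 0.001 < 0.05/8

    def test_bonferroni_strictness(self):
        stub = self._anova_stub(0.9)
        for e in EPOCHS:
            stub[e]["amplitude"]["p"] = 0.008
        flags = amplitude_selectivity_flags(stub)
        assert not flags["any_epoch"]  # 0.008 > 0.00625
        assert flags["planning"]  # 0.008 < 0.0125

    def test_missing_epoch_rejected(self):
        stub = self._anova_stub()
        del stub["LM"]
        with pytest.raises(ValueError, match="missing epochs"):
            amplitude_selectivity_flags(stub)


def _amplitude_effect_table(n_per_target=40, effect_hz=10.0, direction=90.0, seed=0):
    """One neuron, task-1 layout, Poisson rates, amplitude effect confined to
    one direction's large-amplitude targets (built independently of the
    package's simulator)."""
    rng = np.random.default_rng(seed)
    rows = []
    trial = 0
    for d in (0.0, 90.0, 180.0, 270.0):
        for amp in (2.5, 7.0):
            mean = 10.0 + (effect_hz if (d == direction and amp == 7.0) else 0.0)
            for _ in range(n_per_target):
                row = {
                    "neuron_id": 0,
                    "trial_id": trial,
                    "target_index": 0,
                    "direction_deg": d,
                    "amplitude_cm": amp,
                    "rate_baseline_hz": rng.poisson(10.0 * 0.5) / 0.5,
                }
                for e in EPOCHS:
                    row[rate_column(e)] = rng.poisson(mean * 0.5) / 0.5
                rows.append(row)
                trial += 1
    return pd.DataFrame(rows)


class TestDirectionwise:
    def test_localizes_effect_direction(self):
        trials = _amplitude_effect_table(n_per_target=40, effect_hz=10.0, direction=90.0)
        res = directionwise_amplitude_tests(trials, "EM")
        assert res["p_by_direction"][90.0] < 0.05
        assert res["best_direction"] == 90.0

    def test_null_calibration(self):
        rejections = 0
        n_sims = 400
        for seed in range(n_sims):
            trials = _amplitude_effect_table(n_per_target=10, effect_hz=0.0, seed=seed)
            res = directionwise_amplitude_tests(trials, "C")
            rejections += res["p_by_direction"][0.0] < 0.05
        # 99% binomial band around 0.05 for 400 sims
        assert 0.025 <= rejections / n_sims <= 0.082

    def test_degenerate_equal_means(self):
        trials = _amplitude_effect_table(n_per_target=5, effect_hz=0.0)
        for e in EPOCHS:
            trials[rate_column(e)] = 4.0
        res = directionwise_amplitude_tests(trials, "EM")
        assert all(p == 1.0 for p in res["p_by_direction"].values())
        assert len(res["degenerate_directions"]) == 4

    def test_three_amplitudes_rejected(self, task2_config, make_neuron):
        trials = simulate_session(task2_config, [make_neuron()], 3, seed=0)
        with pytest.raises(ValueError, match="amplitude-response-curve"):
            directionwise_amplitude_tests(trials, "EM")


class TestBinomialTest:
    def test_certain_event(self):
        assert population_proportion_test(0, 100, 0.05) == 1.0

    def test_closed_form_all_selective(self):
        assert population_proportion_test(100, 100, 0.05) == pytest.approx(0.05**100, rel=1e-9)

    def test_matches_pmf_summation(self):
        # brute-force tail: sum_{i=10}^{100} C(100,i) 0.05^i 0.95^(100-i)
        expected = sum(stats.binom.pmf(i, 100, 0.05) for i in range(10, 101))
        assert population_proportion_test(10, 100, 0.05) == pytest.approx(expected, rel=1e-12)

    def test_invalid_p0(self):
        with pytest.raises(ValueError):
            population_proportion_test(1, 10, 0.0)


class TestDirectionFactor:
    def test_unstaggered_matches_raw_grouping(self, task2_radial, make_neuron):
        trials = simulate_session(task2_radial, [make_neuron()], 2, seed=0)
        labels = derive_direction_factor(trials)
        # same label iff same raw direction
        for lab in np.unique(labels):
            assert trials.loc[labels == lab, "direction_deg"].nunique() == 1

    def test_staggered_rings_aligned(self, task2_config, make_neuron):
        trials = simulate_session(task2_config, [make_neuron()], 2, seed=0)
        labels = derive_direction_factor(trials)
        assert len(np.unique(labels)) == 16
        # every (label, amplitude) cell occupied
        pivot = pd.crosstab(labels, trials["amplitude_cm"])
        assert (pivot.to_numpy() > 0).all()


class TestShuffleNull:
    def test_deterministic(self, task1_config, make_neuron):
        pop = [
            make_neuron(neuron_id=i, model_id=4, params=[0.0, 2.0, 2.0], gain=25.0)
            for i in range(3)
        ]
        trials = simulate_session(task1_config, pop, 10, seed=0)
        r1 = shuffle_null_proportion(trials, n_shuffles=5, seed=3)
        r2 = shuffle_null_proportion(trials, n_shuffles=5, seed=3)
        assert r1["mean_proportion"] == r2["mean_proportion"]
        np.testing.assert_array_equal(r1["proportions"], r2["proportions"])

    def test_tuned_population_shuffles_to_chance(self, task1_config, make_neuron):
        pop = [
            make_neuron(neuron_id=i, model_id=4, params=[i % 7 - 3, 2.0, 3.0], gain=30.0)
            for i in range(8)
        ]
        trials = simulate_session(task1_config, pop, 20, seed=1)
        results = screen_population(trials)
        unshuffled = np.mean([r.amplitude_selective_any_epoch for r in results])
        shuffled = shuffle_null_proportion(trials, n_shuffles=20, seed=0)["mean_proportion"]
        assert unshuffled > 0.5
        assert shuffled < 0.2

    def test_constant_population_never_flagged(self, task1_config, make_neuron):
        pop = [make_neuron(neuron_id=i, model_id=UNTUNED, baseline=0.0) for i in range(2)]
        trials = simulate_session(task1_config, pop, 5, seed=0)
        res = shuffle_null_proportion(trials, n_shuffles=3, seed=0)
        assert res["mean_proportion"] == 0.0

    def test_invalid_n_shuffles(self, task1_config, make_neuron):
        trials = simulate_session(task1_config, [make_neuron()], 5, seed=0)
        with pytest.raises(ValueError):
            shuffle_null_proportion(trials, n_shuffles=0)


def test_amplitude_f_monotone_in_gain():
    # expected main-amplitude F never decreases as the amplitude effect grows
    a = np.repeat([0, 90, 180, 270], 40)
    b = np.tile(np.repeat([2.5, 7.0], 20), 4)
    mean_f = []
    for gain in (0.0, 5.0, 15.0):
        fs = []
        for rep in range(60):
            rng = np.random.default_rng(1000 + rep)
            lam = (10.0 + gain * (b == 7.0)) * 0.5
            y = rng.poisson(lam) / 0.5
            fs.append(anova2_interaction(y, a, b)["amplitude"]["F"])
        mean_f.append(np.mean(fs))
    assert mean_f[0] < mean_f[1] < mean_f[2]


def test_screen_and_table_shapes(task1_config, make_neuron):
    pop = [
        make_neuron(neuron_id=0, model_id=UNTUNED),
        make_neuron(neuron_id=1, model_id=1, params=[0.5], gain=25.0),
    ]
    trials = simulate_session(task1_config, pop, 30, seed=1)
    results = screen_population(trials)
    table = selectivity_table(results)
    assert len(table) == 2
    assert table.loc[table.neuron_id == 1, "task_related"].item()
    assert not table.loc[table.neuron_id == 0, "task_related"].item()
    p_cols = [c for c in table.columns if c.startswith("p_")]
    vals = table[p_cols].to_numpy()
    assert ((vals >= 0) & (vals <= 1)).all()
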