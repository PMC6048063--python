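import numpy as np
import pytest
from scipy.integrate import quad

from mycostate import (
    RateModel,
    RootPrior,
    SimulationSpec,
    SteppingStoneConfig,
    TipData,
    TreeLikelihood,
    first_gain_test,
    interpret_bf,
    simulate_characters,
    simulate_tree,
    stepping_stone_lnZ,
)
from mycostate.model_compare import SteppingStoneResult

from conftest import state, uniform_data


def quick_cfg(**kw):
    base = dict(n_stones=12, iterations_per_stone=1500, seed=0, rate_prior_mean=0.01)
    base.update(kw)
    return SteppingStoneConfig(**base)


class TestSteppingStone:
    def test_zero_free_parameters_gives_exact_logl(self, space2):
        tree = simulate_tree(SimulationSpec(n_tips=6, seed=1))
        data = TipData({t: state("NM") for t in tree.tip_labels}, space2)
        m = RateModel(space2, {mv: 0.0 for mv in space2.moves},
                      structural_zeros=frozenset(space2.moves))
        root = RootPrior.fixed(state("NM"))
        res = stepping_stone_lnZ(tree, data, m, root, quick_cfg())
        from mycostate import log_likelihood
        assert res.lnZ == log_likelihood(tree, data, m, root)
        assert res.standard_error == 0.0

    def test_all_uncertain_data_lnz_is_zero(self, space2):
        tree = simulate_tree(SimulationSpec(n_tips=6, seed=2))
        res = stepping_stone_lnZ(tree, uniform_data(tree, space2),
                                 RateModel.uniform(space2, 0.01), cfg=quick_cfg())
        assert res.lnZ == pytest.approx(0.0, abs=1e-12)

    def test_one_free_rate_matches_quadrature(self, space2):
        tree = simulate_tree(SimulationSpec(n_tips=12, seed=3))
        data, _ = simulate_characters(tree, RateModel.uniform(space2, 0.01),
                                      state("NM"), seed=4)
        mean = 0.01
        model = RateModel.uniform(space2, mean)
        model.rate_classes = {mv: 1 for mv in space2.moves}
        tl = TreeLikelihood(tree, data)

        def integrand(q):
            return np.exp(tl.log_likelihood(RateModel.uniform(space2, q))
                          - q / mean) / mean

        val, _ = quad(integrand, 0, 1.0, limit=200)
        res = stepping_stone_lnZ(tree, data, model, cfg=quick_cfg(seed=5))
        assert abs(res.lnZ - np.log(val)) < 3 * max(res.standard_error, 1e-3)

    def test_deterministic_given_seed(self, space2):
        tree = simulate_tree(SimulationSpec(n_tips=8, seed=6))
        data, _ = simulate_characters(tree, RateModel.uniform(space2, 0.01),
                                      state("NM"), seed=7)
        m = RateModel.uniform(space2, 0.01)
        cfg = quick_cfg(n_stones=6, iterations_per_stone=400, seed=8)
        r1 = stepping_stone_lnZ(tree, data, m, cfg=cfg)
        r2 = stepping_stone_lnZ(tree, data, m, cfg=cfg)
        assert r1.lnZ == r2.lnZ  # hence BF(base, base) = 0 exactly

    def test_power_schedule_validation(self):
        with pytest.raises(ValueError, match="increase strictly"):
            SteppingStoneConfig(power_schedule=(0.0, 0.5, 0.5, 1.0))
        with pytest.raises(ValueError, match="at least 2"):
            SteppingStoneConfig(n_stones=1)
        betas = SteppingStoneConfig(n_stones=10).betas()
        assert betas[0] == 0.0 and betas[-1] == 1.0 and np.all(np.diff(betas) > 0)

    def test_conflicting_constraints_raise(self, space2):
        tree = simulate_tree(SimulationSpec(n_tips=6, seed=9))
        data = TipData({t: state("M") for t in tree.tip_labels}, space2)
        gain = (space2.index(state("NM")), space2.index(state("M")))
        m = RateModel.uniform(space2, 0.01).with_structural_zero(gain)
        with pytest.raises(ValueError, match="constraint"):
            stepping_stone_lnZ(tree, data, m, RootPrior.fixed(state("NM")),
                               quick_cfg())

    def test_nested_constraint_does_not_increase_lnz(self, space4):
        """Zeroing a move can only shrink the model; its marginal
        likelihood must not exceed the base beyond Monte-Carlo error."""
        tree = simulate_tree(SimulationSpec(n_tips=25, seed=10))
        truth = RateModel.uniform(space4, 0.01)
        data, _ = simulate_characters(tree, truth, state("NM"), seed=11)
        root = RootPrior.fixed(state("NM"))
        base = RateModel.uniform(space4, 0.01)
        cfg = quick_cfg(seed=12)
        lnz_base = stepping_stone_lnZ(tree, data, base, root, cfg)
        gain_m = (space4.index(state("NM")), space4.index(state("M")))
        lnz_con = stepping_stone_lnZ(tree, data, base.with_structural_zero(gain_m),
                                     root, cfg)
        se = np.hypot(lnz_base.standard_error, lnz_con.standard_error)
        assert lnz_con.lnZ <= lnz_base.lnZ + 3 * se + 0.05


class TestInterpretBf:
    @pytest.mark.parametrize("bf, category", [
        (8.35, "substantial"),
        (12.0, "strong"),
        (0.0, "barely worth mentioning"),
        (4.0, "positive"),
        (10.0, "substantial"),
        (10.01, "strong"),
    ])
    def test_kass_raftery_scale(self, bf, category):
        assert interpret_bf(bf) == category

    def test_configurable_boundaries(self):
        assert interpret_bf(3.0, boundaries=(1.0, 2.0, 2.5)) == "strong"


class TestFirstGainTest:
    def test_errors_without_empty_state(self, space2):
        from mycostate import build_state_space
        sp = build_state_space([state("M"), state("G+M")], include_empty=False)
        tree = simulate_tree(SimulationSpec(n_tips=6, seed=13))
        data = TipData({t: state("M") for t in tree.tip_labels}, sp)
        with pytest.raises(ValueError, match="empty"):
            first_gain_test(tree, data, sp)

    def test_errors_without_adjacent_single_gains(self):
        from mycostate import build_state_space
        sp = build_state_space([state("NM"), state("A+B")], include_empty=True)
        tree = simulate_tree(SimulationSpec(n_tips=6, seed=14))
        data = TipData({t: state("NM") for t in tree.tip_labels}, sp)
        with pytest.raises(ValueError, match="adjacent"):
            first_gain_test(tree, data, sp)

    def test_detects_the_simulated_first_gain(self, space4):
        """Data generated entering the symbiosis via the Mucoromycotina
        gain: disallowing that gain must hurt lnZ most."""
        tree = simulate_tree(SimulationSpec(n_tips=40, seed=15))
        truth = _entry_via_m(space4)
        data, _ = simulate_characters(tree, truth, state("NM"), seed=16)
        cfg = quick_cfg(n_stones=8, iterations_per_stone=800, seed=17)
        result = first_gain_test(tree, data, space4, cfg)
        assert set(result.table.index) == {"M", "G"}
        assert result.best_group == "M"
        assert result.table.loc["M", "BF"] > 0

    def test_table_has_categories(self, space4):
        tree = simulate_tree(SimulationSpec(n_tips=15, seed=18))
        data, _ = simulate_characters(tree, _entry_via_m(space4), state("NM"), seed=19)
        cfg = quick_cfg(n_stones=6, iterations_per_stone=400, seed=20)
        result = first_gain_test(tree, data, space4, cfg)
        assert all(c in ("barely worth mentioning", "positive", "substantial", "strong")
                   for c in result.table["category"])


def _entry_via_m(space4):
    """True model whose only route out of NM is the M gain."""
    ix = space4.index_of_label
    rates = {mv: 0.004 for mv in space4.moves}
    rates[(ix("NM"), ix("M"))] = 0.02
    rates[(ix("NM"), ix("G"))] = 0.0
    rates[(ix("M"), ix("G+M"))] = 0.012
    rates[(ix("M"), ix("NM"))] = 0.001
    rates[(ix("G"), ix("NM"))] = 0.001
    return RateModel(space4, rates)
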