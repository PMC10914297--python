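import numpy as np
import pytest
from scipy.optimize import linprog

import healthalloc as ha
from healthalloc.dea import DEAError, DEFAULT_TOL

from conftest import make_frame


def multiplier_crs_theta(X, Y, j0):
    """Independent oracle: the CCR multiplier (dual) LP.

    max u·y0  s.t.  v·x0 = 1,  u·y_j − v·x_j ≤ 0 ∀j,  u, v ≥ 0.
    By LP duality this equals the envelopment θ.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n, m = X.shape
    s = Y.shape[1]
    c = np.concatenate([-Y[j0], np.zeros(m)])  # maximize u·y0
    A_ub = np.hstack([Y, -X])
    b_ub = np.zeros(n)
    A_eq = np.concatenate([np.zeros(s), X[j0]])[None, :]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
                  bounds=[(0, None)] * (s + m), method="highs")
    assert res.status == 0
    return -res.fun


class TestEnvelopment:
    def test_single_dmu_is_self_efficient(self):
        model = ha.DEA([[2.0, 1.0]], [[3.0]])
        theta, lam = model.solve_envelopment(0, "crs")
        assert theta == pytest.approx(1.0, abs=1e-9)
        assert lam == pytest.approx([1.0], abs=1e-6)

    def test_one_input_one_output_crs_closed_form(self):
        model = ha.DEA([[2.0], [4.0]], [[2.0], [2.0]])
        theta_b, _ = model.solve_envelopment(1, "crs")
        assert theta_b == pytest.approx(0.5, abs=1e-10)

    def test_worked_example_a11_b32(self):
        model = ha.DEA([[1.0], [3.0]], [[1.0], [2.0]])
        assert model.solve_envelopment(1, "crs")[0] == pytest.approx(2 / 3, abs=1e-9)
        assert model.solve_envelopment(1, "vrs")[0] == pytest.approx(1.0, abs=1e-9)
        assert model.solve_envelopment(1, "nirs")[0] == pytest.approx(1.0, abs=1e-9)
        res = model.fit()
        assert res.rts == ["constant", "decreasing"]

    def test_two_input_mix_inefficiency(self):
        # C's mix is dominated by the average of A and B: θ_C = 0.75
        model = ha.DEA([[1, 2], [2, 1], [2, 2]], [[1], [1], [1]])
        theta_c, lam = model.solve_envelopment(2, "crs")
        assert theta_c == pytest.approx(0.75, abs=1e-9)
        assert theta_c == pytest.approx(multiplier_crs_theta(
            model.inputs, model.outputs, 2), abs=1e-9)

    def test_envelopment_matches_multiplier_dual_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n, m, s = rng.integers(2, 9), rng.integers(1, 4), rng.integers(1, 3)
            X = rng.uniform(0.5, 10, (n, m))
            Y = rng.uniform(0.5, 10, (n, s))
            model = ha.DEA(X, Y)
            for j in range(n):
                theta, _ = model.solve_envelopment(j, "crs")
                assert theta == pytest.approx(
                    multiplier_crs_theta(X, Y, j), abs=1e-7)

    def test_validation_rejects_bad_problems(self):
        with pytest.raises(DEAError):
            ha.DEA([[0.0, 0.0]], [[1.0]])  # no positive input
        with pytest.raises(DEAError):
            ha.DEA([[1.0]], [[0.0]])  # no positive output
        with pytest.raises(DEAError):
            ha.DEA([[1.0], [-1.0]], [[1.0], [1.0]])
        with pytest.raises(DEAError):
            ha.DEA([[1.0]], [[1.0], [1.0]])


class TestSlacks:
    def test_strongly_efficient_dmu_has_zero_slacks(self):
        model = ha.DEA([[1.0], [3.0]], [[1.0], [2.0]])
        res = model.fit()
        assert res.efficient[0]
        np.testing.assert_allclose(res.input_slacks[0], 0, atol=1e-7)
        np.testing.assert_allclose(res.output_slacks[0], 0, atol=1e-7)

    def test_weakly_efficient_dmu_radially_one_with_input_slack(self):
        # D matches A's output with one extra unit of input 2: θ_VRS = 1, slack 1
        model = ha.DEA([[1.0, 1.0], [1.0, 2.0]], [[1.0], [1.0]])
        theta, _ = model.solve_envelopment(1, "vrs")
        assert theta == pytest.approx(1.0, abs=1e-9)
        s_in, s_out, _ = model.solve_slacks(1, theta, "vrs")
        np.testing.assert_allclose(s_in, [0.0, 1.0], atol=1e-7)
        np.testing.assert_allclose(s_out, [0.0], atol=1e-7)
        res = model.fit(slack_frontier="vrs")
        assert not res.efficient[1]

    def test_slacks_reported_in_original_units(self):
        # scaling input 2's units by 1000 scales its slack by 1000
        model1 = ha.DEA([[1.0, 1.0], [1.0, 2.0]], [[1.0], [1.0]])
        model2 = ha.DEA([[1.0, 1000.0], [1.0, 2000.0]], [[1.0], [1.0]])
        s1 = model1.solve_slacks(1, 1.0, "vrs")[0]
        s2 = model2.solve_slacks(1, 1.0, "vrs")[0]
        assert s2[1] == pytest.approx(1000 * s1[1], rel=1e-6)


class TestReturnsToScale:
    @pytest.mark.parametrize(
        "crs,vrs,nirs,label",
        [
            (1.0, 1.0, 1.0, "constant"),
            (0.991, 1.0, 1.0, "decreasing"),
            (2 / 3, 1.0, 1.0, "decreasing"),
            (0.7, 0.9, 0.7, "increasing"),
        ],
    )
    def test_classification_rule(self, crs, vrs, nirs, label):
        assert ha.returns_to_scale(crs, vrs, nirs) == label

    def test_rejects_out_of_range_scores(self):
        with pytest.raises(ValueError):
            ha.returns_to_scale(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            ha.returns_to_scale(0.5, 1.2, 1.0)


class TestInvariants:
    def _random_model(self, rng):
        n, m, s = rng.integers(3, 10), rng.integers(1, 4), rng.integers(1, 3)
        return ha.DEA(rng.uniform(0.5, 10, (n, m)), rng.uniform(0.5, 10, (n, s)))

    def test_units_invariance_of_theta(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            model = self._random_model(rng)
            X, Y = model.inputs.copy(), model.outputs.copy()
            X[:, 0] *= 137.0
            Y[:, -1] *= 0.004
            res1 = model.fit()
            res2 = ha.DEA(X, Y).fit()
            np.testing.assert_allclose(res1.overall, res2.overall, atol=1e-7)
            np.testing.assert_allclose(res1.technical, res2.technical, atol=1e-7)

    def test_frontier_ordering_and_scale_bound(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            res = self._random_model(rng).fit()
            assert np.all(res.overall <= res.nirs + 1e-9)
            assert np.all(res.nirs <= res.technical + 1e-9)
            assert np.all(res.technical <= 1.0 + 1e-9)
            assert np.all(res.scale <= 1.0 + 1e-9)
            assert np.all(res.overall > 0)

    def test_at_least_one_vrs_efficient_dmu(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            res = self._random_model(rng).fit()
            assert np.any(res.technical >= 1 - DEFAULT_TOL)

    def test_adding_dominated_dmu_never_raises_others(self):
        rng = np.random.default_rng(37)
        X = rng.uniform(1, 5, (4, 2))
        Y = rng.uniform(1, 5, (4, 2))
        base = ha.DEA(X, Y).fit()
        dom_x = X[0] * 1.5
        dom_y = Y[0] * 0.7
        bigger = ha.DEA(np.vstack([X, dom_x]), np.vstack([Y, dom_y])).fit()
        assert np.all(bigger.overall[:4] <= base.overall + 1e-9)
        assert bigger.overall[4] < 1 - DEFAULT_TOL


class TestPanelSchemes:
    def test_proportional_dmus_all_efficient(self, proportional_panel):
        res = ha.run_dea(proportional_panel, "years_as_dmus_on_totals")
        np.testing.assert_allclose(res.overall, 1.0, atol=1e-7)
        assert res.efficient.all()
        per_year = ha.run_dea(proportional_panel, "regions_as_dmus_per_year")
        for year_res in per_year.values():
            np.testing.assert_allclose(year_res.overall, 1.0, atol=1e-7)

    def test_incomplete_panel_rejected(self, paper_shaped_panel):
        broken = ha.Panel(paper_shaped_panel.frame.iloc[1:])
        with pytest.raises(DEAError, match="incomplete"):
            ha.run_dea(broken)

    def test_by_year_table_shape(self, paper_shaped_panel):
        t = ha.dea_by_year_table(paper_shaped_panel)
        assert list(t["year"]) == [str(y) for y in paper_shaped_panel.years]
        assert {"overall_efficiency", "technical_efficiency", "scale_efficiency",
                "returns_to_scale", "status"} <= set(t.columns)
        assert sum(c.startswith("slack_") for c in t.columns) == 6

    def test_by_region_table_shape(self, paper_shaped_panel):
        t = ha.dea_by_region_table(paper_shaped_panel)
        assert len(t) == 21 * 5
        assert ((t.overall_efficiency > 0) & (t.overall_efficiency <= 1 + 1e-9)).all()

    def test_summary_renders(self, paper_shaped_panel):
        res = ha.run_dea(paper_shaped_panel, "years_as_dmus_on_totals")
        text = res.summary(input_names=ha.RESOURCES, output_names=ha.UTILIZATION)
        assert "Input-oriented DEA" in text and "slack_beds" in text
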