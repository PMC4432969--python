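"""Screen quantification: classifier, summaries, inhibition, 4PL, IC50."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from emtkit import (DoseResponseResult, InputError, NumericalError,
                    SimulationConfig, VimClassifier, extract_ic50,
                    fit_dose_response, logistic4, percent_inhibition,
                    quantify_plate, simulate_screen_plate, summarize_wells,
                    train_vim_classifier)


def control_cells(n_per_class, rng, mu_neg=math.log(50), mu_pos=math.log(1000),
                  sigma=0.45, pos_frac_in_pos_ctrl=0.05,
                  pos_frac_in_neg_ctrl=0.60, vim_total=None):
    """Two control-well cell populations mixing vim+/- log-normal components."""
    rows = []
    for role, frac in (("pos_ctrl", pos_frac_in_pos_ctrl),
                       ("neg_ctrl", pos_frac_in_neg_ctrl)):
        is_pos = rng.random(n_per_class) < frac
        mu = np.where(is_pos, mu_pos, mu_neg)
        vm = np.exp(rng.normal(mu, sigma))
        vt = vm * 300.0 if vim_total is None else np.full(n_per_class,
                                                          vim_total)
        for i in range(n_per_class):
            rows.append({"role": role, "vim_mean": vm[i], "vim_total": vt[i],
                         "perk_mean": 1.0})
    return pd.DataFrame(rows)


class TestClassifier:
    def test_separable_case_zero_error(self):
        rng = np.random.default_rng(0)
        low = rng.uniform(1, 10, 200)
        high = rng.uniform(20, 30, 200)
        cells = pd.DataFrame({
            "role": ["pos_ctrl"] * 200 + ["neg_ctrl"] * 200,
            "vim_mean": np.concatenate([low, high]),
            "vim_total": np.ones(400)})
        clf = train_vim_classifier(cells)
        assert clf.training_score == pytest.approx(1.0)
        assert 10 < clf.primary_threshold < 20
        assert not clf.predict(pd.DataFrame(
            {"vim_mean": [5.0], "vim_total": [1.0]}))[0]
        assert clf.predict(pd.DataFrame(
            {"vim_mean": [25.0], "vim_total": [1.0]}))[0]

    def test_threshold_near_bayes_boundary(self):
        # balanced provenance classes with equal-variance log-normal
        # components: the optimal boundary is where the class densities
        # cross; solve it numerically as an independent oracle
        rng = np.random.default_rng(1)
        mu_neg, mu_pos, sigma = math.log(50), math.log(1000), 0.45
        cells = control_cells(10_000, rng, vim_total=1.0)
        clf = train_vim_classifier(cells)
        assert clf.primary_feature == "vim_mean"

        def density_gap(x):
            f_pos = (0.95 * norm.pdf(x, mu_neg, sigma)
                     + 0.05 * norm.pdf(x, mu_pos, sigma))
            f_neg = (0.40 * norm.pdf(x, mu_neg, sigma)
                     + 0.60 * norm.pdf(x, mu_pos, sigma))
            return f_pos - f_neg
        bayes = brentq(density_gap, mu_neg, mu_pos)
        assert math.log(clf.primary_threshold) == pytest.approx(
            bayes, abs=0.1 * bayes)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        cells = control_cells(500, rng)
        clf_a = train_vim_classifier(cells)
        shuffled = cells.sample(frac=1.0, random_state=5).reset_index(drop=True)
        clf_b = train_vim_classifier(shuffled)
        assert clf_a.tree.to_dict() == clf_b.tree.to_dict()

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(3)
        cells = control_cells(300, rng)
        clf = train_vim_classifier(cells)
        again = VimClassifier.from_json(clf.to_json())
        probe = control_cells(200, np.random.default_rng(4))
        assert np.array_equal(clf.predict(probe), again.predict(probe))

    def test_missing_class_rejected(self):
        rng = np.random.default_rng(5)
        cells = control_cells(300, rng)
        with pytest.raises(InputError):
            train_vim_classifier(cells[cells["role"] == "pos_ctrl"])


class TestSummaries:
    def make_plate(self, positives, total):
        cells = pd.DataFrame({
            "well": ["A01"] * total,
            "role": ["dose"] * total,
            "cell_id": [f"c{i}" for i in range(total)],
            "vim_mean": [100.0 if i < positives else 1.0
                         for i in range(total)],
            "vim_total": [1.0] * total,
            "perk_mean": [2.0] * total,
        })
        wells = pd.DataFrame({
            "well": ["A01", "A02"], "role": ["dose", "dose"],
            "compound": ["K", "K"], "dose_uM": [1.0, 2.0],
            "stimulus": ["EGF", "EGF"]})
        from emtkit.screen import _Split
        clf = VimClassifier(tree=_Split("vim_mean", 50.0, False, True),
                            training_score=1.0)
        return cells, wells, clf

    def test_fraction_arithmetic(self):
        cells, wells, clf = self.make_plate(7, 20)
        out = summarize_wells(cells, wells, clf).set_index("well")
        assert out.loc["A01", "pct_vim_pos"] == pytest.approx(35.0)
        assert out.loc["A01", "n_cells"] == 20
        assert out.loc["A02", "flag"] == "no_cells"
        assert math.isnan(out.loc["A02", "pct_vim_pos"])

    def test_all_positive_is_hundred(self):
        cells, wells, clf = self.make_plate(20, 20)
        out = summarize_wells(cells, wells, clf).set_index("well")
        assert out.loc["A01", "pct_vim_pos"] == pytest.approx(100.0)


class TestPercentInhibition:
    def test_anchors_exact(self):
        pos, neg = [10.0, 10.0], [60.0, 60.0]
        assert percent_inhibition(60.0, pos, neg) == pytest.approx(0.0)
        assert percent_inhibition(10.0, pos, neg) == pytest.approx(100.0)
        assert percent_inhibition(35.0, pos, neg) == pytest.approx(50.0)

    def test_not_clipped(self):
        assert percent_inhibition(5.0, [10.0], [60.0]) > 100.0
        assert percent_inhibition(70.0, [10.0], [60.0]) < 0.0

    def test_degenerate_controls_rejected(self):
        with pytest.raises(NumericalError):
            percent_inhibition(1.0, [5.0], [5.0])


class TestDoseResponse:
    doses = 10.0 / 2.0 ** np.arange(11)

    def test_noiseless_recovery(self):
        truth = dict(bottom=0.0, top=100.0, hill=1.0, midpoint=1.0)
        resp = logistic4(self.doses, **truth)
        fit = fit_dose_response(self.doses, resp)
        assert fit.converged
        assert fit.bottom == pytest.approx(0.0, abs=1e-5)
        assert fit.top == pytest.approx(100.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)
        assert fit.midpoint == pytest.approx(1.0, rel=1e-6)

    def test_noisy_midpoint_accuracy(self):
        errors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            resp = logistic4(self.doses, 0.0, 100.0, 1.0, 1.0) \
                + rng.normal(0, 5, self.doses.size)
            fit = fit_dose_response(self.doses, resp)
            assert fit.converged
            errors.append(abs(math.log10(fit.midpoint)))
        assert np.median(errors) < 0.15

    def test_constant_response_flagged(self):
        fit = fit_dose_response(self.doses, np.full(11, 42.0))
        assert not fit.converged
        assert "degenerate" in fit.note

    def test_too_few_doses_rejected(self):
        with pytest.raises(InputError):
            fit_dose_response([1.0, 2.0, 4.0], [10.0, 50.0, 90.0])


class TestExtractIC50:
    def fit(self, bottom, top, hill=1.0, midpoint=1.0, converged=True):
        return DoseResponseResult(bottom=bottom, top=top, hill=hill,
                                  midpoint=midpoint, converged=converged)

    def test_symmetric_curve_equals_midpoint(self):
        assert extract_ic50(self.fit(0.0, 100.0), (0.01, 10.0)) == \
            pytest.approx(1.0)

    def test_low_plateau_censored_high(self):
        assert extract_ic50(self.fit(0.0, 40.0), (0.01, 10.0)) == ">10"

    def test_hand_algebra_offset_bottom(self):
        # 20 + 80/(1 + 1/d) = 50  =>  d = 3/5
        assert extract_ic50(self.fit(20.0, 100.0), (0.01, 10.0)) == \
            pytest.approx(0.6)

    def test_censor_tokens_use_tested_range(self):
        assert extract_ic50(self.fit(0.0, 100.0, midpoint=50.0),
                            (0.02, 25.0)) == ">25"
        assert extract_ic50(self.fit(0.0, 100.0, midpoint=0.001),
                            (0.02, 25.0)) == "<0.02"

    def test_unconverged_censored_high(self):
        assert extract_ic50(self.fit(0, 0, converged=False),
                            (0.01, 10.0)) == ">10"


class TestEndToEnd:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_pipeline_recovers_planted_ic50(self, seed):
        cfg = SimulationConfig(seed=seed)
        plate = simulate_screen_plate(cfg, "KIN-1", "EGF")
        out = quantify_plate(plate.cells, plate.wells)
        for readout in ("pct_vim_pos", "cell_count"):
            ic50 = out["results"][readout].ic50
            truth = cfg.truth_ic50["KIN-1"][readout]
            assert isinstance(ic50, float)
            assert 0.5 * truth <= ic50 <= 2.0 * truth

    def test_well_order_invariance(self):
        cfg = SimulationConfig(seed=3, mean_cells_per_well=40.0)
        plate = simulate_screen_plate(cfg, "KIN-1", "EGF")
        base = quantify_plate(plate.cells, plate.wells)
        shuffled_cells = plate.cells.sample(frac=1.0, random_state=1) \
            .reset_index(drop=True)
        shuffled_wells = plate.wells.sample(frac=1.0, random_state=2) \
            .reset_index(drop=True)
        again = quantify_plate(shuffled_cells, shuffled_wells)
        for readout in ("pct_vim_pos", "cell_count"):
            assert again["results"][readout].ic50 == \
                pytest.approx(base["results"][readout].ic50)
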