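"""Multinomial logit fitting, prediction, policy and model-file round trip."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from evcolor import model, panel, simulate
from evcolor.model import (
    ConvergenceError,
    MLRModel,
    ModelError,
    ModelSpec,
    PolicyRefusalError,
    default_spec,
    fit_mlr,
    load_model,
    missing_marker_policy,
    predict_proba,
    resolve_dosages,
    save_model,
)


def _recovery_spec():
    """Eye-shaped spec over synthetic markers for coefficient-recovery tests."""
    return ModelSpec(
        task="eye",
        categories=("blue", "intermediate", "brown"),
        reference_category="brown",
        marker_ids=tuple(f"m{j}" for j in range(6)),
    )


def _recovery_data(n, seed):
    """Panel with common covariates, moderate effects and balanced classes."""
    spec = _recovery_spec()
    rng = np.random.default_rng(seed)
    freqs = np.array([0.3, 0.5, 0.2, 0.4, 0.25, 0.35])
    x = rng.binomial(2, freqs, size=(n, 6)).astype(float)
    truth = MLRModel(
        spec,
        intercepts=np.array([-0.4, -0.9]),
        coefficients=np.array(
            [
                [1.5, -0.8, 0.6, -1.2, 0.9, -0.5],
                [0.7, -0.3, 0.2, -0.6, 0.4, -0.2],
            ]
        ),
    )
    probs = truth.probabilities(x)
    cum = np.cumsum(probs, axis=1)
    labels = [spec.categories[int((u > c).sum())] for u, c in zip(rng.random(n), cum)]
    return x, labels, truth


def _oracle_fit(x, labels, spec, ridge=model.RIDGE_DEFAULT):
    """Independent maximizer of the same penalized multinomial likelihood."""
    cats = list(spec.nonreference)
    k = len(cats)
    yidx = np.array([cats.index(l) if l in cats else k for l in labels])
    xd = np.column_stack([np.ones(len(x)), x])

    def nll(v):
        th = v.reshape(k, xd.shape[1])
        full = np.column_stack([xd @ th.T, np.zeros(len(xd))])
        logz = np.logaddexp.reduce(full, axis=1)
        return -(full[np.arange(len(xd)), yidx] - logz).sum() + 0.5 * ridge * np.sum(
            th[:, 1:] ** 2
        )

    res = minimize(nll, np.zeros(k * xd.shape[1]), method="BFGS",
                   options={"gtol": 1e-9, "maxiter": 5000})
    return res.x.reshape(k, xd.shape[1])


class TestFit:
    def test_recovers_known_coefficients(self):
        x, labels, truth = _recovery_data(5000, seed=1)
        fit = fit_mlr(x, labels, truth.spec)
        assert np.abs(fit.coefficients - truth.coefficients).max() < 0.15
        # intercepts are correlated nuisance terms with larger sampling error
        assert np.abs(fit.intercepts - truth.intercepts).max() < 0.3

    def test_agrees_with_independent_maximizer(self):
        x, labels, truth = _recovery_data(800, seed=3)
        fit = fit_mlr(x, labels, truth.spec)
        theta = _oracle_fit(x, labels, truth.spec)
        assert np.abs(theta[:, 0] - fit.intercepts).max() < 1e-5
        assert np.abs(theta[:, 1:] - fit.coefficients).max() < 1e-5

    def test_no_signal_gives_null_slopes_and_empirical_frequencies(self):
        rng = np.random.default_rng(11)
        x = rng.binomial(2, 0.4, size=(4000, 2)).astype(float)
        labels = list(rng.choice(["blue", "intermediate", "brown"], size=4000,
                                 p=[0.3, 0.2, 0.5]))
        spec = ModelSpec("eye", ("blue", "intermediate", "brown"), "brown", ("a", "b"))
        fit = fit_mlr(x, labels, spec)
        assert np.abs(fit.coefficients).max() < 0.1
        fitted = fit.probabilities(np.array([[0.8, 0.8]]))[0]  # mean dosage point
        emp = np.array([labels.count(c) / 4000 for c in spec.categories])
        assert np.abs(fitted - emp).max() < 0.05

    def test_binary_spec_matches_standard_logistic_fit(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(5)
        x = rng.binomial(2, 0.35, size=(2000, 3)).astype(float)
        eta = -0.5 + x @ np.array([0.8, -0.6, 0.4])
        y = (rng.random(2000) < 1 / (1 + np.exp(-eta))).astype(int)
        spec = ModelSpec("shade", ("light", "dark"), "dark", ("a", "b", "c"))
        labels = ["light" if v else "dark" for v in y]
        ridge = 1e-4
        fit = fit_mlr(x, labels, spec, ridge=ridge)
        # same penalized objective: sklearn's C = 1/ridge, intercept unpenalized
        sk = LogisticRegression(C=1 / ridge, tol=1e-10, max_iter=10_000)
        sk.fit(x, y)
        assert np.abs(sk.coef_[0] - fit.coefficients[0]).max() < 1e-6
        assert abs(sk.intercept_[0] - fit.intercepts[0]) < 1e-6

    def test_absent_category_rejected(self):
        x = np.zeros((50, 1))
        spec = ModelSpec("shade", ("light", "dark"), "dark", ("a",))
        with pytest.raises(ModelError, match="absent"):
            fit_mlr(x, ["light"] * 50, spec)

    def test_complete_separation_without_penalty_raises(self):
        x = np.array([[0.0]] * 30 + [[2.0]] * 30)
        labels = ["dark"] * 30 + ["light"] * 30
        spec = ModelSpec("shade", ("light", "dark"), "dark", ("a",))
        with pytest.raises(ConvergenceError, match="ridge"):
            fit_mlr(x, labels, spec, ridge=0.0)
        fit_mlr(x, labels, spec, ridge=1e-2)  # penalized fit converges


class TestPredict:
    def test_softmax_matches_brute_force(self):
        spec = _recovery_spec()
        rng = np.random.default_rng(2)
        m = MLRModel(spec, rng.normal(size=2), rng.normal(size=(2, 6)))
        for _ in range(20):
            x = rng.integers(0, 3, size=6).astype(float)
            pv = predict_proba(m, x)
            # direct formula: p_k = exp(eta_k) / (1 + sum_j exp(eta_j))
            denom = 1.0 + sum(
                np.exp(m.intercepts[i] + m.coefficients[i] @ x) for i in range(2)
            )
            for i, cat in enumerate(spec.nonreference):
                expected = np.exp(m.intercepts[i] + m.coefficients[i] @ x) / denom
                assert abs(pv[cat] - expected) < 1e-12
            assert abs(pv["brown"] - 1.0 / denom) < 1e-12

    def test_zero_model_is_uniform(self):
        spec = _recovery_spec()
        m = MLRModel(spec, np.zeros(2), np.zeros((2, 6)))
        pv = predict_proba(m, np.array([2.0, 1, 0, 2, 1, 0]))
        assert all(abs(v - 1 / 3) < 1e-12 for v in pv.probs.values())

    def test_blue_homozygote_predicts_blue(self, default_panel):
        """Two copies of the blue-associated HERC2 allele, no other effect
        alleles, under the default-fitted synthetic eye model."""
        models = simulate.default_true_models(default_panel)
        cfg = simulate.default_sim_config(default_panel, n_individuals=4000, seed=1)
        ref = simulate.simulate_reference_panel(cfg, default_panel)
        spec = default_spec("eye", default_panel)
        fitted = fit_mlr(ref.task_dosages(spec), ref.labels["eye"], spec)
        x = np.zeros(6)
        x[spec.marker_ids.index("rs12913832")] = 2.0
        assert predict_proba(fitted, x).argmax() == "blue"

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_probabilities_normalized(self, seed):
        rng = np.random.default_rng(seed)
        spec = _recovery_spec()
        m = MLRModel(spec, rng.normal(scale=2, size=2), rng.normal(scale=2, size=(2, 6)))
        pv = predict_proba(m, rng.integers(0, 3, size=6).astype(float))
        assert abs(sum(pv.probs.values()) - 1.0) < 1e-9

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000), dose=st.integers(0, 1))
    def test_monotone_in_positive_effect(self, seed, dose):
        """Raising the dosage of a marker with positive beta toward a
        category never lowers that category's probability."""
        rng = np.random.default_rng(seed)
        spec = _recovery_spec()
        coefs = rng.normal(scale=1.5, size=(2, 6))
        coefs[0, 0] = abs(coefs[0, 0])          # positive effect toward blue
        coefs[1, 0] = -abs(coefs[1, 0])         # and away from intermediate
        m = MLRModel(spec, rng.normal(size=2), coefs)
        x = rng.integers(0, 3, size=6).astype(float)
        x[0] = dose
        lo = predict_proba(m, x)["blue"]
        x[0] = dose + 1
        hi = predict_proba(m, x)["blue"]
        assert hi >= lo


class TestPolicy:
    def test_s4_hair_allowed_with_red_caveat(self, consensus_by_sample, default_panel):
        d = missing_marker_policy(consensus_by_sample["S4"], default_panel)
        assert d.eye_allowed and d.hair_allowed and d.shade_allowed
        assert d.imputed_markers == ["N29insA"]
        assert any("red hair cannot be excluded" in c for c in d.caveats)

    def test_s25_hair_refused_eye_allowed(self, consensus_by_sample, default_panel):
        d = missing_marker_policy(consensus_by_sample["S25"], default_panel)
        assert d.eye_allowed
        assert not d.hair_allowed and not d.shade_allowed
        assert any("missing genotypes at 3" in c for c in d.caveats)

    def test_complete_profile_unrestricted(self, consensus_by_sample, default_panel):
        d = missing_marker_policy(consensus_by_sample["S11"], default_panel)
        assert d.eye_allowed and d.hair_allowed and d.shade_allowed
        assert d.caveats == []

    def test_missing_eye_marker_refuses_eye(self, consensus_by_sample, default_panel):
        cp = consensus_by_sample["S11"]
        from evcolor.panel import AlleleCall, ConsensusProfile, ConsensusStatus

        calls = dict(cp.calls)
        calls["rs12913832"] = AlleleCall("rs12913832")
        broken = ConsensusProfile(cp.sample_id, calls, dict(cp.status), 1)
        d = missing_marker_policy(broken, default_panel)
        assert not d.eye_allowed
        assert any("eye prediction refused" in c for c in d.caveats)

    def test_refused_task_raises_on_predict(self, consensus_by_sample, default_panel):
        d = missing_marker_policy(consensus_by_sample["S25"], default_panel)
        models = simulate.default_true_models(default_panel)
        with pytest.raises(PolicyRefusalError, match="hair"):
            predict_proba(models["hair"], np.zeros(22), d)

    def test_imputation_strategies(self, default_panel):
        by_id = panel.marker_map(default_panel)
        dos = np.array([1.0, 2.0])
        mask = np.array([False, True])
        assert resolve_dosages(dos, mask)[1] == 0.0
        freq = resolve_dosages(
            dos, mask, strategy="frequency", panel_by_id=by_id,
            marker_ids=["rs12913832", "rs12913832"],
        )
        assert freq[1] == pytest.approx(2 * by_id["rs12913832"].effect_allele_freq)


class TestModelFiles:
    def test_bit_exact_roundtrip(self, tmp_path, default_panel):
        models = simulate.default_true_models(default_panel)
        cfg = simulate.default_sim_config(default_panel, n_individuals=1500, seed=9)
        ref = simulate.simulate_reference_panel(cfg, default_panel)
        spec = default_spec("hair", default_panel)
        fitted = fit_mlr(ref.task_dosages(spec), ref.labels["hair"], spec)
        path = tmp_path / "hair.model"
        save_model(fitted, path)
        loaded = load_model(path)
        assert loaded.spec == fitted.spec
        assert (loaded.intercepts == fitted.intercepts).all()
        assert (loaded.coefficients == fitted.coefficients).all()
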