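import numpy as np
import pytest

from pathsurv.data_model import SurvivalDataset
from pathsurv.networks import (
    RiskModelConfig,
    build_model,
    fit_cox_ph,
    fit_model,
    forward_risk,
    load_checkpoint,
    pathway_activations,
    save_checkpoint,
    _SortedCoxLoss,
)
from pathsurv.pathway_matrix import PathwayMatrix
from pathsurv.synthetic_data import linear_cohort, simulate_cohort, SimulationConfig


def _zero_weights(model):
    for w in model.weights:
        w[:] = 0.0
    for b in model.biases:
        b[:] = 0.0
    return model


def test_parameter_count_matches_masked_architecture(paper_scale_pm):
    cfg = RiskModelConfig(depth=3, input_dim=37, pathway_informed=True, loss="cox")
    m = build_model(cfg, paper_scale_pm)
    # pathway layer: one weight per mask edge + 138 biases; then 138->64, 64->1
    free_first = int(np.count_nonzero(paper_scale_pm.matrix))
    assert free_first == 468
    total = (free_first + 138) + (138 * 64 + 64) + (64 + 1)
    got = sum(int(np.count_nonzero(m._effective_first_weight() != 0)) if i == 0
              else w.size for i, w in enumerate(m.weights))
    got += sum(b.size for b in m.biases)
    # random init makes nonzero-count of masked layer exactly the edge count
    assert got == total


def test_depth_variants_layer_counts(paper_scale_pm):
    for depth, n_layers in ((2, 2), (3, 3), (4, 4)):
        cfg = RiskModelConfig(depth=depth, input_dim=37, pathway_informed=True)
        m = build_model(cfg, paper_scale_pm)
        assert len(m.weights) == n_layers
        assert m.weights[0].shape == (37, 138)
        assert m.weights[-1].shape[1] == 1
    for depth in (3, 4):
        hidden = build_model(RiskModelConfig(depth=depth, input_dim=37,
                                             pathway_informed=True), paper_scale_pm)
        assert hidden.weights[1].shape == (138, 64)


def test_all_zero_mask_forwards_bias_only():
    pm = PathwayMatrix(np.zeros((3, 4)), ["a", "b", "c"], list("pqrs"))
    cfg = RiskModelConfig(depth=2, input_dim=3, pathway_informed=True)
    m = build_model(cfg, pm)
    m.biases[0][:] = [1.0, -1.0, 0.5, 0.0]
    X = np.random.default_rng(0).normal(size=(5, 3))
    pa = pathway_activations(m, X)
    np.testing.assert_allclose(pa, np.tile([1.0, 0.0, 0.5, 0.0], (5, 1)))


def test_forward_risk_zero_weights_and_sigmoid():
    cfg = RiskModelConfig(depth=2, input_dim=4, loss="cox")
    m = _zero_weights(build_model(cfg))
    X = np.random.default_rng(1).lognormal(size=(6, 4))
    np.testing.assert_allclose(forward_risk(m, X), 0.0)
    cfg2 = RiskModelConfig(depth=2, input_dim=4, loss="bce", head="classification")
    m2 = _zero_weights(build_model(cfg2))
    np.testing.assert_allclose(forward_risk(m2, X), 0.5)


def test_forward_row_equivariance(paper_scale_pm):
    cfg = RiskModelConfig(depth=3, input_dim=37, pathway_informed=True)
    m = build_model(cfg, paper_scale_pm)
    X = np.random.default_rng(2).lognormal(size=(8, 37))
    perm = np.random.default_rng(3).permutation(8)
    np.testing.assert_allclose(forward_risk(m, X)[perm], forward_risk(m, X[perm]))


def test_forward_rejects_nonfinite():
    m = build_model(RiskModelConfig(depth=2, input_dim=2))
    with pytest.raises(ValueError, match="non-finite"):
        forward_risk(m, np.array([[1.0, np.nan]]))


def test_identity_path_single_edge():
    pm = PathwayMatrix(np.array([[1.0]]), ["m"], ["p"])
    cfg = RiskModelConfig(depth=2, input_dim=1, pathway_informed=True)
    m = build_model(cfg, pm)
    m.weights[0][:] = 1.0
    m.biases[0][:] = 0.0
    x = np.array([[0.0], [1.3], [2.6]])
    np.testing.assert_allclose(m.pathway_activations(x), x)  # no normalization set


def test_mask_zero_weights_stay_exactly_zero_through_training(small_cohort, paper_scale_pm):
    ds = small_cohort.dataset
    cfg = RiskModelConfig(depth=3, input_dim=37, pathway_informed=True,
                          max_epochs=100, patience=10**9, seed=1)
    m = build_model(cfg, paper_scale_pm)
    fit_model(m, ds.subset(np.arange(80)), ds.subset(np.arange(80, 100)))
    zero_positions = paper_scale_pm.matrix == 0
    assert np.all(m.weights[0][zero_positions] == 0.0)
    assert np.all(m._effective_first_weight()[zero_positions] == 0.0)
    pa = m.pathway_activations(ds.features)
    assert (pa >= 0).all()


def test_training_is_reproducible(small_cohort, paper_scale_pm):
    ds = small_cohort.dataset
    tr, va = ds.subset(np.arange(80)), ds.subset(np.arange(80, 100))
    cfg = RiskModelConfig(depth=3, input_dim=37, pathway_informed=True,
                          max_epochs=50, seed=3)
    m1 = fit_model(build_model(cfg, paper_scale_pm), tr, va)
    m2 = fit_model(build_model(cfg, paper_scale_pm), tr, va)
    for a, b in zip(m1.weights, m2.weights):
        np.testing.assert_array_equal(a, b)


def test_dropout_trains_and_keeps_mask(paper_scale_pm, small_cohort):
    ds = small_cohort.dataset
    cfg = RiskModelConfig(depth=3, input_dim=37, pathway_informed=True,
                          dropout_rate=0.5, max_epochs=30, seed=0)
    m = fit_model(build_model(cfg, paper_scale_pm),
                  ds.subset(np.arange(80)), ds.subset(np.arange(80, 100)))
    assert np.all(m.weights[0][paper_scale_pm.matrix == 0] == 0.0)
    assert m.epochs_trained > 0


def test_sorted_cox_matches_quadratic_reference():
    from pathsurv.losses import cox_gradient, cox_negative_log_partial_likelihood

    rng = np.random.default_rng(11)
    for _ in range(10):
        n = rng.integers(3, 30)
        h = rng.normal(size=n)
        e = rng.integers(0, 2, size=n)
        e[0] = 1
        d = rng.choice([1.0, 2.0, 5.0, 9.0], size=n)
        sc = _SortedCoxLoss(e, d)
        v, g = sc.value_grad(h)
        assert v * e.sum() == pytest.approx(
            cox_negative_log_partial_likelihood(h, e, d), abs=1e-9)
        np.testing.assert_allclose(g.ravel() * e.sum(), cox_gradient(h, e, d),
                                   atol=1e-9)


def test_cox_ph_parameter_recovery():
    beta = np.array([1.0, -1.0, 0.5, 0.0, 0.0])
    co = linear_cohort(beta, n=2000, seed=3)
    ds = co.dataset
    Xz = (ds.features - ds.features.mean(0)) / ds.features.std(0)
    bh = fit_cox_ph(Xz, ds.events, ds.durations)
    assert np.abs(bh - beta).max() < 0.15
    # null covariates stay near zero
    assert np.abs(bh[3:]).max() < 0.1


def test_cox_ph_invariant_to_dataset_duplication():
    co = linear_cohort([0.8, -0.5], n=300, seed=1)
    ds = co.dataset
    b1 = fit_cox_ph(ds.features, ds.events, ds.durations)
    b2 = fit_cox_ph(np.vstack([ds.features] * 2), np.r_[ds.events, ds.events],
                    np.r_[ds.durations, ds.durations])
    np.testing.assert_allclose(b1, b2, atol=1e-4)


def test_linear_cox_network_matches_newton_fit():
    """Dual route: the depth-1 network trained with the Cox loss converges to
    the same coefficients as the Newton partial-likelihood fit."""
    beta = np.array([1.0, -1.0, 0.5, 0.0, 0.0])
    ds = linear_cohort(beta, n=2000, seed=3).dataset
    Xz = (ds.features - ds.features.mean(0)) / ds.features.std(0)
    bh = fit_cox_ph(Xz, ds.events, ds.durations)
    cfg = RiskModelConfig(depth=1, input_dim=5, loss="cox", learning_rate=0.05,
                          max_epochs=3000, patience=10**9, seed=0)
    m = fit_model(build_model(cfg), ds)
    assert np.abs(m.weights[0].ravel() - bh).max() < 0.05


def test_config_validation():
    with pytest.raises(ValueError, match="depth"):
        RiskModelConfig(depth=5)
    with pytest.raises(ValueError, match="linear"):
        RiskModelConfig(depth=1, pathway_informed=True)
    with pytest.raises(ValueError, match="bce"):
        RiskModelConfig(head="classification", loss="cox")
    with pytest.raises(ValueError, match="pathway matrix"):
        build_model(RiskModelConfig(pathway_informed=True), None)


def test_mask_feature_dimension_mismatch(paper_scale_pm):
    with pytest.raises(ValueError, match="input_dim"):
        build_model(RiskModelConfig(depth=3, input_dim=10, pathway_informed=True),
                    paper_scale_pm)


def test_checkpoint_round_trip(tmp_path, paper_scale_pm, small_cohort):
    ds = small_cohort.dataset
    cfg = RiskModelConfig(depth=3, input_dim=37, pathway_informed=True,
                          max_epochs=20, seed=4)
    m = fit_model(build_model(cfg, paper_scale_pm), ds.subset(np.arange(80)),
                  ds.subset(np.arange(80, 100)))
    path = tmp_path / "model.npz"
    save_checkpoint(m, path)
    m2 = load_checkpoint(path)
    np.testing.assert_array_equal(forward_risk(m, ds.features),
                                  forward_risk(m2, ds.features))
    assert m2.config == m.config
    assert m2.mask.pathway_names == paper_scale_pm.pathway_names


def test_all_losses_train_without_error(small_cohort, paper_scale_pm):
    ds = small_cohort.dataset
    tr, va = ds.subset(np.arange(80)), ds.subset(np.arange(80, 100))
    for loss in ("cox", "deephit", "pc_hazard"):
        cfg = RiskModelConfig(depth=2, input_dim=37, pathway_informed=True,
                              loss=loss, max_epochs=30, seed=0)
        m = fit_model(build_model(cfg, paper_scale_pm), tr, va)
        out = forward_risk(m, ds.features)
        assert np.all(np.isfinite(out))
        if loss == "deephit":
            np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-8)
        if loss == "pc_hazard":
            assert (out >= 0).all()
    cfg = RiskModelConfig(depth=2, input_dim=37, pathway_informed=True,
                          loss="bce", head="classification", max_epochs=30, seed=0)
    m = fit_model(build_model(cfg, paper_scale_pm), tr, va)
    probs = forward_risk(m, ds.features)
    assert ((probs > 0) & (probs < 1)).all()
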