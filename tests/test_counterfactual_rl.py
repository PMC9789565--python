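"""Autoencoder, DDPG losses and counterfactual generation contracts."""

import numpy as np
import pytest

from microcf import (RewardSpec, cf_losses, feature_bounds,
                     generate_counterfactual, generate_counterfactuals,
                     load_checkpoint, save_checkpoint, train_autoencoder,
                     train_ddpg)
from microcf.counterfactual_rl import Experience
from microcf.errors import ContractError, InputError, TrainingError


# ---------------------------------------------------------------------------
# autoencoder
# ---------------------------------------------------------------------------

def test_linear_autoencoder_recovers_low_rank_data():
    rng = np.random.default_rng(0)
    basis = rng.normal(size=(2, 10))
    x = rng.normal(size=(300, 2)) @ basis
    ae = train_autoencoder(x, latent_dim=2, epochs=300, seed=0,
                           hidden_sizes=(), activation="identity")
    assert ae.val_mse[-1] < 1e-3
    assert ae.val_mse[-1] < ae.val_mse[0]


def test_autoencoder_rejects_zero_epochs():
    with pytest.raises(TrainingError):
        train_autoencoder(np.random.default_rng(0).normal(size=(20, 4)),
                          latent_dim=2, epochs=0)


def test_autoencoder_deterministic_per_seed():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(50, 6))
    a1 = train_autoencoder(x, latent_dim=3, epochs=20, seed=5)
    a2 = train_autoencoder(x, latent_dim=3, epochs=20, seed=5)
    assert a1.train_mse == a2.train_mse
    assert a1.val_mse == a2.val_mse


# ---------------------------------------------------------------------------
# the three actor-update losses, checked via stubs
# ---------------------------------------------------------------------------

class _IdentityAE:
    def encode(self, x, c=None):
        return np.atleast_2d(x)


class _ConstantCritic:
    def __init__(self, q):
        self.q = q

    def critic_value(self, z, y_m, y_t, c, z_cf):
        return np.full(np.atleast_2d(z).shape[0], self.q)


def _exp(x, x_cf, z=None, z_cf=None):
    x = np.asarray(x, float)
    x_cf = np.asarray(x_cf, float)
    return Experience(x=x, z=x if z is None else np.asarray(z, float),
                      y_m=0.8, y_t=0,
                      c=np.zeros(0),
                      z_cf=x_cf if z_cf is None else np.asarray(z_cf, float),
                      x_cf=x_cf)


def test_sparsity_loss_zero_at_zero_delta():
    batch = [_exp([0.2, 0.4], [0.2, 0.4]), _exp([0.1, 0.3], [0.1, 0.3])]
    _, l_sp, _ = cf_losses(batch, (_IdentityAE(), _ConstantCritic(0.0), None))
    assert l_sp == 0.0


def test_sparsity_loss_is_mean_l1():
    batch = [_exp([0.2, 0.4], [0.3, 0.4])]
    _, l_sp, _ = cf_losses(batch, (_IdentityAE(), _ConstantCritic(0.0), None))
    assert l_sp == pytest.approx(0.1, abs=1e-12)


def test_max_loss_is_negated_constant_critic():
    batch = [_exp([0.2, 0.4], [0.3, 0.4])] * 3
    l_max, _, _ = cf_losses(batch, (_IdentityAE(), _ConstantCritic(0.7), None))
    assert l_max == pytest.approx(-0.7, abs=1e-12)


def test_consistency_loss_zero_at_encoding_fixed_point():
    # identity encoder and z_cf = x_cf: enc(x_cf) - z_cf = 0 exactly
    batch = [_exp([0.2, 0.4], [0.3, 0.5])]
    _, _, l_con = cf_losses(batch, (_IdentityAE(), _ConstantCritic(0.0), None))
    assert l_con == 0.0


def test_losses_reject_empty_and_mismatched_batches():
    from microcf.errors import DataError
    with pytest.raises(DataError):
        cf_losses([], (_IdentityAE(), _ConstantCritic(0.0), None))
    bad = Experience(x=np.zeros(2), z=np.zeros(2), y_m=0.5, y_t=0,
                     c=np.zeros(0), z_cf=np.zeros(2), x_cf=np.zeros(3))
    with pytest.raises(ContractError):
        cf_losses([bad], (_IdentityAE(), _ConstantCritic(0.0), None))


# ---------------------------------------------------------------------------
# generation contracts
# ---------------------------------------------------------------------------

class _IdentityActor:
    cond_dim = 0

    def act(self, z, y_m, y_t, c=None):
        return np.atleast_2d(z)


class _IdentityDecoderAE(_IdentityAE):
    latent_dim = 2

    def decode(self, z):
        return np.atleast_2d(z)


class _LinearClassifier:
    """Class 1 iff x1 > 0.5."""

    def predict_proba(self, x):
        x = np.atleast_2d(x)
        p1 = 1.0 / (1.0 + np.exp(-50 * (x[:, 0] - 0.5)))
        return np.column_stack([1 - p1, p1])


def test_identity_actor_gives_zero_delta():
    models = (_IdentityDecoderAE(), _IdentityActor(), _LinearClassifier())
    bounds = (np.zeros(2), np.ones(2))
    x = np.array([0.3, 0.6])
    cf = generate_counterfactual(x, 0, models, bounds)
    assert np.array_equal(cf.x_cf, x)
    assert np.all(cf.delta == 0.0)
    assert cf.valid  # x already classified as the target class 0
    cf2 = generate_counterfactual(x, 1, models, bounds)
    assert not cf2.valid


def test_counterfactual_identity_holds_bit_exact():
    rng = np.random.default_rng(3)
    models = (_IdentityDecoderAE(), _IdentityActor(), _LinearClassifier())
    bounds = (np.zeros(2), np.ones(2))
    for _ in range(20):
        x = rng.random(2)
        cf = generate_counterfactual(x, 0, models, bounds)
        assert np.array_equal(cf.x_cf, cf.x + cf.delta)
        assert np.all(cf.x_cf >= bounds[0]) and np.all(cf.x_cf <= bounds[1])


def test_out_of_bounds_input_rejected():
    models = (_IdentityDecoderAE(), _IdentityActor(), _LinearClassifier())
    with pytest.raises(InputError):
        generate_counterfactual(np.array([1.5, 0.2]), 0, models,
                                (np.zeros(2), np.ones(2)))


# ---------------------------------------------------------------------------
# end-to-end on the linearly separable toy task
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def trained_toy(linear_toy):
    x, y, clf = linear_toy
    ae = train_autoencoder(x, latent_dim=2, epochs=200, seed=1)
    ac = train_ddpg(x[y == 1], clf, ae, RewardSpec("indicator"), y_target=0,
                    lambda_s=0.5, lambda_c=0.5, steps=1500, seed=2,
                    bounds=feature_bounds(x))
    return x, y, clf, ae, ac


def test_toy_counterfactuals_cross_the_boundary(trained_toy):
    x, y, clf, ae, ac = trained_toy
    cfs = generate_counterfactuals(x[y == 1], 0, (ae, ac, clf),
                                   feature_bounds(x))
    validity = np.mean([c.valid for c in cfs])
    assert validity >= 0.9
    p_before = clf.predict_proba(x[y == 1])[:, 0].mean()
    p_after = clf.predict_proba(np.vstack([c.x_cf for c in cfs]))[:, 0].mean()
    assert p_after > p_before


def test_ddpg_critic_learns_constant_reward(linear_toy):
    x, y, clf = linear_toy

    class _AlwaysOne(RewardSpec):
        def compute(self, proba, y_target):
            return np.ones(np.atleast_2d(proba).shape[0])

    ae = train_autoencoder(x, latent_dim=2, epochs=50, seed=3)
    ac = train_ddpg(x, clf, ae, _AlwaysOne("indicator"), y_target=0,
                    steps=800, seed=4, bounds=feature_bounds(x))
    z = ae.encode(x[:50])
    q = ac.critic_value(z, clf.predict_proba(x[:50])[:, 1],
                        np.zeros(50), np.zeros((50, 0)), ac.actor(
                            ac.state(z, clf.predict_proba(x[:50])[:, 1],
                                     np.zeros(50), np.zeros((50, 0)))))
    assert abs(q.mean() - 1.0) < 0.05


def test_ddpg_deterministic_trajectory(linear_toy):
    x, y, clf = linear_toy
    ae = train_autoencoder(x, latent_dim=2, epochs=30, seed=5)
    kwargs = dict(y_target=0, steps=300, seed=6, bounds=feature_bounds(x))
    ac1 = train_ddpg(x, clf, ae, RewardSpec(), **kwargs)
    ac2 = train_ddpg(x, clf, ae, RewardSpec(), **kwargs)
    assert ac1.history["validity"] == ac2.history["validity"]
    assert ac1.history["l_sparsity"] == ac2.history["l_sparsity"]


def test_checkpoint_round_trip(tmp_path, trained_toy):
    x, y, clf, ae, ac = trained_toy
    prefix = str(tmp_path / "ckpt")
    save_checkpoint(prefix, ae, ac, manifest={"note": "toy"})
    ae2, ac2, meta = load_checkpoint(prefix)
    assert meta["note"] == "toy"
    z = ae.encode(x[:5])
    assert np.array_equal(z, ae2.encode(x[:5]))
    s = ac.state(z, np.zeros(5), np.zeros(5), np.zeros((5, 0)))
    assert np.array_equal(ac.actor(s), ac2.actor(s))
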