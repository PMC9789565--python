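"""Counterfactual generation for biomarker abundance profiles.

Given a classifier M over biomarker abundances, a counterfactual instance
for a sample x is x_CF = x + delta with M(x_CF) equal to a chosen target
class (healthy), with delta as sparse as possible.  The search runs in the
latent space of an autoencoder: an actor network mu maps the state
(z = enc(x), the model score of x, the target class, an optional
conditioning vector c) to a latent action z_CF, which decodes to
x_CF = clip(dec(z_CF), bounds).  A critic network Q regresses on the
immediate reward R = f(M(x_CF), y_T) and the actor descends

    grad_theta_mu ( L_max + lambda_s * L_sparsity + lambda_c * L_consist )

where L_max is the negated mean critic output, L_sparsity the mean L1
distance between x and x_CF, and L_consist the mean squared error between
enc(x_CF) and z_CF (the action should stay on the decoder's data manifold).
This is the deep-deterministic-policy-gradient scheme for a one-step
(contextual-bandit) episode: the critic needs no bootstrapped target.

All networks are small fully-connected numpy models (see ``_nets``); every
source of randomness is driven by a single seeded generator, so training
trajectories are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._nets import MLP, Adam
from .abundance_io import AbundanceTable
from .errors import ContractError, DataError, InputError, TrainingError

__all__ = [
    "AutoencoderModel", "ActorCritic", "RewardSpec", "Experience",
    "CFInstance", "train_autoencoder", "cf_losses", "train_ddpg",
    "generate_counterfactual", "generate_counterfactuals", "feature_bounds",
    "save_checkpoint", "load_checkpoint",
]


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, AbundanceTable):
        return data.matrix()
    return np.atleast_2d(np.asarray(data, dtype=float))


def feature_bounds(data) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature validity box: [0, observed max] of the training table."""
    x = _as_matrix(data)
    return np.zeros(x.shape[1]), x.max(axis=0)


# ---------------------------------------------------------------------------
# autoencoder
# ---------------------------------------------------------------------------

@dataclass
class AutoencoderModel:
    """Encoder/decoder pair over the biomarker feature space."""

    enc: MLP
    dec: MLP
    latent_dim: int
    seed: int
    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)

    def encode(self, x: np.ndarray, c: np.ndarray | None = None) -> np.ndarray:
        # conditioning is accepted for interface compatibility; the default
        # models are unconditional
        return self.enc(np.atleast_2d(x))

    def decode(self, z: np.ndarray) -> np.ndarray:
        return self.dec(np.atleast_2d(z))


def _default_width(p: int) -> int:
    return int(np.clip(2 * p, 16, 128))


def train_autoencoder(data, latent_dim: int, epochs: int = 200, seed: int = 0,
                      hidden_sizes: Sequence[int] | None = None,
                      activation: str = "tanh", lr: float = 1e-2,
                      batch_size: int = 32,
                      val_fraction: float = 0.1) -> AutoencoderModel:
    """Train a reconstruction autoencoder on abundance rows.

    ``hidden_sizes=()`` gives purely linear encoder/decoder maps.  A held-out
    split (``val_fraction``) tracks generalising reconstruction error per
    epoch.  Identical data, shape and seed give identical loss trajectories.
    """
    x = _as_matrix(data)
    n, p = x.shape
    if epochs < 1:
        raise TrainingError("epochs must be >= 1: no training performed")
    if latent_dim > p:
        raise DataError("latent_dim must be <= number of features")
    rng = np.random.default_rng(seed)
    hidden = list(hidden_sizes) if hidden_sizes is not None \
        else [_default_width(p), _default_width(p)]
    enc = MLP([p, *hidden, latent_dim], rng, hidden=activation)
    dec = MLP([latent_dim, *list(reversed(hidden)), p], rng, hidden=activation)
    opt = Adam(enc.params + dec.params, lr=lr)

    n_val = max(1, int(round(val_fraction * n))) if n > 2 else 0
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size == 0:
        train_idx, val_idx = order, order
    x_train, x_val = x[train_idx], x[val_idx] if n_val else x

    model = AutoencoderModel(enc=enc, dec=dec, latent_dim=latent_dim, seed=seed)
    for _ in range(epochs):
        perm = rng.permutation(len(x_train))
        epoch_loss = 0.0
        for start in range(0, len(x_train), batch_size):
            xb = x_train[perm[start:start + batch_size]]
            z, enc_cache = enc.forward(xb)
            xr, dec_cache = dec.forward(z)
            err = xr - xb
            loss = float((err ** 2).mean())
            if not np.isfinite(loss):
                raise TrainingError("autoencoder loss diverged (non-finite)")
            epoch_loss += loss * len(xb)
            g = 2.0 * err / err.size
            g_z, dec_grads = dec.backward(dec_cache, g)
            _, enc_grads = enc.backward(enc_cache, g_z)
            opt.step(enc_grads + dec_grads)
        model.train_mse.append(epoch_loss / len(x_train))
        val_err = dec(enc(x_val)) - x_val
        model.val_mse.append(float((val_err ** 2).mean()))
    return model


# ---------------------------------------------------------------------------
# reward, experiences, counterfactual instances
# ---------------------------------------------------------------------------

@dataclass
class RewardSpec:
    """Maps the classifier's verdict on x_CF and the target class to R in [0,1].

    ``indicator`` pays 1 when argmax M(x_CF) equals the target class;
    ``target_probability`` pays the predicted probability of the target.
    """

    mode: str = "indicator"

    def __post_init__(self) -> None:
        if self.mode not in ("indicator", "target_probability"):
            raise ContractError(f"unknown reward mode: {self.mode!r}")

    def compute(self, proba: np.ndarray, y_target: int) -> np.ndarray:
        proba = np.atleast_2d(proba)
        if self.mode == "indicator":
            return (np.argmax(proba, axis=1) == y_target).astype(float)
        return proba[:, y_target]


@dataclass
class Experience:
    """One actor transition: state components plus the latent action taken."""

    x: np.ndarray
    z: np.ndarray
    y_m: float          # classifier positive-class probability of x
    y_t: int            # target class index
    c: np.ndarray       # conditioning vector (may be empty)
    z_cf: np.ndarray
    x_cf: np.ndarray


@dataclass
class CFInstance:
    """A generated counterfactual with its audit quantities."""

    x: np.ndarray
    x_cf: np.ndarray
    delta: np.ndarray
    y_m: int
    y_t: int
    valid: bool
    sparsity_l0: int
    sparsity_l1: float

    def __post_init__(self) -> None:
        if not np.array_equal(self.x_cf, self.x + self.delta):
            raise ContractError("x_cf must equal x + delta exactly")


# ---------------------------------------------------------------------------
# actor-critic
# ---------------------------------------------------------------------------

@dataclass
class ActorCritic:
    """Actor mu(z, y_M, y_T, c) -> z_CF and critic Q(state, z_CF) -> scalar."""

    actor: MLP
    critic: MLP
    latent_dim: int
    cond_dim: int
    lambda_s: float
    lambda_c: float
    batch_size: int
    seed: int
    history: dict[str, list[float]] = field(default_factory=dict)

    def state(self, z: np.ndarray, y_m: np.ndarray, y_t: np.ndarray,
              c: np.ndarray | None = None) -> np.ndarray:
        z = np.atleast_2d(z)
        parts = [z, np.reshape(y_m, (-1, 1)), np.reshape(y_t, (-1, 1))]
        if self.cond_dim:
            parts.append(np.atleast_2d(c))
        return np.concatenate(parts, axis=1)

    def act(self, z, y_m, y_t, c=None) -> np.ndarray:
        return self.actor(self.state(z, y_m, y_t, c))

    def critic_value(self, z, y_m, y_t, c, z_cf) -> np.ndarray:
        s = self.state(z, y_m, y_t, c)
        return self.critic(np.concatenate([s, np.atleast_2d(z_cf)], axis=1))[:, 0]


def _stack_batch(batch: Sequence[Experience]):
    x = np.stack([np.asarray(e.x, dtype=float) for e in batch])
    z = np.stack([np.asarray(e.z, dtype=float) for e in batch])
    y_m = np.array([e.y_m for e in batch], dtype=float)
    y_t = np.array([e.y_t for e in batch], dtype=float)
    c = np.stack([np.asarray(e.c, dtype=float).ravel() for e in batch])
    z_cf = np.stack([np.asarray(e.z_cf, dtype=float) for e in batch])
    x_cf = np.stack([np.asarray(e.x_cf, dtype=float) for e in batch])
    return x, z, y_m, y_t, c, z_cf, x_cf


def cf_losses(batch: Sequence[Experience], models) -> tuple[float, float, float]:
    """(L_max, L_sparsity, L_consist) of a batch of experiences.

    ``models`` is ``(autoencoder, actor_critic, classifier)``; the
    autoencoder needs ``encode`` and the actor-critic ``critic_value`` (duck
    typed so that stubs can replace either).  The classifier is unused here —
    it enters through the reward, not the losses.
    """
    if not batch:
        raise DataError("batch must be non-empty")
    ae, ac, _classifier = models
    x, z, y_m, y_t, c, z_cf, x_cf = _stack_batch(batch)
    if x.shape != x_cf.shape or z.shape != z_cf.shape:
        raise ContractError("mismatched experience dimensions")
    q = np.asarray(ac.critic_value(z, y_m, y_t, c, z_cf), dtype=float)
    l_max = float(-np.mean(q))
    l_sparsity = float(np.abs(x - x_cf).sum(axis=1).mean())
    enc_cf = np.atleast_2d(ae.encode(x_cf, c))
    l_consist = float(((enc_cf - z_cf) ** 2).sum(axis=1).mean())
    return l_max, l_sparsity, l_consist


def _clip_decode(dec: MLP, a: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Decode and clip to the validity box; returns (x_cf, cache, pass mask)."""
    raw, cache = dec.forward(a)
    x_cf = np.clip(raw, lo, hi)
    mask = ((raw > lo) & (raw < hi)).astype(float)  # straight-through inside box
    return x_cf, cache, mask


def train_ddpg(data, classifier, ae: AutoencoderModel, reward: RewardSpec,
               y_target: int = 0, lambda_s: float = 0.5, lambda_c: float = 0.5,
               steps: int = 2000, seed: int = 0, batch_size: int = 64,
               actor_lr: float = 1e-3, critic_lr: float = 1e-3,
               noise_sigma: float = 0.2, buffer_size: int = 10000,
               hidden: int | None = None, eval_interval: int = 200,
               cond: np.ndarray | None = None,
               bounds: tuple[np.ndarray, np.ndarray] | None = None) -> ActorCritic:
    """Train the actor-critic counterfactual generator.

    Every instance in ``data`` is driven toward ``y_target``.  Exploration
    adds Gaussian noise to the latent action; the critic learns from a
    replay buffer of noisy actions, the actor from fresh deterministic ones.
    """
    x_all = _as_matrix(data)
    n, p = x_all.shape
    rng = np.random.default_rng(seed)
    lo, hi = bounds if bounds is not None else feature_bounds(x_all)
    z_all = ae.encode(x_all)
    proba_all = np.asarray(classifier.predict_proba(x_all), dtype=float)
    y_m_all = proba_all[:, 1]
    cond = np.zeros((n, 0)) if cond is None else np.atleast_2d(cond)
    cond_dim = cond.shape[1]

    latent = ae.latent_dim
    state_dim = latent + 2 + cond_dim
    width = hidden if hidden is not None else _default_width(latent)
    actor = MLP([state_dim, width, width, latent], rng)
    critic = MLP([state_dim + latent, width, width, 1], rng)
    ac = ActorCritic(actor=actor, critic=critic, latent_dim=latent,
                     cond_dim=cond_dim, lambda_s=lambda_s, lambda_c=lambda_c,
                     batch_size=batch_size, seed=seed)
    actor_opt = Adam(actor.params, lr=actor_lr)
    critic_opt = Adam(critic.params, lr=critic_lr)

    buf_s = np.zeros((buffer_size, state_dim))
    buf_a = np.zeros((buffer_size, latent))
    buf_r = np.zeros(buffer_size)
    buf_n = 0
    buf_ptr = 0

    hist: dict[str, list[float]] = {k: [] for k in
                                    ("step", "critic_loss", "l_max",
                                     "l_sparsity", "l_consist", "validity")}
    y_t_vec = np.full(batch_size, float(y_target))

    for step in range(1, steps + 1):
        idx = rng.integers(0, n, size=batch_size)
        s = ac.state(z_all[idx], y_m_all[idx], y_t_vec, cond[idx])

        # -- explore, observe reward, store -----------------------------
        a_det = actor(s)
        a_expl = a_det + noise_sigma * rng.standard_normal(a_det.shape)
        x_cf, _, _ = _clip_decode(ae.dec, a_expl, lo, hi)
        r = reward.compute(classifier.predict_proba(x_cf), y_target)
        for row in range(batch_size):
            buf_s[buf_ptr] = s[row]
            buf_a[buf_ptr] = a_expl[row]
            buf_r[buf_ptr] = r[row]
            buf_ptr = (buf_ptr + 1) % buffer_size
            buf_n = min(buf_n + 1, buffer_size)

        # -- critic: regress Q on the observed reward --------------------
        sample = rng.integers(0, buf_n, size=min(batch_size, buf_n))
        sa = np.concatenate([buf_s[sample], buf_a[sample]], axis=1)
        q, critic_cache = critic.forward(sa)
        err = q[:, 0] - buf_r[sample]
        critic_loss = float((err ** 2).mean())
        g_q = (2.0 * err / err.size)[:, None]
        _, critic_grads = critic.backward(critic_cache, g_q)
        critic_opt.step(critic_grads)

        # -- actor: descend L_max + lambda_s L_sparsity + lambda_c L_consist
        a, actor_cache = actor.forward(s)
        b = a.shape[0]

        sa_fresh = np.concatenate([s, a], axis=1)
        _, q_cache = critic.forward(sa_fresh)
        g_sa, _ = critic.backward(q_cache, np.full((b, 1), -1.0 / b))
        g_a = g_sa[:, state_dim:].copy()  # dL_max/da

        x_cf_det, dec_cache, box = _clip_decode(ae.dec, a, lo, hi)
        g_xcf_sparse = np.sign(x_cf_det - x_all[idx]) / b * box
        g_a_sparse, _ = ae.dec.backward(dec_cache, g_xcf_sparse)

        enc_cf, enc_cache = ae.enc.forward(x_cf_det)
        e = enc_cf - a
        g_e = 2.0 * e / b
        g_xcf_consist, _ = ae.enc.backward(enc_cache, g_e)
        g_a_consist_via_dec, _ = ae.dec.backward(dec_cache, g_xcf_consist * box)
        g_a_consist = g_a_consist_via_dec - g_e

        g_a += lambda_s * g_a_sparse + lambda_c * g_a_consist
        _, actor_grads = actor.backward(actor_cache, g_a)
        actor_opt.step(actor_grads)

        if step % eval_interval == 0 or step == steps:
            a_eval = actor(ac.state(z_all, y_m_all,
                                    np.full(n, float(y_target)), cond))
            x_cf_eval, _, _ = _clip_decode(ae.dec, a_eval, lo, hi)
            proba = classifier.predict_proba(x_cf_eval)
            validity = float((np.argmax(proba, axis=1) == y_target).mean())
            l1 = float(np.abs(x_cf_eval - x_all).sum(axis=1).mean())
            cons = float(((ae.encode(x_cf_eval) - a_eval) ** 2).sum(axis=1).mean())
            qv = ac.critic_value(z_all, y_m_all, np.full(n, float(y_target)),
                                 cond, a_eval)
            hist["step"].append(step)
            hist["critic_loss"].append(critic_loss)
            hist["l_max"].append(float(-qv.mean()))
            hist["l_sparsity"].append(l1)
            hist["l_consist"].append(cons)
            hist["validity"].append(validity)
    ac.history = hist
    return ac


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _exact_box(x: np.ndarray, raw: np.ndarray, lo: np.ndarray,
               hi: np.ndarray) -> np.ndarray:
    """delta such that x + delta is inside [lo, hi] bit-exactly."""
    delta = np.clip(raw, lo, hi) - x
    for _ in range(5):
        x_cf = x + delta
        clipped = np.clip(x_cf, lo, hi)
        if np.array_equal(clipped, x_cf):
            break
        delta = clipped - x
    return delta


def generate_counterfactual(x: np.ndarray, y_t: int, models,
                            bounds: tuple[np.ndarray, np.ndarray],
                            c: np.ndarray | None = None) -> CFInstance:
    """Generate one counterfactual instance for sample ``x``.

    ``models`` is ``(autoencoder, actor_critic, classifier)``.  The decoder
    output is clipped to the per-feature box and delta is defined so that
    ``x_cf == x + delta`` holds bit-exactly.
    """
    ae, ac, classifier = models
    x = np.asarray(x, dtype=float).ravel()
    lo, hi = bounds
    if np.any(x < lo) or np.any(x > hi):
        raise InputError("x lies outside the feature bounds")
    proba_x = np.asarray(classifier.predict_proba(x[None, :]))[0]
    y_m_class = int(np.argmax(proba_x))
    z = ae.encode(x[None, :])
    cond = np.zeros((1, ac.cond_dim)) if c is None else np.atleast_2d(c)
    z_cf = ac.act(z, np.array([proba_x[1]]), np.array([float(y_t)]), cond)
    raw = ae.decode(z_cf)[0]
    delta = _exact_box(x, raw, lo, hi)
    x_cf = x + delta
    proba_cf = np.asarray(classifier.predict_proba(x_cf[None, :]))[0]
    return CFInstance(
        x=x, x_cf=x_cf, delta=delta, y_m=y_m_class, y_t=int(y_t),
        valid=bool(int(np.argmax(proba_cf)) == int(y_t)),
        sparsity_l0=int(np.sum(np.abs(delta) > 1e-12)),
        sparsity_l1=float(np.abs(delta).sum()),
    )


def save_checkpoint(prefix: str, ae: AutoencoderModel, ac: ActorCritic,
                    manifest: dict | None = None) -> None:
    """Persist networks to ``<prefix>.npz`` plus a JSON manifest.

    The manifest records architecture and seeds (and whatever the caller
    adds, e.g. the classifier learner name and feature list so the
    classifier can be refit deterministically at generation time).
    """
    import json
    from pathlib import Path

    arrays: dict[str, np.ndarray] = {}
    meta: dict = dict(manifest or {})
    meta["networks"] = {}
    for name, net in (("enc", ae.enc), ("dec", ae.dec),
                      ("actor", ac.actor), ("critic", ac.critic)):
        meta["networks"][name] = {"sizes": net.sizes, "hidden": net.hidden,
                                  "out": net.out}
        for i, (w, b) in enumerate(zip(net.weights, net.biases)):
            arrays[f"{name}_w{i}"] = w
            arrays[f"{name}_b{i}"] = b
    meta["latent_dim"] = ae.latent_dim
    meta["cond_dim"] = ac.cond_dim
    meta["lambda_s"] = ac.lambda_s
    meta["lambda_c"] = ac.lambda_c
    meta["ae_seed"] = ae.seed
    meta["ac_seed"] = ac.seed
    np.savez(f"{prefix}.npz", **arrays)
    Path(f"{prefix}.json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(prefix: str) -> tuple[AutoencoderModel, ActorCritic, dict]:
    """Load networks saved by :func:`save_checkpoint`."""
    import json
    from pathlib import Path

    meta = json.loads(Path(f"{prefix}.json").read_text())
    data = np.load(f"{prefix}.npz")
    rng = np.random.default_rng(0)
    nets = {}
    for name, spec in meta["networks"].items():
        net = MLP(spec["sizes"], rng, hidden=spec["hidden"], out=spec["out"])
        for i in range(net.n_layers):
            net.weights[i] = data[f"{name}_w{i}"]
            net.biases[i] = data[f"{name}_b{i}"]
        nets[name] = net
    ae = AutoencoderModel(enc=nets["enc"], dec=nets["dec"],
                          latent_dim=int(meta["latent_dim"]),
                          seed=int(meta["ae_seed"]))
    ac = ActorCritic(actor=nets["actor"], critic=nets["critic"],
                     latent_dim=int(meta["latent_dim"]),
                     cond_dim=int(meta["cond_dim"]),
                     lambda_s=float(meta["lambda_s"]),
                     lambda_c=float(meta["lambda_c"]),
                     batch_size=0, seed=int(meta["ac_seed"]))
    return ae, ac, meta


def generate_counterfactuals(data, y_t: int, models,
                             bounds: tuple[np.ndarray, np.ndarray] | None = None
                             ) -> list[CFInstance]:
    """Vector-batched convenience wrapper over :func:`generate_counterfactual`."""
    x = _as_matrix(data)
    if bounds is None:
        bounds = feature_bounds(x)
    return [generate_counterfactual(x[i], y_t, models, bounds)
            for i in range(x.shape[0])]
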