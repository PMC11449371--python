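"""Wasserstein GAN with gradient penalty for bulk expression profiles.

Generator and critic are small fully connected networks written directly on
NumPy, with reverse-mode gradients derived by hand. The gradient penalty
lambda * E[(||grad_x D(x_hat)|| - 1)^2] needs the gradient of an input
gradient with respect to the critic parameters; this is computed exactly by
a forward-over-reverse pass (a Jacobian-vector product through the critic
followed by backpropagation through that extended graph), not by finite
differences. All gradients are verified against numerical differentiation
in the test suite.

Training follows the usual WGAN-GP recipe: ``critic_steps`` critic updates
per generator update, RMSprop for both players, generator checkpoints kept
at several late-training steps so downstream simulation can average over
model snapshots.
"""

from __future__ import annotations

import copy
import json
import logging
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import pearson_rows, child_seed
from .data_io import ExpressionMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Activations: value, first and second derivative (second derivative is
# needed by the double-backprop pass; it is identically zero for piecewise
# linear activations).
# ---------------------------------------------------------------------------

def _leaky_relu(a):
    return np.where(a > 0, a, 0.2 * a)


def _leaky_relu_p(a):
    return np.where(a > 0, 1.0, 0.2)


def _tanh_p(a):
    return 1.0 - np.tanh(a) ** 2


def _tanh_pp(a):
    t = np.tanh(a)
    return -2.0 * t * (1.0 - t * t)


ACTIVATIONS = {
    "leaky_relu": (_leaky_relu, _leaky_relu_p, lambda a: np.zeros_like(a)),
    "tanh": (np.tanh, _tanh_p, _tanh_pp),
    "identity": (lambda a: a, lambda a: np.ones_like(a), lambda a: np.zeros_like(a)),
}


class MLP:
    """Fully connected network; hidden layers share one activation, output is linear."""

    def __init__(self, sizes, activation="leaky_relu", rng=None, dtype=np.float64):
        if len(sizes) < 2:
            raise ValueError("need at least input and output sizes")
        if activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        rng = np.random.default_rng(rng)
        self.sizes = list(sizes)
        self.activation = activation
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.W.append(rng.normal(0.0, scale, size=(fan_out, fan_in)).astype(dtype))
            self.b.append(np.zeros(fan_out, dtype=dtype))

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def _acts(self, layer: int):
        # hidden layers use self.activation, the last layer is linear
        name = self.activation if layer < self.n_layers - 1 else "identity"
        return ACTIVATIONS[name]

    # -- forward ---------------------------------------------------------------
    def forward(self, x, want_cache=False):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        h = [x]
        a = []
        for l in range(self.n_layers):
            f, _, _ = self._acts(l)
            al = h[-1] @ self.W[l].T + self.b[l]
            a.append(al)
            h.append(f(al))
        if want_cache:
            return h[-1], (h, a)
        return h[-1]

    __call__ = forward

    # -- reverse mode ----------------------------------------------------------
    def backward(self, cache, dout):
        """Parameter gradients and input gradient of sum(dout * output)."""
        h, a = cache
        gW = [None] * self.n_layers
        gb = [None] * self.n_layers
        d = np.asarray(dout, dtype=float)
        for l in range(self.n_layers - 1, -1, -1):
            _, fp, _ = self._acts(l)
            d = d * fp(a[l])
            gW[l] = d.T @ h[l]
            gb[l] = d.sum(axis=0)
            d = d @ self.W[l]
        return (gW, gb), d

    def input_gradient(self, x):
        """grad_x of the (scalar) output, one row per input row."""
        if self.sizes[-1] != 1:
            raise ValueError("input_gradient requires a scalar-output network")
        out, cache = self.forward(x, want_cache=True)
        _, dx = self.backward(cache, np.ones_like(out))
        return dx

    # -- gradient penalty and its parameter gradients ----------------------------
    def penalty_and_grads(self, xhat, eps=1e-12):
        """mean((||grad_x D(xhat)|| - 1)^2) and its exact parameter gradients.

        Chain rule: with g(theta) = grad_x D(xhat; theta) and v = dP/dg held
        fixed, dP/dtheta equals the theta-gradient of sum(v . g), which is a
        directional (forward-mode) derivative of the critic with input
        tangent v, backpropagated through the doubled computation graph.
        """
        B = xhat.shape[0]
        out, cache = self.forward(xhat, want_cache=True)
        h, a = cache
        _, g = self.backward(cache, np.ones_like(out))
        norm = np.sqrt(np.einsum("ij,ij->i", g, g))
        penalty = float(np.mean((norm - 1.0) ** 2))
        v = (2.0 / B) * ((norm - 1.0) / np.maximum(norm, eps))[:, None] * g

        # forward tangent pass: t_l is the JVP of h_l in direction v
        ts = [v]
        tas = []
        for l in range(self.n_layers):
            _, fp, _ = self._acts(l)
            ta = ts[-1] @ self.W[l].T
            tas.append(ta)
            ts.append(fp(a[l]) * ta)

        # reverse pass through the doubled graph
        gW = [np.zeros_like(W) for W in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        dt = np.ones_like(ts[-1])
        dh = np.zeros_like(h[-1])
        for l in range(self.n_layers - 1, -1, -1):
            _, fp, fpp = self._acts(l)
            fpa = fp(a[l])
            dta = dt * fpa
            da = dt * tas[l] * fpp(a[l]) + dh * fpa
            gW[l] = dta.T @ ts[l] + da.T @ h[l]
            gb[l] = da.sum(axis=0)
            dt = dta @ self.W[l]
            dh = da @ self.W[l]
        return penalty, (gW, gb)

    # -- parameter plumbing -----------------------------------------------------
    def parameters(self):
        return self.W + self.b

    def copy(self):
        return copy.deepcopy(self)


class RMSprop:
    """RMSprop with the usual running second-moment normalization."""

    def __init__(self, params, lr=1e-3, rho=0.9, eps=1e-8):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.cache = [np.zeros_like(p) for p in params]

    def step(self, grads):
        for p, c, g in zip(self.params, self.cache, grads):
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def gradient_penalty(critic: MLP, x_real, x_fake, rng) -> float:
    """Penalty on random interpolates x_hat = eps*x_real + (1-eps)*x_fake."""
    x_real = np.asarray(x_real, dtype=float)
    x_fake = np.asarray(x_fake, dtype=float)
    if x_real.shape != x_fake.shape:
        raise ValueError(f"batch shape mismatch: {x_real.shape} vs {x_fake.shape}")
    rng = np.random.default_rng(rng)
    eps = rng.uniform(0.0, 1.0, size=(x_real.shape[0], 1))
    xhat = eps * x_real + (1.0 - eps) * x_fake
    g = critic.input_gradient(xhat)
    norm = np.sqrt(np.einsum("ij,ij->i", g, g))
    return float(np.mean((norm - 1.0) ** 2))


def wgan_gp_loss(critic: MLP, x_real, x_fake, lambda_gp: float = 10.0, rng=0):
    """(critic_loss, generator_loss) of the penalized Wasserstein objective.

    critic_loss = E[D(fake)] - E[D(real)] + lambda * penalty;
    generator_loss = -E[D(fake)].
    """
    x_real = np.asarray(x_real, dtype=float)
    x_fake = np.asarray(x_fake, dtype=float)
    if x_real.shape != x_fake.shape:
        raise ValueError(f"batch shape mismatch: {x_real.shape} vs {x_fake.shape}")
    d_real = critic(x_real).mean()
    d_fake = critic(x_fake).mean()
    pen = gradient_penalty(critic, x_real, x_fake, rng)
    return float(d_fake - d_real + lambda_gp * pen), float(-d_fake)


# ---------------------------------------------------------------------------
# Configuration and trained-model containers
# ---------------------------------------------------------------------------

@dataclass
class GanConfig:
    """Hyperparameters of the adversarial trainer (desk-scale defaults)."""

    latent_dim: int = 32
    hidden: tuple[int, ...] = (128, 128)
    lambda_gp: float = 10.0
    critic_steps: int = 5
    learning_rate: float = 1e-3
    batch_size: int = 64
    total_steps: int = 2000
    checkpoint_steps: tuple[int, ...] | None = None
    n_checkpoints: int = 10
    quality_threshold: float = 0.95
    activation: str = "leaky_relu"
    standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.lambda_gp <= 0:
            raise ValueError("lambda_gp must be > 0")
        if not (0 < self.quality_threshold <= 1):
            raise ValueError("quality_threshold must be in (0, 1]")
        if self.checkpoint_steps is None:
            # evenly spaced snapshots across the second half of training
            lo = self.total_steps // 2
            self.checkpoint_steps = tuple(
                int(s) for s in np.linspace(lo, self.total_steps, self.n_checkpoints)
            )
        self.checkpoint_steps = tuple(sorted(int(s) for s in self.checkpoint_steps))
        if list(self.checkpoint_steps) != sorted(set(self.checkpoint_steps)):
            raise ValueError("checkpoint_steps must be strictly ascending")


@dataclass
class GeneratorCheckpoint:
    """A generator snapshot plus the per-gene scaling needed to emit log-expression."""

    net: MLP
    step: int
    gene_ids: list[str]
    mu: np.ndarray
    sd: np.ndarray

    @property
    def latent_dim(self) -> int:
        return self.net.sizes[0]

    def generate(self, z, dtype=np.float32) -> np.ndarray:
        """Map latent rows to expression rows on the original log scale.

        Decoding defaults to single precision: screening tens of thousands of
        candidate latents is matrix-multiply bound and float32 is far faster,
        while the ~1e-7 relative rounding is orders of magnitude below the
        biological noise floor. Pass dtype=np.float64 where exact double
        arithmetic matters (e.g. algebraic identities of a linear generator).
        """
        z = np.atleast_2d(np.asarray(z, dtype=dtype))
        if dtype == np.float64:
            x = self.net(z)
        else:
            h = z
            for l in range(self.net.n_layers):
                f, _, _ = self.net._acts(l)
                h = f(h @ self.net.W[l].T.astype(dtype) + self.net.b[l].astype(dtype))
            x = h
        return np.asarray(x, dtype=float) * self.sd + self.mu

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "GeneratorCheckpoint":
        with open(path, "rb") as fh:
            return pickle.load(fh)


@dataclass
class TrainResult:
    checkpoints: list[GeneratorCheckpoint]
    critic: MLP
    history: pd.DataFrame
    config: GanConfig

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for ck in self.checkpoints:
            ck.save(out / f"generator_step{ck.step:06d}.pkl")
        self.history.to_csv(out / "training_log.csv", index=False)
        cfg = asdict(self.config)
        cfg["checkpoint_steps"] = list(cfg["checkpoint_steps"])
        cfg["hidden"] = list(cfg["hidden"])
        with open(out / "gan_config.json", "w") as fh:
            json.dump(cfg, fh, indent=1)

    @staticmethod
    def load_checkpoints(out_dir) -> list[GeneratorCheckpoint]:
        paths = sorted(Path(out_dir).glob("generator_step*.pkl"))
        return [GeneratorCheckpoint.load(p) for p in paths]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(X: ExpressionMatrix, config: GanConfig) -> TrainResult:
    """Train a WGAN-GP on an (augmented) expression matrix.

    Both groups are trained jointly: the generator must span the control and
    treated states so that latent interpolation between them is meaningful.
    Raises on non-finite losses (divergence) rather than returning garbage.
    """
    rng = np.random.default_rng(config.seed)
    data = X.matrix()  # samples x genes
    n_samples, n_genes = data.shape
    if config.standardize:
        mu = data.mean(axis=0)
        sd = data.std(axis=0)
        sd[sd == 0] = 1.0
    else:
        mu = np.zeros(n_genes)
        sd = np.ones(n_genes)
    train_data = (data - mu) / sd

    d = config.latent_dim
    gen = MLP([d, *config.hidden, n_genes], config.activation, rng=child_seed(config.seed, 1))
    critic = MLP([n_genes, *config.hidden, 1], config.activation, rng=child_seed(config.seed, 2))
    opt_g = RMSprop(gen.parameters(), lr=config.learning_rate)
    opt_c = RMSprop(critic.parameters(), lr=config.learning_rate)
    B = min(config.batch_size, n_samples)

    checkpoints: list[GeneratorCheckpoint] = []
    records = []
    ckpt_set = set(config.checkpoint_steps)
    for step in range(1, config.total_steps + 1):
        # critic updates
        for _ in range(config.critic_steps):
            idx = rng.integers(0, n_samples, size=B)
            x_real = train_data[idx]
            z = rng.standard_normal((B, d))
            x_fake = gen(z)
            # Wasserstein part: d/dtheta [mean D(fake) - mean D(real)]
            out_f, cache_f = critic.forward(x_fake, want_cache=True)
            (gWf, gbf), _ = critic.backward(cache_f, np.full_like(out_f, 1.0 / B))
            out_r, cache_r = critic.forward(x_real, want_cache=True)
            (gWr, gbr), _ = critic.backward(cache_r, np.full_like(out_r, -1.0 / B))
            eps = rng.uniform(0.0, 1.0, size=(B, 1))
            xhat = eps * x_real + (1.0 - eps) * x_fake
            pen, (gWp, gbp) = critic.penalty_and_grads(xhat)
            grads = [
                gf + gr + config.lambda_gp * gp
                for gf, gr, gp in zip(gWf + gbf, gWr + gbr, gWp + gbp)
            ]
            opt_c.step(grads)
            critic_loss = float(out_f.mean() - out_r.mean() + config.lambda_gp * pen)

        # generator update: minimize -mean D(G(z))
        z = rng.standard_normal((B, d))
        x_fake, cache_g = gen.forward(z, want_cache=True)
        out_f, cache_f = critic.forward(x_fake, want_cache=True)
        _, dx = critic.backward(cache_f, np.full_like(out_f, -1.0 / B))
        (gWg, gbg), _ = gen.backward(cache_g, dx)
        opt_g.step(gWg + gbg)
        gen_loss = float(-out_f.mean())

        if not (np.isfinite(critic_loss) and np.isfinite(gen_loss)):
            raise RuntimeError(
                f"training diverged at step {step}: critic_loss={critic_loss}, "
                f"gen_loss={gen_loss}"
            )
        records.append((step, critic_loss, gen_loss, pen))
        if step in ckpt_set:
            checkpoints.append(
                GeneratorCheckpoint(
                    net=gen.copy(), step=step, gene_ids=X.gene_ids, mu=mu.copy(), sd=sd.copy()
                )
            )
        if step % max(1, config.total_steps // 10) == 0:
            log.info(
                "step %d/%d critic_loss=%.4f gen_loss=%.4f penalty=%.4f",
                step, config.total_steps, critic_loss, gen_loss, pen,
            )

    history = pd.DataFrame(records, columns=["step", "critic_loss", "gen_loss", "penalty"])
    return TrainResult(checkpoints=checkpoints, critic=critic, history=history, config=config)


# ---------------------------------------------------------------------------
# Generation quality
# ---------------------------------------------------------------------------

@dataclass
class QualityReport:
    best_r: pd.Series
    gene_mean_r: float
    gene_var_r: float
    threshold: float

    @property
    def passes(self) -> bool:
        return bool((self.best_r >= self.threshold).all())


def generation_quality(
    gen: GeneratorCheckpoint,
    X_real: ExpressionMatrix,
    n_draws: int = 2000,
    seed: int = 0,
    threshold: float = 0.95,
) -> QualityReport:
    """Distributional check of a trained generator against the real samples.

    Reports, per real sample, the best Pearson correlation against ``n_draws``
    generated profiles (the gate the simulation stage enforces at 0.95), plus
    the correlation of per-gene means and variances between the real and
    generated sets -- a quantitative surrogate for visual overlap checks of
    real and fake samples in an embedding.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, gen.latent_dim))
    fakes = gen.generate(z)
    real = X_real.matrix()
    best = [float(pearson_rows(fakes, real[i]).max()) for i in range(real.shape[0])]
    from ._utils import pearson

    gene_mean_r = pearson(fakes.mean(axis=0), real.mean(axis=0))
    # variance correlation is meaningless if either side is constant
    fv, rv = fakes.var(axis=0), real.var(axis=0)
    gene_var_r = pearson(fv, rv) if fv.std() > 0 and rv.std() > 0 else float("nan")
    report = QualityReport(
        best_r=pd.Series(best, index=X_real.sample_ids, name="best_r"),
        gene_mean_r=gene_mean_r,
        gene_var_r=gene_var_r,
        threshold=threshold,
    )
    if not report.passes:
        log.warning(
            "generation quality gate not met: min best_r = %.4f < %.2f",
            report.best_r.min(), threshold,
        )
    return report
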