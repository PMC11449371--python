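"""Resembled fakes, latent interpolation, and trajectory averaging.

For every real sample a "resembled fake" is built: draw a large pool of
latent vectors, rank the generated profiles by Pearson correlation against
the target sample, and average the k best latents (all of which must meet
the 0.95 correlation gate). Interpolating between the control and treated
resembled-fake latents, z_i = z_SN + (z_CN - z_SN) * i/100 for i = 1..99,
and decoding through the generator yields a 101-timestep transcriptome
trajectory per SN x CN pair. Averaging trajectories over all pairs and over
several generator checkpoints gives the simulated time-course profile that
the network and differential-expression stages consume.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import pearson, pearson_rows, child_seed
from .data_io import ExpressionMatrix, GROUP_CONTROL, GROUP_TREATED
from .gan import GeneratorCheckpoint

log = logging.getLogger(__name__)

N_CANDIDATES = 35_000
K_NEAREST = 10
QUALITY_THRESHOLD = 0.95
N_INTERMEDIATE = 99


class ResembledFakeError(RuntimeError):
    """Raised when no resembled fake meets the gate within the retry budget."""

    def __init__(self, sample_id: str, best_r: float, retries: int):
        self.sample_id = sample_id
        self.best_r = best_r
        super().__init__(
            f"resembled fake failed for sample {sample_id!r} after {retries} seed "
            f"retries; best Pearson attained = {best_r:.4f}"
        )


@dataclass
class ResembledFake:
    sample_id: str
    z_bar: np.ndarray
    achieved_r: float
    contributing_r: np.ndarray
    seed_used: int
    n_candidates: int
    k: int
    retries: int


@dataclass
class SimulationConfig:
    n_candidates: int = N_CANDIDATES
    k: int = K_NEAREST
    threshold: float = QUALITY_THRESHOLD
    max_retries: int = 20
    steps: int = N_INTERMEDIATE
    seed: int = 0


def resembled_fake(
    gen: GeneratorCheckpoint,
    x_target: np.ndarray,
    sample_id: str = "",
    n_candidates: int = N_CANDIDATES,
    k: int = K_NEAREST,
    threshold: float = QUALITY_THRESHOLD,
    max_retries: int = 20,
    seed: int = 0,
) -> ResembledFake:
    """Average of the k latents whose decodings best match a real sample.

    A draw is successful when the k selected correlations and the correlation
    of G(z_bar) itself all reach ``threshold``; otherwise the candidate pool
    is redrawn with a new derived seed, up to ``max_retries`` times.
    """
    if k > n_candidates:
        raise ValueError("k cannot exceed n_candidates")
    x_target = np.asarray(x_target, dtype=float).ravel()
    best_seen = -np.inf
    for retry in range(max_retries + 1):
        retry_seed = child_seed(seed, retry)
        rng = np.random.default_rng(retry_seed)
        z = rng.standard_normal((n_candidates, gen.latent_dim))
        fakes = gen.generate(z)
        r = pearson_rows(fakes, x_target)
        top = np.argsort(r)[::-1][:k]
        best_seen = max(best_seen, float(r[top[0]]))
        if r[top[-1]] < threshold:
            continue
        z_bar = z[top].mean(axis=0)
        achieved = pearson(gen.generate(z_bar[None])[0], x_target)
        if achieved < threshold:
            continue
        return ResembledFake(
            sample_id=sample_id,
            z_bar=z_bar,
            achieved_r=achieved,
            contributing_r=np.sort(r[top])[::-1],
            seed_used=retry_seed,
            n_candidates=n_candidates,
            k=k,
            retries=retry,
        )
    raise ResembledFakeError(sample_id, best_seen, max_retries)


def interpolate_pair(
    gen: GeneratorCheckpoint,
    z_sn: np.ndarray,
    z_cn: np.ndarray,
    steps: int = N_INTERMEDIATE,
    dtype=np.float32,
) -> np.ndarray:
    """Decode the latent segment from a control to a treated resembled fake.

    Returns a (steps + 2) x genes matrix: row 0 is G(z_SN), rows 1..steps are
    the decoded intermediates at fractions i/(steps+1), row steps+1 is G(z_CN).
    """
    z_sn = np.asarray(z_sn, dtype=float).ravel()
    z_cn = np.asarray(z_cn, dtype=float).ravel()
    if z_sn.shape != z_cn.shape:
        raise ValueError(f"latent length mismatch: {z_sn.shape} vs {z_cn.shape}")
    frac = np.arange(steps + 2, dtype=float)[:, None] / (steps + 1)
    zs = z_sn[None, :] + (z_cn - z_sn)[None, :] * frac
    return gen.generate(zs, dtype=dtype)


@dataclass
class TrajectoryStack:
    """Repeat x timestep x gene simulated expression.

    The repeat axis indexes generator checkpoints; each slice is already the
    mean over all SN x CN pair trajectories for that checkpoint. The mean
    over the repeat axis is the averaged profile consumed by the network
    stage; the repeat-level slices double as biological replicas for the
    serial differential-expression test.
    """

    values: np.ndarray
    gene_ids: list[str]
    checkpoint_steps: list[int]
    fake_log: pd.DataFrame = field(default=None, repr=False)
    pair_values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError("values must be repeat x timestep x gene")

    @property
    def n_repeats(self) -> int:
        return self.values.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[1]

    @property
    def timesteps(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, self.n_timesteps)

    def averaged_profile(self) -> pd.DataFrame:
        """Timestep x gene mean over the repeat axis (the WGCNA input)."""
        return pd.DataFrame(
            self.values.mean(axis=0),
            index=np.arange(self.n_timesteps),
            columns=self.gene_ids,
        )

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.save(out / "trajectory_stack.npy", self.values)
        index = {
            "gene_ids": self.gene_ids,
            "checkpoint_steps": [int(s) for s in self.checkpoint_steps],
            "n_timesteps": int(self.n_timesteps),
        }
        with open(out / "trajectory_index.json", "w") as fh:
            json.dump(index, fh)
        if self.fake_log is not None:
            self.fake_log.to_csv(out / "resembled_fakes.tsv", sep="\t", index=False)
        self.averaged_profile().to_csv(out / "averaged_profile.tsv", sep="\t")

    @staticmethod
    def load(out_dir) -> "TrajectoryStack":
        out = Path(out_dir)
        values = np.load(out / "trajectory_stack.npy")
        with open(out / "trajectory_index.json") as fh:
            index = json.load(fh)
        log_path = out / "resembled_fakes.tsv"
        fake_log = pd.read_csv(log_path, sep="\t") if log_path.exists() else None
        return TrajectoryStack(
            values=values,
            gene_ids=index["gene_ids"],
            checkpoint_steps=index["checkpoint_steps"],
            fake_log=fake_log,
        )


def average_profile(
    checkpoints: list[GeneratorCheckpoint],
    X_real: ExpressionMatrix,
    config: SimulationConfig | None = None,
    keep_pairs: bool = False,
) -> TrajectoryStack:
    """Simulate the full time course: fakes -> pair trajectories -> averages.

    Per checkpoint: build resembled fakes for every real sample, decode the
    latent segment of every SN x CN combination, and average the pair
    trajectories into one timestep x gene matrix. Stacking the checkpoints
    gives the repeat axis. Any sample that fails the resembled-fake gate
    aborts the simulation with the list of failures.
    """
    config = config or SimulationConfig()
    if not checkpoints:
        raise ValueError("need at least one generator checkpoint")
    X_real.require_two_groups(min_per_group=1)
    sn = X_real.samples_in(GROUP_CONTROL)
    cn = X_real.samples_in(GROUP_TREATED)
    real = X_real.values
    n_t = config.steps + 2

    slices = []
    pair_slices = []
    log_rows = []
    failures = []
    for ci, gen in enumerate(checkpoints):
        fakes: dict[str, ResembledFake] = {}
        for si, sample in enumerate([*sn, *cn]):
            try:
                rf = resembled_fake(
                    gen,
                    real[sample].to_numpy(),
                    sample_id=sample,
                    n_candidates=config.n_candidates,
                    k=config.k,
                    threshold=config.threshold,
                    max_retries=config.max_retries,
                    seed=child_seed(config.seed, ci, si),
                )
            except ResembledFakeError as err:
                failures.append(str(err))
                continue
            fakes[sample] = rf
            log_rows.append(
                {
                    "checkpoint_step": gen.step,
                    "sample_id": sample,
                    "n_candidates": rf.n_candidates,
                    "k": rf.k,
                    "achieved_r": rf.achieved_r,
                    "min_contributing_r": float(rf.contributing_r.min()),
                    "retries": rf.retries,
                    "seed_used": rf.seed_used,
                }
            )
        if failures:
            continue
        acc = np.zeros((n_t, X_real.n_genes))
        pairs = np.zeros((len(sn) * len(cn), n_t, X_real.n_genes)) if keep_pairs else None
        pi = 0
        for s in sn:
            for c in cn:
                traj = interpolate_pair(gen, fakes[s].z_bar, fakes[c].z_bar, config.steps)
                acc += traj
                if keep_pairs:
                    pairs[pi] = traj
                pi += 1
        slices.append(acc / (len(sn) * len(cn)))
        if keep_pairs:
            pair_slices.append(pairs)
    if failures:
        raise ResembledFakeError(
            "; ".join(failures), float("nan"), config.max_retries
        )
    stack = TrajectoryStack(
        values=np.stack(slices),
        gene_ids=X_real.gene_ids,
        checkpoint_steps=[g.step for g in checkpoints],
        fake_log=pd.DataFrame(log_rows),
        pair_values=np.stack(pair_slices) if keep_pairs else None,
    )
    log.info(
        "simulated %d repeats x %d timesteps x %d genes (%d pair trajectories each)",
        stack.n_repeats, stack.n_timesteps, len(stack.gene_ids), len(sn) * len(cn),
    )
    return stack
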