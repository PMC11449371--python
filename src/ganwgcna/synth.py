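"""Synthetic two-condition bulk expression with planted module structure.

The generator emulates the data regime the pipeline is designed for: a
control group ("SN") and a treated group ("CN") observed only at the two
endpoints of an unobserved 0..100 pseudo-time course. Genes are organised
into planted co-expression modules, each driven by one latent activity that
follows a trajectory archetype:

* ``monotone_up``     -- linear rise from 0 to ``effect_size``;
* ``monotone_down``   -- linear fall from ``effect_size`` to 0;
* ``intermediate_peak`` -- a Gaussian bump centred strictly inside (0, 100),
  with near-zero endpoint difference (the genes a conventional endpoint DEG
  comparison misses, and the rescue analysis should recover);
* ``flat``            -- constant in pseudo-time (module activity varies
  only through per-sample biological jitter).

A behavioral trait (addiction index, zero for controls) is loaded on exactly
one planted module, so module-trait alignment has a known positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, TraitTable, GROUP_CONTROL, GROUP_TREATED

ARCHETYPES = ("monotone_up", "monotone_down", "intermediate_peak", "flat")

#: default archetype cycle for planted modules (module 1 carries the trait)
DEFAULT_ARCHETYPES = ("monotone_up", "monotone_down", "intermediate_peak", "intermediate_peak", "flat")
DEFAULT_PEAK_TIMES = (40.0, 60.0)
PEAK_WIDTH = 15.0  # sd of the Gaussian bump, in pseudo-time units

# Study-condition defaults: 300 genes in 5 modules of 50 plus background,
# 12 samples per group, a 2-unit log2 separation and 0.25 log2 residual sd
# (typical bulk RNA-seq residual variability on the log scale).
DEFAULT_N_GENES = 300
DEFAULT_N_MODULES = 5
DEFAULT_SAMPLES_PER_GROUP = 12
DEFAULT_EFFECT_SIZE = 2.0
DEFAULT_NOISE_SD = 0.25
DEFAULT_JITTER_SD = 0.3
DEFAULT_TRAIT_NOISE_SD = 0.1
MIN_MODULE_SIZE = 10


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic fixture (module ids are 1-based; 0 = background)."""

    module_of_gene: pd.Series
    archetype_of_module: dict[int, str]
    peak_time: dict[int, float]
    trait_module: int
    effect_size: float
    noise_sd: float
    loadings: pd.Series = field(repr=False, default=None)
    baseline: pd.Series = field(repr=False, default=None)

    def genes_of(self, module: int) -> list[str]:
        return list(self.module_of_gene.index[self.module_of_gene == module])

    def to_json(self, path) -> None:
        payload = {
            "module_of_gene": {g: int(m) for g, m in self.module_of_gene.items()},
            "archetype_of_module": {str(k): v for k, v in self.archetype_of_module.items()},
            "peak_time": {str(k): v for k, v in self.peak_time.items()},
            "trait_module": self.trait_module,
            "effect_size": self.effect_size,
            "noise_sd": self.noise_sd,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def truth_trajectory(truth: SyntheticTruth, module: int, t) -> np.ndarray:
    """Noiseless latent activity of a planted module at pseudo-time t (0..100)."""
    if module not in truth.archetype_of_module:
        raise ValueError(f"module {module} was not planted")
    t = np.asarray(t, dtype=float)
    kind = truth.archetype_of_module[module]
    e = truth.effect_size
    if kind == "monotone_up":
        out = e * t / 100.0
    elif kind == "monotone_down":
        out = e * (1.0 - t / 100.0)
    elif kind == "intermediate_peak":
        p = truth.peak_time[module]
        out = e * np.exp(-((t - p) ** 2) / (2.0 * PEAK_WIDTH**2))
    elif kind == "flat":
        out = np.zeros_like(t)
    else:  # pragma: no cover - archetypes validated at construction
        raise ValueError(f"unknown archetype {kind!r}")
    return out


def make_synthetic(
    n_genes: int = DEFAULT_N_GENES,
    n_modules: int = DEFAULT_N_MODULES,
    samples_per_group: int = DEFAULT_SAMPLES_PER_GROUP,
    effect_size: float = DEFAULT_EFFECT_SIZE,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    module_size: int | None = None,
    archetypes: tuple[str, ...] | None = None,
    jitter_sd: float = DEFAULT_JITTER_SD,
    trait_noise_sd: float = DEFAULT_TRAIT_NOISE_SD,
    counts: bool = False,
) -> tuple[ExpressionMatrix, TraitTable, SyntheticTruth]:
    """Generate a two-condition fixture with planted modules and a trait.

    Gene g in module m of sample s:
        x[g, s] = baseline_g + loading_g * A_m(s) + eps,  eps ~ N(0, noise_sd^2)
    where the module activity A_m(s) = archetype_m(t_s) + N(0, jitter_sd^2)
    and t_s is 0 for SN samples, 100 for CN samples. Background genes are
    baseline plus iid noise. The CN trait is the trait module's activity
    plus noise (slope 1, intercept 0), clipped at zero; SN traits are 0.

    ``counts=True`` returns a negative-binomial count matrix instead (for
    feeding ``log_cpm`` end to end); mean counts are 2**x scaled to a
    realistic library size.
    """
    module_size = module_size if module_size is not None else n_genes // (n_modules + 1)
    if module_size < MIN_MODULE_SIZE:
        raise ValueError(
            f"infeasible sizes: module_size={module_size} < {MIN_MODULE_SIZE} "
            f"(n_genes={n_genes}, n_modules={n_modules})"
        )
    if n_genes < n_modules * module_size:
        raise ValueError("infeasible sizes: n_genes < n_modules * module_size")
    if samples_per_group < 3:
        raise ValueError("need samples_per_group >= 3")
    if archetypes is None:
        archetypes = tuple(DEFAULT_ARCHETYPES[i % len(DEFAULT_ARCHETYPES)] for i in range(n_modules))
    if len(archetypes) != n_modules:
        raise ValueError("archetypes must have one entry per module")
    for a in archetypes:
        if a not in ARCHETYPES:
            raise ValueError(f"unknown archetype {a!r}")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    labels = np.zeros(n_genes, dtype=int)
    for m in range(1, n_modules + 1):
        labels[(m - 1) * module_size : m * module_size] = m
    module_of_gene = pd.Series(labels, index=gene_ids)

    peak_iter = iter(np.resize(DEFAULT_PEAK_TIMES, sum(a == "intermediate_peak" for a in archetypes)))
    archetype_of_module = {m: archetypes[m - 1] for m in range(1, n_modules + 1)}
    peak_time = {
        m: float(next(peak_iter))
        for m, a in archetype_of_module.items()
        if a == "intermediate_peak"
    }
    trait_module = next(
        (m for m, a in archetype_of_module.items() if a == "monotone_up"), 1
    )

    baseline = rng.uniform(4.0, 12.0, size=n_genes)
    loadings = rng.uniform(0.7, 1.3, size=n_genes)
    truth = SyntheticTruth(
        module_of_gene=module_of_gene,
        archetype_of_module=archetype_of_module,
        peak_time=peak_time,
        trait_module=trait_module,
        effect_size=effect_size,
        noise_sd=noise_sd,
        loadings=pd.Series(loadings, index=gene_ids),
        baseline=pd.Series(baseline, index=gene_ids),
    )

    n = samples_per_group
    sample_ids = [f"SN{i:02d}" for i in range(n)] + [f"CN{i:02d}" for i in range(n)]
    groups = pd.Series([GROUP_CONTROL] * n + [GROUP_TREATED] * n, index=sample_ids)
    t_of_sample = np.array([0.0] * n + [100.0] * n)

    # module activities per sample: archetype value at the sample's endpoint
    # plus biological jitter
    activity = np.zeros((n_modules + 1, 2 * n))  # row 0 unused (background)
    for m in range(1, n_modules + 1):
        activity[m] = truth_trajectory(truth, m, t_of_sample) + rng.normal(
            0.0, jitter_sd, size=2 * n
        )

    values = (
        baseline[:, None]
        + loadings[:, None] * activity[labels]
        + rng.normal(0.0, noise_sd, size=(n_genes, 2 * n))
    )
    values[labels == 0] = (
        baseline[labels == 0, None]
        + rng.normal(0.0, noise_sd, size=((labels == 0).sum(), 2 * n))
    )

    trait_vals = np.zeros(2 * n)
    trait_vals[n:] = np.clip(
        activity[trait_module, n:] + rng.normal(0.0, trait_noise_sd, size=n), 0.0, None
    )
    traits = TraitTable(trait=pd.Series(trait_vals, index=sample_ids, name="trait"))

    if counts:
        mean = 2.0**values
        mean *= 3e6 / mean.sum(axis=0, keepdims=True)
        dispersion = 10.0  # NB size parameter; moderate overdispersion
        p = dispersion / (dispersion + mean)
        cdf = rng.negative_binomial(dispersion, p)
        df = pd.DataFrame(cdf, index=gene_ids, columns=sample_ids)
        X = ExpressionMatrix(values=df.astype(float), sample_group=groups)
        return X, traits, truth

    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    X = ExpressionMatrix(values=df, sample_group=groups)
    return X, traits, truth


def truth_stack(
    truth: SyntheticTruth,
    n_repeats: int = 10,
    n_timesteps: int = 101,
    noise_sd: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Truth-driven repeat x timestep x gene array of expression values.

    This bypasses the generative model entirely: each repeat is the noiseless
    archetype trajectory of every gene plus iid Gaussian noise. It exists to
    validate the downstream stages (network construction, serial testing)
    against known trajectories.
    """
    rng = np.random.default_rng(seed)
    noise_sd = truth.noise_sd if noise_sd is None else noise_sd
    t = np.linspace(0.0, 100.0, n_timesteps)
    genes = truth.module_of_gene.index
    n_genes = len(genes)
    labels = truth.module_of_gene.to_numpy()
    base = np.zeros((n_timesteps, n_genes))
    for m in truth.archetype_of_module:
        sel = labels == m
        base[:, sel] = truth_trajectory(truth, m, t)[:, None] * truth.loadings.to_numpy()[None, sel]
    base += truth.baseline.to_numpy()[None, :]
    out = base[None] + rng.normal(0.0, noise_sd, size=(n_repeats, n_timesteps, n_genes))
    return out
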