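"""Weighted co-expression network construction and module-trait alignment.

The network is built from scratch on the simulated timestep x gene profile:
soft-thresholded correlation adjacency, topological overlap, average-linkage
clustering of the TOM dissimilarity with a static height cut and minimum
module size, module eigengenes (first principal component), and finally
recomputation of each module's eigengene in the *real* samples so that it
can be correlated with a behavioral trait that only real samples carry.

The default network is signed, a = ((1 + r)/2)^beta, so that genes moving in
opposite directions over the time course land in different modules; the
unsigned variant |r|^beta is available through ``NetworkConfig``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from ._utils import corr_pvalue
from .data_io import ExpressionMatrix, TraitTable

log = logging.getLogger(__name__)


@dataclass
class NetworkConfig:
    beta_grid: tuple[int, ...] = tuple(range(1, 21))
    rsq_target: float = 0.8
    min_module_size: int = 10
    cut_height_fraction: float = 0.8
    merge_corr: float | None = None  # eigengene-merge threshold; off by default
    network_type: str = "signed"
    min_beta_fallback: int = 6
    variance_tol: float = 1e-12

    def __post_init__(self):
        if not self.beta_grid or list(self.beta_grid) != sorted(self.beta_grid):
            raise ValueError("beta_grid must be nonempty and ascending")
        if not (0 < self.rsq_target < 1):
            raise ValueError("rsq_target must be in (0, 1)")
        if self.network_type not in ("signed", "unsigned"):
            raise ValueError("network_type must be 'signed' or 'unsigned'")


@dataclass
class ModuleAssignment:
    """gene -> module id; 0 means unassigned/background."""

    labels: pd.Series

    @property
    def module_ids(self) -> list[int]:
        return sorted(m for m in set(self.labels) if m != 0)

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != 0].value_counts().sort_index()

    def genes_of(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def to_tsv(self, path) -> None:
        self.labels.rename("module").to_frame().to_csv(path, sep="\t", index_label="gene")


@dataclass
class EigengeneProfile:
    """Per-module eigengene over the observation axis of the input matrix."""

    eigengenes: pd.DataFrame  # observations x modules, unit variance columns
    loadings: dict[int, pd.Series]
    explained_variance: pd.Series


@dataclass
class ModuleTraitResult:
    module: int
    r: float
    p: float
    passes: bool
    n_genes: int
    region: str | None = None


# ---------------------------------------------------------------------------
# Adjacency / TOM
# ---------------------------------------------------------------------------

def _gene_correlation(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError(f"zero-variance gene at column index {int(np.argmax(sd == 0))}")
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(X, rowvar=False)
    return np.clip(r, -1.0, 1.0)


def adjacency(X, beta: int, network_type: str = "signed") -> np.ndarray:
    """Soft-thresholded co-expression adjacency of an obs x gene matrix.

    signed:   a_ij = ((1 + r_ij)/2)^beta;  unsigned: a_ij = |r_ij|^beta.
    Diagonal is 1 in both conventions.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X.to_numpy()
    r = _gene_correlation(X)
    if network_type == "unsigned":
        a = np.abs(r) ** beta
    elif network_type == "signed":
        a = ((1.0 + r) / 2.0) ** beta
    else:
        raise ValueError(f"unknown network_type {network_type!r}")
    np.fill_diagonal(a, 1.0)
    return a


def tom(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency with unit diagonal.

    w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, where
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; w_ii = 1.
    """
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be a symmetric square matrix")
    n = A.shape[0]
    Aod = A.copy()
    np.fill_diagonal(Aod, 0.0)
    # zero diagonal makes the u == i and u == j terms of the matrix product
    # vanish, so (Aod @ Aod)_ij already equals sum_{u != i,j} a_iu a_uj
    L = Aod @ Aod
    k = Aod.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (L + Aod) / (kmin + 1.0 - Aod)
    w[~np.isfinite(w)] = 0.0
    np.fill_diagonal(w, 1.0)
    return np.clip(w, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Soft-threshold selection
# ---------------------------------------------------------------------------

def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression.

    Connectivities are binned, log10(frequency) is regressed on log10(mean k
    per bin); the fit index is R^2 signed by the negative of the slope, as is
    conventional for scale-free topology checks (a positive slope is evidence
    *against* scale-freeness and yields a negative index).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < 10 or np.ptp(k) < 1e-12:
        return -1.0
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return -1.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2)


def drop_constant_genes(X: pd.DataFrame, tol: float = 1e-12) -> pd.DataFrame:
    """Remove genes with (numerically) zero variance over the observations."""
    sd = X.std(axis=0, ddof=0)
    dropped = list(X.columns[sd <= tol])
    if dropped:
        log.warning("dropping %d constant gene(s): %s ...", len(dropped), dropped[:5])
    return X.loc[:, sd > tol]


def pick_soft_threshold(
    X: pd.DataFrame, config: NetworkConfig | None = None
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by the scale-free topology criterion.

    Returns the smallest beta whose signed fit index reaches ``rsq_target``;
    if none does (which happens on strongly modular or degenerate inputs),
    falls back to the beta maximising the index, floored at
    ``min_beta_fallback``. The fit table (beta, fit index, mean/max
    connectivity) is returned alongside.
    """
    config = config or NetworkConfig()
    X = drop_constant_genes(pd.DataFrame(X), config.variance_tol)
    if X.shape[1] < 10 or X.shape[0] < 3:
        raise ValueError("need >= 10 variable genes and >= 3 observations")
    rows = []
    for beta in config.beta_grid:
        A = adjacency(X, beta, config.network_type)
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        rows.append(
            {"beta": beta, "fit_rsq": scale_free_fit(k), "mean_k": k.mean(), "max_k": k.max()}
        )
    table = pd.DataFrame(rows)
    ok = table[table.fit_rsq >= config.rsq_target]
    if len(ok):
        beta = int(ok.beta.iloc[0])
    else:
        beta = int(max(table.loc[table.fit_rsq.idxmax(), "beta"], config.min_beta_fallback))
        log.warning(
            "scale-free fit target %.2f not reached (max %.3f); falling back to beta=%d",
            config.rsq_target, table.fit_rsq.max(), beta,
        )
    return beta, table


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def detect_modules(tom_matrix: np.ndarray, gene_ids, config: NetworkConfig | None = None) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    The dendrogram is cut at ``cut_height_fraction`` times the maximum merge
    height; clusters smaller than ``min_module_size`` are set to module 0
    (unassigned). Remaining modules are renumbered by decreasing size.
    """
    config = config or NetworkConfig()
    d = 1.0 - np.asarray(tom_matrix, dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = average(squareform(d, checks=False))
    height = config.cut_height_fraction * Z[:, 2].max()
    raw = fcluster(Z, t=height, criterion="distance")
    labels = np.zeros(len(raw), dtype=int)
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= config.min_module_size].index
    order = sizes.loc[keep].sort_values(ascending=False).index
    for new_id, old in enumerate(order, start=1):
        labels[raw == old] = new_id
    if labels.max() <= 1 and len(set(raw)) == 1:
        log.warning("all genes fell into a single cluster at the chosen cut height")
    return ModuleAssignment(labels=pd.Series(labels, index=list(gene_ids)))


# ---------------------------------------------------------------------------
# Eigengenes
# ---------------------------------------------------------------------------

def _first_pc(Xm: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """First principal component of a standardized obs x gene block.

    Returns (scores with unit variance, gene loadings, explained variance
    fraction), sign-oriented so the scores correlate nonnegatively with the
    block's mean profile.
    """
    mu = Xm.mean(axis=0)
    sd = Xm.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Xm - mu) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, 0] * S[0]
    loadings = Vt[0]
    explained = float(S[0] ** 2 / (S**2).sum()) if (S**2).sum() > 0 else 0.0
    mean_profile = Z.mean(axis=1)
    if np.dot(scores, mean_profile) < 0:
        scores, loadings = -scores, -loadings
    s = scores.std()
    if s > 0:
        scores = scores / s
    return scores, loadings, explained


def eigengene(X: pd.DataFrame, assignment: ModuleAssignment) -> EigengeneProfile:
    """Per-module first-PC profiles of an observations x genes matrix.

    Single-gene modules degenerate to the standardized gene itself.
    Eigengenes have unit variance and are oriented to correlate nonnegatively
    with the module's mean (standardized) expression profile.
    """
    X = pd.DataFrame(X)
    cols = {}
    loadings = {}
    explained = {}
    for m in assignment.module_ids:
        genes = [g for g in assignment.genes_of(m) if g in X.columns]
        if not genes:
            raise ValueError(f"module {m}: none of its genes are present in the matrix")
        block = X[genes].to_numpy(dtype=float)
        scores, load, ev = _first_pc(block)
        cols[m] = scores
        loadings[m] = pd.Series(load, index=genes)
        explained[m] = ev
    return EigengeneProfile(
        eigengenes=pd.DataFrame(cols, index=X.index),
        loadings=loadings,
        explained_variance=pd.Series(explained),
    )


# ---------------------------------------------------------------------------
# Module-trait alignment
# ---------------------------------------------------------------------------

def module_trait_alignment(
    assignment: ModuleAssignment,
    X_real: ExpressionMatrix,
    traits: TraitTable,
    sim_loadings: dict[int, pd.Series] | None = None,
    r_threshold: float = 0.5,
    p_threshold: float = 0.05,
    region: str | None = None,
) -> list[ModuleTraitResult]:
    """Correlate real-sample module eigengenes with the behavioral trait.

    Modules come from the simulated time course, but the eigengene is
    recomputed by PCA across the real samples. If the simulated-profile gene
    loadings are supplied, each real eigengene's sign is linked to the
    simulated one through the correlation of the two loading vectors, so
    positive/negative trait correlations are comparable across the two
    domains. A module passes when p < ``p_threshold`` and |r| >
    ``r_threshold``.
    """
    if X_real.n_samples < 4:
        raise ValueError(f"need >= 4 real samples, got {X_real.n_samples}")
    missing = [
        g for g in assignment.labels.index[assignment.labels != 0]
        if g not in X_real.values.index
    ]
    if missing:
        raise ValueError(f"genes absent from the real matrix: {missing[:10]}")
    trait = traits.aligned_to(X_real)
    if trait.std() == 0:
        raise ValueError("trait has zero variance; correlation undefined")
    real = pd.DataFrame(X_real.matrix(), index=X_real.sample_ids, columns=X_real.gene_ids)
    prof = eigengene(real, assignment)
    results = []
    n = X_real.n_samples
    for m in assignment.module_ids:
        eg = prof.eigengenes[m].to_numpy()
        if sim_loadings is not None and m in sim_loadings:
            common = prof.loadings[m].index.intersection(sim_loadings[m].index)
            if len(common) >= 2:
                lr = np.corrcoef(
                    prof.loadings[m][common], sim_loadings[m][common]
                )[0, 1]
                if np.isfinite(lr) and lr < 0:
                    eg = -eg
        tv = trait.to_numpy()
        r = float(np.corrcoef(eg, tv)[0, 1])
        p = corr_pvalue(r, n)
        results.append(
            ModuleTraitResult(
                module=m,
                r=r,
                p=p,
                passes=bool(p < p_threshold and abs(r) > r_threshold),
                n_genes=len(assignment.genes_of(m)),
                region=region,
            )
        )
    return results


def trait_results_frame(results: list[ModuleTraitResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module": r.module,
                "Corr": r.r,
                "P.val": r.p,
                "passes": r.passes,
                "n_genes": r.n_genes,
                "region": r.region,
            }
            for r in results
        ]
    )
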