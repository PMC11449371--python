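"""Temporal alignment and module-module correlation networks.

Each module is aligned to the timestep where its simulated eigengene peaks,
staged as early/mid/late on the 0..100 pseudo-time scale, and connected to
other modules by the Pearson correlation of their eigengene time profiles.
Within a stage, modules are split into pattern groups (e.g. mid1/mid2) by
hierarchical clustering of the correlation submatrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

T_EARLY = 10
T_LATE = 90
EDGE_THRESHOLD = 0.5


@dataclass
class TemporalNetwork:
    nodes: pd.DataFrame  # module, peak, stage[, group]
    edges: pd.DataFrame  # m1, m2, r, sign
    corr: pd.DataFrame   # full module-module correlation matrix

    def save(self, node_path, edge_path) -> None:
        self.nodes.to_csv(node_path, sep="\t", index=False)
        self.edges.to_csv(edge_path, sep="\t", index=False)


def peak_align(
    eigengenes: pd.DataFrame,
    timesteps: np.ndarray | None = None,
    t_early: float = T_EARLY,
    t_late: float = T_LATE,
    mode: str = "peak",
) -> pd.DataFrame:
    """Per-module peak timestep and early/mid/late stage.

    ``eigengenes`` is timestep x module (oriented upstream). The peak is the
    argmax of the profile (ties break to the earliest timestep, so a constant
    eigengene lands at t=0 / early -- a documented artifact of the tie rule).
    ``mode="diff"`` aligns instead to the peak of |first difference|, which
    highlights where a module changes fastest rather than where it is
    highest.
    """
    eigengenes = pd.DataFrame(eigengenes)
    if timesteps is None:
        timesteps = np.linspace(0.0, 100.0, len(eigengenes))
    rows = []
    for m in eigengenes.columns:
        prof = eigengenes[m].to_numpy()
        if mode == "peak":
            idx = int(np.argmax(prof))
        elif mode == "diff":
            idx = int(np.argmax(np.abs(np.diff(prof)))) + 1
        else:
            raise ValueError(f"unknown alignment mode {mode!r}")
        t = float(timesteps[idx])
        stage = "early" if t <= t_early else ("late" if t >= t_late else "mid")
        rows.append({"module": m, "peak": t, "stage": stage})
    return pd.DataFrame(rows)


def module_network(
    eigengenes: pd.DataFrame,
    edge_threshold: float = EDGE_THRESHOLD,
    t_early: float = T_EARLY,
    t_late: float = T_LATE,
    mode: str = "peak",
) -> TemporalNetwork:
    """Peak-aligned module nodes plus signed correlation edges.

    Edges connect module pairs whose eigengene time profiles correlate with
    |r| >= ``edge_threshold``; the sign column distinguishes co-activation
    from opposition. Self edges are excluded; the network is undirected.
    """
    eigengenes = pd.DataFrame(eigengenes)
    if eigengenes.shape[1] < 2:
        raise ValueError("need at least 2 modules for a module network")
    nodes = peak_align(eigengenes, t_early=t_early, t_late=t_late, mode=mode)
    corr = eigengenes.corr(method="pearson")
    mods = list(eigengenes.columns)
    rows = []
    for i, m1 in enumerate(mods):
        for m2 in mods[i + 1 :]:
            r = float(corr.loc[m1, m2])
            if abs(r) >= edge_threshold:
                rows.append(
                    {"m1": m1, "m2": m2, "r": r, "sign": "positive" if r >= 0 else "negative"}
                )
    edges = pd.DataFrame(rows, columns=["m1", "m2", "r", "sign"])
    return TemporalNetwork(nodes=nodes, edges=edges, corr=corr)


def cluster_modules(network: TemporalNetwork, n_groups: int = 2) -> pd.Series:
    """Split each stage's modules into correlation-pattern groups.

    Within a stage, average-linkage clustering on 1 - r of the module
    correlation submatrix is cut into ``n_groups`` clusters (fewer when the
    stage has fewer modules); groups are labelled stage+index by decreasing
    size (mid1, mid2, ...). Returns module -> group label.
    """
    labels = {}
    for stage, part in network.nodes.groupby("stage"):
        mods = list(part.module)
        if len(mods) == 1:
            labels[mods[0]] = f"{stage}1"
            continue
        sub = network.corr.loc[mods, mods].to_numpy()
        d = np.clip(1.0 - sub, 0.0, None)
        np.fill_diagonal(d, 0.0)
        Z = average(squareform((d + d.T) / 2.0, checks=False))
        raw = fcluster(Z, t=min(n_groups, len(mods)), criterion="maxclust")
        sizes = pd.Series(raw).value_counts()
        order = {old: i + 1 for i, old in enumerate(sizes.sort_values(ascending=False).index)}
        for m, c in zip(mods, raw):
            labels[m] = f"{stage}{order[c]}"
    return pd.Series(labels, name="group")
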