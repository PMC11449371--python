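"""Tabular I/O, normalization, and linear augmentation of training data.

The pipeline works on log-scale gene x sample matrices. Raw counts are
normalized to log2 counts-per-million (log-CPM) with a 0.5 pseudocount;
pre-normalized matrices are accepted verbatim. Before adversarial training
the (small) set of real samples is expanded by within-group convex
combinations of random sample pairs ("linear augmentation"), which enlarges
the training set without ever extrapolating outside the per-group envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GROUP_CONTROL = "SN"
GROUP_TREATED = "CN"
VALID_GROUPS = (GROUP_CONTROL, GROUP_TREATED)


@dataclass
class ExpressionMatrix:
    """A validated gene x sample expression matrix with sample metadata.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns
    (genes in rows is the internal convention everywhere). ``sample_group``
    maps each sample to "SN" (control) or "CN" (treated); ``region`` is an
    optional per-sample label (the pipeline is run once per region).
    """

    values: pd.DataFrame
    sample_group: pd.Series
    region: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = sorted(set(v.index[v.index.duplicated()]))
            raise ValueError(f"duplicate gene ids: {dups}")
        if v.columns.duplicated().any():
            dups = sorted(set(v.columns[v.columns.duplicated()]))
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = [
                (str(v.index[i]), str(v.columns[j]))
                for i, j in zip(*np.where(~np.vectorize(_is_number)(arr)))
            ][:5]
            raise ValueError(f"non-numeric expression values at (gene, sample): {bad}")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        self.sample_group = pd.Series(self.sample_group, dtype=str).reindex(v.columns)
        if self.sample_group.isna().any():
            missing = list(v.columns[self.sample_group.isna()])
            raise ValueError(f"samples without a group label: {missing}")
        bad_groups = sorted(set(self.sample_group) - set(VALID_GROUPS))
        if bad_groups:
            raise ValueError(f"unknown group labels {bad_groups}; expected {VALID_GROUPS}")
        if self.region is not None:
            self.region = pd.Series(self.region, dtype=str).reindex(v.columns)

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.sample_group.items() if g == group]

    def matrix(self) -> np.ndarray:
        """Samples x genes float array (the orientation models train on)."""
        return self.values.to_numpy(dtype=float).T

    def require_two_groups(self, min_per_group: int = 2) -> None:
        for g in VALID_GROUPS:
            n = len(self.samples_in(g))
            if n < min_per_group:
                raise ValueError(f"group {g} has {n} samples; need >= {min_per_group}")

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


@dataclass
class TraitTable:
    """Per-sample behavioral score (addiction index); zero for controls."""

    trait: pd.Series

    def aligned_to(self, X: ExpressionMatrix) -> pd.Series:
        """Trait values for every sample of X; control samples default to 0."""
        out = self.trait.reindex(X.sample_ids)
        is_control = (self.sample_group_of(X) == GROUP_CONTROL).to_numpy()
        filled = out.to_numpy(dtype=float)
        filled[np.isnan(filled) & is_control] = 0.0
        if np.isnan(filled).any():
            missing = [s for s, v in zip(X.sample_ids, filled) if np.isnan(v)]
            raise ValueError(f"treated samples without trait values: {missing}")
        return pd.Series(filled, index=X.sample_ids, name="trait")

    @staticmethod
    def sample_group_of(X: ExpressionMatrix) -> pd.Series:
        return X.sample_group


@dataclass
class GeneSetCollection:
    """term id -> (term name, set of gene ids)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def genes(self, term_id: str) -> frozenset[str]:
        return self.sets[term_id][1]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(
    path,
    layout: str = "genes_in_rows",
    meta_path=None,
    group: pd.Series | dict | None = None,
    region: pd.Series | dict | None = None,
) -> ExpressionMatrix:
    """Read a TSV/CSV expression matrix plus sample group labels.

    ``layout`` is "genes_in_rows" (first column gene ids, header sample ids)
    or "samples_in_rows" (the transpose). Group labels come either from a
    sidecar metadata table (columns: sample_id, group[, region]) or directly
    via ``group``/``region``.
    """
    if layout not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown layout {layout!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if layout == "samples_in_rows":
        df = df.T
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    for col in df.columns:
        bad = df[col][~df[col].map(_is_number)]
        if len(bad):
            raise ValueError(
                f"non-numeric value {bad.iloc[0]!r} at gene {bad.index[0]!r}, "
                f"sample {col!r}"
            )
    df = df.astype(float)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep=_sep_for(meta_path))
        meta = meta.set_index(meta.columns[0])
        meta.index = meta.index.map(str)
        group = meta["group"]
        region = meta["region"] if "region" in meta.columns else None
    if group is None:
        raise ValueError("sample group labels are required (meta_path or group=)")
    X = ExpressionMatrix(
        values=df,
        sample_group=pd.Series(group),
        region=pd.Series(region) if region is not None else None,
    )
    log.info("read expression matrix: %d genes x %d samples", X.n_genes, X.n_samples)
    return X


def read_traits(path) -> TraitTable:
    """Read a two-column (sample_id, trait) table."""
    df = pd.read_csv(path, sep=_sep_for(path))
    df = df.set_index(df.columns[0])
    df.index = df.index.map(str)
    s = df.iloc[:, 0].astype(float)
    if (s < 0).any():
        bad = list(s.index[s < 0])
        raise ValueError(f"negative trait values for samples {bad}")
    return TraitTable(trait=s)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >= 3 fields, got {len(fields)}")
            term, desc, genes = fields[0], fields[1], fields[2:]
            genes = frozenset(g for g in genes if g)
            if not genes:
                raise ValueError(f"GMT line {lineno}: term {term!r} has no genes")
            sets[term] = (desc, genes)
    return GeneSetCollection(sets=sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in collection:
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Normalization and augmentation
# ---------------------------------------------------------------------------

def log_cpm(
    counts: pd.DataFrame,
    sample_group: pd.Series | dict,
    region: pd.Series | dict | None = None,
    drop_all_zero: bool = True,
) -> ExpressionMatrix:
    """log2 counts-per-million with a 0.5 pseudocount.

    value[g, s] = log2((count[g, s] + 0.5) / (libsize[s] + 1) * 1e6)

    The +0.5 / +1 offsets keep zero counts finite; for counts >> 1 the
    transform is scale-free in sequencing depth.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative count at gene {counts.index[i]!r}, sample {counts.columns[j]!r}"
        )
    lib = arr.sum(axis=0)
    if (lib <= 0).any():
        bad = list(counts.columns[lib <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    if drop_all_zero:
        keep = arr.sum(axis=1) > 0
        counts = counts.loc[keep]
        arr = arr[keep]
    vals = np.log2((arr + 0.5) / (lib + 1.0) * 1e6)
    df = pd.DataFrame(vals, index=counts.index, columns=counts.columns)
    return ExpressionMatrix(
        values=df,
        sample_group=pd.Series(sample_group),
        region=pd.Series(region) if region is not None else None,
    )


def linear_augment(X: ExpressionMatrix, fold: int = 10, seed: int = 0) -> ExpressionMatrix:
    """Expand each group with fold x (group size) convex sample combinations.

    Every synthetic sample is alpha*x_a + (1-alpha)*x_b for a random
    within-group pair (a, b), alpha ~ Uniform(0, 1), so augmentation never
    leaves the per-gene [min, max] envelope of its group. Original samples
    are retained alongside the synthetic ones.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    rng = np.random.default_rng(seed)
    cols = [X.values]
    groups = [X.sample_group]
    regions = [X.region] if X.region is not None else None
    for g in VALID_GROUPS:
        members = X.samples_in(g)
        if len(members) < 2:
            raise ValueError(f"group {g} has {len(members)} sample(s); need >= 2 to augment")
        n_new = fold * len(members)
        base = X.values[members].to_numpy()
        ia = rng.integers(0, len(members), size=n_new)
        ib = (ia + 1 + rng.integers(0, len(members) - 1, size=n_new)) % len(members)
        alpha = rng.uniform(0.0, 1.0, size=n_new)
        new = alpha * base[:, ia] + (1.0 - alpha) * base[:, ib]
        ids = [f"{g}_aug{i:04d}" for i in range(n_new)]
        cols.append(pd.DataFrame(new, index=X.values.index, columns=ids))
        groups.append(pd.Series([g] * n_new, index=ids))
        if regions is not None:
            reg = X.region[members[0]]
            regions.append(pd.Series([reg] * n_new, index=ids))
    out = ExpressionMatrix(
        values=pd.concat(cols, axis=1),
        sample_group=pd.concat(groups),
        region=pd.concat(regions) if regions is not None else None,
    )
    log.info(
        "linear augmentation fold=%d: %d -> %d samples", fold, X.n_samples, out.n_samples
    )
    return out
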