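"""Hypergeometric over-representation of module genes in gene-set collections.

For a module of n genes tested against a term with K genes in a universe of
N, the enrichment p-value is the upper tail P(X >= k) of the hypergeometric
distribution, the odds ratio is computed on the 2x2 overlap table (with a
Haldane +0.5 correction when a cell is empty), and the enrichment ratio is
the fold over-representation (k/n)/(K/N). Per module, the "primary" term is
the most significant term passing the p-value cutoff among terms no larger
than the size cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .data_io import GeneSetCollection

PVALUE_CUTOFF = 0.05
CUTOFF_SIZE = 50


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # overlap
    n: int  # module size (within universe)
    K: int  # term size (within universe)
    N: int  # universe size
    p: float
    odds_ratio: float
    enrichment_ratio: float
    is_primary: bool = False


def hypergeom_test(module_genes, term_genes, universe) -> EnrichmentResult:
    """Upper-tail hypergeometric test of a module against one gene set."""
    universe = set(universe)
    if len(universe) < 2:
        raise ValueError("universe must contain at least 2 genes")
    module = set(module_genes) & universe
    if not module:
        raise ValueError("empty module (no genes in universe)")
    term = set(term_genes) & universe
    k = len(module & term)
    n, K, N = len(module), len(term), len(universe)
    p = float(hypergeom.sf(k - 1, N, K, n))
    a, b, c, d = k, n - k, K - k, N - K - (n - k)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a / b) / (c / d)
    enrichment_ratio = (k / n) / (K / N) if K > 0 else 0.0
    return EnrichmentResult(
        term_id="", term_name="", k=k, n=n, K=K, N=N,
        p=p, odds_ratio=float(odds_ratio), enrichment_ratio=float(enrichment_ratio),
    )


def enrich_module(
    module_genes,
    collection: GeneSetCollection,
    universe,
    cutoff_size: int = CUTOFF_SIZE,
    size_mode: str = "max",
) -> list[EnrichmentResult]:
    """Test a module against every eligible term of a collection.

    ``cutoff_size`` bounds the effective (in-universe) term size; with
    ``size_mode="max"`` (default) only terms of at most that size are tested,
    which biases primary-term selection toward specific terms. ``"min"``
    inverts the rule for collections where small terms are noise.
    """
    universe = set(universe)
    out = []
    for term_id, (name, genes) in collection:
        eff = len(set(genes) & universe)
        if eff == 0:
            continue
        if size_mode == "max" and eff > cutoff_size:
            continue
        if size_mode == "min" and eff < cutoff_size:
            continue
        res = hypergeom_test(module_genes, genes, universe)
        res.term_id = term_id
        res.term_name = name
        out.append(res)
    out.sort(key=lambda r: (r.p, r.K, r.term_id))
    return out


def primary_term(
    module_genes,
    collection: GeneSetCollection,
    universe,
    pvalue_cutoff: float = PVALUE_CUTOFF,
    cutoff_size: int = CUTOFF_SIZE,
    size_mode: str = "max",
) -> EnrichmentResult | None:
    """Most significant eligible term below the p-value cutoff, or None.

    Ties on p break toward the smaller (more specific) term, then by id.
    """
    results = enrich_module(module_genes, collection, universe, cutoff_size, size_mode)
    passing = [r for r in results if r.p < pvalue_cutoff]
    if not passing:
        return None
    best = passing[0]
    best.is_primary = True
    return best


def enrichment_frame(results: dict[int, list[EnrichmentResult]]) -> pd.DataFrame:
    rows = []
    for module, res_list in results.items():
        for r in res_list:
            rows.append(
                {
                    "module": module, "term": r.term_id, "name": r.term_name,
                    "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                    "G.Pv": r.p, "OR": r.odds_ratio, "ER": r.enrichment_ratio,
                    "is_primary": r.is_primary,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["module", "term", "name", "k", "n", "K", "N", "G.Pv", "OR", "ER", "is_primary"],
    )
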