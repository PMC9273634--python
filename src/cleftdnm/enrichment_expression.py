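"""Gene-set enrichment (Fisher / EASE hypergeometric) and craniofacial
expression summarization (row-scaled heat values and tissue contrasts)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError
from .models import ExpressionMatrix, GeneSetCollection

NOMINAL_ALPHA = 0.05
RATIO_EPSILON = 1.0  # fluorescence-intensity floor guarding zero denominators


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # overlap
    n: int  # query size (annotated)
    K: int  # set size
    N: int  # background size
    p_value: float
    significant: bool
    p_adjusted: Optional[float] = None


@dataclass(frozen=True)
class TissueContrast:
    gene: str
    intensity_a: Optional[float]
    intensity_b: Optional[float]
    ratio: Optional[float]
    elevated: Optional[bool]
    missing: bool = False


def hypergeom_upper_p(k: int, n: int, K: int, N: int, ease: bool = False) -> float:
    """One-sided upper-tail hypergeometric p-value P(X >= k).

    With ``ease=True`` the tail is evaluated at k-1 (floored at 0), DAVID's
    conservative EASE variant, so EASE p >= Fisher p always.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N or K > N:
        raise ValidationError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    k_eff = max(k - 1, 0) if ease else k
    if k_eff == 0:
        return 1.0
    return float(hypergeom.sf(k_eff - 1, N, K, n))


def enrich(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    background: Optional[int] = None,
    ease: bool = False,
    bh_correction: bool = False,
    alpha: float = NOMINAL_ALPHA,
) -> list[EnrichmentResult]:
    """Test each term for over-representation in the query gene list.

    The query is deduplicated and restricted to annotated genes (those that
    appear in at least one set). ``background`` defaults to the number of
    annotated genes. No multiple-testing correction by default (nominal p);
    Benjamini-Hochberg is available behind ``bh_correction`` and fills
    ``p_adjusted`` (the ``significant`` flag stays nominal).
    """
    query = {g.upper() for g in query_genes}
    if not query:
        raise ValidationError("query gene list is empty")
    universe = collection.universe()
    N = background if background is not None else len(universe)
    annotated_query = query & universe
    n = len(annotated_query)
    results = []
    for term in sorted(collection.sets):
        gene_set = collection.sets[term]
        K = len(gene_set.genes)
        if K > N:
            raise ValidationError(f"gene set {term} larger than background ({K} > {N})")
        k = len(annotated_query & gene_set.genes)
        p = hypergeom_upper_p(k, n, K, N, ease=ease)
        results.append(
            EnrichmentResult(term=term, k=k, n=n, K=K, N=N, p_value=p, significant=p < alpha)
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    if bh_correction and results:
        m = len(results)
        order = np.argsort([r.p_value for r in results])
        adjusted = np.empty(m)
        running = 1.0
        for rank_from_end, idx in enumerate(reversed(order)):
            rank = m - rank_from_end
            running = min(running, results[idx].p_value * m / rank)
            adjusted[idx] = running
        results = [
            EnrichmentResult(
                term=r.term, k=r.k, n=r.n, K=r.K, N=r.N, p_value=r.p_value,
                significant=r.significant, p_adjusted=float(adjusted[i]),
            )
            for i, r in enumerate(results)
        ]
    return results


def tissue_contrast(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    tissue_a: str,
    tissue_b: str,
    threshold: float = 1.0,
    epsilon: float = RATIO_EPSILON,
) -> list[TissueContrast]:
    """Per-gene intensity ratio (A + eps) / (B + eps); elevated iff ratio > threshold.

    Genes absent from the matrix are reported as missing, never an exception.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    for col in (tissue_a, tissue_b):
        if col not in matrix.data.columns:
            raise ValidationError(f"column {col!r} not in expression matrix")
    out = []
    for gene in genes:
        if gene not in matrix.data.index:
            out.append(TissueContrast(gene, None, None, None, None, missing=True))
            continue
        a = float(matrix.data.at[gene, tissue_a])
        b = float(matrix.data.at[gene, tissue_b])
        ratio = (a + epsilon) / (b + epsilon)
        out.append(TissueContrast(gene, a, b, ratio, ratio > threshold))
    return out


def heat_values(matrix: ExpressionMatrix, genes: Sequence[str]) -> pd.DataFrame:
    """Row-wise min-max scaled intensities in [0, 1]; constant rows map to 0.5."""
    missing = [g for g in genes if g not in matrix.data.index]
    if missing:
        raise ValidationError(f"genes absent from expression matrix: {missing}")
    sub = matrix.data.loc[list(genes)].astype(float)
    lo = sub.min(axis=1)
    hi = sub.max(axis=1)
    span = hi - lo
    scaled = sub.sub(lo, axis=0).div(span.replace(0.0, np.nan), axis=0)
    return scaled.fillna(0.5)
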