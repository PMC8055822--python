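"""GO-term over/under-representation for a protein subset versus the
detected background.

The test is the classical 2x2 Fisher exact test per GO term: foreground
membership x term annotation, with the background being the *detected*
protein set (what the instrument could have reported), not the genome --
using the genome would conflate detectability with biology.  Families
are corrected per GO category (the three ontologies are tested
separately) with Bonferroni by default; Benjamini-Hochberg is available
but not the default, since Bonferroni is the named convention here.

Annotations are used exactly as given: no propagation of terms up the
GO graph.  Propagated and unpropagated analyses can rank terms quite
differently; if ancestor closure is wanted it must be applied to the
annotation before it reaches this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Collection, Sequence

import numpy as np
from scipy import stats

from .design import PipelineParams
from .tables_io import GO_ASPECTS, GoAnnotation

__all__ = ["EnrichmentResult", "fisher_two_sided", "enrich"]

#: Relative tie tolerance: tables whose probability is mathematically
#: equal to the observed one must land in the tail despite float noise.
_TIE_SLACK = 1e-9


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    category: str
    k: int        # foreground genes annotated with the term
    n: int        # foreground size
    K: int        # background genes annotated
    N: int        # background size
    fold: float   # (k/n) / (K/N)
    p_raw: float
    p_adj: float
    direction: str  # over | under
    significant: bool


def fisher_two_sided(k: int, n: int, K: int, N: int) -> float:
    """Two-sided Fisher exact p for the table [[k, n-k], [K-k, N-n-(K-k)]].

    Defined as the total hypergeometric probability of all tables with
    the same margins whose probability does not exceed the observed
    table's.  Margins: n foreground of N background, K annotated.
    """
    if not (0 <= k <= n <= N and k <= K <= N and n - k <= N - K):
        raise ValueError(
            f"inconsistent 2x2 margins: k={k}, n={n}, K={K}, N={N}"
        )
    lo = max(0, n + K - N)
    hi = min(n, K)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, K, n)
    p_obs = stats.hypergeom.pmf(k, N, K, n)
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_SLACK)].sum())
    return min(1.0, p)


def _adjust(p_values: Sequence[float], method: str) -> list[float]:
    if method == "bonferroni":
        m = len(p_values)
        return [min(1.0, p * m) for p in p_values]
    if method == "bh":
        if not p_values:
            return []
        return list(stats.false_discovery_control(p_values, method="bh"))
    raise ValueError(f"unknown correction method {method!r}")


def enrich(
    foreground: Collection[str],
    background: Collection[str],
    annotation: GoAnnotation,
    params: PipelineParams | None = None,
    method: str = "bonferroni",
) -> list[EnrichmentResult]:
    """Test every GO term annotated in the background, per category.

    The foreground must be a subset of the background (hard error
    naming offenders).  Within each category, the number of tests m is
    the number of terms with at least one annotated background gene;
    ``p_adj`` = min(1, p_raw * m) under Bonferroni.  Results are sorted
    by (p_adj, term); ``significant`` iff p_adj < alpha.
    """
    params = params or PipelineParams()
    fg = set(foreground)
    bg = set(background)
    strays = sorted(fg - bg)
    if strays:
        raise ValueError(
            "foreground genes missing from background: "
            + ", ".join(strays[:10])
            + ("..." if len(strays) > 10 else "")
        )
    n = len(fg)
    N = len(bg)

    results: list[EnrichmentResult] = []
    for category in sorted(set(GO_ASPECTS.values())):
        # term -> annotated background genes
        by_term: dict[str, set[str]] = {}
        for gene in bg:
            for term, cat in annotation.by_gene.get(gene, ()):
                if cat == category:
                    by_term.setdefault(term, set()).add(gene)
        terms = sorted(by_term)
        raw: list[float] = []
        rows: list[tuple[str, int, int]] = []
        for term in terms:
            annotated = by_term[term]
            K = len(annotated)
            k = len(annotated & fg)
            raw.append(fisher_two_sided(k, n, K, N))
            rows.append((term, k, K))
        adjusted = _adjust(raw, method)
        for (term, k, K), p_raw, p_adj in zip(rows, raw, adjusted):
            fold = ((k / n) / (K / N)) if n > 0 else math.nan
            results.append(EnrichmentResult(
                term=term, category=category, k=k, n=n, K=K, N=N,
                fold=fold, p_raw=p_raw, p_adj=p_adj,
                direction="over" if fold > 1 else "under",
                significant=p_adj < params.alpha,
            ))
    results.sort(key=lambda r: (r.p_adj, r.term))
    return results
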