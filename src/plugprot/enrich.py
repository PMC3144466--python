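"""Term-for-term functional overrepresentation with Bonferroni correction.

Each annotation term is tested independently with the upper-tail
hypergeometric probability of seeing at least the observed number of
annotated genes in the study set, against a population of annotated genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Set

import pandas as pd
from scipy import stats

__all__ = ["EnrichmentResult", "hypergeometric_tail", "term_for_term"]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    population_annotated: int  # K
    population_size: int  # N
    study_annotated: int  # k
    study_size: int  # n
    p_raw: float
    p_bonferroni: float


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: population size, K: annotated in population, n: study-set size,
    k: annotated in study set.
    """
    if min(N, K, n, k) < 0:
        raise ValueError("counts must be non-negative")
    if K > N or n > N:
        raise ValueError("K and n cannot exceed N")
    if k > n or k > K:
        raise ValueError("k cannot exceed n or K")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def term_for_term(
    study: Set[str],
    population: Set[str],
    annotations: Mapping[str, Set[str]],
) -> list[EnrichmentResult]:
    """One enrichment result per term annotated in the study set.

    The population is restricted to annotated genes (genes with at least
    one term), matching the usual term-for-term denominator; the study set
    is restricted the same way. The Bonferroni multiplier is the number of
    terms tested (terms with >= 1 study-set annotation). Results sorted by
    raw p.
    """
    study = set(study)
    population = set(population)
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    annotated_pop = {g for g in population if annotations.get(g)}
    annotated_study = {g for g in study if annotations.get(g)}
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in annotated_pop:
        for term in annotations[gene]:
            term_pop[term] = term_pop.get(term, 0) + 1
            if gene in annotated_study:
                term_study[term] = term_study.get(term, 0) + 1
    m = len(term_study)
    results = []
    for term, k in term_study.items():
        p = hypergeometric_tail(
            len(annotated_pop), term_pop[term], len(annotated_study), k
        )
        results.append(
            EnrichmentResult(
                term_id=term,
                population_annotated=term_pop[term],
                population_size=len(annotated_pop),
                study_annotated=k,
                study_size=len(annotated_study),
                p_raw=p,
                p_bonferroni=min(1.0, m * p),
            )
        )
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "K": r.population_annotated,
                "N": r.population_size,
                "k": r.study_annotated,
                "n": r.study_size,
                "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
            }
            for r in results
        ],
        columns=["term_id", "K", "N", "k", "n", "p_raw", "p_bonferroni"],
    )
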