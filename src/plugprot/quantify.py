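"""Spectral-count quantification: NSAF, discovery curves, replicate checks.

NSAF (normalized spectral abundance factor) is a rough relative-abundance
proxy: a gene's spectral count divided by its protein length (SAF),
normalized so SAF sums to 1 over all identified genes. Counts here are the
experiment-wide sums over the biological samples, and genes with multiple
transcripts use the median transcript length by default.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .evolve import wilcoxon_rank_sum

__all__ = [
    "nsaf",
    "effective_length",
    "discovery_curve",
    "arcsin_sqrt",
    "first_vs_later_nsaf",
]


def nsaf(
    counts: Mapping[str, float], lengths: Mapping[str, float]
) -> pd.DataFrame:
    """NSAF records: gene_id, count, length, saf, nsaf, rank.

    saf = count / length; nsaf = saf / sum(saf). NSAF sums to 1 over the
    genes supplied. Per-sample NSAF is the same call restricted to one
    sample's counts.
    """
    if not counts:
        raise ValueError("no counts supplied")
    rows = []
    for gene_id, count in counts.items():
        length = lengths.get(gene_id)
        if length is None:
            raise ValueError(f"no length for gene {gene_id}")
        if length <= 0:
            raise ValueError(f"non-positive length for gene {gene_id}")
        rows.append({"gene_id": gene_id, "count": float(count), "length": float(length)})
    table = pd.DataFrame(rows)
    table["saf"] = table["count"] / table["length"]
    total = table["saf"].sum()
    if total <= 0:
        raise ValueError("all spectral counts are zero")
    table["nsaf"] = table["saf"] / total
    table["rank"] = (
        table["nsaf"].rank(ascending=False, method="first").astype(int)
    )
    return table.sort_values("rank", ignore_index=True)


def effective_length(
    transcript_lengths: Sequence[float],
    rule: str = "median",
    seed: int | None = None,
) -> float:
    """Collapse multiple transcript lengths to one effective length.

    ``median`` (default; even-length lists use the mean of the central
    pair), ``shortest``, ``longest``, or ``random`` (seeded draw).
    """
    if not transcript_lengths:
        raise ValueError("empty transcript length list")
    if rule == "median":
        return float(np.median(transcript_lengths))
    if rule == "shortest":
        return float(min(transcript_lengths))
    if rule == "longest":
        return float(max(transcript_lengths))
    if rule == "random":
        rng = np.random.default_rng(seed)
        return float(rng.choice(transcript_lengths))
    raise ValueError(f"unknown rule {rule!r}")


def discovery_curve(
    replicate_sets: Sequence[Iterable[str]],
) -> tuple[list[int], list[int]]:
    """Cumulative distinct genes across ordered technical replicates.

    Returns (cumulative counts, per-replicate new-gene increments).
    """
    seen: set[str] = set()
    cumulative, increments = [], []
    for genes in replicate_sets:
        before = len(seen)
        seen |= set(genes)
        cumulative.append(len(seen))
        increments.append(len(seen) - before)
    return cumulative, increments


def arcsin_sqrt(values: Iterable[float]) -> np.ndarray:
    """Variance-stabilizing arcsin-square-root transform, clipped to [0, 1]."""
    arr = np.clip(np.asarray(list(values), dtype=float), 0.0, 1.0)
    return np.arcsin(np.sqrt(arr))


def first_vs_later_nsaf(
    first_set: Iterable[str],
    later_set: Iterable[str],
    nsaf_table: pd.DataFrame,
) -> dict:
    """Compare NSAF of first-replicate vs later-discovered genes.

    Applies the arcsin-sqrt transform and a two-sided Wilcoxon rank-sum
    test; abundant proteins should be found immediately, so the
    first-replicate group is expected to sit higher.
    """
    first = set(first_set)
    later = set(later_set)
    if first & later:
        raise ValueError("first and later gene sets must be disjoint")
    by_gene = nsaf_table.set_index("gene_id")["nsaf"]
    missing = (first | later) - set(by_gene.index)
    if missing:
        raise ValueError(f"genes without NSAF: {sorted(missing)[:5]}")
    x = arcsin_sqrt(by_gene.loc[sorted(first)])
    y = arcsin_sqrt(by_gene.loc[sorted(later)])
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    w, p = wilcoxon_rank_sum(x, y)
    return {
        "median_first": float(np.median(x)),
        "median_later": float(np.median(y)),
        "W": w,
        "p_value": p,
        "n_first": len(x),
        "n_later": len(y),
    }
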