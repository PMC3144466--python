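"""Molecular-evolution stage: dN/dS, QC filters, selection tests, statistics.

Maximum-likelihood codon-model fitting (M7/M8/M8a) and FEL site tests are
consumed as input tables; this module owns the decisions built on them:
pairwise quality control with the printed boundary semantics, the
likelihood-ratio tests, the five-criterion recurrent-positive-selection
verdict, and the two comparative statistics (Wilcoxon rank-sum with the
pair-counting W convention, Fisher's exact test). A Nei-Gojobori (1986)
pathway-counting dN/dS estimator is included so synthetic codon data can
be scored without external fitters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DnDsResult",
    "SelectionVerdict",
    "ng86_dnds",
    "pairwise_qc",
    "five_species_qc",
    "lrt_pvalue",
    "selection_verdict",
    "verdict_table",
    "wilcoxon_rank_sum",
    "fisher_exact_2x2",
]

_BASES = "TCAG"
_CODON_TABLE: dict[str, str] = {}
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _aa = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"[
                _i * 16 + _j * 4 + _k
            ]
            _CODON_TABLE[_b1 + _b2 + _b3] = _aa

_STOPS = {c for c, aa in _CODON_TABLE.items() if aa == "*"}


@dataclass(frozen=True)
class DnDsResult:
    dn: float
    ds: float
    omega: float | None  # None when dS == 0 (undefined ratio)


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    At each position, the synonymous fraction of the three possible
    single-nucleotide changes; mutations creating stop codons count as
    nonsynonymous.
    """
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_TABLE[mutant] == _CODON_TABLE[codon]:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons,
    averaged over all substitution orderings with equal weights; orderings
    passing through a stop codon are excluded (all orderings used if every
    one is blocked)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        current = c1
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
                break
            if _CODON_TABLE[nxt] == _CODON_TABLE[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if not blocked:
            paths.append((syn, nonsyn))
    if not paths:  # every ordering hits a stop; fall back to all orderings
        for order in permutations(diff_pos):
            current = c1
            syn = nonsyn = 0
            for pos in order:
                nxt = current[:pos] + c2[pos] + current[pos + 1 :]
                if _CODON_TABLE[nxt] == _CODON_TABLE[current]:
                    syn += 1
                else:
                    nonsyn += 1
                current = nxt
            paths.append((syn, nonsyn))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    # saturation: the correction diverges at p = 3/4 (e.g. a single fully
    # substituted site); report an infinite distance rather than failing
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _validate_cds(cds: str, name: str) -> str:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"{name} length {len(cds)} is not a multiple of 3")
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon not in _CODON_TABLE:
            raise ValueError(f"invalid codon {codon!r} at position {i} in {name}")
        if codon in _STOPS:
            raise ValueError(f"internal stop codon {codon} at position {i} in {name}")
    return cds


def ng86_dnds(cds1: str, cds2: str) -> DnDsResult:
    """Nei-Gojobori (1986) pairwise dN/dS with Jukes-Cantor correction.

    Synonymous/nonsynonymous sites are averaged between the two
    sequences; differences use equal-weight pathway counting. ``omega``
    is None when dS = 0.
    """
    cds1 = _validate_cds(cds1, "cds1")
    cds2 = _validate_cds(cds2, "cds2")
    if len(cds1) != len(cds2):
        raise ValueError("sequences must have equal length")
    if not cds1:
        raise ValueError("empty sequences")
    s_sites = n_sites = sd = nd = 0.0
    for i in range(0, len(cds1), 3):
        a, b = cds1[i : i + 3], cds2[i : i + 3]
        sa, na = _codon_sites(a)
        sb, nb = _codon_sites(b)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        d_s, d_n = _pathway_differences(a, b)
        sd += d_s
        nd += d_n
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    omega = None if ds == 0.0 else dn / ds
    return DnDsResult(dn=dn, ds=ds, omega=omega)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def pairwise_qc(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise ortholog QC with the printed boundary semantics.

    Removes genes with aligned_codons < 100, dN > 1 (dN = 1 kept), or
    dS >= 0.381 (dS = 0.381 removed). Returns (kept, removed) where the
    removed table carries comma-joined reason codes.
    """
    required = {"gene_id", "aligned_codons", "dN", "dS"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (records["dN"] < 0).any() or (records["dS"] < 0).any():
        raise ValueError("negative substitution rates")
    reasons = []
    for _, row in records.iterrows():
        codes = []
        if row["aligned_codons"] < 100:
            codes.append("codons")
        if row["dN"] > 1.0:
            codes.append("dn")
        if row["dS"] >= 0.381:
            codes.append("ds")
        reasons.append(",".join(codes))
    records = records.copy()
    records["qc_reasons"] = reasons
    kept = records[records["qc_reasons"] == ""].drop(columns="qc_reasons")
    removed = records[records["qc_reasons"] != ""]
    return kept.reset_index(drop=True), removed.reset_index(drop=True)


def five_species_qc(
    fits: pd.DataFrame, max_ratio: float = 2.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop genes whose maximum pairwise dS exceeds ``max_ratio`` times
    the genome median (strictly greater; the ``pairwise_dS_max_ratio``
    column is already expressed relative to the genome median)."""
    if "pairwise_dS_max_ratio" not in fits.columns:
        raise ValueError("fits table lacks pairwise_dS_max_ratio")
    mask = fits["pairwise_dS_max_ratio"] > max_ratio
    return (
        fits[~mask].reset_index(drop=True),
        fits[mask].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# likelihood-ratio machinery
# ---------------------------------------------------------------------------

def lrt_pvalue(
    lnl_null: float, lnl_alt: float, df: int
) -> tuple[float, float]:
    """(2ΔL, p) for a nested likelihood-ratio test.

    p is the plain chi-square upper tail with ``df`` degrees of freedom
    (M7 vs M8: df=2; M8a vs M8: df=1). Small negative gaps from optimizer
    noise (> -1e-6) are clamped to zero.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    gap = lnl_alt - lnl_null
    if gap < -1e-6:
        raise ValueError(
            f"alternative log-likelihood below null by {-gap:.3g}; not nested fits?"
        )
    if gap < 0.0:
        logger.warning("clamping negative log-likelihood gap %.3g to 0", gap)
        gap = 0.0
    two_delta = 2.0 * gap
    return two_delta, float(stats.chi2.sf(two_delta, df))


@dataclass(frozen=True)
class SelectionVerdict:
    """Five-criterion recurrent-positive-selection call for one gene."""

    gene_id: str
    c1_m7_vs_m8: bool  # M8 beats M7 at alpha1 (df 2)
    c2_m8a_vs_m8: bool  # M8 beats M8a at alpha2 (df 1)
    c3_omega_gt: bool  # extra omega class > omega_min
    c4_prop_ge: bool  # >= prop_min of codons in that class
    c5_fel_sites: bool  # >= fel_min FEL-positive codons

    @property
    def selected(self) -> bool:
        return (
            self.c1_m7_vs_m8
            and self.c2_m8a_vs_m8
            and self.c3_omega_gt
            and self.c4_prop_ge
            and self.c5_fel_sites
        )


def selection_verdict(
    fit: Mapping,
    alpha1: float = 0.01,
    alpha2: float = 0.01,
    omega_min: float = 1.1,
    prop_min: float = 0.01,
    fel_min: int = 1,
) -> SelectionVerdict:
    """Apply the five recurrent-selection criteria to one site-model fit."""
    for key in ("lnL_M7", "lnL_M8", "lnL_M8a"):
        if key not in fit or fit[key] is None or (
            isinstance(fit[key], float) and math.isnan(fit[key])
        ):
            raise ValueError(f"missing likelihood {key}")
    _, p1 = lrt_pvalue(fit["lnL_M7"], fit["lnL_M8"], df=2)
    _, p2 = lrt_pvalue(fit["lnL_M8a"], fit["lnL_M8"], df=1)
    return SelectionVerdict(
        gene_id=str(fit.get("gene_id", "")),
        c1_m7_vs_m8=p1 < alpha1,
        c2_m8a_vs_m8=p2 < alpha2,
        c3_omega_gt=fit["omega_extra"] > omega_min,
        c4_prop_ge=fit["prop_extra"] >= prop_min,
        c5_fel_sites=fit["fel_sites"] >= fel_min,
    )


def verdict_table(fits: pd.DataFrame, **kwargs) -> pd.DataFrame:
    rows = []
    for _, fit in fits.iterrows():
        v = selection_verdict(fit, **kwargs)
        rows.append(
            {
                "gene_id": v.gene_id,
                "c1": v.c1_m7_vs_m8,
                "c2": v.c2_m8a_vs_m8,
                "c3": v.c3_omega_gt,
                "c4": v.c4_prop_ge,
                "c5": v.c5_fel_sites,
                "selected": v.selected,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "c1", "c2", "c3", "c4", "c5", "selected"]
    )


# ---------------------------------------------------------------------------
# comparative statistics
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    W is the number of (x_i, y_j) pairs with x_i > y_j plus half the
    ties — the Mann-Whitney U of the first sample, the convention used
    by R's ``wilcox.test``. The two-sided p-value is exact (the full
    permutation null distribution of U) when min(n, m) <= 8 and there
    are no ties, and a tie-corrected normal approximation with
    continuity correction otherwise; a degenerate statistic (all values
    tied) yields p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    has_ties = len(np.unique(pooled)) < n1 + n2
    if not has_ties and min(n1, n2) <= 8:
        # exact null distribution of U (doubled smaller tail); computed by
        # scipy's recursion, which matches full permutation enumeration
        result = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="exact"
        )
        return float(u), float(result.pvalue)

    mean = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return float(u), 1.0
    delta = u - mean
    cc = 0.5 * np.sign(delta)
    z = (delta - cc) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return float(u), float(p)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test on a 2x2 table.

    Point-probability rule: sums the probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's.
    """
    counts = (a, b, c, d)
    if any(v < 0 or int(v) != v for v in counts):
        raise ValueError("counts must be non-negative integers")
    if sum(counts) == 0:
        raise ValueError("all-zero table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)
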