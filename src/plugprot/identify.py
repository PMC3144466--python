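"""Protein identification: decoys, FDR filtering, inference, counting.

The identification contract mirrors conservative shotgun-proteomics
practice: a target-decoy search controls the per-spectrum false discovery
rate at 1%, and a gene counts as identified only when matched by at least
two distinct peptides, at least one mapping uniquely to that gene. Spectra
from peptides shared among paralogs are apportioned fractionally (1/n per
mapped gene), which conserves total spectral counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import n15_mass_adjustment, peptide_mass, tryptic_digest
from .simulate import ProteomeFixture, Protein

__all__ = [
    "GeneIdentification",
    "FdrResult",
    "decoy_database",
    "filter_psms_fdr",
    "build_peptide_index",
    "match_labeled_mode",
    "map_peptides",
    "infer_genes",
    "fractional_counts",
    "female_induced_filter",
    "identification_report",
]


@dataclass
class GeneIdentification:
    gene_id: str
    peptides: set[str]
    n_unique_peptides: int
    spectral_count: float


# ---------------------------------------------------------------------------
# decoys
# ---------------------------------------------------------------------------

def decoy_database(fixture: ProteomeFixture, seed: int = 0) -> ProteomeFixture:
    """One shuffled decoy per target protein (same length and residue
    multiset), gene ids prefixed ``DECOY_``."""
    if not fixture.proteins:
        raise ValueError("fixture is empty")
    rng = np.random.default_rng(seed)
    decoys = [
        Protein(
            gene_id=f"DECOY_{p.gene_id}",
            origin=p.origin,
            sequence="".join(rng.permutation(list(p.sequence))),
        )
        for p in fixture.proteins
    ]
    family_map = {d.gene_id: f"DECOY_{fixture.family_map[p.gene_id]}"
                  for d, p in zip(decoys, fixture.proteins)}
    return ProteomeFixture(proteins=decoys, family_map=family_map)


# ---------------------------------------------------------------------------
# FDR filtering
# ---------------------------------------------------------------------------

@dataclass
class FdrResult:
    accepted: pd.DataFrame
    threshold: float | None
    n_targets_at_threshold: int
    n_decoys_at_threshold: int

    @property
    def estimated_fdr(self) -> float:
        if self.n_targets_at_threshold == 0:
            return 0.0
        return self.n_decoys_at_threshold / self.n_targets_at_threshold


def filter_psms_fdr(psms: pd.DataFrame, fdr: float = 0.01) -> FdrResult:
    """Accept target PSMs at a decoy-estimated per-spectrum FDR.

    Finds the lowest score threshold ``s`` such that
    ``(#decoys >= s) / (#targets >= s) <= fdr`` and accepts all target
    PSMs with score >= s (ties at the threshold accepted). Returns an
    empty acceptance when no threshold attains the requested FDR.
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError(f"fdr must be in (0, 1), got {fdr}")
    if "is_decoy" not in psms.columns or "score" not in psms.columns:
        raise ValueError("psms must carry 'score' and 'is_decoy' columns")
    is_decoy = psms["is_decoy"].to_numpy(dtype=bool)
    if not is_decoy.any():
        raise ValueError("no decoy PSMs: FDR is undefined")
    scores = psms["score"].to_numpy(dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite PSM score")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_decoy = is_decoy[order]
    cum_decoys = np.cumsum(sorted_decoy)
    cum_targets = np.cumsum(~sorted_decoy)
    # candidate thresholds: each distinct score, evaluated at the last
    # (lowest-ranked) PSM carrying it so ties are fully included
    last_of_score = np.r_[sorted_scores[:-1] != sorted_scores[1:], True]
    ok = np.zeros(len(sorted_scores), dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cum_targets > 0, cum_decoys / np.maximum(cum_targets, 1),
                         np.inf)
    ok = last_of_score & (ratio <= fdr) & (cum_targets > 0)
    if not ok.any():
        empty = psms.iloc[0:0]
        return FdrResult(empty, None, 0, 0)
    best = np.flatnonzero(ok)[-1]  # lowest qualifying threshold
    threshold = float(sorted_scores[best])
    accepted = psms[(scores >= threshold) & ~is_decoy]
    return FdrResult(
        accepted=accepted.reset_index(drop=True),
        threshold=threshold,
        n_targets_at_threshold=int(cum_targets[best]),
        n_decoys_at_threshold=int(cum_decoys[best]),
    )


# ---------------------------------------------------------------------------
# labeled-mode matching
# ---------------------------------------------------------------------------

def build_peptide_index(
    fixture: ProteomeFixture, max_missed: int = 0
) -> dict[str, float]:
    """peptide -> monoisotopic mass over all tryptic peptides of the
    fixture (unique peptide strings)."""
    index: dict[str, float] = {}
    for protein in fixture.proteins:
        for pep in tryptic_digest(protein.sequence, max_missed):
            if pep not in index:
                index[pep] = peptide_mass(pep)
    return index


def match_labeled_mode(
    query_mass: float,
    peptide_index: Mapping[str, float],
    incorporation: float = 0.95,
    tol_ppm: float = 10.0,
    exact: bool = False,
) -> list[str]:
    """Peptides whose labeled mass lies within ``tol_ppm`` of the query.

    The labeled (expected) mass is the peptide's monoisotopic mass plus
    the per-nitrogen labeling shift; with ``incorporation=0`` this is
    plain natural-mode matching. Tolerance is relative to the expected
    mass.
    """
    if not peptide_index:
        raise ValueError("empty peptide index")
    matches = []
    for pep, mass in peptide_index.items():
        expected = mass + n15_mass_adjustment(pep, incorporation, exact=exact)
        if abs(query_mass - expected) <= expected * tol_ppm * 1e-6:
            matches.append(pep)
    return sorted(matches)


# ---------------------------------------------------------------------------
# peptide -> gene mapping and inference
# ---------------------------------------------------------------------------

def map_peptides(
    peptides: Iterable[str],
    fixture: ProteomeFixture,
    decoys: ProteomeFixture | None = None,
    max_missed: int = 0,
) -> dict[str, tuple[list[str], int]]:
    """peptide -> (sorted gene list containing it, n_locations).

    Containment is exact tryptic-peptide identity against each gene's
    digest; decoy genes, when given, participate so decoy hits are
    attributable. n_locations counts distinct genes.
    """
    per_gene: dict[str, set[str]] = {}
    for fx in filter(None, (fixture, decoys)):
        per_gene.update(fx.tryptic_peptides(max_missed))
    wanted = set(peptides)
    hits: dict[str, list[str]] = {p: [] for p in wanted}
    for gene_id, peps in per_gene.items():
        for p in wanted & peps:
            hits[p].append(gene_id)
    return {p: (sorted(genes), len(genes)) for p, genes in hits.items()}


def infer_genes(
    accepted: pd.DataFrame,
    mapping: Mapping[str, tuple[list[str], int]],
) -> tuple[list[GeneIdentification], list[GeneIdentification]]:
    """Apply the two-peptide / one-unique rule.

    A gene is identified iff >= 2 distinct peptides map to it and at
    least one of them maps uniquely (n_locations == 1). Genes failing
    only the uniqueness clause are returned separately as ambiguous
    identifications. Spectral counts are fractional (1/n_locations per
    PSM).
    """
    counts = fractional_counts(accepted, mapping)
    gene_peptides: dict[str, set[str]] = {}
    gene_unique: dict[str, set[str]] = {}
    for pep in set(accepted["peptide"]):
        genes, n_loc = mapping.get(pep, ([], 0))
        for g in genes:
            gene_peptides.setdefault(g, set()).add(pep)
            if n_loc == 1:
                gene_unique.setdefault(g, set()).add(pep)
    identified, ambiguous = [], []
    for gene_id in sorted(gene_peptides):
        peps = gene_peptides[gene_id]
        n_unique = len(gene_unique.get(gene_id, ()))
        record = GeneIdentification(
            gene_id=gene_id,
            peptides=peps,
            n_unique_peptides=n_unique,
            spectral_count=counts.get(gene_id, 0.0),
        )
        if len(peps) >= 2 and n_unique >= 1:
            identified.append(record)
        elif len(peps) >= 2:
            ambiguous.append(record)
    return identified, ambiguous


def fractional_counts(
    accepted: pd.DataFrame,
    mapping: Mapping[str, tuple[list[str], int]],
) -> dict[str, float]:
    """Each PSM contributes 1/n_locations to every gene containing its
    peptide; the sum over genes equals the number of mapped PSMs."""
    counts: dict[str, float] = {}
    psm_per_peptide = accepted["peptide"].value_counts()
    for pep, n_psm in psm_per_peptide.items():
        genes, n_loc = mapping.get(pep, ([], 0))
        if n_loc == 0:
            continue
        share = n_psm / n_loc
        for g in genes:
            counts[g] = counts.get(g, 0.0) + share
    return counts


def identification_report(
    identified: Sequence[GeneIdentification],
    ambiguous: Sequence[GeneIdentification] = (),
) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id,
            "n_peptides": len(r.peptides),
            "n_unique": r.n_unique_peptides,
            "spectral_count": r.spectral_count,
            "status": status,
        }
        for status, records in (("identified", identified), ("ambiguous", ambiguous))
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "n_peptides", "n_unique", "spectral_count", "status"]
    )


# ---------------------------------------------------------------------------
# female induced-protein filter
# ---------------------------------------------------------------------------

def female_induced_filter(
    labeled_ids: Iterable[str],
    secretion_prob: Mapping[str, float],
    unmated_ids: Iterable[str],
    male_ids: Iterable[str],
    secretion_threshold: float = 0.90,
) -> pd.DataFrame:
    """Three-criteria filter for mating-induced female proteins.

    A labeled (female-derived) gene is retained iff it (i) has a
    predicted secretion signal at P > ``secretion_threshold``, (ii) was
    not identified in the unmated labeled control, and (iii) is not a
    male-derived seminal-fluid gene. Genes with no secretion probability
    fail criterion (i). Returns the per-gene criterion breakdown.
    """
    unmated = set(unmated_ids)
    male = set(male_ids)
    rows = []
    for gene_id in sorted(set(labeled_ids)):
        prob = secretion_prob.get(gene_id)
        c_secretion = prob is not None and prob > secretion_threshold
        c_not_unmated = gene_id not in unmated
        c_not_male = gene_id not in male
        rows.append(
            {
                "gene_id": gene_id,
                "secretion_prob": np.nan if prob is None else prob,
                "c_secretion": c_secretion,
                "c_not_unmated": c_not_unmated,
                "c_not_male": c_not_male,
                "induced": c_secretion and c_not_unmated and c_not_male,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "secretion_prob",
            "c_secretion",
            "c_not_unmated",
            "c_not_male",
            "induced",
        ],
    )
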