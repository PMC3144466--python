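"""Synthetic-data generation for the whole pipeline.

The real experiment mated unlabeled males to 15N-labeled females and ran
the female reproductive-tract contents (two copulatory plugs, two uterine
fluids, one unmated control) through LC-MS/MS technical replicates. No raw
data are available, so this module emulates the statistical structure of
that experiment at the peptide-spectrum-match level: a proteome with
paralogous families and seven plug proteins that dominate spectral counts,
a sample/replicate design, 15N labeling of female-origin peptides with
rare unlabeled leakage, decoy matches, and incorrect target matches drawn
from the null score distribution. A companion generator produces
evolutionary-rate tables with known ground truth for the selection
classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem import n15_mass_adjustment, peptide_mass, tryptic_digest

__all__ = [
    "Protein",
    "ProteomeFixture",
    "SampleSpec",
    "AbundanceModel",
    "ExperimentDesign",
    "SimulationResult",
    "generate_proteome",
    "simulate_experiment",
    "generate_annotations",
    "generate_evolution_table",
    "tryptic_digest",
    "PSM_COLUMNS",
]

ORIGINS = ("male_seminal", "male_plug", "female", "contaminant")

#: PSM-table columns: the interchange columns plus two trailing truth
#: columns (the injected-incorrect-match flag, needed to measure realized
#: FDR, and the generating gene, needed to audit abundance structure).
PSM_COLUMNS = [
    "spectrum_id",
    "sample_id",
    "replicate",
    "peptide",
    "charge",
    "observed_mass",
    "score",
    "is_decoy",
    "label_mode_truth",
    "is_false_truth",
    "gene_id_truth",
]

_INTERIOR_RESIDUES = np.array(list("ACDEFGHILMNQSTVWY"))  # no K/R/P
_INTERIOR_WITH_P = np.array(list("ACDEFGHILMNPQSTVWY"))


@dataclass(frozen=True)
class Protein:
    gene_id: str
    origin: str
    sequence: str


@dataclass
class ProteomeFixture:
    """A synthetic protein universe with paralog-family structure."""

    proteins: list[Protein]
    family_map: dict[str, str]

    def __post_init__(self) -> None:
        ids = [p.gene_id for p in self.proteins]
        if len(set(ids)) != len(ids):
            raise ValueError("gene_ids must be unique")
        for p in self.proteins:
            if not p.sequence:
                raise ValueError(f"empty sequence for {p.gene_id}")
            if p.origin not in ORIGINS:
                raise ValueError(f"unknown origin {p.origin!r}")

    @property
    def gene_ids(self) -> list[str]:
        return [p.gene_id for p in self.proteins]

    def by_origin(self, *origins: str) -> list[Protein]:
        return [p for p in self.proteins if p.origin in origins]

    def sequences(self) -> dict[str, str]:
        return {p.gene_id: p.sequence for p in self.proteins}

    def lengths(self) -> dict[str, int]:
        return {p.gene_id: len(p.sequence) for p in self.proteins}

    def tryptic_peptides(self, max_missed: int = 0) -> dict[str, set[str]]:
        return {
            p.gene_id: set(tryptic_digest(p.sequence, max_missed))
            for p in self.proteins
        }

    def to_fasta(self, path) -> None:
        from . import io

        io.write_fixture_fasta(self, path)

    @classmethod
    def from_fasta(cls, path) -> "ProteomeFixture":
        from . import io

        return io.read_fixture_fasta(path)


def _random_block(rng: np.random.Generator, seen: set[str]) -> str:
    """One tryptic 'block': interior residues without K/R, terminal K/R,
    no proline in first position (so the upstream cleavage is real).
    Globally unique via the ``seen`` set."""
    for _ in range(200):
        length = int(rng.integers(6, 31))
        first = rng.choice(_INTERIOR_RESIDUES)
        interior = rng.choice(_INTERIOR_WITH_P, size=length - 2)
        terminal = rng.choice(np.array(["K", "R"]))
        block = str(first) + "".join(interior) + str(terminal)
        if block not in seen:
            seen.add(block)
            return block
    raise RuntimeError("could not generate a unique tryptic block")


def generate_proteome(
    n_male: int = 20,
    n_female: int = 30,
    n_plug: int = 7,
    length_range: tuple[int, int] = (80, 400),
    family_fraction: float = 0.2,
    seed: int = 0,
    n_contaminant: int = 0,
) -> ProteomeFixture:
    """Generate a synthetic proteome fixture.

    Proteins are concatenations of unique tryptic blocks, so with
    ``family_fraction=0`` no tryptic peptide occurs in two genes. A
    ``family_fraction`` of genes is grouped into paralog families of 2-3
    members sharing one identical tryptic peptide, which exercises
    multi-mapping downstream. The first ``n_plug`` male genes model the
    copulatory-plug proteins (seminal-vesicle secretions plus the
    cross-linking transglutaminase).
    """
    if n_male <= 0 or n_female <= 0:
        raise ValueError("n_male and n_female must be positive")
    if n_plug < 0 or n_plug > n_male:
        raise ValueError("need 0 <= n_plug <= n_male")
    if not 0.0 <= family_fraction < 1.0:
        raise ValueError("family_fraction must be in [0, 1)")
    if n_contaminant < 0:
        raise ValueError("n_contaminant must be >= 0")
    lo, hi = length_range
    if lo < 10 or hi < lo:
        raise ValueError(f"invalid length_range {length_range}")

    rng = np.random.default_rng(seed)
    seen: set[str] = set()

    specs: list[tuple[str, str]] = []
    for i in range(n_plug):
        specs.append((f"PLUG{i + 1}", "male_plug"))
    for i in range(n_male - n_plug):
        specs.append((f"MALE{i + 1:03d}", "male_seminal"))
    for i in range(n_female):
        specs.append((f"FEM{i + 1:03d}", "female"))
    for i in range(n_contaminant):
        specs.append((f"CONT{i + 1:02d}", "contaminant"))

    blocks: dict[str, list[str]] = {}
    for gene_id, _ in specs:
        target = int(rng.integers(lo, hi + 1))
        gene_blocks: list[str] = []
        total = 0
        while total < target:
            block = _random_block(rng, seen)
            gene_blocks.append(block)
            total += len(block)
        blocks[gene_id] = gene_blocks

    family_map = {gene_id: gene_id for gene_id, _ in specs}
    n_family_genes = int(round(family_fraction * len(specs)))
    if n_family_genes >= 2:
        order = rng.permutation(len(specs))[:n_family_genes]
        members = [specs[i][0] for i in order]
        fam_idx = 0
        pos = 0
        while len(members) - pos >= 2:
            size = 3 if (len(members) - pos >= 3 and rng.random() < 0.5) else 2
            size = min(size, len(members) - pos)
            fam_idx += 1
            shared = _random_block(rng, seen)
            for gene_id in members[pos : pos + size]:
                insert_at = int(rng.integers(0, len(blocks[gene_id]) + 1))
                blocks[gene_id].insert(insert_at, shared)
                family_map[gene_id] = f"FAM{fam_idx}"
            pos += size

    proteins = [
        Protein(gene_id, origin, "".join(blocks[gene_id]))
        for gene_id, origin in specs
    ]
    return ProteomeFixture(proteins=proteins, family_map=family_map)


# ---------------------------------------------------------------------------
# experiment design & simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    kind: str  # plug | uterine | unmated_control
    n_replicates: int

    def __post_init__(self) -> None:
        if self.kind not in ("plug", "uterine", "unmated_control"):
            raise ValueError(f"unknown sample kind {self.kind!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class AbundanceModel:
    """Log-normal per-gene expected spectra with a plug-gene multiplier.

    ``log_mu``/``log_sigma`` parameterize the log-normal of a gene's
    expected total spectra per biological sample; the skew reproduces the
    few-genes-many-spectra character of real spectral counts. The plug
    multiplier is calibrated per draw so the plug genes' expected share of
    true male spectra equals ``plug_share`` (default 37%, the share the
    seven plug proteins carried in the study). ``female_scale`` scales
    female-protein abundance relative to male.
    """

    log_mu: float = math.log(20.0)
    log_sigma: float = 1.0
    plug_share: float = 0.37
    female_scale: float = 0.5


@dataclass(frozen=True)
class ExperimentDesign:
    """The study design: samples, labeling, abundance and noise models."""

    samples: tuple[SampleSpec, ...] = (
        SampleSpec("plug1", "plug", 7),
        SampleSpec("plug2", "plug", 7),
        SampleSpec("uterine1", "uterine", 5),
        SampleSpec("uterine2", "uterine", 5),
        SampleSpec("control", "unmated_control", 1),
    )
    enrichment: float = 0.95
    leakage_rate: float = 0.02
    abundance: AbundanceModel = AbundanceModel()
    decoy_rate: float = 0.10
    detect_prob: float = 0.5
    detect_length: tuple[int, int] = (6, 30)
    true_score_mean: float = 4.0
    null_score_mean: float = 1.5
    score_sd: float = 1.0
    mass_ppm_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("enrichment", "leakage_rate", "decoy_rate", "detect_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not self.samples:
            raise ValueError("at least one sample required")

    @property
    def n_tables(self) -> int:
        return sum(s.n_replicates for s in self.samples)


@dataclass
class SimulationResult:
    """PSM tables keyed by (sample_id, replicate) plus generation truth."""

    tables: dict[tuple[str, int], pd.DataFrame]
    gene_expected: pd.DataFrame  # gene_id, origin, per-sample expectation
    n_decoys: int
    n_false_targets: int
    design: ExperimentDesign

    def combined(self) -> pd.DataFrame:
        return pd.concat(self.tables.values(), ignore_index=True)

    @property
    def n_psms(self) -> int:
        return sum(len(t) for t in self.tables.values())


def _detectable_peptides(
    fixture: ProteomeFixture, length_bounds: tuple[int, int]
) -> dict[str, list[str]]:
    lo, hi = length_bounds
    result = {}
    for protein in fixture.proteins:
        peptides = [
            p for p in tryptic_digest(protein.sequence) if lo <= len(p) <= hi
        ]
        result[protein.gene_id] = peptides or tryptic_digest(protein.sequence)
    return result


def simulate_experiment(
    fixture: ProteomeFixture, design: ExperimentDesign
) -> SimulationResult:
    """Simulate PSM tables for every sample x technical replicate.

    Per biological sample, each gene's total spectra are Poisson around a
    log-normal expectation; each technical replicate then sees a binomial
    thinning of that total (``detect_prob``), which makes discovery curves
    across replicates emergent. Female-origin PSMs are 15N-labeled with
    probability ``1 - leakage_rate`` and carry the exact labeled mass
    shift; male and contaminant PSMs are natural. The unmated control
    contains only female-origin material. Decoy matches and incorrect
    target matches are injected at ``decoy_rate`` each, with scores from
    the shifted null distribution.
    """
    if not fixture.proteins:
        raise ValueError("fixture is empty")
    rng = np.random.default_rng(design.seed)
    model = design.abundance

    peptides = _detectable_peptides(fixture, design.detect_length)
    pep_mass = {
        g: np.array([peptide_mass(p) for p in peps])
        for g, peps in peptides.items()
    }
    pep_shift = {
        g: np.array(
            [n15_mass_adjustment(p, design.enrichment, exact=True) for p in peps]
        )
        for g, peps in peptides.items()
    }

    origins = {p.gene_id: p.origin for p in fixture.proteins}
    gene_ids = fixture.gene_ids
    lam = rng.lognormal(model.log_mu, model.log_sigma, size=len(gene_ids))
    lam = dict(zip(gene_ids, lam))
    for g in lam:
        if origins[g] == "female":
            lam[g] *= model.female_scale

    plug = [g for g in gene_ids if origins[g] == "male_plug"]
    other_male = [g for g in gene_ids if origins[g] == "male_seminal"]
    if plug and other_male and model.plug_share > 0:
        target = model.plug_share
        multiplier = (
            target / (1.0 - target)
            * sum(lam[g] for g in other_male)
            / sum(lam[g] for g in plug)
        )
        for g in plug:
            lam[g] *= multiplier

    all_target_peps = [p for peps in peptides.values() for p in peps]
    tables: dict[tuple[str, int], pd.DataFrame] = {}
    n_decoys_total = 0
    n_false_total = 0
    expected_rows = []

    for sample in design.samples:
        if sample.kind == "unmated_control":
            active = [g for g in gene_ids if origins[g] == "female"]
        else:
            active = list(gene_ids)
        totals = {g: rng.poisson(lam[g]) for g in active}
        for g in active:
            expected_rows.append(
                {
                    "gene_id": g,
                    "origin": origins[g],
                    "sample_id": sample.sample_id,
                    "expected": lam[g],
                    "total_drawn": totals[g],
                }
            )
        for rep in range(1, sample.n_replicates + 1):
            rows: list[dict] = []
            for g in active:
                count = int(rng.binomial(totals[g], design.detect_prob))
                if count == 0:
                    continue
                idx = rng.integers(0, len(peptides[g]), size=count)
                charges = rng.choice([2, 3], size=count, p=[0.7, 0.3])
                if origins[g] == "female":
                    labeled = rng.random(count) >= design.leakage_rate
                else:
                    labeled = np.zeros(count, dtype=bool)
                base = pep_mass[g][idx] + np.where(labeled, pep_shift[g][idx], 0.0)
                masses = base * (
                    1.0 + rng.normal(0.0, design.mass_ppm_sd, count) * 1e-6
                )
                scores = rng.normal(design.true_score_mean, design.score_sd, count)
                for k in range(count):
                    rows.append(
                        {
                            "peptide": peptides[g][idx[k]],
                            "charge": int(charges[k]),
                            "observed_mass": float(masses[k]),
                            "score": float(scores[k]),
                            "is_decoy": False,
                            "label_mode_truth": "labeled" if labeled[k] else "natural",
                            "is_false_truth": False,
                            "gene_id_truth": g,
                        }
                    )
            n_true = len(rows)
            n_decoy = int(round(design.decoy_rate * n_true))
            n_false = int(round(design.decoy_rate * n_true))
            for _ in range(n_decoy):
                source = all_target_peps[int(rng.integers(0, len(all_target_peps)))]
                shuffled = "".join(rng.permutation(list(source)))
                rows.append(
                    {
                        "peptide": shuffled,
                        "charge": int(rng.choice([2, 3])),
                        "observed_mass": peptide_mass(shuffled),
                        "score": float(
                            rng.normal(design.null_score_mean, design.score_sd)
                        ),
                        "is_decoy": True,
                        "label_mode_truth": "natural",
                        "is_false_truth": False,
                        "gene_id_truth": "decoy",
                    }
                )
            for _ in range(n_false):
                source = all_target_peps[int(rng.integers(0, len(all_target_peps)))]
                rows.append(
                    {
                        "peptide": source,
                        "charge": int(rng.choice([2, 3])),
                        "observed_mass": peptide_mass(source),
                        "score": float(
                            rng.normal(design.null_score_mean, design.score_sd)
                        ),
                        "is_decoy": False,
                        "label_mode_truth": "natural",
                        "is_false_truth": True,
                        "gene_id_truth": "random_match",
                    }
                )
            n_decoys_total += n_decoy
            n_false_total += n_false
            table = pd.DataFrame(rows)
            table.insert(0, "replicate", rep)
            table.insert(0, "sample_id", sample.sample_id)
            table.insert(
                0,
                "spectrum_id",
                [
                    f"{sample.sample_id}_r{rep}_s{i:06d}"
                    for i in range(len(table))
                ],
            )
            tables[(sample.sample_id, rep)] = table[PSM_COLUMNS]

    return SimulationResult(
        tables=tables,
        gene_expected=pd.DataFrame(expected_rows),
        n_decoys=n_decoys_total,
        n_false_targets=n_false_total,
        design=design,
    )


def generate_annotations(
    fixture: ProteomeFixture,
    n_terms: int = 15,
    male_term: str = "GO:male_biased",
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic gene -> term annotation table (one pair per row).

    Background terms are assigned at random; ``male_term`` is enriched
    among male-origin genes so the overrepresentation stage has a real
    signal to find.
    """
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i + 1:04d}" for i in range(n_terms)]
    rows = []
    for protein in fixture.proteins:
        k = int(rng.integers(1, 4))
        for term in rng.choice(terms, size=k, replace=False):
            rows.append({"gene_id": protein.gene_id, "term_id": term})
        is_male = protein.origin in ("male_seminal", "male_plug")
        if rng.random() < (0.5 if is_male else 0.05):
            rows.append({"gene_id": protein.gene_id, "term_id": male_term})
    return pd.DataFrame(rows).drop_duplicates(ignore_index=True)


# ---------------------------------------------------------------------------
# evolutionary-rate tables with ground truth
# ---------------------------------------------------------------------------

_ORTHO_COLUMNS = ["gene_id", "aligned_codons", "dN", "dS", "omega"]
_FIT_COLUMNS = [
    "gene_id",
    "lnL_M7",
    "lnL_M8",
    "lnL_M8a",
    "omega_extra",
    "prop_extra",
    "fel_sites",
    "pairwise_dS_max_ratio",
]
_TRUTH_COLUMNS = [
    "gene_id",
    "selected",
    "qc_fail_codons",
    "qc_fail_dn",
    "qc_fail_ds",
    "qc_fail_pairwise",
]


def generate_evolution_table(
    n_genes: int,
    fraction_selected: float,
    effect: float = 1.0,
    seed: int = 0,
    qc_violation_rate: float = 0.05,
    gene_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Ortholog-rate and site-model-fit tables with known truth labels.

    Selected genes draw their likelihood-ratio statistics from noncentral
    chi-square distributions (noncentrality scaled by ``effect``), carry an
    extra omega class above 1.1 occupying at least 1% of codons, and at
    least one FEL-positive site, so for large ``effect`` they exceed the
    critical values of the five selection criteria with high probability.
    Null genes draw central chi-square statistics. Each QC rule (aligned
    codons, dN, dS, pairwise-dS ratio) is violated by an independent
    ``qc_violation_rate`` fraction of genes, flagged in the truth table.
    """
    if not 0.0 <= fraction_selected <= 1.0:
        raise ValueError("fraction_selected must be in [0, 1]")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if n_genes == 0:
        return (
            pd.DataFrame(columns=_ORTHO_COLUMNS),
            pd.DataFrame(columns=_FIT_COLUMNS),
            pd.DataFrame(columns=_TRUTH_COLUMNS),
        )
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    codons = rng.integers(120, 600, size=n_genes)
    dn = np.minimum(rng.lognormal(math.log(0.08), 0.8, size=n_genes), 0.99)
    ds = rng.uniform(0.05, 0.3, size=n_genes)
    ratio = rng.uniform(0.3, 1.8, size=n_genes)

    fail_codons = rng.random(n_genes) < qc_violation_rate
    fail_dn = rng.random(n_genes) < qc_violation_rate
    fail_ds = rng.random(n_genes) < qc_violation_rate
    fail_pairwise = rng.random(n_genes) < qc_violation_rate
    codons[fail_codons] = rng.integers(30, 100, size=int(fail_codons.sum()))
    dn[fail_dn] = rng.uniform(1.01, 2.0, size=int(fail_dn.sum()))
    ds[fail_ds] = rng.uniform(0.381, 0.6, size=int(fail_ds.sum()))
    ratio[fail_pairwise] = rng.uniform(2.05, 3.5, size=int(fail_pairwise.sum()))

    selected = rng.random(n_genes) < fraction_selected
    n_sel = int(selected.sum())

    two_dl1 = stats.chi2.rvs(2, size=n_genes, random_state=rng)
    two_dl2 = stats.chi2.rvs(1, size=n_genes, random_state=rng)
    if n_sel:
        two_dl1[selected] = stats.ncx2.rvs(
            2, 25.0 * effect, size=n_sel, random_state=rng
        )
        two_dl2[selected] = stats.ncx2.rvs(
            1, 20.0 * effect, size=n_sel, random_state=rng
        )

    lnl_m7 = -3000.0 + rng.normal(0.0, 50.0, size=n_genes)
    lnl_m8 = lnl_m7 + two_dl1 / 2.0
    lnl_m8a = lnl_m8 - two_dl2 / 2.0

    omega_extra = rng.uniform(0.3, 1.5, size=n_genes)
    prop_extra = rng.uniform(0.0, 0.05, size=n_genes)
    fel = rng.poisson(0.05, size=n_genes)
    if n_sel:
        omega_extra[selected] = 1.1 + effect * (
            0.3 + rng.exponential(0.5, size=n_sel)
        )
        prop_extra[selected] = rng.uniform(0.02, 0.12, size=n_sel)
        fel[selected] = 1 + rng.poisson(2.0, size=n_sel)

    ortho = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "aligned_codons": codons,
            "dN": dn,
            "dS": ds,
            "omega": dn / ds,
        }
    )
    fits = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "lnL_M7": lnl_m7,
            "lnL_M8": lnl_m8,
            "lnL_M8a": lnl_m8a,
            "omega_extra": omega_extra,
            "prop_extra": prop_extra,
            "fel_sites": fel,
            "pairwise_dS_max_ratio": ratio,
        }
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "selected": selected,
            "qc_fail_codons": fail_codons,
            "qc_fail_dn": fail_dn,
            "qc_fail_ds": fail_ds,
            "qc_fail_pairwise": fail_pairwise,
        }
    )
    return ortho, fits, truth
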