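"""End-to-end orchestration: simulate -> identify -> quantify -> enrich ->
evolve -> acquire, with a single root seed and a serializable config.

Every stage writes its TSV artifacts under the output directory and
contributes to a summary dictionary; any stage failure aborts with an
error naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acquire, enrich, identify, io, quantify
from .evolve import (
    fisher_exact_2x2,
    five_species_qc,
    pairwise_qc,
    verdict_table,
    wilcoxon_rank_sum,
)
from .simulate import (
    ExperimentDesign,
    generate_annotations,
    generate_evolution_table,
    generate_proteome,
    simulate_experiment,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All pipeline parameters; round-trips through YAML unchanged."""

    seed: int = 0
    # proteome
    n_male: int = 20
    n_female: int = 30
    n_plug: int = 7
    family_fraction: float = 0.2
    # identification
    fdr: float = 0.01
    incorporation: float = 0.95
    # acquisition
    ppm: float = 10.0
    rt_halfwidth: float = 1.5
    # evolution
    alpha1: float = 0.01
    alpha2: float = 0.01
    fraction_selected: float = 0.1
    selection_effect: float = 2.0
    # enrichment
    bonferroni_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr < 1.0:
            raise ValueError(f"fdr must be in (0, 1), got {self.fdr}")
        if not 0.0 <= self.incorporation <= 1.0:
            raise ValueError("incorporation must be in [0, 1]")
        if self.ppm <= 0 or self.rt_halfwidth <= 0:
            raise ValueError("acquisition tolerances must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineStageError(name, exc) from exc

        return inner

    return wrap


@_stage("simulate")
def _run_simulate(config: PipelineConfig, outdir: Path):
    fixture = generate_proteome(
        n_male=config.n_male,
        n_female=config.n_female,
        n_plug=config.n_plug,
        family_fraction=config.family_fraction,
        seed=config.seed,
    )
    design = ExperimentDesign(seed=config.seed)
    result = simulate_experiment(fixture, design)
    fixture.to_fasta(outdir / "proteome.fasta")
    io.write_psm_tables(result, outdir / "psms.tsv")
    return fixture, design, result


@_stage("identify")
def _run_identify(config: PipelineConfig, outdir: Path, fixture, result):
    decoys = identify.decoy_database(fixture, seed=config.seed)
    decoys.to_fasta(outdir / "decoys.fasta")
    combined = result.combined()
    if config.fdr <= 0:
        raise ValueError("FDR of 0 is unattainable")
    fdr_result = identify.filter_psms_fdr(combined, fdr=config.fdr)
    accepted = fdr_result.accepted
    mapping = identify.map_peptides(set(accepted["peptide"]), fixture)
    identified, ambiguous = identify.infer_genes(accepted, mapping)
    report = identify.identification_report(identified, ambiguous)
    report.to_csv(outdir / "identifications.tsv", sep="\t", index=False)
    accepted.to_csv(outdir / "accepted_psms.tsv", sep="\t", index=False)
    return fdr_result, accepted, mapping, identified, ambiguous


@_stage("quantify")
def _run_quantify(outdir: Path, fixture, design, accepted, mapping, identified):
    mated_samples = {
        s.sample_id for s in design.samples if s.kind != "unmated_control"
    }
    main = accepted[accepted["sample_id"].isin(mated_samples)]
    counts = identify.fractional_counts(main, mapping)
    identified_ids = {r.gene_id for r in identified}
    counts = {g: c for g, c in counts.items() if g in identified_ids}
    nsaf_table = quantify.nsaf(counts, fixture.lengths())
    nsaf_table.to_csv(outdir / "nsaf.tsv", sep="\t", index=False)

    # per-replicate discovery within the first mated sample of the design
    sample_id = next(
        s.sample_id for s in design.samples if s.kind != "unmated_control"
    )
    reps = sorted(accepted[accepted["sample_id"] == sample_id]["replicate"].unique())
    rep_sets = []
    for rep in reps:
        psms = accepted[
            (accepted["sample_id"] == sample_id) & (accepted["replicate"] == rep)
        ]
        ident, _ = identify.infer_genes(psms, mapping)
        rep_sets.append({r.gene_id for r in ident})
    cumulative, increments = quantify.discovery_curve(rep_sets)
    pd.DataFrame(
        {"replicate": reps, "cumulative": cumulative, "new_genes": increments}
    ).to_csv(outdir / "discovery_curve.tsv", sep="\t", index=False)

    nsaf_genes = set(nsaf_table["gene_id"])
    first = rep_sets[0] & nsaf_genes if rep_sets else set()
    later = (set().union(*rep_sets[1:]) if len(rep_sets) > 1 else set()) - first
    later &= nsaf_genes
    replicate_test = None
    if first and later:
        replicate_test = quantify.first_vs_later_nsaf(first, later, nsaf_table)
    return counts, nsaf_table, cumulative, replicate_test


@_stage("enrich")
def _run_enrich(config: PipelineConfig, outdir: Path, fixture, identified):
    annotations = generate_annotations(fixture, seed=config.seed)
    io.write_annotations(annotations, outdir / "annotations.tsv")
    mapping = io.annotations_to_mapping(annotations)
    male = {
        p.gene_id
        for p in fixture.by_origin("male_seminal", "male_plug")
    }
    study = {r.gene_id for r in identified} & male
    population = set(fixture.gene_ids)
    results = enrich.term_for_term(study, population, mapping)
    table = enrich.enrichment_table(results)
    table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    return table


@_stage("evolve")
def _run_evolve(config: PipelineConfig, outdir: Path, fixture, identified):
    n = len(fixture.proteins)
    ortho, fits, truth = generate_evolution_table(
        n_genes=n,
        fraction_selected=config.fraction_selected,
        effect=config.selection_effect,
        seed=config.seed,
        gene_ids=fixture.gene_ids,
    )
    ortho.to_csv(outdir / "orthologs.tsv", sep="\t", index=False)
    fits.to_csv(outdir / "site_model_fits.tsv", sep="\t", index=False)
    kept, removed = pairwise_qc(ortho)
    kept_fits, _ = five_species_qc(fits)
    verdicts = verdict_table(
        kept_fits, alpha1=config.alpha1, alpha2=config.alpha2
    )
    verdicts.to_csv(outdir / "selection_verdicts.tsv", sep="\t", index=False)

    male = {p.gene_id for p in fixture.by_origin("male_seminal", "male_plug")}
    study_ids = {r.gene_id for r in identified} & male
    study_omega = kept[kept["gene_id"].isin(study_ids)]["omega"]
    other_omega = kept[~kept["gene_id"].isin(study_ids)]["omega"]
    stats_summary: dict = {"n_qc_removed": int(len(removed))}
    if len(study_omega) and len(other_omega):
        w, p = wilcoxon_rank_sum(study_omega, other_omega)
        stats_summary["wrst_W"] = w
        stats_summary["wrst_p"] = p
        # ortholog-recovery contrast: QC-passing vs removed, study vs rest
        a = int(len(study_omega))
        b = int(study_ids.__len__() - len(study_omega))
        c = int(len(other_omega))
        d = int(len(ortho) - len(study_ids) - len(other_omega))
        if min(a + b, c + d) > 0 and a + b + c + d > 0:
            stats_summary["ortholog_fisher_p"] = fisher_exact_2x2(a, b, c, d)
    stats_summary["n_selected"] = int(verdicts["selected"].sum())
    return verdicts, stats_summary


@_stage("acquire")
def _run_acquire(config: PipelineConfig, outdir: Path, accepted, mapping):
    sample_id = accepted["sample_id"].iloc[0]
    rep1 = accepted[
        (accepted["sample_id"] == sample_id) & (accepted["replicate"] == 1)
    ]
    rng = np.random.default_rng(config.seed)
    features = []
    for _, row in rep1.drop_duplicates("peptide").iterrows():
        genes, _ = mapping.get(row["peptide"], ([], 0))
        features.append(
            acquire.Feature(
                mz=(row["observed_mass"] + row["charge"] * 1.00727646688)
                / row["charge"],
                rt=float(rng.uniform(5.0, 90.0)),
                is_natural=row["label_mode_truth"] == "natural",
                previously_sampled=False,
                gene_id=genes[0] if genes else "unmapped",
                intensity=float(rng.lognormal(0.0, 1.0)),
            )
        )
    windows = acquire.build_inclusion_list(
        features, ppm=config.ppm, rt_halfwidth=config.rt_halfwidth
    )
    io.write_inclusion_list(windows, outdir / "inclusion_list.tsv")
    directed = acquire.simulate_acquisition(
        features, mode="directed", seed=config.seed,
        ppm=config.ppm, rt_halfwidth=config.rt_halfwidth,
    )
    dda = acquire.simulate_acquisition(features, mode="dda", seed=config.seed)
    _, summary = acquire.compare_directed_vs_dda(directed, dda)
    return len(windows), summary


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on synthetic data; returns the summary bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    logger.info("pipeline parameters: %s", dataclasses.asdict(config))

    fixture, design, result = _run_simulate(config, outdir)
    fdr_result, accepted, mapping, identified, ambiguous = _run_identify(
        config, outdir, fixture, result
    )
    counts_all = identify.fractional_counts(accepted, mapping)
    counts, nsaf_table, discovery, replicate_test = _run_quantify(
        outdir, fixture, design, accepted, mapping, identified
    )
    enrichment = _run_enrich(config, outdir, fixture, identified)
    verdicts, evolution_stats = _run_evolve(config, outdir, fixture, identified)
    n_windows, acquisition_summary = _run_acquire(config, outdir, accepted, mapping)

    summary = {
        "seed": config.seed,
        "n_psms_simulated": result.n_psms,
        "n_psms_accepted": int(len(accepted)),
        "fdr_threshold": fdr_result.threshold,
        "estimated_fdr": fdr_result.estimated_fdr,
        "n_genes_identified": len(identified),
        "n_genes_ambiguous": len(ambiguous),
        "fractional_count_total": float(sum(counts_all.values())),
        "count_conservation_ok": abs(
            sum(counts_all.values()) - len(accepted)
        )
        < 1e-6,
        "nsaf_sum": float(nsaf_table["nsaf"].sum()),
        "discovery_curve": discovery,
        "replicate_nsaf_test": replicate_test,
        "top_terms": enrichment.head(3)["term_id"].tolist(),
        "evolution": evolution_stats,
        "n_inclusion_windows": n_windows,
        "acquisition": acquisition_summary,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
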