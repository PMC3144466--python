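"""Readers and writers for the pipeline's plain-text interchange formats.

FASTA carries the proteome (header ``gene_id|origin|family``); everything
else is tab-separated: PSM tables, identification reports, NSAF reports,
annotation pairs, transcript-length lists, ortholog-rate and
site-model-fit tables, isotope envelopes, and inclusion lists.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .acquire import InclusionWindow
from .chem import IsotopeEnvelope
from .simulate import PSM_COLUMNS, Protein, ProteomeFixture, SimulationResult

__all__ = [
    "write_fixture_fasta",
    "read_fixture_fasta",
    "write_psm_tables",
    "read_psm_tables",
    "write_annotations",
    "read_annotations",
    "annotations_to_mapping",
    "write_lengths",
    "read_lengths",
    "write_envelope",
    "read_envelope",
    "write_inclusion_list",
]


def write_fixture_fasta(fixture: ProteomeFixture, path) -> None:
    records = [
        SeqRecord(
            Seq(p.sequence),
            id=f"{p.gene_id}|{p.origin}|{fixture.family_map.get(p.gene_id, p.gene_id)}",
            description="",
        )
        for p in fixture.proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fixture_fasta(path) -> ProteomeFixture:
    proteins = []
    family_map = {}
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.id.split("|")
        if len(parts) != 3:
            raise ValueError(f"malformed FASTA header {record.id!r}")
        gene_id, origin, family = parts
        proteins.append(Protein(gene_id, origin, str(record.seq)))
        family_map[gene_id] = family
    return ProteomeFixture(proteins=proteins, family_map=family_map)


def write_psm_tables(result: SimulationResult, path) -> None:
    """All sample x replicate tables in one TSV (sample_id and replicate
    columns distinguish them)."""
    result.combined().to_csv(path, sep="\t", index=False)


def read_psm_tables(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(PSM_COLUMNS[:-1]) - set(table.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    return table


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations[["gene_id", "term_id"]].to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def annotations_to_mapping(annotations: pd.DataFrame) -> dict[str, set[str]]:
    return {
        gene: set(group["term_id"])
        for gene, group in annotations.groupby("gene_id")
    }


def write_lengths(lengths: Mapping[str, Sequence[float]], path) -> None:
    """gene_id TAB comma-separated transcript lengths."""
    with open(path, "w") as fh:
        fh.write("gene_id\ttranscript_lengths\n")
        for gene_id, values in lengths.items():
            fh.write(f"{gene_id}\t{','.join(str(v) for v in values)}\n")


def read_lengths(path) -> dict[str, list[float]]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return {
        row["gene_id"]: [float(v) for v in row["transcript_lengths"].split(",")]
        for _, row in table.iterrows()
    }


def write_envelope(envelope: IsotopeEnvelope, path) -> None:
    with open(path, "w") as fh:
        fh.write("mz\tintensity\n")
        for mz, intensity in zip(envelope.mz_values, envelope.intensities):
            fh.write(f"{mz:.5f}\t{intensity:.6g}\n")


def read_envelope(path, charge: int) -> IsotopeEnvelope:
    table = pd.read_csv(path, sep="\t")
    return IsotopeEnvelope(
        charge=charge,
        mz_values=tuple(table["mz"]),
        intensities=tuple(table["intensity"]),
    )


def write_inclusion_list(windows: Sequence[InclusionWindow], path) -> None:
    with open(path, "w") as fh:
        fh.write("mz_center\tmz_low\tmz_high\trt_low\trt_high\n")
        for w in windows:
            center = (w.mz_low + w.mz_high) / 2.0
            fh.write(
                f"{center:.5f}\t{w.mz_low:.5f}\t{w.mz_high:.5f}"
                f"\t{w.rt_low:.3f}\t{w.rt_high:.3f}\n"
            )
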