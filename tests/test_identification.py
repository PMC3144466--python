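"""Decoys, FDR filtering, peptide mapping, inference, induced-protein filter."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from plugprot.chem import peptide_mass, tryptic_digest
from plugprot.identify import (
    build_peptide_index,
    decoy_database,
    female_induced_filter,
    filter_psms_fdr,
    fractional_counts,
    infer_genes,
    map_peptides,
    match_labeled_mode,
)
from plugprot.simulate import Protein, ProteomeFixture


def psm_frame(targets, decoys):
    rows = [{"peptide": f"T{i}", "score": s, "is_decoy": False}
            for i, s in enumerate(targets)]
    rows += [{"peptide": f"D{i}", "score": s, "is_decoy": True}
             for i, s in enumerate(decoys)]
    return pd.DataFrame(rows)


class TestDecoyDatabase:
    def test_shuffle_preserves_length_and_residues(self, default_fixture):
        decoys = decoy_database(default_fixture, seed=4)
        for target, decoy in zip(default_fixture.proteins, decoys.proteins):
            assert decoy.gene_id == f"DECOY_{target.gene_id}"
            assert len(decoy.sequence) == len(target.sequence)
            assert Counter(decoy.sequence) == Counter(target.sequence)

    def test_deterministic_per_seed(self, default_fixture):
        a = decoy_database(default_fixture, seed=4)
        b = decoy_database(default_fixture, seed=4)
        assert [p.sequence for p in a.proteins] == [p.sequence for p in b.proteins]

    def test_rarely_shares_long_tryptic_peptides(self, default_fixture):
        decoys = decoy_database(default_fixture, seed=4)
        target_peps = {
            p
            for peps in default_fixture.tryptic_peptides().values()
            for p in peps
            if len(p) >= 8
        }
        n_overlapping = sum(
            1
            for p in decoys.proteins
            if any(
                pep in target_peps
                for pep in tryptic_digest(p.sequence)
                if len(pep) >= 8
            )
        )
        assert n_overlapping <= 0.01 * len(decoys.proteins)


class TestFdrFilter:
    def test_lowest_threshold_satisfying_ratio(self):
        # decoys >= 2 is 1, targets >= 2 is 4 -> ratio 0.25 <= 0.34
        result = filter_psms_fdr(psm_frame([5, 4, 3, 2], [4.5, 1]), fdr=0.34)
        assert result.threshold == 2
        assert len(result.accepted) == 4
        assert result.estimated_fdr == pytest.approx(0.25)

    def test_tight_fdr_climbs_above_all_decoys(self):
        result = filter_psms_fdr(psm_frame([5, 4, 3, 2], [4.5, 1]), fdr=0.2)
        assert result.threshold == 5
        assert len(result.accepted) == 1

    def test_all_decoys_below_targets_accepts_everything(self):
        result = filter_psms_fdr(psm_frame([5, 4, 3], [0.5, 0.2]), fdr=0.01)
        assert len(result.accepted) == 3

    def test_all_targets_below_decoys_accepts_nothing(self):
        result = filter_psms_fdr(psm_frame([1, 0.9, 0.8], [5, 4]), fdr=0.01)
        assert result.accepted.empty
        assert result.threshold is None

    def test_no_decoys_is_an_error(self):
        with pytest.raises(ValueError, match="decoy"):
            filter_psms_fdr(psm_frame([1, 2], []), fdr=0.01)

    def test_invalid_fdr(self):
        with pytest.raises(ValueError):
            filter_psms_fdr(psm_frame([1], [1]), fdr=0.0)

    def test_ties_at_threshold_all_accepted(self):
        result = filter_psms_fdr(
            psm_frame([3, 3, 3, 2], [2.5]), fdr=0.40
        )
        assert result.threshold == 2
        assert len(result.accepted) == 4


class TestLabeledMatching:
    @pytest.fixture(scope="class")
    def index(self, small_fixture):
        return build_peptide_index(small_fixture)

    def test_shifted_query_matches(self, index):
        query = peptide_mass("AAAAAAK") + 0.95 * 8  # 8 nitrogens (6 Ala + Lys 2)
        assert "AAAAAAK" in match_labeled_mode(query, index, 0.95, tol_ppm=10)

    def test_unshifted_query_misses_labeled_mode(self, index):
        query = peptide_mass("AAAAAAK")
        assert "AAAAAAK" not in match_labeled_mode(query, index, 0.95, tol_ppm=10)

    def test_zero_incorporation_is_natural_mode(self, index):
        query = peptide_mass("AAAAAAK")
        assert "AAAAAAK" in match_labeled_mode(query, index, 0.0, tol_ppm=10)

    def test_empty_index_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            match_labeled_mode(500.0, {}, 0.95)


class TestMappingAndInference:
    def test_unique_and_shared_locations(self, small_fixture):
        mapping = map_peptides(
            {"AAAAAAK", "TTTTTTK", "GGGGGGR"}, small_fixture
        )
        assert mapping["AAAAAAK"] == (["GENE_A"], 1)
        assert mapping["TTTTTTK"] == (["GENE_A", "GENE_B"], 2)
        assert mapping["GGGGGGR"] == (["GENE_C"], 1)

    def test_unique_fraction_is_total_without_families(self):
        from plugprot.simulate import generate_proteome

        fx = generate_proteome(
            n_male=6, n_female=6, n_plug=2, family_fraction=0.0, seed=9
        )
        peptides = {p for peps in fx.tryptic_peptides().values() for p in peps}
        mapping = map_peptides(peptides, fx)
        assert all(n_loc == 1 for _, n_loc in mapping.values())

    @staticmethod
    def accepted_frame(peptides):
        return pd.DataFrame({"peptide": peptides})

    def test_two_peptide_one_unique_rule(self, small_fixture):
        mapping = map_peptides(
            {"AAAAAAK", "TTTTTTK", "DDDDDDK", "GGGGGGR"}, small_fixture
        )
        accepted = self.accepted_frame(
            ["AAAAAAK", "TTTTTTK", "TTTTTTK", "DDDDDDK", "GGGGGGR"]
        )
        identified, ambiguous = infer_genes(accepted, mapping)
        ids = {r.gene_id for r in identified}
        # GENE_A: unique AAAAAAK + shared TTTTTTK -> identified
        # GENE_B: unique DDDDDDK + shared TTTTTTK -> identified
        # GENE_C: single unique peptide -> not identified
        assert ids == {"GENE_A", "GENE_B"}
        assert not ambiguous

    def test_shared_only_gene_is_ambiguous(self):
        proteins = [
            Protein("P1", "male_seminal", "AAAAAAKTTTTTTKCCCCCCR"),
            Protein("P2", "male_seminal", "AAAAAAKTTTTTTKDDDDDDR"),
        ]
        fx = ProteomeFixture(proteins, {"P1": "F", "P2": "F"})
        mapping = map_peptides({"AAAAAAK", "TTTTTTK"}, fx)
        identified, ambiguous = infer_genes(
            self.accepted_frame(["AAAAAAK", "TTTTTTK"]), mapping
        )
        assert not identified
        assert {r.gene_id for r in ambiguous} == {"P1", "P2"}

    def test_matches_brute_force_on_small_fixtures(self):
        """Inference agrees with direct rule enumeration on <= 10 genes."""
        from plugprot.simulate import generate_proteome

        rng = np.random.default_rng(12)
        fx = generate_proteome(
            n_male=5, n_female=5, n_plug=2, family_fraction=0.4, seed=12
        )
        all_peps = sorted(
            {p for peps in fx.tryptic_peptides().values() for p in peps}
        )
        chosen = list(rng.choice(all_peps, size=60, replace=True))
        mapping = map_peptides(set(chosen), fx)
        identified, ambiguous = infer_genes(self.accepted_frame(chosen), mapping)

        # oracle: direct set enumeration per gene from the digest
        digests = fx.tryptic_peptides()
        expect_identified, expect_ambiguous = set(), set()
        for gene, peps in digests.items():
            present = set(chosen) & peps
            unique = {
                p for p in present
                if sum(p in other for other in digests.values()) == 1
            }
            if len(present) >= 2 and unique:
                expect_identified.add(gene)
            elif len(present) >= 2:
                expect_ambiguous.add(gene)
        assert {r.gene_id for r in identified} == expect_identified
        assert {r.gene_id for r in ambiguous} == expect_ambiguous


class TestFractionalCounts:
    def test_shared_peptide_split_across_genes(self, small_fixture):
        mapping = map_peptides({"TTTTTTK"}, small_fixture)
        counts = fractional_counts(
            pd.DataFrame({"peptide": ["TTTTTTK"] * 6}), mapping
        )
        assert counts == {"GENE_A": 3.0, "GENE_B": 3.0}

    def test_unique_peptide_full_weight(self, small_fixture):
        mapping = map_peptides({"AAAAAAK"}, small_fixture)
        counts = fractional_counts(
            pd.DataFrame({"peptide": ["AAAAAAK"] * 4}), mapping
        )
        assert counts == {"GENE_A": 4.0}

    def test_three_way_split(self):
        proteins = [
            Protein(f"P{i}", "male_seminal", "AAAAAAKTTTTTTK" + extra)
            for i, extra in enumerate(["CCCCCCR", "DDDDDDR", "EEEEEER"])
        ]
        fx = ProteomeFixture(proteins, {p.gene_id: "F" for p in proteins})
        mapping = map_peptides({"TTTTTTK"}, fx)
        counts = fractional_counts(
            pd.DataFrame({"peptide": ["TTTTTTK"] * 6}), mapping
        )
        assert counts == {"P0": 2.0, "P1": 2.0, "P2": 2.0}

    def test_totals_conserved_exactly(self, default_fixture, default_simulation):
        combined = default_simulation.combined()
        targets = combined[~combined.is_decoy]
        mapping = map_peptides(set(targets["peptide"]), default_fixture)
        mapped = targets[
            targets["peptide"].map(lambda p: mapping.get(p, ([], 0))[1] > 0)
        ]
        counts = fractional_counts(mapped, mapping)
        assert sum(counts.values()) == pytest.approx(len(mapped), abs=1e-9)


class TestFemaleInducedFilter:
    secretion = {"lactotransferrin": 0.95, "lowsignal": 0.85, "inunmated": 0.99}

    def test_all_criteria_pass(self):
        table = female_induced_filter(
            ["lactotransferrin"], self.secretion, [], []
        )
        assert table.loc[0, "induced"]

    def test_low_secretion_probability_fails(self):
        table = female_induced_filter(["lowsignal"], self.secretion, [], [])
        assert not table.loc[0, "c_secretion"]
        assert not table.loc[0, "induced"]

    def test_present_in_unmated_control_fails(self):
        table = female_induced_filter(
            ["inunmated"], self.secretion, ["inunmated"], []
        )
        assert not table.loc[0, "c_not_unmated"]

    def test_male_gene_fails(self):
        table = female_induced_filter(
            ["lactotransferrin"], self.secretion, [], ["lactotransferrin"]
        )
        assert not table.loc[0, "c_not_male"]

    def test_missing_probability_fails_conservatively(self):
        table = female_induced_filter(["unknown"], self.secretion, [], [])
        assert not table.loc[0, "c_secretion"]
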