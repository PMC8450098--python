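"""Temperature survey: classification, mapping, frequency tables."""

import math

import numpy as np
import pytest
from scipy import stats

from srmotif import (
    classify_temperature,
    extract_motif_columns,
    map_alignment_columns,
    pair_frequency_table,
    select_representatives,
    trend_summary,
)
from srmotif.motif import PROTOTYPE, SLOTS
from srmotif.simulate import AlignSimSpec, generate_annotated_alignment
from srmotif.survey import (
    TEMP_CLASSES,
    AnnotatedSequence,
    MotifObservation,
    annotate_fasta_records,
    read_annotations_tsv,
)


def seq(sid, aligned, species=None, phylum="Proteobacteria", topt=37.0):
    return AnnotatedSequence(id=sid, species=species or sid, phylum=phylum,
                             topt=topt, aligned_seq=aligned)


class TestClassifyTemperature:
    @pytest.mark.parametrize("topt,expected", [
        (15.0, "psychrophile"),
        (19.9, "psychrophile"),
        (20.0, "mesophile"),
        (49.9, "mesophile"),
        (50.0, "thermophile"),
        (69.9, "thermophile"),
        (70.0, "hyperthermophile"),
        (105.0, "hyperthermophile"),
    ])
    def test_boundaries(self, topt, expected):
        assert classify_temperature(topt) == expected

    def test_missing_temperature_rejected(self):
        with pytest.raises(ValueError):
            classify_temperature(float("nan"))


class TestSelectRepresentatives:
    def test_most_complete_sequence_wins(self):
        group = [seq("s1", "ACGU" * 5 + "N---", species="sp"),
                 seq("s2", "ACGU" * 6, species="sp"),
                 seq("s3", "ACGU" * 4 + "NNNN---N", species="sp")]
        assert select_representatives(group)["sp"].id == "s2"

    def test_tie_breaks_to_smallest_id(self):
        group = [seq("b", "ACGU" * 5, species="sp"),
                 seq("a", "UGCA" * 5, species="sp")]
        assert select_representatives(group)["sp"].id == "a"

    def test_singleton_group(self):
        only = seq("x", "ACGU" * 5, species="sp")
        assert select_representatives([only])["sp"] is only

    def test_invariant_to_input_order(self, rng):
        group = [seq("s%02d" % i, "ACGU" * 5 + "N" * (i % 3), species="sp")
                 for i in range(8)]
        chosen = select_representatives(group)["sp"].id
        for _ in range(5):
            shuffled = list(group)
            rng.shuffle(shuffled)
            assert select_representatives(shuffled)["sp"].id == chosen


class TestMapAlignmentColumns:
    STRUCTURE = "ACGUACGUACGUACGUACGU"  # 20 residues

    def test_identity_mapping_for_gapless_identical_row(self):
        mapping = map_alignment_columns([seq("ref", self.STRUCTURE)],
                                        self.STRUCTURE)
        assert mapping.column_to_position == {
            i: i for i in range(1, 21)}
        assert mapping.reference_id == "ref"
        assert mapping.n_aligned_columns == 20

    def test_gap_column_in_reference_is_unmapped(self):
        # a gap at column 8 shifts later columns by one; the oracle
        # mapping is written out by hand
        row = self.STRUCTURE[:7] + "-" + self.STRUCTURE[7:]
        mapping = map_alignment_columns([seq("ref", row)], self.STRUCTURE)
        expected = {c: c for c in range(1, 8)}
        expected.update({c: c - 1 for c in range(9, 22)})
        assert mapping.column_to_position == expected
        assert 8 not in mapping.column_to_position

    def test_unresolved_structure_residue_leaves_column_unmapped(self):
        # structure lacks residue 10 (unresolved in the 3D model)
        structure = self.STRUCTURE[:9] + self.STRUCTURE[10:]
        mapping = map_alignment_columns([seq("ref", self.STRUCTURE)],
                                        structure)
        expected = {c: c for c in range(1, 10)}
        expected.update({c: c - 1 for c in range(11, 21)})
        assert mapping.column_to_position == expected
        assert 10 not in mapping.column_to_position

    def test_best_of_multiple_candidates_is_used(self):
        noisy = "UUUU" + self.STRUCTURE[4:]   # 4 mismatches
        mapping = map_alignment_columns(
            [seq("bad", noisy), seq("good", self.STRUCTURE)],
            self.STRUCTURE)
        assert mapping.reference_id == "good"

    def test_low_identity_rejected(self):
        scrambled = "GGGGGGGGGGCCCCCCCCCC"
        with pytest.raises(ValueError, match="unreliable"):
            map_alignment_columns([seq("ref", scrambled)], self.STRUCTURE)

    def test_gapped_structure_rejected(self):
        with pytest.raises(ValueError, match="ungapped"):
            map_alignment_columns([seq("ref", self.STRUCTURE)],
                                  "ACGU-ACGU")


class TestExtractMotifColumns:
    def test_planted_motif_recovered(self):
        structure = "GGGG" + PROTOTYPE.sequence + "CCCC"
        rows = [seq("ref", structure),
                seq("s1", "GGGG" + PROTOTYPE.sequence + "CCCC")]
        mapping = map_alignment_columns([rows[0]], structure)
        obs = extract_motif_columns(rows[1:], mapping, list(range(5, 18)))
        assert "".join(obs[0].bases) == PROTOTYPE.sequence
        assert not obs[0].flagged

    def test_gap_at_motif_column_flags_record(self):
        structure = "GGGG" + PROTOTYPE.sequence + "CCCC"
        gapped = "GGGG" + "-" + PROTOTYPE.sequence[1:] + "CCCC"
        mapping = map_alignment_columns([seq("ref", structure)], structure)
        obs = extract_motif_columns([seq("s1", gapped)], mapping,
                                    list(range(5, 18)))
        assert obs[0].flagged

    def test_thymine_reported_as_uracil(self):
        structure = "GGGG" + PROTOTYPE.sequence + "CCCC"
        dna_style = structure.replace("U", "T")
        mapping = map_alignment_columns([seq("ref", structure)], structure)
        obs = extract_motif_columns([seq("s1", dna_style)], mapping,
                                    list(range(5, 18)))
        assert "".join(obs[0].bases) == PROTOTYPE.sequence

    def test_unmapped_position_names_itself(self):
        structure = "GGGG" + PROTOTYPE.sequence + "CCCC"
        mapping = map_alignment_columns([seq("ref", structure)], structure)
        with pytest.raises(ValueError, match="position 999"):
            extract_motif_columns([], mapping, [5, 999])


def make_obs(bases, cls="mesophile", phylum="Firmicutes", sid="s",
             flagged=None):
    flag = flagged if flagged is not None else \
        any(b not in "ACGU" for b in bases)
    return MotifObservation(seq_id=sid, temp_class=cls, phylum=phylum,
                            bases=tuple(bases), flagged=flag)


class TestPairFrequencyTable:
    def test_counts_sum_to_class_denominator(self):
        obs = [make_obs(PROTOTYPE.sequence, sid="s%d" % i)
               for i in range(10)]
        table = pair_frequency_table(obs)
        for slot in table.counts:
            assert sum(table.counts[slot]["mesophile"].values()) == \
                table.totals[slot]["mesophile"] == 10

    def test_empty_class_reports_absent_fraction(self):
        obs = [make_obs(PROTOTYPE.sequence)]
        table = pair_frequency_table(obs)
        assert table.fraction("tHS(6,9)", "psychrophile", "AG") is None

    def test_gapped_record_excluded_per_slot_only(self):
        bases = list(PROTOTYPE.sequence)
        bases[5] = "-"  # position 6: first member of the upper pair
        obs = [make_obs(bases), make_obs(PROTOTYPE.sequence)]
        table = pair_frequency_table(obs)
        assert table.totals["tHS(6,9)"]["mesophile"] == 1
        assert table.excluded["tHS(6,9)"]["mesophile"] == 1
        # slots not touching position 6 keep both records
        assert table.totals["tSH(2,12)"]["mesophile"] == 2

    def test_deduplication_counts_unique_motifs_once(self):
        obs = [make_obs(PROTOTYPE.sequence, sid="s%d" % i)
               for i in range(5)]
        table = pair_frequency_table(obs, deduplicate=True)
        assert table.totals["tHS(6,9)"]["mesophile"] == 1

    def test_phylum_stratification_reported(self):
        obs = [make_obs(PROTOTYPE.sequence, phylum="Aquificae"),
               make_obs(PROTOTYPE.sequence, phylum="Firmicutes")]
        table = pair_frequency_table(obs)
        strata = table.phylum_counts["tHS(6,9)"]
        assert set(strata) == {"Aquificae", "Firmicutes"}


class TestTrendSummary:
    def _table_with_counts(self, per_class):
        obs = []
        i = 0
        for cls, (n_ag, n_aa) in per_class.items():
            for combo, n in (("AG", n_ag), ("AA", n_aa)):
                bases = list(PROTOTYPE.sequence)
                bases[5], bases[8] = combo[0], combo[1]
                obs += [make_obs(bases, cls=cls, sid="s%d" % (i := i + 1))
                        for _ in range(n)]
        return pair_frequency_table(obs)

    def test_monotone_fractions_flagged(self):
        table = self._table_with_counts({
            "psychrophile": (30, 70), "mesophile": (50, 50),
            "thermophile": (80, 20), "hyperthermophile": (95, 5)})
        trend = trend_summary(table, "tHS(6,9)", "AG", "AA")
        assert trend.fractions == (0.30, 0.50, 0.80, 0.95)
        assert trend.monotonic_nondecreasing
        assert not trend.insufficient_classes

    def test_non_monotone_fractions_not_flagged(self):
        table = self._table_with_counts({
            "psychrophile": (60, 40), "mesophile": (20, 80),
            "thermophile": (80, 20), "hyperthermophile": (95, 5)})
        trend = trend_summary(table, "tHS(6,9)", "AG", "AA")
        assert not trend.monotonic_nondecreasing

    def test_single_class_is_insufficient(self):
        table = self._table_with_counts({"mesophile": (5, 5)})
        trend = trend_summary(table, "tHS(6,9)", "AG", "AA")
        assert trend.monotonic_nondecreasing
        assert trend.insufficient_classes


class TestEndToEndRecovery:
    def test_planted_composition_recovered_within_binomial_interval(self):
        """Survey of a seeded synthetic alignment reproduces the planted
        class-conditional upper-pair composition within the exact
        binomial 99% interval at n = 500 per class."""
        spec = AlignSimSpec(
            n_per_class={c: 500 for c in TEMP_CLASSES},
            gap_rate=0.005, ambiguity_rate=0.002, seed=20240918)
        sim = generate_annotated_alignment(spec)
        refs = [s for s in sim.sequences if s.id in sim.reference_ids]
        mapping = map_alignment_columns(refs, sim.structure_seq)
        obs = extract_motif_columns(sim.survey_rows(), mapping,
                                    sim.motif_positions)
        table = pair_frequency_table(obs)
        for cls in TEMP_CLASSES:
            p = sim.slot_composition["tHS(6,9)"][cls]["AG"]
            n = table.totals["tHS(6,9)"][cls]
            k = table.counts["tHS(6,9)"][cls].get("AG", 0)
            lo, hi = stats.binom.interval(0.99, n, p)
            assert lo <= k <= hi, (cls, k, n, p)

    def test_mapping_round_trip_recovers_planted_columns(self):
        spec = AlignSimSpec(n_per_class={c: 5 for c in TEMP_CLASSES},
                            gap_rate=0.02, seed=7)
        sim = generate_annotated_alignment(spec)
        refs = [s for s in sim.sequences if s.id in sim.reference_ids]
        mapping = map_alignment_columns(refs, sim.structure_seq)
        for pos, col in sim.true_column_of_position.items():
            assert mapping.column_to_position.get(col) == pos


class TestInputFormats:
    def test_annotation_rows_missing_topt_excluded(self):
        text = ("id\tspecies\tphylum\ttopt_c\n"
                "a\tSp a\tFirmicutes\t37.0\n"
                "b\tSp b\tFirmicutes\tNA\n")
        ann = read_annotations_tsv(text)
        assert set(ann) == {"a"}

    def test_orphan_annotations_rejected(self):
        from Bio.SeqRecord import SeqRecord
        from Bio.Seq import Seq
        records = [SeqRecord(Seq("ACGU" * 5), id="a")]
        ann = {"a": {"species": "x", "phylum": "y", "topt": 30.0},
               "ghost": {"species": "z", "phylum": "y", "topt": 30.0}}
        with pytest.raises(ValueError, match="ghost"):
            annotate_fasta_records(records, ann)

    def test_length_mismatch_rejected(self):
        from Bio.SeqRecord import SeqRecord
        from Bio.Seq import Seq
        records = [SeqRecord(Seq("ACGU" * 5), id="a"),
                   SeqRecord(Seq("ACGU" * 6), id="b")]
        ann = {sid: {"species": sid, "phylum": "y", "topt": 30.0}
               for sid in "ab"}
        with pytest.raises(ValueError, match="differing lengths"):
            annotate_fasta_records(records, ann)
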