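"""Temperature-class survey of motif composition in rRNA alignments.

Pipeline: annotate aligned 16S-style sequences with the optimal growth
temperature class of their source organism, keep one representative
sequence per species, map alignment columns onto the residue numbering
of a reference 3D structure, pull out the columns holding the motif, and
tabulate basepair-slot composition per temperature class.

The survey is descriptive: it reports per-class fractions and a simple
monotonicity flag, not inferential statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import Align

from srmotif.motif import SLOTS, Slot

logger = logging.getLogger(__name__)

__all__ = [
    "TEMP_CLASSES",
    "AnnotatedSequence",
    "AlignmentMapping",
    "MotifObservation",
    "PairFrequencyTable",
    "TrendSummary",
    "classify_temperature",
    "select_representatives",
    "map_alignment_columns",
    "extract_motif_columns",
    "pair_frequency_table",
    "trend_summary",
]

#: Optimal-growth-temperature classes in ascending temperature order.
TEMP_CLASSES = ("psychrophile", "mesophile", "thermophile",
                "hyperthermophile")

_GAPS = {"-", "."}


def classify_temperature(topt_celsius: float) -> str:
    """Temperature class from an optimal growth temperature in degC.

    Boundaries: psychrophile < 20 <= mesophile < 50 <= thermophile
    < 70 <= hyperthermophile.
    """
    t = float(topt_celsius)
    if t != t:  # NaN
        raise ValueError("optimal growth temperature is missing (NaN)")
    if t < 20.0:
        return "psychrophile"
    if t < 50.0:
        return "mesophile"
    if t < 70.0:
        return "thermophile"
    return "hyperthermophile"


@dataclass(frozen=True)
class AnnotatedSequence:
    """One gapped alignment row with its organism annotation."""

    id: str
    species: str
    phylum: str
    topt: float          # optimal growth temperature, degC
    aligned_seq: str     # gapped, over A/C/G/U/N/-/. (T accepted as U)

    def __post_init__(self):
        seq = self.aligned_seq.upper().replace("T", "U")
        object.__setattr__(self, "aligned_seq", seq)
        if not seq:
            raise ValueError("aligned sequence of %r is empty" % self.id)
        bad = set(seq) - set("ACGUN-.")
        if bad:
            raise ValueError("sequence %r contains invalid characters %r"
                             % (self.id, sorted(bad)))

    @property
    def temp_class(self) -> str:
        return classify_temperature(self.topt)

    def ungapped(self) -> str:
        return "".join(c for c in self.aligned_seq if c not in _GAPS)

    def acgu_content(self) -> int:
        """Number of unambiguous A/C/G/U characters (the completeness
        measure used for representative selection)."""
        return sum(1 for c in self.aligned_seq if c in "ACGU")


def select_representatives(
        sequences: Iterable[AnnotatedSequence]) -> Dict[str, AnnotatedSequence]:
    """One representative per species: the most complete sequence.

    Picks, within each species, the sequence with the highest count of
    unambiguous A/C/G/U characters; ties break to the lexicographically
    smallest id, so the result is independent of input order.
    """
    best: Dict[str, AnnotatedSequence] = {}
    for seq in sequences:
        incumbent = best.get(seq.species)
        if incumbent is None:
            best[seq.species] = seq
            continue
        key_new = (-seq.acgu_content(), seq.id)
        key_old = (-incumbent.acgu_content(), incumbent.id)
        if key_new < key_old:
            best[seq.species] = seq
    return best


@dataclass(frozen=True)
class AlignmentMapping:
    """Partial map from 1-based alignment columns to 1-based structure
    positions, plus the provenance of the reference row that defined it."""

    column_to_position: Dict[int, int]
    reference_id: str
    n_aligned_columns: int

    def __post_init__(self):
        cols = sorted(self.column_to_position)
        pos = [self.column_to_position[c] for c in cols]
        if len(set(pos)) != len(pos) or pos != sorted(pos):
            raise ValueError("mapping must be injective and strictly "
                             "increasing over mapped columns")

    def position_to_column(self) -> Dict[int, int]:
        return {p: c for c, p in self.column_to_position.items()}


def _make_aligner() -> Align.PairwiseAligner:
    # near-identical sequences; scoring pinned for determinism
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner


def map_alignment_columns(reference_rows: Sequence[AnnotatedSequence],
                          structure_seq: str,
                          min_identity: float = 0.9) -> AlignmentMapping:
    """Correlate alignment columns with structure residue numbers.

    Each candidate reference row is degapped and globally aligned to the
    ungapped structure sequence; the row with the largest number of
    identically aligned, non-gap positions wins, and the column-to-
    position map is threaded back through that row's gap structure.
    Fails when no candidate reaches ``min_identity`` over the structure
    length, since a poor alignment would yield an unreliable mapping.
    """
    if not reference_rows:
        raise ValueError("need at least one candidate reference row")
    structure = structure_seq.upper().replace("T", "U")
    if any(c in _GAPS for c in structure):
        raise ValueError("structure sequence must be ungapped")
    aligner = _make_aligner()

    best = None  # (n_identical, row, pairs)
    for row in reference_rows:
        degapped = row.ungapped()
        alignment = aligner.align(degapped, structure)[0]
        pairs: List[Tuple[int, int]] = []   # (row residue idx, struct idx)
        n_identical = 0
        for (r0, r1), (s0, s1) in zip(*alignment.aligned):
            for k in range(r1 - r0):
                ri, si = r0 + k, s0 + k
                pairs.append((ri, si))
                if degapped[ri] == structure[si]:
                    n_identical += 1
        if best is None or n_identical > best[0]:
            best = (n_identical, row, pairs)

    n_identical, row, pairs = best
    identity = n_identical / len(structure)
    if identity < min_identity:
        raise ValueError(
            "best reference row %r matches only %.1f%% of the structure "
            "sequence (minimum %.0f%%); refusing to build an unreliable "
            "column mapping" % (row.id, 100 * identity, 100 * min_identity))

    # residue index in the degapped row -> alignment column (0-based)
    residue_to_column = [i for i, c in enumerate(row.aligned_seq)
                         if c not in _GAPS]
    column_to_position = {residue_to_column[ri] + 1: si + 1
                          for ri, si in pairs}
    return AlignmentMapping(column_to_position=column_to_position,
                            reference_id=row.id,
                            n_aligned_columns=n_identical)


@dataclass(frozen=True)
class MotifObservation:
    """The motif bases of one surveyed sequence.

    ``flagged`` marks records with a gap or ambiguity character at one
    or more motif columns; they are retained but excluded from the
    affected slots' denominators downstream.
    """

    seq_id: str
    temp_class: str
    phylum: str
    bases: Tuple[str, ...]
    flagged: bool


def extract_motif_columns(sequences: Iterable[AnnotatedSequence],
                          mapping: AlignmentMapping,
                          motif_positions: Sequence[int]
                          ) -> List[MotifObservation]:
    """Pull the motif bases out of every aligned sequence.

    ``motif_positions`` are 1-based structure positions in template
    order (13 of them for the standard motif).  Every motif position
    must be mapped; an unmapped one is an error naming the position.
    """
    pos_to_col = mapping.position_to_column()
    columns = []
    for p in motif_positions:
        if p not in pos_to_col:
            raise ValueError(
                "structure position %d is not mapped to any alignment "
                "column; cannot extract the motif" % p)
        columns.append(pos_to_col[p])
    out = []
    for seq in sequences:
        bases = tuple(seq.aligned_seq[c - 1] if c <= len(seq.aligned_seq)
                      else "-" for c in columns)
        flagged = any(b not in "ACGU" for b in bases)
        out.append(MotifObservation(seq_id=seq.id,
                                    temp_class=seq.temp_class,
                                    phylum=seq.phylum,
                                    bases=bases, flagged=flagged))
    return out


@dataclass
class PairFrequencyTable:
    """Per-slot, per-temperature-class counts of base combinations.

    ``counts[slot][cls][combo]`` holds the number of surveyed sequences
    showing that combination; ``totals[slot][cls]`` the per-class
    denominator (sequences with unambiguous bases at both columns of the
    slot); ``excluded[slot][cls]`` how many were dropped for gaps or
    ambiguity at the slot.  ``phylum_counts`` stratifies the same counts
    by phylum for inspection; it is never used for filtering.
    """

    counts: Dict[str, Dict[str, Dict[str, int]]]
    totals: Dict[str, Dict[str, int]]
    excluded: Dict[str, Dict[str, int]]
    phylum_counts: Dict[str, Dict[str, Dict[str, Dict[str, int]]]]
    deduplicated: bool = False

    def fraction(self, slot: str, temp_class: str,
                 combo: str) -> Optional[float]:
        total = self.totals[slot][temp_class]
        if total == 0:
            return None
        return self.counts[slot][temp_class].get(combo, 0) / total

    def to_long_rows(self) -> List[dict]:
        rows = []
        for slot in self.counts:
            for cls in TEMP_CLASSES:
                for combo, n in sorted(self.counts[slot][cls].items()):
                    frac = self.fraction(slot, cls, combo)
                    rows.append({"slot": slot, "class": cls, "combo": combo,
                                 "count": n, "fraction": frac})
        return rows


def pair_frequency_table(observations: Sequence[MotifObservation],
                         slots: Sequence[Slot] = SLOTS,
                         deduplicate: bool = False) -> PairFrequencyTable:
    """Tabulate basepair-slot composition by temperature class.

    A record with a gap or ambiguity at one of a slot's two columns is
    excluded from that slot only (and counted in ``excluded``).  With
    ``deduplicate=True``, identical motif base tuples within a class are
    counted once, the strict reading of counting unique sequences.
    """
    if deduplicate:
        seen = set()
        kept = []
        for obs in observations:
            key = (obs.temp_class, obs.bases)
            if key not in seen:
                seen.add(key)
                kept.append(obs)
        observations = kept

    counts = {s.name: {c: {} for c in TEMP_CLASSES} for s in slots}
    totals = {s.name: {c: 0 for c in TEMP_CLASSES} for s in slots}
    excluded = {s.name: {c: 0 for c in TEMP_CLASSES} for s in slots}
    phylum_counts: Dict[str, dict] = {s.name: {} for s in slots}

    for obs in observations:
        for slot in slots:
            b1 = obs.bases[slot.pos1 - 1]
            b2 = obs.bases[slot.pos2 - 1]
            cls = obs.temp_class
            if b1 not in "ACGU" or b2 not in "ACGU":
                excluded[slot.name][cls] += 1
                continue
            combo = b1 + b2
            counts[slot.name][cls][combo] = \
                counts[slot.name][cls].get(combo, 0) + 1
            totals[slot.name][cls] += 1
            ph = phylum_counts[slot.name].setdefault(
                obs.phylum, {c: {} for c in TEMP_CLASSES})
            ph[cls][combo] = ph[cls].get(combo, 0) + 1

    return PairFrequencyTable(counts=counts, totals=totals,
                              excluded=excluded,
                              phylum_counts=phylum_counts,
                              deduplicated=deduplicate)


@dataclass(frozen=True)
class TrendSummary:
    """Per-class fraction of one combination among a competing pair."""

    slot: str
    combo_a: str
    combo_b: str
    fractions: Tuple[Optional[float], ...]  # psychro -> hyper; None = no data
    monotonic_nondecreasing: bool
    n_classes_with_data: int

    @property
    def insufficient_classes(self) -> bool:
        return self.n_classes_with_data < 2


def trend_summary(table: PairFrequencyTable, slot: str,
                  combo_a: str, combo_b: str) -> TrendSummary:
    """Fraction of ``combo_a`` among {combo_a, combo_b} per class.

    Classes without either combination report no fraction.  The
    monotonicity flag is true when the observed fractions are
    non-decreasing from psychrophiles to hyperthermophiles; it is a
    description of this dataset, not a hypothesis test.
    """
    fractions: List[Optional[float]] = []
    for cls in TEMP_CLASSES:
        n_a = table.counts[slot][cls].get(combo_a, 0)
        n_b = table.counts[slot][cls].get(combo_b, 0)
        denom = n_a + n_b
        fractions.append(n_a / denom if denom else None)
    present = [f for f in fractions if f is not None]
    monotone = all(b >= a for a, b in zip(present, present[1:]))
    return TrendSummary(slot=slot, combo_a=combo_a, combo_b=combo_b,
                        fractions=tuple(fractions),
                        monotonic_nondecreasing=monotone,
                        n_classes_with_data=len(present))


# ---------------------------------------------------------------------------
# plain-text formats


def read_annotations_tsv(text: str) -> Dict[str, dict]:
    """Parse ``id<TAB>species<TAB>phylum<TAB>topt_c`` annotation rows.

    Rows with a missing/unparseable temperature are excluded with a
    logged reason rather than raising.
    """
    annotations = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#") \
                or line.lower().startswith("id\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError("annotation line %d: expected 4 tab-separated "
                             "fields, got %d" % (lineno, len(parts)))
        sid, species, phylum, topt = (p.strip() for p in parts)
        try:
            topt_value = float(topt)
        except ValueError:
            topt_value = float("nan")
        if topt_value != topt_value:
            logger.info("excluding %s: missing optimal growth temperature",
                        sid)
            continue
        annotations[sid] = {"species": species, "phylum": phylum,
                            "topt": topt_value}
    return annotations


def annotate_fasta_records(records, annotations: Dict[str, dict]
                           ) -> List[AnnotatedSequence]:
    """Join Bio.SeqIO records with the annotation table.

    Records without an annotation are excluded with a logged reason;
    annotations without a sequence raise, listing the orphans.
    """
    out = []
    seen = set()
    for rec in records:
        seen.add(rec.id)
        ann = annotations.get(rec.id)
        if ann is None:
            logger.info("excluding %s: no annotation row", rec.id)
            continue
        out.append(AnnotatedSequence(id=rec.id, species=ann["species"],
                                     phylum=ann["phylum"], topt=ann["topt"],
                                     aligned_seq=str(rec.seq)))
    orphans = sorted(set(annotations) - seen)
    if orphans:
        raise ValueError("annotation rows without a matching sequence: %s"
                         % ", ".join(orphans))
    lengths = {len(s.aligned_seq) for s in out}
    if len(lengths) > 1:
        raise ValueError("alignment rows have differing lengths: %s"
                         % sorted(lengths))
    return out


def write_frequency_tsv(table: PairFrequencyTable, path=None) -> str:
    """Long-format TSV: slot, class, combo, count, fraction."""
    lines = ["slot\tclass\tcombo\tcount\tfraction"]
    for row in table.to_long_rows():
        frac = "%.3f" % row["fraction"] if row["fraction"] is not None else "NA"
        lines.append("%s\t%s\t%s\t%d\t%s" % (
            row["slot"], row["class"], row["combo"], row["count"], frac))
    text = "\n".join(lines) + "\n"
    if path is not None:
        from pathlib import Path
        Path(path).write_text(text)
    return text
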