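"""Seeded generators for every input the analysis pipeline consumes.

Two families of synthetic data:

* UV melting curves from the closed-form two-state model plus iid
  Gaussian absorbance noise on the instrument's 15-90 degC, 0.5 degC
  grid — a stand-in for the spectrophotometer;
* gapped 16S-style alignments whose motif columns have temperature-
  class-dependent basepair composition, annotated with species, phylum
  and optimal growth temperature — a stand-in for a curated alignment
  database.

All generators are pure functions of their spec including the seed:
identical specs give bitwise-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from srmotif.meltfit import MeltingCurve
from srmotif.motif import PROTOTYPE, SLOTS
from srmotif.survey import TEMP_CLASSES, AnnotatedSequence
from srmotif.thermo import Baselines, ThermoParams, predicted_absorbance

__all__ = [
    "MeltSimSpec",
    "AlignSimSpec",
    "SimulatedAlignment",
    "DEFAULT_BASELINES",
    "DEFAULT_SLOT_COMPOSITION",
    "replicate_seeds",
    "generate_melt_curve",
    "generate_replicates",
    "generate_concentration_series",
    "generate_annotated_alignment",
]

#: Default optical baselines: a hyperchromic melt with a transition
#: amplitude of roughly 0.2 AU over the measured range, typical of a
#: short duplex read at 260 nm.
DEFAULT_BASELINES = Baselines(m_ds=5e-4, b_ds=0.70, m_ss=1e-3, b_ss=0.86)

#: Default absorbance noise (AU).  The instrument's true noise level is
#: a convention here, chosen so that two-state fits of the synthetic
#: curves typically reach R^2 >= 0.99 as real fits do.
DEFAULT_NOISE_SD = 0.002


@dataclass(frozen=True)
class MeltSimSpec:
    """Everything needed to simulate one melting curve."""

    params: ThermoParams
    baselines: Baselines = DEFAULT_BASELINES
    c_total: float = 1e-4       # mol/L
    t_start: float = 15.0       # degC
    t_end: float = 90.0
    t_step: float = 0.5
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        if self.t_start >= self.t_end:
            raise ValueError("t_start must be below t_end")
        if self.t_step <= 0:
            raise ValueError("t_step must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.c_total <= 0:
            raise ValueError("c_total must be positive")


def replicate_seeds(master_seed: int, n: int) -> List[int]:
    """Derive ``n`` deterministic sub-seeds (< 2**31) from a master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s >> 1) for s in state]


def generate_melt_curve(spec: MeltSimSpec) -> MeltingCurve:
    """One two-state melting curve with Gaussian absorbance noise.

    The grid holds ``floor((t_end - t_start)/t_step) + 1`` points (151
    for the default 15-90 degC range at 0.5 degC).  ``noise_sd = 0``
    reproduces the analytical forward model exactly.
    """
    n_points = int(np.floor((spec.t_end - spec.t_start) / spec.t_step)) + 1
    t = spec.t_start + spec.t_step * np.arange(n_points)
    a = predicted_absorbance(spec.params, spec.baselines, t, spec.c_total)
    a = np.asarray(a, dtype=float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        a = a + rng.normal(0.0, spec.noise_sd, size=n_points)
    return MeltingCurve(temperatures=t, absorbances=a,
                        c_total=spec.c_total, label=spec.label)


def generate_replicates(spec: MeltSimSpec, n: int) -> List[MeltingCurve]:
    """``n`` replicate curves with sub-seeds derived from the master seed."""
    if n < 1:
        raise ValueError("need at least one replicate")
    # replicates share the duplex label so downstream aggregation can
    # group them; only the seed differs
    return [generate_melt_curve(dataclasses.replace(spec, seed=sub))
            for sub in replicate_seeds(spec.seed, n)]


def generate_concentration_series(params: ThermoParams,
                                  concentrations: Sequence[float],
                                  baselines: Baselines = DEFAULT_BASELINES,
                                  noise_sd: float = DEFAULT_NOISE_SD,
                                  seed: int = 0,
                                  label: str = "") -> List[MeltingCurve]:
    """One curve per total strand concentration (for Van't Hoff analysis)."""
    if any(c <= 0 for c in concentrations):
        raise ValueError("all concentrations must be positive")
    curves = []
    subs = replicate_seeds(seed, len(concentrations))
    for ct, sub in zip(concentrations, subs):
        spec = MeltSimSpec(params=params, baselines=baselines, c_total=ct,
                           noise_sd=noise_sd, seed=sub,
                           label="%s_ct%.3g" % (label or "series", ct))
        curves.append(generate_melt_curve(spec))
    return curves


# ---------------------------------------------------------------------------
# annotated alignments


def _prototype_composition() -> Dict[str, Dict[str, Dict[str, float]]]:
    """Conserved prototype combination at every slot, all classes."""
    comp = {}
    for slot in SLOTS:
        combo = "%s%s" % PROTOTYPE.slot_bases(slot)
        comp[slot.name] = {cls: {combo: 1.0} for cls in TEMP_CLASSES}
    return comp


def _default_slot_composition() -> Dict[str, Dict[str, Dict[str, float]]]:
    comp = _prototype_composition()
    # upper sheared pair: AG fraction rises with growth temperature,
    # AA is the cold-adapted alternative
    comp["tHS(6,9)"] = {
        "psychrophile": {"AG": 0.30, "AA": 0.70},
        "mesophile": {"AG": 0.50, "AA": 0.50},
        "thermophile": {"AG": 0.80, "AA": 0.20},
        "hyperthermophile": {"AG": 0.95, "AA": 0.05},
    }
    # bulged base: conserved G in hot classes, U/A/C leak in cold ones
    comp["cSH(4,5)"] = {
        "psychrophile": {"GU": 0.70, "UU": 0.15, "AU": 0.10, "CU": 0.05},
        "mesophile": {"GU": 0.90, "UU": 0.04, "AU": 0.04, "CU": 0.02},
        "thermophile": {"GU": 1.0},
        "hyperthermophile": {"GU": 1.0},
    }
    return comp


#: Default class-conditional slot composition, emulating the qualitative
#: survey picture: the upper tHS pair shifts from AA toward AG as growth
#: temperature rises and the bulged G is replaced by U/A/C mostly in
#: cold-adapted organisms; all other slots are conserved.
DEFAULT_SLOT_COMPOSITION = _default_slot_composition()

#: Class counts of the kind of curated 16S dataset the survey targets.
DEFAULT_N_PER_CLASS = {"psychrophile": 82, "mesophile": 328,
                       "thermophile": 108, "hyperthermophile": 44}

_CLASS_TOPT_RANGE = {"psychrophile": (0.0, 20.0), "mesophile": (20.0, 50.0),
                     "thermophile": (50.0, 70.0),
                     "hyperthermophile": (70.0, 95.0)}

_PHYLA = ("Bacteroidetes", "Firmicutes", "Proteobacteria", "Aquificae",
          "Thermotogae", "Deinococcus-Thermus")


@dataclass(frozen=True)
class AlignSimSpec:
    """Specification for a synthetic annotated gapped alignment."""

    n_per_class: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_CLASS))
    slot_composition: Dict[str, Dict[str, Dict[str, float]]] = field(
        default_factory=lambda: DEFAULT_SLOT_COMPOSITION)
    background_length: int = 120   # ungapped structure length incl. motif
    motif_start: int = 40          # 1-based structure position of motif pos 1
    gap_rate: float = 0.01
    ambiguity_rate: float = 0.002
    background_mutation_rate: float = 0.02
    n_reference_rows: int = 2
    seed: int = 0

    def __post_init__(self):
        for slot, per_class in self.slot_composition.items():
            for cls, probs in per_class.items():
                total = sum(probs.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        "slot %s class %s probabilities sum to %g, not 1"
                        % (slot, cls, total))
        if not (0 <= self.gap_rate < 1 and 0 <= self.ambiguity_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.motif_start < 1 or \
                self.motif_start + 12 > self.background_length:
            raise ValueError("motif does not fit inside the background")


@dataclass(frozen=True)
class SimulatedAlignment:
    """A synthetic alignment plus the ground truth used to build it."""

    sequences: Tuple[AnnotatedSequence, ...]   # survey rows + reference rows
    reference_ids: Tuple[str, ...]
    structure_seq: str                         # ungapped reference sequence
    motif_positions: Tuple[int, ...]           # 13 structure positions
    true_column_of_position: Dict[int, int]    # structure pos -> column
    slot_composition: Dict[str, Dict[str, Dict[str, float]]]
    seed: int

    def survey_rows(self) -> List[AnnotatedSequence]:
        ref = set(self.reference_ids)
        return [s for s in self.sequences if s.id not in ref]

    def ground_truth_json(self) -> str:
        payload = {
            "reference_ids": list(self.reference_ids),
            "structure_seq": self.structure_seq,
            "motif_positions": list(self.motif_positions),
            "true_column_of_position": {
                str(k): v for k, v in self.true_column_of_position.items()},
            "slot_composition": self.slot_composition,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _draw_motif(rng: np.random.Generator, spec: AlignSimSpec,
                temp_class: str) -> str:
    """Draw one 13-base motif; earlier slots own shared positions."""
    bases: List[Optional[str]] = [None] * 13
    for slot in SLOTS:
        probs = spec.slot_composition[slot.name][temp_class]
        combos = sorted(probs)
        p = np.array([probs[c] for c in combos])
        combo = combos[rng.choice(len(combos), p=p / p.sum())]
        for pos, b in ((slot.pos1, combo[0]), (slot.pos2, combo[1])):
            if bases[pos - 1] is None:
                bases[pos - 1] = b
    return "".join(bases)  # every position is covered by some slot


def generate_annotated_alignment(spec: AlignSimSpec) -> SimulatedAlignment:
    """Build a gapped, annotated alignment with planted motif columns.

    The structure sequence is a random background carrying the prototype
    motif; survey rows share the background (with point substitutions at
    ``background_mutation_rate``), carry class-conditional motif draws,
    and acquire deletions ('-') and ambiguities ('N') at the stated
    rates — never inside the reference rows, which reproduce the
    structure sequence exactly so the column mapping is well defined.
    Insertion columns (gap in every reference row) are added at
    ``gap_rate`` per column.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.background_length
    m0 = spec.motif_start - 1
    motif_positions = tuple(range(spec.motif_start, spec.motif_start + 13))

    background = rng.choice(list("ACGU"), size=L)
    structure = background.copy()
    structure[m0:m0 + 13] = list(PROTOTYPE.sequence)
    structure_seq = "".join(structure)

    # choose insertion columns in alignment coordinates
    n_insert = rng.binomial(L, spec.gap_rate)
    insert_after = np.sort(rng.integers(0, L + 1, size=n_insert))
    # alignment column (1-based) of each structure position
    col_of_pos = {}
    col = 0
    ins_iter = list(insert_after)
    # columns: for each structure index, first any insertions scheduled
    # before it, then the residue column
    ins_ptr = 0
    insertion_cols = []
    for pos in range(L + 1):
        while ins_ptr < len(ins_iter) and ins_iter[ins_ptr] == pos:
            col += 1
            insertion_cols.append(col)
            ins_ptr += 1
        if pos < L:
            col += 1
            col_of_pos[pos + 1] = col
    n_columns = col

    def to_alignment(residues: Sequence[str], fill_insertions) -> str:
        row = ["-"] * n_columns
        for p, c in col_of_pos.items():
            row[c - 1] = residues[p - 1]
        for c in insertion_cols:
            row[c - 1] = fill_insertions()
        return "".join(row)

    sequences: List[AnnotatedSequence] = []
    reference_ids = []
    for i in range(spec.n_reference_rows):
        rid = "ref_ecoli_%d" % (i + 1)
        reference_ids.append(rid)
        sequences.append(AnnotatedSequence(
            id=rid, species="Escherichia coli", phylum="Proteobacteria",
            topt=37.0, aligned_seq=to_alignment(structure_seq, lambda: "-")))

    counter = 0
    for cls in TEMP_CLASSES:
        lo, hi = _CLASS_TOPT_RANGE[cls]
        for _ in range(spec.n_per_class.get(cls, 0)):
            counter += 1
            residues = background.copy()
            # background divergence outside the motif
            mut = rng.random(L) < spec.background_mutation_rate
            mut[m0:m0 + 13] = False
            for idx in np.nonzero(mut)[0]:
                residues[idx] = rng.choice(list("ACGU"))
            residues[m0:m0 + 13] = list(_draw_motif(rng, spec, cls))
            row = list(to_alignment(
                "".join(residues),
                lambda: rng.choice(["-", "A", "C", "G", "U"],
                                   p=[0.9, 0.025, 0.025, 0.025, 0.025])))
            # deletions and ambiguities on residue columns
            for c in col_of_pos.values():
                r = rng.random()
                if r < spec.gap_rate:
                    row[c - 1] = "-"
                elif r < spec.gap_rate + spec.ambiguity_rate:
                    row[c - 1] = "N"
            sid = "seq%04d" % counter
            sequences.append(AnnotatedSequence(
                id=sid,
                species="Species_%s_%04d" % (cls[:5], counter),
                phylum=str(rng.choice(_PHYLA)),
                topt=float(np.round(rng.uniform(lo, hi), 1)),
                aligned_seq="".join(row)))

    return SimulatedAlignment(
        sequences=tuple(sequences),
        reference_ids=tuple(reference_ids),
        structure_seq=structure_seq,
        motif_positions=motif_positions,
        true_column_of_position={p: col_of_pos[p] for p in motif_positions},
        slot_composition=spec.slot_composition,
        seed=spec.seed)


def write_alignment_fasta(sim: SimulatedAlignment, path=None) -> str:
    """Gapped FASTA of all rows (reference rows included)."""
    lines = []
    for seq in sim.sequences:
        lines.append(">%s" % seq.id)
        lines.append(seq.aligned_seq)
    text = "\n".join(lines) + "\n"
    if path is not None:
        from pathlib import Path
        Path(path).write_text(text)
    return text


def write_annotations_tsv(sim: SimulatedAlignment, path=None) -> str:
    """Annotation table in the survey's input dialect."""
    lines = ["id\tspecies\tphylum\ttopt_c"]
    for seq in sim.sequences:
        lines.append("%s\t%s\t%s\t%.1f" % (seq.id, seq.species, seq.phylum,
                                           seq.topt))
    text = "\n".join(lines) + "\n"
    if path is not None:
        from pathlib import Path
        Path(path).write_text(text)
    return text
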