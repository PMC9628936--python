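"""DNA part libraries and assembled characterization constructs.

A *part* is a functional DNA fragment — promoter, ribosome-binding site
(RBS), coding sequence or terminator — that regulates expression of the
reporter in the characterization circuit.  The measurable unit of the
pipeline is a *part combination*: one part per slot, assembled in circuit
order promoter–RBS–CDS–terminator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: assembly order of the slots in the GFP reporter module
SLOT_ORDER = ("promoter", "rbs", "cds", "terminator")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"empty sequence for {name}")
    if set(seq.upper()) - set("ACGT"):
        raise ValueError(f"non-ACGT characters in sequence for {name}")


@dataclass(frozen=True, order=True)
class PartCombination:
    """One part per slot; identifies a single assembled construct.

    Ordering (lexicographic on ids) is the deterministic tie-break used
    whenever two constructs score equally.
    """

    promoter_id: str
    rbs_id: str
    terminator_id: str
    cds_id: str = "sfGFP"

    @property
    def label(self) -> str:
        return f"{self.promoter_id}-{self.rbs_id}-{self.cds_id}-{self.terminator_id}"

    def part_id(self, slot: str) -> str:
        return {
            "promoter": self.promoter_id,
            "rbs": self.rbs_id,
            "cds": self.cds_id,
            "terminator": self.terminator_id,
        }[slot]


@dataclass
class PartLibrary:
    """Part sequences keyed by slot then part id."""

    slots: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for slot, parts in self.slots.items():
            if slot not in SLOT_ORDER:
                raise ValueError(f"unknown slot {slot!r}; expected one of {SLOT_ORDER}")
            for pid, seq in parts.items():
                _check_dna(seq, f"{slot}:{pid}")
                parts[pid] = seq.upper()

    def ids(self, slot: str) -> list[str]:
        return list(self.slots.get(slot, {}))

    def sequence(self, slot: str, part_id: str) -> str:
        try:
            return self.slots[slot][part_id]
        except KeyError:
            raise KeyError(f"unknown part {part_id!r} in slot {slot!r}") from None

    def validate_combination(self, combo: PartCombination) -> None:
        for slot in SLOT_ORDER:
            self.sequence(slot, combo.part_id(slot))

    def combinations(self) -> list[PartCombination]:
        """Cartesian product of the slots, in deterministic sorted order."""
        for slot in SLOT_ORDER:
            if not self.slots.get(slot):
                raise ValueError(f"slot {slot!r} has no parts")
        combos = [
            PartCombination(promoter_id=p, rbs_id=r, terminator_id=t, cds_id=c)
            for p, r, c, t in itertools.product(
                sorted(self.slots["promoter"]),
                sorted(self.slots["rbs"]),
                sorted(self.slots["cds"]),
                sorted(self.slots["terminator"]),
            )
        ]
        return sorted(combos)

    def assemble(self, combo: PartCombination) -> str:
        """Concatenate the combination's parts in circuit order."""
        return "".join(self.sequence(slot, combo.part_id(slot)) for slot in SLOT_ORDER)

    # ---------------------------------------------------------------- I/O

    @classmethod
    def from_fasta(cls, paths: dict[str, str | Path]) -> "PartLibrary":
        """Load one FASTA file per slot; record ids become part ids."""
        slots: dict[str, dict[str, str]] = {}
        for slot, path in paths.items():
            parts: dict[str, str] = {}
            for rec in SeqIO.parse(str(path), "fasta"):
                if rec.id in parts:
                    raise ValueError(f"duplicate part id {rec.id!r} in slot {slot!r}")
                parts[rec.id] = str(rec.seq).upper()
            if not parts:
                raise ValueError(f"no sequences in {path} for slot {slot!r}")
            slots[slot] = parts
        return cls(slots=slots)

    def to_fasta(self, outdir: str | Path) -> dict[str, Path]:
        """Write one FASTA per slot; returns the manifest of paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, Path] = {}
        for slot in SLOT_ORDER:
            if slot not in self.slots:
                continue
            path = outdir / f"{slot}.fasta"
            records = [
                SeqRecord(Seq(seq), id=pid, description="")
                for pid, seq in sorted(self.slots[slot].items())
            ]
            SeqIO.write(records, str(path), "fasta")
            manifest[slot] = path
        return manifest


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def random_part_library(
    n_promoters: int = 4,
    n_rbs: int = 5,
    n_terminators: int = 1,
    seed: int = 0,
    promoter_len: int = 40,
    rbs_len: int = 20,
    cds_len: int = 120,
    terminator_len: int = 40,
) -> PartLibrary:
    """Synthetic part library with random sequences, for fixtures and demos.

    Part ids follow registry-style naming (P1..Pn promoters, R1..Rn RBSs,
    T1 terminator, sfGFP CDS).  Sequences are uniform random DNA — real
    parts have composition biases this does not emulate, but identity of
    parts, not their biology, is what downstream alignment consumes.
    """
    rng = np.random.default_rng(seed)
    slots = {
        "promoter": {f"P{i+1}": random_dna(promoter_len, rng) for i in range(n_promoters)},
        "rbs": {f"R{i+1}": random_dna(rbs_len, rng) for i in range(n_rbs)},
        "cds": {"sfGFP": random_dna(cds_len, rng)},
        "terminator": {f"T{i+1}": random_dna(terminator_len, rng) for i in range(n_terminators)},
    }
    return PartLibrary(slots=slots)
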