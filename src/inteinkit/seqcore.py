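"""Sequence records, FASTA I/O, and elementary sequence computations.

Every downstream module (split-site scanning, construct design) works on the
two record types defined here.  Residue numbering is 1-based throughout, so a
"69/70" split site refers to the peptide bond between residues 69 and 70 of
the target protein.  FASTA reading/writing and translation are delegated to
Biopython; molecular weights come from a packaged table of average residue
masses (gel-scale comparisons use average, not monoisotopic, masses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DNA_BASES = "ACGT"


class SequenceError(ValueError):
    """Raised for malformed or out-of-alphabet sequences."""


@dataclass
class ProteinRecord:
    """A named protein sequence with a declared numbering convention.

    ``numbering_base`` is the residue number assigned to the first residue
    (default 1).  ``residue(i)`` and slicing helpers interpret positions in
    that numbering.
    """

    id: str
    seq: str
    numbering_base: int = 1

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise SequenceError(f"protein record {self.id!r} has an empty sequence")
        if self.numbering_base < 0:
            raise SequenceError("numbering_base must be >= 0")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_canonical(self) -> bool:
        return all(c in AMINO_ACIDS for c in self.seq)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos`` (in the record's numbering)."""
        i = pos - self.numbering_base
        if not 0 <= i < len(self.seq):
            raise IndexError(f"position {pos} outside {self.id} (length {len(self)})")
        return self.seq[i]

    def subseq(self, start: int, end: int) -> str:
        """Residues ``start..end`` inclusive, 1-based."""
        if start > end:
            raise IndexError("start > end")
        self.residue(start)
        self.residue(end)
        i = start - self.numbering_base
        return self.seq[i : i + (end - start + 1)]


@dataclass
class DnaRecord:
    """A DNA sequence with optional 1-based inclusive feature intervals."""

    id: str
    seq: str
    features: list = field(default_factory=list)  # (name, start, end, strand)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise SequenceError(f"DNA record {self.id!r} has an empty sequence")
        bad = set(self.seq) - set(DNA_BASES)
        if bad:
            raise SequenceError(
                f"DNA record {self.id!r} contains non-ACGT characters: {sorted(bad)}"
            )
        for name, start, end, strand in self.features:
            if not (1 <= start <= end <= len(self.seq)):
                raise SequenceError(
                    f"feature {name!r} interval ({start},{end}) outside sequence bounds"
                )

    def __len__(self) -> int:
        return len(self.seq)


Record = Union[ProteinRecord, DnaRecord]


def _looks_like_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= set(DNA_BASES)


def read_fasta(path, kind: str = "auto", strict: bool = True) -> list:
    """Read a FASTA file into :class:`ProteinRecord` / :class:`DnaRecord` lists.

    ``kind`` is one of ``"protein"``, ``"dna"`` or ``"auto"`` (per-record
    guess: sequences over the ACGT alphabet become DNA).  Sequences are
    uppercased with whitespace stripped; record order is preserved.  In strict
    mode an out-of-alphabet character raises; otherwise it is warned about.
    """
    if kind not in ("auto", "protein", "dna"):
        raise ValueError(f"unknown kind {kind!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        this_kind = kind
        if kind == "auto":
            this_kind = "dna" if _looks_like_dna(seq) else "protein"
        if this_kind == "dna":
            records.append(DnaRecord(rec.id, seq))
        else:
            prot = ProteinRecord(rec.id, seq)
            if not prot.is_canonical:
                bad = sorted(set(seq) - set(AMINO_ACIDS))
                msg = f"record {rec.id!r} has non-canonical residues: {bad}"
                if strict:
                    raise SequenceError(msg)
                warnings.warn(msg)
            records.append(prot)
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[Record], path) -> None:
    """Write records as multi-FASTA, sequence lines wrapped at 60 columns."""
    seqrecs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seqrecs, str(path), "fasta")


def translate(dna: Union[DnaRecord, str], allow_internal_stop: bool = False) -> ProteinRecord:
    """Translate a coding DNA sequence with the standard genetic code.

    The length must be a multiple of 3.  A single trailing stop codon is
    consumed; an internal stop raises unless ``allow_internal_stop`` is set,
    in which case translation truncates at the first stop.
    """
    rec = dna if isinstance(dna, DnaRecord) else DnaRecord("dna", dna)
    if len(rec.seq) % 3 != 0:
        raise SequenceError(f"length {len(rec.seq)} is not a multiple of 3")
    prot = str(Seq(rec.seq).translate())
    if "*" in prot:
        first = prot.index("*")
        if first < len(prot) - 1 and not allow_internal_stop:
            raise SequenceError(f"internal stop codon at codon {first + 1}")
        prot = prot[:first]
    if not prot:
        raise SequenceError("translation is empty (sequence is a bare stop codon)")
    return ProteinRecord(rec.id, prot)


def gc_content(dna: Union[DnaRecord, str]) -> float:
    """Fraction of G+C bases, in [0, 1]."""
    seq = dna.seq if isinstance(dna, DnaRecord) else dna.upper()
    if not seq:
        raise SequenceError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def reverse_complement(dna: Union[DnaRecord, str]) -> str:
    seq = dna.seq if isinstance(dna, DnaRecord) else dna.upper()
    return str(Seq(seq).reverse_complement())


@dataclass
class ResidueMassTable:
    """Average residue (monomer) masses in daltons, plus the mass of water.

    A peptide of residues r1..rn has mass sum(mass[ri]) + water: one water is
    gained at chain termini.
    """

    masses: dict
    water: float

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.masses)
        if missing:
            raise ValueError(f"mass table missing residues: {sorted(missing)}")
        if any(m <= 0 for m in self.masses.values()) or self.water <= 0:
            raise ValueError("masses must be positive")

    @classmethod
    def load(cls, path=None) -> "ResidueMassTable":
        """Load from TSV (columns ``residue``, ``average_mass_da``); default packaged table."""
        if path is None:
            path = resources.files("inteinkit.data") / "residue_masses.tsv"
        masses, water = {}, None
        for line in Path(str(path)).read_text().splitlines()[1:]:
            key, val = line.split("\t")
            if key == "water":
                water = float(val)
            else:
                masses[key] = float(val)
        if water is None:
            raise ValueError("mass table lacks a 'water' row")
        return cls(masses, water)


_DEFAULT_MASSES: ResidueMassTable | None = None


def default_mass_table() -> ResidueMassTable:
    global _DEFAULT_MASSES
    if _DEFAULT_MASSES is None:
        _DEFAULT_MASSES = ResidueMassTable.load()
    return _DEFAULT_MASSES


def molecular_weight(protein: Union[ProteinRecord, str], table: ResidueMassTable = None) -> float:
    """Average molecular weight of a peptide in Da (residue masses + one water)."""
    seq = protein.seq if isinstance(protein, ProteinRecord) else protein.upper()
    table = table or default_mass_table()
    try:
        total = sum(table.masses[c] for c in seq)
    except KeyError as exc:
        raise SequenceError(f"unknown residue {exc.args[0]!r}") from None
    return total + table.water
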