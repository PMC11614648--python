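"""Design of trans-splicing precursor constructs for a chosen split site.

Given a target protein split at k/k+1 and a split-intein pair, the two
precursors are single open reading frames:

    N-precursor:  extein[1..k] ++ N-intein ++ tag
    C-precursor:  C-intein ++ extein[k+1..N] ++ tag

(tags default to 6xHis at the C-terminus of both precursors).  Splicing
ligates the two extein portions back into the full-length target and excises
the joined intein halves, so the designer also predicts the molecular weights
of precursors and reaction products for gel-based verification.

Downstream of the protein design sit the DNA steps: back-translation against
a codon usage table (either most-frequent codons or GC-minimizing codons,
used to lower the GC content of the synthetic gene), restriction-site
screening, addition of cloning flanks (BamHI/HindIII by default), and tiling
of the gene into overlapping fragments for two-step overlap-extension PCR.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import pandas as pd

from .seqcore import (
    AMINO_ACIDS,
    DnaRecord,
    ProteinRecord,
    ResidueMassTable,
    SequenceError,
    default_mass_table,
    gc_content,
    molecular_weight,
)

#: Default restriction enzymes: name -> recognition sequence.
DEFAULT_ENZYMES = {"BamHI": "GGATCC", "HindIII": "AAGCTT"}

HIS6_TAG = "HHHHHH"

#: Advisory note attached to design reports (not used in any computation).
MASS_RATIO_ADVICE = (
    "Transfect N- and C-precursor plasmids at a 2:1 N:C mass ratio to compensate "
    "for unequal precursor expression and reduce unspliced C-precursor excess."
)


@dataclass
class InteinPair:
    """A split intein: N-half, C-half, and the C+1 extein residues it tolerates."""

    name: str
    family: str
    n_intein: str
    c_intein: str
    allowed_c1: frozenset = frozenset({"C"})
    kinetics_note: Optional[str] = None

    def __post_init__(self) -> None:
        self.n_intein = self.n_intein.upper()
        self.c_intein = self.c_intein.upper()
        if not self.n_intein or not self.c_intein:
            raise SequenceError(f"intein pair {self.name!r}: both halves must be non-empty")
        self.allowed_c1 = frozenset(self.allowed_c1)
        if not self.allowed_c1:
            raise SequenceError(f"intein pair {self.name!r}: allowed_c1 must be non-empty")


def load_intein_registry(path) -> list:
    """Load intein pairs from FASTA (headers ``<name>_N`` / ``<name>_C``) or JSON.

    DnaE-family pairs default to allowed_c1 = {C}, the cysteine required for
    the trans-thioesterification step.
    """
    path = str(path)
    if path.endswith(".json"):
        entries = json.load(open(path))
        return [
            InteinPair(
                name=e["name"],
                family=e.get("family", "unknown"),
                n_intein=e["n_intein"],
                c_intein=e["c_intein"],
                allowed_c1=frozenset(e.get("allowed_c1", ["C"])),
                kinetics_note=e.get("kinetics_note"),
            )
            for e in entries
        ]
    from Bio import SeqIO

    halves: dict = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id.endswith("_N") or rec.id.endswith("_C"):
            name, side = rec.id[:-2], rec.id[-1]
        else:
            raise SequenceError(f"registry header {rec.id!r} must end in _N or _C")
        halves.setdefault(name, {})[side] = str(rec.seq).upper()
    pairs = []
    for name, sides in halves.items():
        missing = {"N", "C"} - set(sides)
        if missing:
            raise SequenceError(f"intein {name!r} is missing its {sorted(missing)} half")
        family = "DnaE" if "DNAE" in name.upper() else "unknown"
        pairs.append(InteinPair(name=name, family=family, n_intein=sides["N"], c_intein=sides["C"]))
    return pairs


class Product(NamedTuple):
    name: str
    seq: str
    mw: float


@dataclass
class ConstructSet:
    """Precursors, controls, and predicted reaction products for one split."""

    split_k: int
    target: ProteinRecord
    intein: InteinPair
    tag: str
    n_precursor: ProteinRecord = None
    c_precursor: ProteinRecord = None
    control_full: ProteinRecord = None
    control_no_intein: tuple = None  # (N-half, C-half) tag-less exteins
    predicted_products: list = field(default_factory=list)
    advice: str = MASS_RATIO_ADVICE

    @property
    def extein_n(self) -> str:
        return self.target.seq[: self.split_k]

    @property
    def extein_c(self) -> str:
        return self.target.seq[self.split_k :]


def design_split_constructs(
    protein: ProteinRecord,
    k: int,
    intein_pair: InteinPair,
    tag: str = HIS6_TAG,
    linker: str = "",
    mass_table: Optional[ResidueMassTable] = None,
) -> ConstructSet:
    """Build the N/C precursor ORFs and controls for a split at k/k+1.

    ``tag`` may be empty (no-tag mode); ``linker`` is inserted between extein
    and intein halves on both sides (none by default).  A warning is emitted
    when the C+1 extein residue is outside the intein's tolerated set — such
    a construct is expected not to splice (useful as a negative control).
    """
    n = len(protein)
    if not 1 <= k <= n - 1:
        raise SequenceError(f"split position {k} out of range [1, {n - 1}]")
    c1 = protein.seq[k]
    if c1 not in intein_pair.allowed_c1:
        warnings.warn(
            f"C+1 residue {c1!r} at position {k + 1} is not in "
            f"{sorted(intein_pair.allowed_c1)} for {intein_pair.name}; "
            "splicing is expected to fail"
        )
    cs = ConstructSet(split_k=k, target=protein, intein=intein_pair, tag=tag)
    base = f"{protein.id}_{k}_{intein_pair.name}"
    cs.n_precursor = ProteinRecord(
        f"{base}_Nprec", cs.extein_n + linker + intein_pair.n_intein + tag
    )
    cs.c_precursor = ProteinRecord(
        f"{base}_Cprec", intein_pair.c_intein + linker + cs.extein_c + tag
    )
    cs.control_full = ProteinRecord(f"{protein.id}_full", protein.seq)
    cs.control_no_intein = (
        ProteinRecord(f"{protein.id}_1-{k}", cs.extein_n),
        ProteinRecord(f"{protein.id}_{k + 1}-{n}", cs.extein_c),
    )
    cs.predicted_products = predict_products(cs, mass_table)
    return cs


def predict_products(construct_set: ConstructSet, mass_table: Optional[ResidueMassTable] = None) -> list:
    """Species expected on a gel: both precursors, the spliced target, the excised intein."""
    table = mass_table or default_mass_table()
    cs = construct_set
    spliced = cs.extein_n + cs.extein_c
    excised = cs.intein.n_intein + cs.intein.c_intein
    species = [
        ("n_precursor", cs.n_precursor.seq),
        ("c_precursor", cs.c_precursor.seq),
        ("spliced_product", spliced),
        ("excised_intein", excised),
    ]
    return [Product(name, seq, molecular_weight(seq, table)) for name, seq in species]


@dataclass
class CodonUsageTable:
    """Relative synonymous-codon frequencies: residue -> [(codon, frequency)]."""

    codons: dict

    def __post_init__(self) -> None:
        for res, entries in self.codons.items():
            if not entries:
                raise ValueError(f"residue {res!r} has no codons")
            total = sum(f for _, f in entries)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"frequencies for residue {res!r} sum to {total}, not 1")

    @classmethod
    def load(cls, path) -> "CodonUsageTable":
        """Load from TSV with columns ``residue``, ``codon``, ``frequency``."""
        df = pd.read_csv(path, sep="\t")
        codons: dict = {}
        for row in df.itertuples(index=False):
            codons.setdefault(row.residue, []).append((row.codon.upper(), float(row.frequency)))
        return cls(codons)


def back_translate(
    protein: ProteinRecord,
    codon_table: CodonUsageTable,
    mode: str = "max-frequency",
    gc_floor: float = 0.10,
) -> DnaRecord:
    """Deterministic back-translation of a protein into a coding sequence.

    ``max-frequency`` picks each residue's most frequent codon.
    ``gc-minimize`` picks, among codons with relative frequency >= ``gc_floor``
    (avoiding rare codons), the one with the fewest G/C bases, breaking ties
    by higher frequency — this lowers the GC content of the synthetic gene.
    """
    if mode not in ("max-frequency", "gc-minimize"):
        raise ValueError(f"unknown mode {mode!r}")
    parts = []
    for res in protein.seq:
        if res not in codon_table.codons:
            raise SequenceError(f"residue {res!r} absent from codon table")
        entries = codon_table.codons[res]
        if mode == "max-frequency":
            codon = max(entries, key=lambda e: e[1])[0]
        else:
            admissible = [e for e in entries if e[1] >= gc_floor]
            if not admissible:
                admissible = [max(entries, key=lambda e: e[1])]
            codon = min(
                admissible, key=lambda e: (e[0].count("G") + e[0].count("C"), -e[1])
            )[0]
        parts.append(codon)
    return DnaRecord(f"{protein.id}_cds", "".join(parts))


def scan_restriction_sites(dna: DnaRecord, enzymes: Optional[dict] = None) -> list:
    """All (enzyme, 1-based position) matches on the given strand.

    The default BamHI/HindIII sites are palindromic, so a single-strand scan
    finds every cut site.
    """
    enzymes = enzymes if enzymes is not None else DEFAULT_ENZYMES
    hits = []
    for name, site in enzymes.items():
        start = dna.seq.find(site)
        while start != -1:
            hits.append((name, start + 1))
            start = dna.seq.find(site, start + 1)
    hits.sort(key=lambda h: h[1])
    return hits


def add_cloning_flanks(
    dna: DnaRecord,
    five_prime_site: str = DEFAULT_ENZYMES["BamHI"],
    three_prime_site: str = DEFAULT_ENZYMES["HindIII"],
    spacer: str = "",
) -> DnaRecord:
    """Append restriction sites (plus optional spacer bases) to both ends.

    The insert must not contain either site internally — internal cuts would
    destroy the fragment during cloning — and an error listing the offending
    positions is raised if it does.
    """
    sites = {"5' site": five_prime_site.upper(), "3' site": three_prime_site.upper()}
    internal = scan_restriction_sites(dna, sites)
    if internal:
        raise SequenceError(f"insert contains cloning sites internally: {internal}")
    five = spacer + sites["5' site"]
    three = sites["3' site"] + spacer
    seq = five + dna.seq + three
    features = [
        ("5p_flank", 1, len(five), 1),
        ("insert", len(five) + 1, len(five) + len(dna.seq), 1),
        ("3p_flank", len(five) + len(dna.seq) + 1, len(seq), 1),
    ]
    return DnaRecord(dna.id + "_flanked", seq, features)


def melting_temp(oligo: str) -> float:
    """Oligo melting temperature in deg C.

    Wallace rule 2(A+T) + 4(G+C) for oligos shorter than 14 nt; the GC
    formula 64.9 + 41*(GC - 16.4)/length otherwise.  These simple closed
    forms suit annealing-program sanity checks, not thermodynamic design.
    """
    oligo = oligo.upper()
    if not oligo:
        raise SequenceError("empty oligo")
    bad = set(oligo) - set("ACGT")
    if bad:
        raise SequenceError(f"non-ACGT characters in oligo: {sorted(bad)}")
    gc = oligo.count("G") + oligo.count("C")
    at = len(oligo) - gc
    if len(oligo) < 14:
        return 2.0 * at + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / len(oligo)


class Oligo(NamedTuple):
    seq: str
    tm: float
    overlap_partner: str  # "frag_i/frag_i+1"
    overlap_len: int


@dataclass
class PrimerSet:
    """Overlapping fragments tiling a gene, plus the junction oligos."""

    fragments: list  # list[DnaRecord]
    oligos: list  # list[Oligo]


def design_overlap_fragments(
    dna: DnaRecord,
    n_fragments: int,
    overlap_len: int = 20,
    tm_target: float = 60.0,
) -> PrimerSet:
    """Tile ``dna`` into ``n_fragments`` pieces sharing ``overlap_len``-base junctions.

    Consecutive fragments share exactly ``overlap_len`` bases so that
    overlap-extension PCR reassembles the input; each junction's overlap
    sequence is reported as an oligo with its melting temperature, and a
    warning is emitted when an overlap Tm falls below ``tm_target`` (the
    annealing temperature of the assembly program, 60 deg C by default).
    """
    n = len(dna.seq)
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if n_fragments == 1:
        return PrimerSet([DnaRecord(f"{dna.id}_frag1", dna.seq)], [])
    # Each junction needs overlap_len bases and each fragment core >= 1 base.
    if n < n_fragments + (n_fragments - 1) * overlap_len:
        raise SequenceError(
            f"sequence of length {n} too short for {n_fragments} fragments "
            f"with {overlap_len}-base overlaps"
        )
    # Cut points of the non-overlapping partition; fragment i is then
    # extended overlap_len bases into fragment i+1.
    cuts = [round(i * n / n_fragments) for i in range(n_fragments + 1)]
    fragments, oligos = [], []
    for i in range(n_fragments):
        start = cuts[i]
        end = min(cuts[i + 1] + overlap_len, n) if i < n_fragments - 1 else n
        fragments.append(DnaRecord(f"{dna.id}_frag{i + 1}", dna.seq[start:end]))
    for i in range(n_fragments - 1):
        ov_start = cuts[i + 1]
        ov = dna.seq[ov_start : min(ov_start + overlap_len, n)]
        tm = melting_temp(ov)
        if tm < tm_target:
            warnings.warn(
                f"overlap {i + 1}/{i + 2} Tm {tm:.1f} C below target {tm_target:.1f} C"
            )
        oligos.append(Oligo(ov, tm, f"frag{i + 1}/frag{i + 2}", len(ov)))
    return PrimerSet(fragments, oligos)


def merge_overlap_fragments(primer_set: PrimerSet) -> str:
    """Reassemble a fragment tiling by overlap merging (the PCR-assembly model)."""
    frags = [f.seq for f in primer_set.fragments]
    if not frags:
        return ""
    assembled = frags[0]
    for nxt, oligo in zip(frags[1:], primer_set.oligos):
        if not assembled.endswith(oligo.seq) or not nxt.startswith(oligo.seq):
            raise SequenceError(f"fragments do not share the reported overlap {oligo.seq!r}")
        assembled += nxt[oligo.overlap_len :]
    return assembled
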