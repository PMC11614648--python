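"""Split-site scanning for intein-mediated protein trans-splicing.

A split at position k breaks the peptide bond between residues k and k+1.
Splicing efficiency of DnaE-family inteins depends strongly on the six extein
residues flanking the junction: three on the N side (N-3, N-2, N-1 = residues
k-2, k-1, k) and three on the C side (C+1, C+2, C+3 = residues k+1, k+2,
k+3).  An :class:`ImpactMatrix` holds a per-position, per-residue score of
that influence, measured experimentally for a given intein family; a
candidate window's site score is the sum of its six per-position entries.

Scanning enumerates every position with a complete 6-mer window, scores it,
optionally annotates protein secondary structure (structure is reported but
never enters the score), and ranks sites by descending score.  For DnaE
inteins the C+1 residue must be a cysteine — the nucleophile of the splicing
chemistry — so candidate selection filters on the C+1 identity while keeping
a low-scoring, filter-failing site as the negative control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .seqcore import AMINO_ACIDS, ProteinRecord

#: Window positions relative to the split, N-terminal to C-terminal.
POSITIONS = ("N-3", "N-2", "N-1", "C+1", "C+2", "C+3")

ALPHA_HELIX = "ALFA-HELIX"
BETA_SHEET = "BETA-SHEET"
UNSTRUCTURED = "NON STRUCTED"

_STRUCTURE_NAMES = {"H": ALPHA_HELIX, "E": BETA_SHEET, "C": UNSTRUCTURED}
#: DSSP 8-class to 3-class collapse.
_DSSP_TO_3 = {"G": "H", "H": "H", "I": "H", "E": "E", "B": "E"}


class ScanError(ValueError):
    pass


@dataclass
class ImpactMatrix:
    """Per-position (N-3..C+3), per-residue splicing-impact scores.

    ``scores`` is a DataFrame indexed by the 20 canonical residues with the
    six window positions as columns.  ``meta`` records provenance (intein
    family, source).
    """

    scores: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.scores.columns) != POSITIONS:
            raise ScanError(f"matrix columns must be {POSITIONS}, got {tuple(self.scores.columns)}")
        missing = sorted(set(AMINO_ACIDS) - set(self.scores.index))
        if missing:
            warnings.warn(f"impact matrix missing residues {missing}; imputing 0")
            for res in missing:
                self.scores.loc[res] = 0.0
        self.scores = self.scores.loc[list(AMINO_ACIDS)].astype(float)

    def score(self, position: str, residue: str) -> float:
        return float(self.scores.at[residue, position])


def load_impact_matrix(path, meta: Optional[dict] = None) -> ImpactMatrix:
    """Load an impact matrix from TSV (``residue`` column + six position columns)."""
    df = pd.read_csv(path, sep="\t")
    if "residue" not in df.columns:
        raise ScanError("impact matrix TSV needs a 'residue' column")
    if df["residue"].duplicated().any():
        dups = sorted(df.loc[df["residue"].duplicated(), "residue"])
        raise ScanError(f"duplicate residue rows: {dups}")
    cols = [c for c in df.columns if c != "residue"]
    if tuple(cols) != POSITIONS:
        raise ScanError(f"expected position columns {POSITIONS}, got {tuple(cols)}")
    df = df.set_index("residue")[list(POSITIONS)]
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ScanError(f"non-numeric matrix cell: {exc}") from None
    meta = dict(meta or {})
    meta.setdefault("source", str(path))
    return ImpactMatrix(df, meta)


def save_impact_matrix(matrix: ImpactMatrix, path) -> None:
    out = matrix.scores.copy()
    out.insert(0, "residue", out.index)
    out.to_csv(path, sep="\t", index=False)


@dataclass
class SplitSite:
    """One candidate split between residues k and k+1."""

    k: int
    window: str  # residues k-2 .. k+3
    score: float
    rank: Optional[int] = None
    structure: Optional[str] = None
    passes_c1: Optional[bool] = None

    @property
    def c1(self) -> str:
        """The C+1 extein residue (residue k+1, 4th window character)."""
        return self.window[3]

    @property
    def label(self) -> str:
        """Site position label in the k/k+1 convention, e.g. ``"69/70"``."""
        return f"{self.k}/{self.k + 1}"


@dataclass
class StructureTrack:
    """Per-residue 3-state secondary-structure labels (H/E/C) for a protein."""

    labels: str
    source: str = ""

    def __post_init__(self) -> None:
        self.labels = self.labels.upper()
        bad = set(self.labels) - set("HEC")
        if bad:
            raise ScanError(f"structure labels must be H/E/C, got {sorted(bad)}")

    @classmethod
    def from_file(cls, path, dssp: bool = False) -> "StructureTrack":
        """Read a single-line H/E/C string or a per-residue TSV (label in last column).

        With ``dssp=True`` 8-class DSSP codes are collapsed to 3 classes
        (G/H/I -> H, E/B -> E, everything else -> C).
        """
        text = open(path).read().strip()
        if "\t" in text:
            labels = "".join(line.split("\t")[-1].strip() for line in text.splitlines() if line.strip())
        else:
            labels = "".join(text.split())
        if dssp:
            labels = "".join(_DSSP_TO_3.get(c, "C") for c in labels.upper())
        return cls(labels, source=str(path))


def enumerate_sites(protein: ProteinRecord) -> list:
    """Split positions k with a complete 6-mer window: k in [3, N-3], N-5 sites."""
    n = len(protein)
    if n < 6:
        warnings.warn(f"protein {protein.id!r} shorter than 6 residues; no scannable sites")
        return []
    return list(range(3, n - 2))


def window(protein: ProteinRecord, k: int) -> str:
    """The 6-mer of residues k-2..k+3 around the split k/k+1 (1-based)."""
    n = len(protein)
    if not 3 <= k <= n - 3:
        raise ScanError(f"split position {k} out of range [3, {n - 3}]")
    return protein.seq[k - 3 : k + 3]


def score_window(win: str, matrix: ImpactMatrix, strict: bool = True) -> float:
    """Sum of per-position impact scores over the six window residues."""
    if len(win) != 6:
        raise ScanError(f"window must have length 6, got {len(win)}")
    total = 0.0
    for pos, res in zip(POSITIONS, win):
        if res not in matrix.scores.index:
            if strict:
                raise ScanError(f"non-canonical residue {res!r} in window {win!r}")
            continue
        total += matrix.score(pos, res)
    return total


def annotate_structure(site: SplitSite, track: StructureTrack, protein_length: Optional[int] = None) -> str:
    """Majority 3-state label over the site's six window residues.

    H -> ALFA-HELIX, E -> BETA-SHEET, C -> NON STRUCTED; a tie for the
    majority resolves to NON STRUCTED.
    """
    if protein_length is not None and len(track.labels) != protein_length:
        raise ScanError(
            f"structure track length {len(track.labels)} != protein length {protein_length}"
        )
    span = track.labels[site.k - 3 : site.k + 3]
    if len(span) != 6:
        raise ScanError(f"structure track too short for site {site.label}")
    counts = {c: span.count(c) for c in "HEC"}
    best = max(counts.values())
    winners = [c for c, v in counts.items() if v == best]
    if len(winners) > 1:
        return UNSTRUCTURED
    return _STRUCTURE_NAMES[winners[0]]


def scan(
    protein: ProteinRecord,
    matrix: ImpactMatrix,
    structure_track: Optional[StructureTrack] = None,
    c1_filter: Optional[Iterable[str]] = None,
) -> list:
    """Enumerate, score, annotate, and rank every split site of ``protein``.

    Sites are sorted by descending score with ties broken by ascending
    position; ranks run 1..M.  ``c1_filter`` only marks ``passes_c1`` — the
    constraint is applied at selection time, not during scanning, so
    filter-failing sites keep their ranks (they serve as negative controls).
    """
    if structure_track is not None and len(structure_track.labels) != len(protein):
        raise ScanError(
            f"structure track length {len(structure_track.labels)} != protein length {len(protein)}"
        )
    allowed = set(c1_filter) if c1_filter is not None else None
    sites = []
    for k in enumerate_sites(protein):
        win = window(protein, k)
        site = SplitSite(k=k, window=win, score=score_window(win, matrix))
        if structure_track is not None:
            site.structure = annotate_structure(site, structure_track)
        if allowed is not None:
            site.passes_c1 = site.c1 in allowed
        sites.append(site)
    sites.sort(key=lambda s: (-s.score, s.k))
    for rank, site in enumerate(sites, start=1):
        site.rank = rank
    return sites


def apply_c1_filter(sites: Sequence[SplitSite], allowed_residues: Iterable[str] = ("C",)) -> list:
    """Keep sites whose C+1 residue is allowed; order and ranks are untouched."""
    allowed = set(allowed_residues)
    if not allowed:
        raise ScanError("allowed_residues must be non-empty")
    kept = []
    for site in sites:
        site.passes_c1 = site.c1 in allowed
        if site.passes_c1:
            kept.append(site)
    return kept


def select_candidates(
    ranked_sites: Sequence[SplitSite],
    n: int = 3,
    c1_residues: Iterable[str] = ("C",),
    negative_control_k: Optional[int] = None,
):
    """Pick the top-n constraint-passing sites plus one failing negative control.

    The default negative control is the lowest-scoring constraint-failing
    site; ``negative_control_k`` overrides it by split position.  Returns
    ``(candidates, control)`` where ``control`` may be None if every site
    passes the constraint.
    """
    if n < 1:
        raise ScanError("n must be >= 1")
    ordered = sorted(ranked_sites, key=lambda s: s.rank)
    passing = apply_c1_filter(ordered, c1_residues)
    failing = [s for s in ordered if not s.passes_c1]
    if len(passing) < n:
        warnings.warn(f"only {len(passing)} of the requested {n} sites pass the C+1 constraint")
    candidates = passing[:n]
    if negative_control_k is not None:
        matches = [s for s in ordered if s.k == negative_control_k]
        if not matches:
            raise ScanError(f"no site at position {negative_control_k}")
        control = matches[0]
        if control.passes_c1:
            warnings.warn(
                f"negative control at {control.label} passes the C+1 constraint; "
                "it may not abolish splicing"
            )
    else:
        control = max(failing, key=lambda s: s.rank) if failing else None
    return candidates, control


def report_table(sites: Sequence[SplitSite], path=None) -> pd.DataFrame:
    """Ranked site report with the standard five columns; optionally written as TSV."""
    rows = [
        {
            "Rating position": s.rank,
            "Sequence": s.window,
            "Site score": round(s.score, 2),
            "Site position": s.label,
            "Secondary structure": s.structure if s.structure is not None else "",
        }
        for s in sorted(sites, key=lambda s: s.rank)
    ]
    df = pd.DataFrame(rows, columns=[
        "Rating position", "Sequence", "Site score", "Site position", "Secondary structure",
    ])
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.2f")
    return df
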