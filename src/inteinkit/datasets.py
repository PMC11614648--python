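"""Packaged data assets and published example datasets.

The package ships small text assets needed for the worked example: the
238-residue GFP fixture (avGFP numbering, F64L/S65T chromophore variant), the
average residue-mass table, a human codon-usage table, and a registry of
synthetic stand-in DnaE intein pairs (Ssp/Npu/Ava-like halves with the
family-correct lengths, an N-intein starting cysteine and a C-intein terminal
asparagine; they are not the InBase database entries).

The experimentally measured NpuDnaE extein-impact matrix (the 485-variant
screen) is an *optional* asset: it is not redistributable with the package,
so :func:`published_impact_matrix` loads it from ``data/npu_extein_impact.tsv``
only if the user has placed it there.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .constructs import CodonUsageTable, load_intein_registry
from .scanner import ImpactMatrix, load_impact_matrix
from .seqcore import ProteinRecord, ResidueMassTable, read_fasta


def _data_path(name: str):
    return resources.files("inteinkit.data") / name


def gfp_fixture() -> ProteinRecord:
    """The packaged 238-residue GFP target protein (avGFP numbering)."""
    return read_fasta(str(_data_path("gfp_fixture.fasta")), kind="protein")[0]


def residue_mass_table() -> ResidueMassTable:
    """Average residue masses used for gel-scale molecular weights."""
    return ResidueMassTable.load(_data_path("residue_masses.tsv"))


def human_codon_usage() -> CodonUsageTable:
    """Relative synonymous-codon frequencies for human coding sequences."""
    return CodonUsageTable.load(str(_data_path("codon_usage_human.tsv")))


def intein_registry() -> list:
    """Synthetic stand-in Ssp/Npu/Ava DnaE intein pairs (see module docstring)."""
    return load_intein_registry(str(_data_path("dnae_inteins_synthetic.fasta")))


def published_impact_matrix() -> ImpactMatrix:
    """The published NpuDnaE extein-impact matrix, if the user supplied it.

    Expects a 20x6 TSV at ``inteinkit/data/npu_extein_impact.tsv`` (columns
    residue, N-3..C+3).  Raises FileNotFoundError with instructions when the
    optional asset is absent.
    """
    path = _data_path("npu_extein_impact.tsv")
    try:
        exists = path.is_file()
    except AttributeError:  # non-filesystem traversable
        exists = False
    if not exists:
        raise FileNotFoundError(
            "The published NpuDnaE extein-impact matrix is an optional asset "
            "that is not redistributed with inteinkit. Obtain the 485-variant "
            "extein screen table and save it as "
            "inteinkit/data/npu_extein_impact.tsv "
            "(TSV: residue\\tN-3\\tN-2\\tN-1\\tC+1\\tC+2\\tC+3, 20 rows)."
        )
    return load_impact_matrix(str(path), meta={"family": "NpuDnaE", "source": "user-supplied"})


#: AAV5 transduction dose ladder (Vg/cell) and percent GFP-positive cells.
AAV5_DOSE_RESPONSE = (
    (5e3, 7.2),
    (1e4, 13.7),
    (2e4, 38.7),
    (5e4, 58.6),
    (1e5, 72.4),
    (2e5, 80.2),
)


def aav5_dose_response():
    """The six-point AAV5 transduction dose-response (doses in Vg/cell, %GFP+)."""
    arr = np.asarray(AAV5_DOSE_RESPONSE, dtype=float)
    return arr[:, 0], arr[:, 1]
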