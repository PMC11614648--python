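"""Seeded synthetic-data generators.

Every generator is a pure function of its seed and parameters, so the whole
toolkit is testable without downloads: random proteins stand in for targets,
Gaussian impact matrices (optionally with a "planted" dominant window) stand
in for the experimental extein screen, and the assay generators produce
dose-response tables and qPCR dilution series from known ground-truth
parameters for parameter-recovery checks.

Defaults mirror the study conditions: a 238-residue target, a six-dose AAV
ladder from 5e3 to 2e5 Vg/cell, and a six-level 10-fold qPCR dilution series
spanning 1e4-1e9 copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .scanner import POSITIONS, ImpactMatrix
from .seqcore import AMINO_ACIDS, ProteinRecord

#: The six-dose AAV transduction ladder (Vg/cell).
DEFAULT_DOSES = (5e3, 1e4, 2e4, 5e4, 1e5, 2e5)
#: Six 10-fold qPCR dilution levels, highest first (copies per reaction).
DEFAULT_QPCR_LEVELS = (1e9, 1e8, 1e7, 1e6, 1e5, 1e4)


@dataclass
class FixtureConfig:
    """One bundle of generator settings; the seed fixes all output bit-for-bit."""

    seed: int = 0
    protein_length: int = 238
    matrix_effect_sd: float = 5.0
    planted_site: Optional[int] = None
    dose_params: tuple = (2.0, 90.0, 4e4, 1.5)  # (a, d, c, b)
    noise_sd: float = 2.0
    qpcr_efficiency: float = 0.95

    def __post_init__(self) -> None:
        if self.protein_length < 6:
            raise ValueError("protein_length must be >= 6")


def gen_random_protein(length: int, seed: int, id: str = "synthetic") -> ProteinRecord:
    """Uniform-random protein over the 20 canonical residues."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ProteinRecord(id, seq)


def gen_impact_matrix(
    seed: int,
    effect_sd: float = 5.0,
    planted_window: Optional[str] = None,
) -> ImpactMatrix:
    """Gaussian impact matrix, optionally with one window planted as rank 1.

    Cells are N(0, effect_sd).  When ``planted_window`` is given, each of its
    residues receives a bonus at its window position large enough that no
    other 6-mer can out-score it (the bonus exceeds 12x the largest absolute
    background cell, and a non-identical window shares at most 5 of the 6
    boosted cells).
    """
    if effect_sd < 0:
        raise ValueError("effect_sd must be >= 0")
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, effect_sd, size=(20, 6))
    df = pd.DataFrame(values, index=list(AMINO_ACIDS), columns=list(POSITIONS))
    meta = {"source": f"synthetic(seed={seed}, effect_sd={effect_sd})", "family": "synthetic"}
    if planted_window is not None:
        if len(planted_window) != 6:
            raise ValueError("planted window must have length 6")
        bonus = 12.0 * float(np.abs(values).max()) + 1.0
        for pos, res in zip(POSITIONS, planted_window):
            df.at[res, pos] += bonus
        meta["planted_window"] = planted_window
    return ImpactMatrix(df, meta)


def gen_dose_response(
    params: tuple = (2.0, 90.0, 4e4, 1.5),
    doses: Sequence[float] = DEFAULT_DOSES,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Dose/response table from a 4PL ground truth plus Gaussian noise."""
    a, d, c, b = params
    x = np.asarray(doses, dtype=float)
    mean = d + (a - d) / (1.0 + (x / c) ** b)
    rng = np.random.default_rng(seed)
    y = mean + rng.normal(0.0, noise_sd, size=x.size) if noise_sd > 0 else mean
    return pd.DataFrame({"dose": x, "response": y})


def gen_standard_curve(
    efficiency: float = 0.95,
    intercept: float = 40.0,
    levels: Sequence[float] = DEFAULT_QPCR_LEVELS,
    reps: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR dilution-series table: Ct = intercept + slope*log10(copies) + noise.

    slope = -1/log10(1 + efficiency); efficiency 1.0 gives the perfect-
    doubling slope of about -3.3219 Ct per decade.
    """
    if efficiency <= 0:
        raise ValueError("efficiency must be > 0")
    slope = -1.0 / np.log10(1.0 + efficiency)
    rng = np.random.default_rng(seed)
    rows = []
    for copies in levels:
        mean_ct = intercept + slope * np.log10(copies)
        for rep in range(1, reps + 1):
            ct = mean_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"copies": float(copies), "ct": float(ct), "replicate": rep})
    return pd.DataFrame(rows)
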