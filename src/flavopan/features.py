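"""Feature-class profiles, secretome regression, and predictor consensus.

Per-genome counts of feature classes (e.g. carbohydrate-active enzyme --
CAZy -- families such as GH, CE, PL, CBM) are ordinated by PCA either on
presence/absence or on raw counts; clade labels, when supplied, are
carried through for plotting but never enter the computation.

The secretome regression estimates the fraction of a Gram-negative
proteome exported by the type 2 secretion pathway from proteome size
alone:  percent = 0.0017 * proteome_size + 23.8.

``consensus_calls`` intersects the positive-call sets of two independent
signal-peptide predictors, the standard way to harden such predictions.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import pandas as pd

from flavopan.pangenome import PcaResult, pca

logger = logging.getLogger(__name__)

SECRETOME_SLOPE = 0.0017  # % per protein
SECRETOME_INTERCEPT = 23.8  # %


@dataclasses.dataclass
class FeatureMatrix:
    """Genomes x feature classes, non-negative counts, optional clade labels."""

    df: pd.DataFrame
    clades: pd.Series | None = None  # genome -> terrestrial|aquatic|unknown

    def __post_init__(self) -> None:
        if (self.df.values < 0).any():
            raise ValueError("feature counts must be non-negative")
        if self.df.columns.duplicated().any():
            raise ValueError("feature labels must be unique")
        if self.clades is not None:
            missing = set(self.df.index) - set(self.clades.index)
            if missing:
                raise ValueError(f"clade labels missing for genomes: {sorted(missing)}")


def feature_pca(matrix: FeatureMatrix, mode: str = "presence") -> tuple[PcaResult, pd.DataFrame]:
    """PCA of a feature-class matrix.

    mode="presence" binarizes counts (>0 -> 1) and uses the binary
    defaults (centered, unscaled); mode="counts" uses raw counts,
    centered and unit-variance scaled.  Returns the PCA result plus the
    coordinates joined with clade labels.
    """
    if matrix.df.shape[0] < 3:
        raise ValueError("feature PCA needs at least 3 genomes")
    if mode == "presence":
        df = (matrix.df > 0).astype(int)
        result = pca(df, center=True, scale=False)
    elif mode == "counts":
        result = pca(matrix.df, center=True, scale=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    coords = result.coordinates.copy()
    coords["clade"] = (
        matrix.clades.reindex(coords.index)
        if matrix.clades is not None
        else "unknown"
    )
    return result, coords


@dataclasses.dataclass
class SecretomePrediction:
    proteome_size: int
    secretome_percent: float
    secretome_count: int

    def __post_init__(self) -> None:
        if self.secretome_percent <= 0:
            raise ValueError("secretome percent must be positive")


def secretome_estimate(proteome_size: int) -> SecretomePrediction:
    """Expected secretome size from the proteome-size regression.

    percent = 0.0017 * proteome_size + 23.8; the protein count rounds
    half away from zero.
    """
    if proteome_size < 1:
        raise ValueError("proteome_size must be >= 1")
    percent = SECRETOME_SLOPE * proteome_size + SECRETOME_INTERCEPT
    count = math.floor(percent / 100.0 * proteome_size + 0.5)
    return SecretomePrediction(
        proteome_size=proteome_size,
        secretome_percent=percent,
        secretome_count=count,
    )


def consensus_calls(calls_a: set[str], calls_b: set[str]) -> set[str]:
    """Proteins called positive by both predictors (set intersection)."""
    out = set(calls_a) & set(calls_b)
    logger.info(
        "consensus_calls: %d and %d calls -> %d consensus",
        len(calls_a),
        len(calls_b),
        len(out),
    )
    return out
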