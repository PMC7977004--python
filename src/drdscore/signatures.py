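"""Non-negative least-squares decomposition of catalogs into signatures.

A mutational catalog ``m`` (96 channels) is decomposed over a fixed
signature matrix ``S`` (96 x 30, columns AC1..AC30, each a probability
distribution over channels) by solving

    minimize || m - S e ||_2   subject to   e >= 0

with Lawson-Hanson active-set NNLS.  Exposures are reported in mutation
counts (the scale of the catalog), not proportions, because the downstream
risk-score coefficients multiply raw per-signature magnitudes.

The bundled matrix ``ac30_signatures_synthetic.tsv`` is a synthetic
stand-in with the same shape, naming (AC = "Alexandrov COSMIC") and
column-stochastic structure as the 30-signature COSMIC v2 set; see the
methods note.  Any 96 x 30 matrix in the same TSV layout can be supplied
instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .catalog import SBS96_LABELS, MutationalCatalog
from .io import ParseError, ValidationError

__all__ = ["SignatureMatrix", "ExposureVector", "load_signatures",
           "fit_exposures", "SIGNATURE_NAMES"]

SIGNATURE_NAMES = [f"AC{i}" for i in range(1, 31)]


@dataclass
class SignatureMatrix:
    """96 x 30 channel-probability matrix, columns named AC1..AC30."""

    matrix: np.ndarray
    names: list[str]
    contexts: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.names)} signature names"
            )
        if not np.isfinite(self.matrix).all():
            raise ValidationError("signature probabilities must be finite")
        if (self.matrix < 0).any():
            raise ValidationError("signature probabilities must be non-negative")
        sums = self.matrix.sum(axis=0)
        off = np.abs(sums - 1.0) > 1e-6
        if off.any():
            bad = [self.names[i] for i in np.where(off)[0]]
            raise ValidationError(f"signature columns must sum to 1: {bad}")

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, index=self.contexts, columns=self.names)
        df.index.name = "context"
        df.to_csv(path, sep="\t", float_format="%.8g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="context")
        if list(df.index) != SBS96_LABELS:
            raise ParseError(
                f"{path}: contexts must be the canonical 96 COSMIC labels "
                f"in canonical order"
            )
        return cls(df.to_numpy(), list(df.columns), list(df.index))


def load_signatures(path: str | Path | None = None) -> SignatureMatrix:
    """Load a signature matrix TSV; the bundled synthetic AC1-AC30 set by default."""
    if path is None:
        ref = resources.files("drdscore.data") / "ac30_signatures_synthetic.tsv"
        with resources.as_file(ref) as p:
            return SignatureMatrix.from_tsv(p)
    return SignatureMatrix.from_tsv(path)


@dataclass
class ExposureVector:
    """Per-signature exposures (mutation counts) plus the NNLS residual norm."""

    values: np.ndarray
    names: list[str]
    residual: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValidationError("exposure length does not match names")
        if (self.values < -1e-12).any():
            raise ValidationError("exposures must be non-negative")
        self.values = np.clip(self.values, 0.0, None)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def fit_exposures(
    catalog: MutationalCatalog, signatures: SignatureMatrix
) -> ExposureVector:
    """Decompose ``catalog`` over ``signatures`` by non-negative least squares.

    The catalog and matrix must share the canonical channel ordering (both
    carry it by construction; a matrix with reordered contexts is rejected
    at load time, never silently reordered).  Deterministic for fixed input.
    """
    if signatures.contexts != catalog.labels:
        raise ValidationError("channel ordering mismatch between catalog and matrix")
    exposures, residual = nnls(signatures.matrix, catalog.counts)
    return ExposureVector(exposures, list(signatures.names), float(residual))
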