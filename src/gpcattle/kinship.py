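"""Genomic relationship matrix (VanRaden method 1).

G = W W' / sum_j 2 p_j (1 - p_j), where W is the dosage matrix with each
column centered at twice the observed allele frequency.  Observed
frequencies are used throughout (no base-population frequencies are
available for this design).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix

__all__ = ["GRM", "vanraden_grm", "grm_submatrix", "write_grm", "read_grm"]


@dataclass
class GRM:
    values: np.ndarray
    sample_ids: np.ndarray
    denominator: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def with_ridge(self, rel: float = 1e-6) -> "GRM":
        """Add rel * mean(diag) to the diagonal (positive-definiteness for
        solvers); the shift is deliberately tiny and documented here."""
        delta = rel * float(np.mean(np.diag(self.values)))
        return GRM(self.values + delta * np.eye(self.n_samples),
                   self.sample_ids, self.denominator)


def vanraden_grm(geno: GenotypeMatrix) -> GRM:
    """Method-1 genomic relationships from a complete dosage matrix."""
    Z = geno.values()
    p = Z.mean(axis=0) / 2.0
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom == 0.0:
        raise ValueError("all markers monomorphic: VanRaden denominator is zero")
    W = Z - 2.0 * p
    G = (W @ W.T) / denom
    return GRM(values=G, sample_ids=geno.sample_ids, denominator=denom)


def grm_submatrix(grm: GRM, ids) -> GRM:
    """Principal submatrix in the requested id order."""
    rank = {str(s): i for i, s in enumerate(grm.sample_ids)}
    try:
        idx = np.array([rank[str(s)] for s in ids])
    except KeyError as exc:
        raise ValueError(f"unknown sample id {exc.args[0]!r}") from exc
    return GRM(grm.values[np.ix_(idx, idx)],
               np.asarray(list(ids), dtype=object), grm.denominator)


def write_grm(grm: GRM, path) -> None:
    df = pd.DataFrame(grm.values, index=grm.sample_ids, columns=grm.sample_ids)
    with open(path, "w") as fh:
        fh.write(f"# denominator={grm.denominator!r}\n")
        df.to_csv(fh, sep="\t", index_label="id")


def read_grm(path) -> GRM:
    with open(path) as fh:
        first = fh.readline()
        denom = float(first.split("=", 1)[1]) if first.startswith("#") else np.nan
        if not first.startswith("#"):
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return GRM(df.to_numpy(dtype=float), np.asarray(df.index, dtype=object), denom)
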