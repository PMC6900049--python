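"""Variant quality control: call-rate/MAF/HWE filters, windowed LD pruning
and mean imputation.

Filter thresholds follow the usual strict conventions: a marker survives
with MAF > maf_min, missing proportion < miss_max and HWE p > hwe_min.
The filter order is missingness -> MAF -> HWE, and the per-stage counts
are reported so the composition is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeMatrix

__all__ = [
    "QCReport",
    "allele_frequencies",
    "call_rates",
    "hwe_pvalue",
    "hwe_pvalues",
    "ld_r2",
    "apply_variant_filters",
    "ld_prune",
    "mean_impute",
]


@dataclass
class QCReport:
    """Stage-by-stage marker counts plus per-marker diagnostics."""

    stages: list = field(default_factory=list)  # (name, n_in, n_out, threshold)
    diagnostics: pd.DataFrame | None = None

    def add_stage(self, name: str, n_in: int, n_out: int, threshold: float) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name}: n_out {n_out} > n_in {n_in}")
        if self.stages and self.stages[-1][2] != n_in:
            raise ValueError(f"stage {name}: n_in does not telescope")
        self.stages.append((name, n_in, n_out, threshold))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages,
                            columns=["stage", "n_in", "n_out", "threshold"])


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Counted-allele frequency p_j = (sum of dosages) / (2 * calls)."""
    calls = (~np.ma.getmaskarray(geno.dosages)).sum(axis=0)
    if (calls == 0).any():
        j = int(np.argmax(calls == 0))
        raise ValueError(f"marker {geno.marker_ids[j]!r} has no non-missing calls")
    return np.asarray(geno.dosages.sum(axis=0) / (2.0 * calls))


def minor_allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    p = allele_frequencies(geno)
    return np.minimum(p, 1.0 - p)


def call_rates(geno: GenotypeMatrix) -> np.ndarray:
    return np.asarray(
        (~np.ma.getmaskarray(geno.dosages)).mean(axis=0), dtype=float)


def hwe_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-df chi-square goodness-of-fit p-value against Hardy-Weinberg
    proportions; monomorphic markers return 1 by convention."""
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotype calls")
    p = (2 * n_aa + n_Aa) / (2.0 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_pvalues(geno: GenotypeMatrix) -> np.ndarray:
    dos = geno.dosages
    out = np.empty(geno.n_markers)
    for j in range(geno.n_markers):
        col = dos[:, j].compressed()
        out[j] = hwe_pvalue(int((col == 0).sum()), int((col == 1).sum()),
                            int((col == 2).sum()))
    return out


def ld_r2(g_j: np.ndarray, g_k: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over pairwise
    complete samples; defined as 0 when either is constant on that set."""
    a = np.ma.masked_invalid(np.ma.masked_array(g_j, copy=False).astype(float))
    b = np.ma.masked_invalid(np.ma.masked_array(g_k, copy=False).astype(float))
    shared = ~(np.ma.getmaskarray(a) | np.ma.getmaskarray(b))
    if shared.sum() < 2:
        raise ValueError("fewer than 2 pairwise-complete samples")
    x = np.asarray(a[shared])
    y = np.asarray(b[shared])
    if x.var() == 0 or y.var() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def apply_variant_filters(geno: GenotypeMatrix, maf_min: float = 0.05,
                          miss_max: float = 0.05, hwe_min: float = 1e-6):
    """Strict-inequality variant filters in the order missingness, MAF, HWE.

    Returns the filtered matrix and a :class:`QCReport` whose stage counts
    telescope.
    """
    for name, v in [("maf_min", maf_min), ("miss_max", miss_max),
                    ("hwe_min", hwe_min)]:
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")

    report = QCReport()
    m0 = geno.n_markers

    cr = call_rates(geno)
    keep = (1.0 - cr) < miss_max
    report.add_stage("missingness", m0, int(keep.sum()), miss_max)
    geno = geno.take_markers(np.flatnonzero(keep))

    maf = minor_allele_frequencies(geno)
    keep = maf > maf_min
    report.add_stage("maf", geno.n_markers, int(keep.sum()), maf_min)
    geno = geno.take_markers(np.flatnonzero(keep))

    hwe = hwe_pvalues(geno)
    keep = hwe > hwe_min
    report.add_stage("hwe", geno.n_markers, int(keep.sum()), hwe_min)
    geno = geno.take_markers(np.flatnonzero(keep))

    report.diagnostics = pd.DataFrame({
        "marker_id": geno.marker_ids,
        "maf": minor_allele_frequencies(geno),
        "call_rate": call_rates(geno),
        "hwe_p": hwe_pvalues(geno),
    })
    return geno, report


def ld_prune(geno: GenotypeMatrix, window: int = 100, r2_max: float = 0.995):
    """Greedy left-to-right windowed LD pruning within chromosomes.

    A marker is dropped when its r² with any already-kept marker at most
    ``window - 1`` positions back in the (kept) marker index exceeds
    ``r2_max``; the left marker of a correlated pair therefore survives.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    complete = geno.is_complete
    X = geno.values() if complete else None
    if complete:
        Xc = X - X.mean(axis=0)
        sd = Xc.std(axis=0)

    keep_idx: list[int] = []
    for chrom in pd.unique(geno.chromosome):
        cols = np.flatnonzero(geno.chromosome == chrom)
        kept_local: list[int] = []
        for j in cols:
            trail = kept_local[-(window - 1):]
            drop = False
            if trail:
                if complete:
                    if sd[j] == 0:
                        r2 = np.zeros(len(trail))
                    else:
                        B = Xc[:, trail]
                        num = B.T @ Xc[:, j] / len(Xc)
                        den = sd[trail] * sd[j]
                        r2 = np.zeros(len(trail))
                        ok = den > 0
                        r2[ok] = (num[ok] / den[ok]) ** 2
                    drop = bool((r2 > r2_max).any())
                else:
                    for k in trail:
                        if ld_r2(geno.dosages[:, k], geno.dosages[:, j]) > r2_max:
                            drop = True
                            break
            if not drop:
                kept_local.append(j)
        keep_idx.extend(kept_local)
    keep_idx = sorted(keep_idx)
    pruned = geno.take_markers(np.array(keep_idx, dtype=int))
    return pruned, list(pruned.marker_ids)


def mean_impute(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the marker mean 2*p_j (real-valued)."""
    p = allele_frequencies(geno)  # raises on all-missing markers
    dos = geno.dosages.astype(float)
    filled = np.where(np.ma.getmaskarray(dos), 2.0 * p[None, :],
                      dos.filled(0.0))
    out = GenotypeMatrix(
        dosages=np.ma.masked_array(filled),
        sample_ids=geno.sample_ids,
        marker_ids=geno.marker_ids,
        chromosome=geno.chromosome,
        position=geno.position,
        counted_allele=geno.counted_allele,
        other_allele=geno.other_allele,
    )
    return out
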