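"""Genotype quality control and population-structure components.

Hardy-Weinberg tests use the 1-df goodness-of-fit chi-square on genotype
counts (the era-standard test; no exact test). Principal components follow the
standard genotype-matrix construction: mean-impute missing calls, centre each
marker at twice its allele frequency and scale by sqrt(p(1-p)) before the
decomposition, so the top axes track ancestry rather than common-allele
variance. Sign indeterminacy is resolved by forcing the largest-magnitude
loading of each component positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import MISSING, GenotypeMatrix

__all__ = [
    "HWEResult",
    "PCResult",
    "allele_frequency",
    "genotype_counts",
    "hwe_test",
    "hwe_table",
    "bonferroni_threshold",
    "compute_pcs",
]

#: Reporting threshold used when flagging HWE departures.
HWE_FLAG_P = 0.02


@dataclass(frozen=True)
class HWEResult:
    rsid: str
    n0: int  # major homozygotes (minor-allele count 0)
    n1: int  # heterozygotes
    n2: int  # minor homozygotes
    expected: tuple[float, float, float]
    chi2: float
    p_value: float
    flagged: bool  # p <= 0.02 reporting rule
    degenerate: bool = False  # monomorphic SNP: test not informative

    @property
    def maf(self) -> float:
        n = self.n0 + self.n1 + self.n2
        return (self.n1 + 2 * self.n2) / (2 * n) if n else float("nan")


@dataclass
class PCResult:
    """Top-k principal components of a genotype matrix."""

    individual_ids: list[str]
    coordinates: np.ndarray  # (n, k)
    variance_fractions: np.ndarray  # (k,) non-increasing

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.coordinates, index=self.individual_ids, columns=cols)


def allele_frequency(column: np.ndarray) -> float:
    """Minor-allele frequency of one genotype column, ignoring missing calls.

    If the computed frequency exceeds 0.5 the complementary allele is the true
    minor allele and its frequency (1 - f) is returned.
    """
    g = np.asarray(column)
    g = g[g != MISSING]
    if g.size == 0:
        raise ValueError("cannot compute an allele frequency from an all-missing column")
    f = g.sum() / (2.0 * g.size)
    return float(min(f, 1.0 - f))


def genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    """(n0, n1, n2) counts of minor-allele dosages, ignoring missing calls."""
    g = np.asarray(column)
    g = g[g != MISSING]
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def hwe_test(n0: int, n1: int, n2: int, rsid: str = "", min_total: int = 10) -> HWEResult:
    """Goodness-of-fit chi-square test against Hardy-Weinberg proportions.

    Expected counts come from the estimated allele frequency
    ``q = (n1 + 2 n2) / (2 n)``: ``n (1-q)^2, 2 n q (1-q), n q^2``; the
    statistic ``sum (obs-exp)^2 / exp`` is referred to chi-square with 1 df
    (3 genotype classes, 1 estimated frequency). Monomorphic columns return
    p = 1 with a degeneracy note instead of erroring.
    """
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n < min_total:
        raise ValueError(f"total genotype count {n} below minimum {min_total}")
    q = (n1 + 2 * n2) / (2 * n)
    if q == 0.0 or q == 1.0:
        return HWEResult(rsid, n0, n1, n2, (float(n0), float(n1), float(n2)),
                         0.0, 1.0, False, degenerate=True)
    exp = (n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q ** 2)
    chi2 = sum((o - e) ** 2 / e for o, e in zip((n0, n1, n2), exp))
    p = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(rsid, n0, n1, n2, exp, float(chi2), p, p <= HWE_FLAG_P)


def hwe_table(genotypes: GenotypeMatrix, min_total: int = 10) -> pd.DataFrame:
    """Per-SNP HWE results for a genotype matrix, one row per variant."""
    rows = []
    for rsid in genotypes.variant_ids:
        n0, n1, n2 = genotype_counts(genotypes.column(rsid))
        res = hwe_test(n0, n1, n2, rsid=rsid, min_total=min_total)
        rows.append({
            "rsid": rsid, "n0": res.n0, "n1": res.n1, "n2": res.n2,
            "maf": res.maf, "chi2": res.chi2, "p_value": res.p_value,
            "flagged": res.flagged, "degenerate": res.degenerate,
        })
    return pd.DataFrame(rows)


def bonferroni_threshold(alpha: float, n_tests: int) -> tuple[float, float]:
    """(exact cut-off alpha/n, display cut-off rounded to 1 significant figure)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    exact = alpha / n_tests
    if exact == 0:
        return 0.0, 0.0
    magnitude = 10.0 ** np.floor(np.log10(exact))
    display = float(np.round(exact / magnitude) * magnitude)
    return float(exact), display


def compute_pcs(genotypes: GenotypeMatrix, k: int) -> PCResult:
    """Top-k PCA of a (background) genotype matrix, Price-style scaling.

    Missing calls are mean-imputed per marker; each column is centred at its
    mean dosage and divided by sqrt(p(1-p)) with p the allele frequency; the
    decomposition is a thin SVD. Deterministic: each component's
    largest-magnitude loading is made positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = genotypes.counts.astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])

    p = col_mean / 2.0
    scale = np.sqrt(np.clip(p * (1.0 - p), 1e-12, None))
    Z = (X - col_mean) / scale
    # drop monomorphic columns (zero variance): no ancestry information
    keep = Z.std(axis=0) > 0
    Z = Z[:, keep]

    max_k = min(Z.shape)
    if k > max_k:
        raise ValueError(f"k={k} exceeds the rank bound {max_k}")
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    coords = U[:, :k] * S[:k]
    # sign convention: largest |loading| positive per component
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            coords[:, j] *= -1
    var_frac = (S ** 2) / np.sum(S ** 2)
    return PCResult(list(genotypes.individual_ids), coords, var_frac[:k])
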