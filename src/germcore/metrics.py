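"""Genetic diversity indices, accession distance matrices and PCA.

All indices operate on biallelic loci.  With alternate-allele frequency p
and q = 1 - p:

* observed heterozygosity Ho — fraction of heterozygous (dosage 1) calls;
* expected heterozygosity He = 2pq (optionally Nei's small-sample
  correction 2n/(2n-1));
* polymorphism information content PIC = 1 - (p^2 + q^2) - 2 p^2 q^2;
* Shannon's diversity index I = -(p ln p + q ln q), 0 ln 0 = 0;
* genetic evenness J' = I / ln(a) with a the number of observed alleles;
  monomorphic loci (a = 1) are excluded from the J' mean.

Distances between accessions use within-individual allele fractions
(0, 1/2, 1 per allele): Modified Rogers' distance is the Euclidean metric
on dosage/2 scaled to [0, 1]; the Cavalli-Sforza & Edwards chord distance
is Euclidean on square-rooted allele fractions normalized by 2L so it is
also bounded by 1.  Both are computed over pairwise-complete loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, allele_frequencies

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Per-locus diversity indices

def observed_heterozygosity(
    g: GenotypeMatrix, subset: Sequence[str] | None = None
) -> np.ndarray:
    """Per-locus fraction of non-missing genotypes that are heterozygous.

    Loci with no non-missing genotype in the subset are NaN.
    """
    idx = g.accession_indices(subset)
    if idx.size == 0:
        raise ValueError("subset must be nonempty")
    d = g.dosage[idx]
    n_obs = (d != MISSING).sum(axis=0)
    n_het = (d == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_obs > 0, n_het / np.maximum(n_obs, 1), np.nan)
    return ho


def expected_heterozygosity(
    freqs: np.ndarray, n_obs: np.ndarray | None = None, unbiased: bool = False
) -> np.ndarray:
    """He_l = 2 p (1 - p); with ``unbiased``, Nei's 2n/(2n-1) correction.

    ``n_obs`` (non-missing genotype count per locus) is required only for
    the unbiased form.  Undefined frequencies propagate as NaN.
    """
    p = np.asarray(freqs, dtype=float)
    he = 2.0 * p * (1.0 - p)
    if unbiased:
        if n_obs is None:
            raise ValueError("unbiased He needs per-locus sample sizes")
        n = np.asarray(n_obs, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            he = he * np.where(n > 0.5, 2.0 * n / np.maximum(2.0 * n - 1.0, 1.0), np.nan)
    return he


def pic(freqs: np.ndarray) -> np.ndarray:
    """Biallelic polymorphism information content per locus."""
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def shannon_index(freqs: np.ndarray) -> np.ndarray:
    """I_l = -(p ln p + q ln q) with the 0 ln 0 = 0 convention."""
    p = np.asarray(freqs, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = np.where(p > 0, p * np.log(p), 0.0)
        q = 1.0 - p
        t2 = np.where(q > 0, q * np.log(q), 0.0)
    out = -(t1 + t2)
    out[np.isnan(p)] = np.nan
    return out


def evenness(freqs: np.ndarray) -> np.ndarray:
    """J'_l = I_l / ln(a_l); NaN at monomorphic loci (a_l = 1)."""
    p = np.asarray(freqs, dtype=float)
    i = shannon_index(p)
    a = np.where((p > 0) & (p < 1), 2, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        j = np.where(a > 1, i / np.log(2.0), np.nan)
    j[np.isnan(p)] = np.nan
    return j


@dataclass
class DiversityReport:
    """Mean and per-locus diversity indices for one accession set."""

    ho: float
    he: float
    pic: float
    shannon: float
    evenness: float
    per_locus: pd.DataFrame = field(repr=False)

    def as_row(self) -> dict:
        return {
            "Ho": self.ho,
            "He": self.he,
            "PIC": self.pic,
            "I": self.shannon,
            "J'": self.evenness,
        }


def diversity_report(
    g: GenotypeMatrix,
    subset: Sequence[str] | None = None,
    unbiased_he: bool = False,
) -> DiversityReport:
    """Compute Ho, He, PIC, I and J' (means over defined loci) for a subset."""
    idx = g.accession_indices(subset)
    freqs = allele_frequencies(g, subset)
    n_obs = (g.dosage[idx] != MISSING).sum(axis=0)
    ho = observed_heterozygosity(g, subset)
    he = expected_heterozygosity(freqs, n_obs=n_obs, unbiased=unbiased_he)
    pic_l = pic(freqs)
    i_l = shannon_index(freqs)
    j_l = evenness(freqs)
    if np.all(np.isnan(j_l)):
        raise ValueError("evenness undefined: all loci monomorphic")
    per_locus = pd.DataFrame(
        {"Ho": ho, "He": he, "PIC": pic_l, "I": i_l, "J'": j_l}
    )
    return DiversityReport(
        ho=float(np.nanmean(ho)),
        he=float(np.nanmean(he)),
        pic=float(np.nanmean(pic_l)),
        shannon=float(np.nanmean(i_l)),
        evenness=float(np.nanmean(j_l)),
        per_locus=per_locus,
    )


# ----------------------------------------------------------------------
# Distance matrices

@dataclass
class DistanceMatrix:
    """Symmetric accession distance matrix tagged with its metric."""

    metric: str  # "MR" or "CE"
    accession_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.accession_ids):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        self.values = v

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        idx = np.array([pos[str(a)] for a in ids], dtype=int)
        return DistanceMatrix(
            metric=self.metric,
            accession_ids=[str(a) for a in ids],
            values=self.values[np.ix_(idx, idx)].copy(),
        )


def _masked_sq_dist(x: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum of squared differences over shared-defined loci, plus pair counts.

    x must already be zero-filled where mask is 0.
    """
    x2 = x * x
    shared = mask @ mask.T
    s = (x2 @ mask.T) + (mask @ x2.T) - 2.0 * (x @ x.T)
    return s, shared


def _finalize(metric, ids, s, shared) -> DistanceMatrix:
    if np.any(shared[np.triu_indices_from(shared, k=1)] == 0):
        raise ValueError(
            f"{metric} distance undefined: an accession pair shares no genotyped locus"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.maximum(s, 0.0) / shared)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(metric=metric, accession_ids=list(ids), values=d)


def mr_distance_matrix(
    g: GenotypeMatrix, subset: Sequence[str] | None = None
) -> DistanceMatrix:
    """Modified Rogers' distance over pairwise-complete loci.

    d(i,j) = sqrt( (1/L_ij) sum_l ((g_il - g_jl)/2)^2 ), in [0, 1].
    """
    idx = g.accession_indices(subset)
    if idx.size < 2:
        raise ValueError("need at least 2 accessions")
    ids = [g.accession_ids[i] for i in idx]
    d = g.dosage[idx].astype(np.float64)
    mask = (g.dosage[idx] != MISSING).astype(np.float64)
    x = np.where(mask > 0, d / 2.0, 0.0)
    s, shared = _masked_sq_dist(x, mask)
    return _finalize("MR", ids, s, shared)


def ce_distance_matrix(
    g: GenotypeMatrix, subset: Sequence[str] | None = None
) -> DistanceMatrix:
    """Cavalli-Sforza & Edwards chord distance over pairwise-complete loci.

    With within-individual allele fractions x in {0, 1/2, 1} per allele,
    d(i,j) = sqrt( (1/(2 L_ij)) sum_l sum_a (sqrt(x_ila) - sqrt(x_jla))^2 ),
    bounded by 1 under the 2L normalization.
    """
    idx = g.accession_indices(subset)
    if idx.size < 2:
        raise ValueError("need at least 2 accessions")
    ids = [g.accession_ids[i] for i in idx]
    d = g.dosage[idx].astype(np.float64)
    mask = (g.dosage[idx] != MISSING).astype(np.float64)
    alt = np.where(mask > 0, np.sqrt(d / 2.0), 0.0)
    ref = np.where(mask > 0, np.sqrt(1.0 - d / 2.0), 0.0)
    s_alt, shared = _masked_sq_dist(alt, mask)
    s_ref, _ = _masked_sq_dist(ref, mask)
    return _finalize("CE", ids, s_alt + s_ref, 2.0 * shared)


# ----------------------------------------------------------------------
# PCA

@dataclass
class PcaResult:
    accession_ids: list[str]
    scores: np.ndarray = field(repr=False)
    explained_fraction: np.ndarray = field(repr=False)


def genotype_pca(
    g: GenotypeMatrix, subset: Sequence[str] | None = None, n_components: int = 10
) -> PcaResult:
    """PCA of the mean-centered dosage matrix, missing imputed to locus mean.

    Variance-explained fractions are relative to the full spectrum of the
    accession covariance, sorted descending.
    """
    idx = g.accession_indices(subset)
    if idx.size < 2:
        raise ValueError("need at least 2 accessions for PCA")
    x = g.dosage[idx].astype(np.float64)
    miss = g.dosage[idx] == MISSING
    x[miss] = np.nan
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(x))
    x[inds] = col_mean[inds[1]]
    x -= x.mean(axis=0)
    # economy SVD: full spectrum of the accession covariance
    u, sing, _ = np.linalg.svd(x, full_matrices=False)
    var = sing**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    k = min(n_components, len(sing))
    return PcaResult(
        accession_ids=[g.accession_ids[i] for i in idx],
        scores=u[:, :k] * sing[:k],
        explained_fraction=frac[:k],
    )


@dataclass
class PhenotypePcaResult:
    """Correlation-matrix PCA of standardized traits (Table-style summary)."""

    eigenvalues: np.ndarray
    contribution_pct: np.ndarray
    cumulative_pct: np.ndarray
    top_traits: list[list[str]]
    loadings: pd.DataFrame = field(repr=False)
    scores: pd.DataFrame = field(repr=False)

    def summary(self, n_components: int = 3) -> pd.DataFrame:
        k = min(n_components, len(self.eigenvalues))
        return pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(k)],
                "eigenvalue": np.round(self.eigenvalues[:k], 4),
                "contribution_pct": np.round(self.contribution_pct[:k], 2),
                "cumulative_pct": np.round(self.cumulative_pct[:k], 2),
                "top_traits": [",".join(t) for t in self.top_traits[:k]],
            }
        )


def phenotype_pca(
    phen: pd.DataFrame, subset: Sequence[str] | None = None
) -> PhenotypePcaResult:
    """Eigen-decomposition of the trait correlation matrix.

    Traits are standardized to unit variance; zero-variance traits are
    dropped with a warning.  Contribution percentages are eigenvalues as a
    share of their sum (the trait count), so they total 100.
    """
    df = phen if subset is None else phen.loc[[str(s) for s in subset]]
    df = df.select_dtypes(include=[np.number])
    if df.shape[1] < 2:
        raise ValueError("need at least 2 traits")
    sd = df.std(ddof=1)
    zero_var = sd[sd == 0].index.tolist()
    if zero_var:
        logger.warning("dropping zero-variance traits: %s", zero_var)
        df = df.drop(columns=zero_var)
    z = (df - df.mean()) / df.std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    contrib = 100.0 * eigval / eigval.sum()
    traits = list(df.columns)
    top = [
        [traits[i] for i in np.argsort(-np.abs(eigvec[:, c]))[:3]]
        for c in range(len(eigval))
    ]
    loadings = pd.DataFrame(
        eigvec, index=traits, columns=[f"PC{i + 1}" for i in range(len(eigval))]
    )
    scores = pd.DataFrame(
        z.to_numpy() @ eigvec,
        index=df.index,
        columns=loadings.columns,
    )
    return PhenotypePcaResult(
        eigenvalues=eigval,
        contribution_pct=contrib,
        cumulative_pct=np.cumsum(contrib),
        top_traits=top,
        loadings=loadings,
        scores=scores,
    )


# ----------------------------------------------------------------------
# Differentiation (used to validate simulated divergence)

def hudson_fst(
    g: GenotypeMatrix, ids_a: Sequence[str], ids_b: Sequence[str]
) -> float:
    """Hudson-type Fst between two accession sets, ratio-of-sums over loci."""
    pa = allele_frequencies(g, ids_a)
    pb = allele_frequencies(g, ids_b)
    ia = g.accession_indices(ids_a)
    ib = g.accession_indices(ids_b)
    na = (g.dosage[ia] != MISSING).sum(axis=0) * 2.0  # allele counts
    nb = (g.dosage[ib] != MISSING).sum(axis=0) * 2.0
    ok = ~np.isnan(pa) & ~np.isnan(pb) & (na > 1) & (nb > 1)
    pa, pb, na, nb = pa[ok], pb[ok], na[ok], nb[ok]
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    return float(num.sum() / den.sum())
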