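"""Genotype dosage matrix: the central container for all downstream analysis.

Genotypes are stored as alternate-allele dosages (0, 1, 2) for diploid
biallelic loci, with ``MISSING`` (-1) as the missing sentinel.  Accessions
are rows, loci are columns.  Locus metadata (chromosome, 1-based position,
alleles, minor-allele frequency, missing rate) travels alongside in a
pandas DataFrame and is refreshed after every row or column subsetting so
that per-locus statistics always describe the current matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid genotype.
MISSING: int = -1

_ALLOWED = frozenset({-1, 0, 1, 2})

LOCUS_COLUMNS = ["chrom", "pos", "ref", "alt", "maf", "missing_rate"]


@dataclass
class GenotypeMatrix:
    """Accessions x loci alternate-allele dosage matrix.

    Parameters
    ----------
    accession_ids
        Unique accession identifiers, one per row.
    loci
        DataFrame with columns ``chrom, pos, ref, alt, maf, missing_rate``;
        one row per locus.  ``maf`` / ``missing_rate`` are recomputed on
        construction and after subsetting.
    dosage
        int8 array of shape (n_accessions, n_loci) with values in
        {0, 1, 2, MISSING}.
    """

    accession_ids: list[str]
    loci: pd.DataFrame
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D array")
        n, l = self.dosage.shape
        if n != len(self.accession_ids):
            raise ValueError(
                f"{len(self.accession_ids)} accession ids but {n} dosage rows"
            )
        if l != len(self.loci):
            raise ValueError(f"{len(self.loci)} loci but {l} dosage columns")
        if len(set(self.accession_ids)) != n:
            raise ValueError("accession ids are not unique")
        bad = set(np.unique(self.dosage)) - _ALLOWED
        if bad:
            raise ValueError(f"dosage values outside {{0,1,2,missing}}: {bad}")
        self.loci = self.loci.reset_index(drop=True)
        keys = list(zip(self.loci["chrom"], self.loci["pos"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos) locus keys")
        if len(self.loci) and (self.loci["pos"] < 1).any():
            raise ValueError("locus positions must be 1-based (>= 1)")
        self.refresh_locus_stats()

    # ------------------------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    def dosage_float(self) -> np.ndarray:
        """Dosage as float64 with missing entries as NaN."""
        x = self.dosage.astype(np.float64)
        x[self.dosage == MISSING] = np.nan
        return x

    def accession_indices(self, subset: Sequence[str] | None) -> np.ndarray:
        """Map accession ids to row indices (all rows when subset is None)."""
        if subset is None:
            return np.arange(self.n_accessions)
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return np.array([pos[str(a)] for a in subset], dtype=int)
        except KeyError as e:  # pragma: no cover - message matters, not path
            raise KeyError(f"unknown accession id: {e.args[0]}") from None

    # ------------------------------------------------------------------
    def refresh_locus_stats(self) -> None:
        """Recompute per-locus MAF and missing rate from the current matrix."""
        d = self.dosage
        miss = d == MISSING
        n_obs = (~miss).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(miss, 0, d).sum(axis=0, dtype=np.int64)
            freq = np.where(n_obs > 0, s / (2.0 * np.maximum(n_obs, 1)), np.nan)
        maf = np.minimum(freq, 1.0 - freq)
        self.loci = self.loci.assign(
            maf=maf,
            missing_rate=miss.mean(axis=0) if len(d) else np.nan,
        )

    def subset_loci(self, mask_or_idx: np.ndarray) -> "GenotypeMatrix":
        """New matrix keeping the given loci (boolean mask or index array)."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            loci=self.loci.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx].copy(),
        )

    def subset_accessions(self, ids: Iterable[str]) -> "GenotypeMatrix":
        """New matrix keeping the given accessions, stats refreshed."""
        ids = list(ids)
        idx = self.accession_indices(ids)
        return GenotypeMatrix(
            accession_ids=ids,
            loci=self.loci.copy(),
            dosage=self.dosage[idx].copy(),
        )


def allele_frequencies(
    g: GenotypeMatrix, subset: Sequence[str] | None = None
) -> np.ndarray:
    """Per-locus alternate-allele frequency over the given accessions.

    Frequency is mean dosage over non-missing entries divided by 2.  Loci
    with no non-missing genotype in the subset are returned as NaN
    (undefined).
    """
    idx = g.accession_indices(subset)
    if idx.size == 0:
        raise ValueError("subset must be nonempty")
    d = g.dosage[idx]
    miss = d == MISSING
    n_obs = (~miss).sum(axis=0)
    s = np.where(miss, 0, d).sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, s / (2.0 * np.maximum(n_obs, 1)), np.nan)
    return freq
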