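"""Matrix-level variant filtering and LD pruning.

Site-level hard filters that need sequencing annotations (depth, mapping
quality, strand bias) are assumed to have been applied upstream by the
variant caller; this module only implements the filters expressible on a
plain genotype matrix: missing-rate, minor-allele-frequency and
biallelic-only, plus sliding-window LD pruning of correlated loci.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


def filter_loci(
    g: GenotypeMatrix,
    max_missing: float | None = 0.10,
    min_maf: float | None = 0.05,
    biallelic_only: bool = True,
) -> GenotypeMatrix:
    """Drop loci failing missing-rate, MAF or biallelic criteria.

    A locus is removed when its missing rate exceeds ``max_missing``, when
    its minor-allele frequency is below ``min_maf`` (monomorphic loci have
    MAF 0 and are removed by any positive threshold), or — with
    ``biallelic_only`` — when its ALT field does not denote a single SNP
    allele.  Thresholds set to None disable the corresponding criterion.
    Per-locus statistics are refreshed before testing, and the surviving
    matrix carries refreshed statistics as well.  An empty result is
    permitted (with a warning).
    """
    for name, thr in (("max_missing", max_missing), ("min_maf", min_maf)):
        if thr is not None and not (0.0 <= thr <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {thr}")
    g.refresh_locus_stats()
    keep = np.ones(g.n_loci, dtype=bool)
    n0 = g.n_loci
    if max_missing is not None:
        keep &= g.loci["missing_rate"].to_numpy() <= max_missing
        logger.info("missing-rate filter: %d loci fail", n0 - int(keep.sum()))
    if min_maf is not None:
        maf = g.loci["maf"].to_numpy()
        keep &= ~np.isnan(maf) & (maf >= min_maf)
    if biallelic_only:
        alt = g.loci["alt"].astype(str)
        ref = g.loci["ref"].astype(str)
        keep &= (~alt.str.contains(",")).to_numpy() & (ref != alt).to_numpy()
    out = g.subset_loci(keep)
    logger.info("filter_loci: %d -> %d loci", n0, out.n_loci)
    if out.n_loci == 0:
        logger.warning("filter_loci removed every locus")
    return out


def _pairwise_r2(dosage_window: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between loci, pairwise-complete rows."""
    df = pd.DataFrame(dosage_window)
    r = df.corr(min_periods=2).to_numpy()
    return r * r


def _prune_window(
    d_float: np.ndarray,
    idx: np.ndarray,
    maf: np.ndarray,
    r2_threshold: float,
    removed: set[int],
) -> None:
    """Greedily remove loci in one window until no pair exceeds the threshold.

    Highest-r2 pair first; within a pair the lower-MAF locus is removed,
    ties broken toward the larger locus index.  Mutates ``removed``.
    """
    live = [i for i in idx if i not in removed]
    if len(live) < 2:
        return
    r2 = _pairwise_r2(d_float[:, live])
    np.fill_diagonal(r2, np.nan)
    live = np.asarray(live)
    alive = np.ones(len(live), dtype=bool)
    while True:
        masked = np.where(np.outer(alive, alive), r2, np.nan)
        np.fill_diagonal(masked, np.nan)
        if np.all(np.isnan(masked)):
            break
        flat = np.nanargmax(masked)
        a, b = np.unravel_index(flat, masked.shape)
        if not masked[a, b] > r2_threshold:
            break
        ga, gb = live[a], live[b]
        if maf[ga] < maf[gb]:
            drop_local = a
        elif maf[gb] < maf[ga]:
            drop_local = b
        else:  # tie -> larger locus index
            drop_local = a if ga > gb else b
        alive[drop_local] = False
        removed.add(int(live[drop_local]))


def ld_prune(
    g: GenotypeMatrix,
    window: int = 100,
    step: int = 10,
    r2_threshold: float = 0.2,
) -> GenotypeMatrix:
    """Sliding-window LD pruning of the dosage matrix.

    Within each window of ``window`` loci advanced by ``step``, pairwise
    squared Pearson correlation of dosages (pairwise-complete accessions)
    is computed among loci still retained; while any pair exceeds
    ``r2_threshold`` the member with the lower MAF is removed (tie: the
    later locus).  Deterministic given input order.  Windows with fewer
    than two live loci are skipped.
    """
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must be in (0, 1]")
    g.refresh_locus_stats()
    maf = g.loci["maf"].to_numpy()
    d_float = g.dosage_float()
    removed: set[int] = set()
    start = 0
    while start < g.n_loci:
        idx = np.arange(start, min(start + window, g.n_loci))
        _prune_window(d_float, idx, maf, r2_threshold, removed)
        start += step
    keep = np.array([i not in removed for i in range(g.n_loci)])
    logger.info("ld_prune: %d -> %d loci", g.n_loci, int(keep.sum()))
    return g.subset_loci(keep)
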