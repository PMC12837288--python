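"""Two-step evaluation of candidate cores: genetic screening, then
phenotypic representativeness.

Phenotypic representativeness of a core against the full collection is
summarized by four statistics over the n traits:

* MD — mean difference percentage, 100 * St / n, with St the number of
  traits whose core and full means differ significantly (t-test, alpha);
* VD — variance difference percentage, 100 * SF / n, with SF counted from
  two-sided variance-ratio F-tests;
* CR — coincidence rate of range, the mean ratio of the core trait range
  to the full trait range, times 100;
* VR — coefficient-of-variation ratio, the mean ratio of core CV to full
  CV, times 100 (values above 100 indicate dispersion enrichment).

A core is conventionally accepted when MD < 20% and CR > 80%; among
passing candidates a higher CR, VD and VR and a lower MD indicate better
representativeness (VD and VR reward retention of trait variance, so
higher is preferred even though they count/score differences).  The
core is always compared against the full collection including its own
members, matching standard practice for these statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .metrics import (
    DiversityReport,
    diversity_report,
    genotype_pca,
    phenotype_pca,
)
from .selection import CoreSet

logger = logging.getLogger(__name__)


def reduction_pct(n_full: int, n_core: int) -> float:
    """Percentage size reduction from the full collection to the core."""
    if n_full <= 0 or n_core < 0 or n_core > n_full:
        raise ValueError("need 0 <= n_core <= n_full with n_full positive")
    return 100.0 * (n_full - n_core) / n_full


def _trait_frames(core: pd.DataFrame, full: pd.DataFrame) -> list[str]:
    traits = [c for c in full.columns if c in core.columns]
    if not traits:
        raise ValueError("no shared trait columns")
    return traits


def mean_difference_pct(
    core: pd.DataFrame,
    full: pd.DataFrame,
    alpha: float = 0.05,
    welch: bool = True,
) -> tuple[float, pd.DataFrame]:
    """MD = 100 * St / n from per-trait two-sample t-tests (Welch default).

    Traits with fewer than two non-missing values in either table are
    skipped (n reduced, with a warning).
    """
    traits = _trait_frames(core, full)
    rows = []
    for t in traits:
        a = core[t].dropna().to_numpy(dtype=float)
        b = full[t].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            logger.warning("trait %s skipped in MD: <2 observations", t)
            continue
        res = stats.ttest_ind(a, b, equal_var=not welch)
        p = float(res.pvalue)
        if np.isnan(p):  # identical constant samples
            p = 1.0
        rows.append({"trait": t, "t": float(res.statistic), "p": p,
                     "significant": p < alpha})
    detail = pd.DataFrame(rows)
    if detail.empty:
        raise ValueError("no testable traits for MD")
    st = int(detail["significant"].sum())
    return 100.0 * st / len(detail), detail


def variance_difference_pct(
    core: pd.DataFrame, full: pd.DataFrame, alpha: float = 0.05
) -> tuple[float, pd.DataFrame]:
    """VD = 100 * SF / n from per-trait two-sided variance-ratio F-tests."""
    traits = _trait_frames(core, full)
    rows = []
    for t in traits:
        a = core[t].dropna().to_numpy(dtype=float)
        b = full[t].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            logger.warning("trait %s skipped in VD: <2 observations", t)
            continue
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va == 0 or vb == 0:
            logger.warning("trait %s skipped in VD: zero variance", t)
            continue
        f = va / vb
        dist = stats.f(len(a) - 1, len(b) - 1)
        p = 2.0 * min(dist.cdf(f), dist.sf(f))
        rows.append({"trait": t, "F": f, "p": min(p, 1.0), "significant": p < alpha})
    detail = pd.DataFrame(rows)
    if detail.empty:
        raise ValueError("no testable traits for VD")
    sf = int(detail["significant"].sum())
    return 100.0 * sf / len(detail), detail


def coincidence_rate(
    core: pd.DataFrame, full: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """CR = mean over traits of (core range / full range) * 100."""
    traits = _trait_frames(core, full)
    rows = []
    for t in traits:
        a = core[t].dropna()
        b = full[t].dropna()
        ri = float(b.max() - b.min())
        if ri == 0 or np.isnan(ri):
            logger.warning("trait %s skipped in CR: zero full range", t)
            continue
        rc = float(a.max() - a.min()) if len(a) else np.nan
        rows.append({"trait": t, "range_core": rc, "range_full": ri, "ratio": rc / ri})
    detail = pd.DataFrame(rows)
    if detail.empty:
        raise ValueError("no testable traits for CR")
    return 100.0 * float(detail["ratio"].mean()), detail


def variation_coefficient_ratio(
    core: pd.DataFrame, full: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """VR = mean over traits of (core CV / full CV) * 100; may exceed 100."""
    traits = _trait_frames(core, full)
    rows = []
    for t in traits:
        a = core[t].dropna()
        b = full[t].dropna()
        if len(a) < 2 or len(b) < 2:
            continue
        if a.mean() == 0 or b.mean() == 0:
            logger.warning("trait %s skipped in VR: zero mean", t)
            continue
        cv_c = a.std(ddof=1) / abs(a.mean())
        cv_f = b.std(ddof=1) / abs(b.mean())
        if cv_f == 0:
            logger.warning("trait %s skipped in VR: zero full CV", t)
            continue
        rows.append({"trait": t, "cv_core": cv_c, "cv_full": cv_f, "ratio": cv_c / cv_f})
    detail = pd.DataFrame(rows)
    if detail.empty:
        raise ValueError("no testable traits for VR")
    return 100.0 * float(detail["ratio"].mean()), detail


@dataclass
class EvaluationReport:
    """MD/VD/CR/VR plus pass flags for one candidate core."""

    md_pct: float
    vd_pct: float
    cr_pct: float
    vr_pct: float
    st: int
    sf: int
    n_traits: int
    pass_md: bool
    pass_cr: bool
    detail: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)

    @property
    def passes(self) -> bool:
        return self.pass_md and self.pass_cr


def evaluate_core(
    core_ids: Sequence[str],
    phen: pd.DataFrame,
    alpha: float = 0.05,
    md_max: float = 20.0,
    cr_min: float = 80.0,
    welch: bool = True,
) -> EvaluationReport:
    """Phenotypic MD/VD/CR/VR of a core against the full phenotype table."""
    core_ids = [str(a) for a in core_ids]
    missing = set(core_ids) - set(phen.index.astype(str))
    if missing:
        raise ValueError(f"core accessions without phenotypes: {sorted(missing)[:5]}")
    core = phen.loc[core_ids]
    md, md_d = mean_difference_pct(core, phen, alpha=alpha, welch=welch)
    vd, vd_d = variance_difference_pct(core, phen, alpha=alpha)
    cr, cr_d = coincidence_rate(core, phen)
    vr, vr_d = variation_coefficient_ratio(core, phen)
    return EvaluationReport(
        md_pct=md,
        vd_pct=vd,
        cr_pct=cr,
        vr_pct=vr,
        st=int(md_d["significant"].sum()),
        sf=int(vd_d["significant"].sum()),
        n_traits=len(md_d),
        pass_md=md < md_max,
        pass_cr=cr > cr_min,
        detail={"MD": md_d, "VD": vd_d, "CR": cr_d, "VR": vr_d},
    )


# ----------------------------------------------------------------------
# Two-step framework

@dataclass
class TwoStepResult:
    report: pd.DataFrame = field(repr=False)
    winner: CoreSet | None = None


def two_step_select(
    candidates: Sequence[CoreSet],
    g: GenotypeMatrix,
    phen: pd.DataFrame,
    alpha: float = 0.05,
    md_max: float = 20.0,
    cr_min: float = 80.0,
    retain: int = 5,
) -> TwoStepResult:
    """Screen candidates genetically, then pick the phenotypic winner.

    Step 1 ranks all candidates by genetic diversity (He, then PIC, then
    I, descending) and retains the top ``retain``.  Step 2 computes
    MD/VD/CR/VR for the retained set, applies MD < md_max and CR > cr_min
    as hard filters, and among passers prefers higher CR, then VD, then
    VR, then lower MD.  With no passer the report is still returned and
    ``winner`` is None.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    rows = []
    for c in candidates:
        rep = diversity_report(g, c.selected)
        rows.append({"label": c.strategy.label, "size": len(c.selected), **rep.as_row()})
    div = pd.DataFrame(rows, index=range(len(candidates)))
    div = div.sort_values(["He", "PIC", "I"], ascending=False, kind="mergesort")
    retained = div.head(retain)
    report_rows = []
    scored: list[tuple[tuple, int]] = []
    for i in retained.index:
        c = candidates[i]
        rep = evaluate_core(c.selected, phen, alpha=alpha, md_max=md_max, cr_min=cr_min)
        report_rows.append(
            {
                "label": c.strategy.label,
                "size": len(c.selected),
                "He": div.loc[i, "He"],
                "MD_pct": rep.md_pct,
                "VD_pct": rep.vd_pct,
                "CR_pct": rep.cr_pct,
                "VR_pct": rep.vr_pct,
                "pass": rep.passes,
            }
        )
        if rep.passes:
            scored.append(((-rep.cr_pct, -rep.vd_pct, -rep.vr_pct, rep.md_pct), i))
    report = pd.DataFrame(report_rows)
    winner = None
    if scored:
        scored.sort()
        winner = candidates[scored[0][1]]
    return TwoStepResult(report=report, winner=winner)


# ----------------------------------------------------------------------
# Validation of a chosen core against the original collection

def _letters(p: float, mean_core: float, mean_full: float, alpha: float) -> tuple[str, str]:
    """Two-group significance letters: shared letter iff not significant."""
    if p >= alpha or np.isnan(p):
        return "a", "a"
    return ("a", "b") if mean_core > mean_full else ("b", "a")


@dataclass
class ValidationReport:
    indices: pd.DataFrame = field(repr=False)
    traits: pd.DataFrame = field(repr=False)
    genotype_pca_explained: pd.DataFrame = field(repr=False)
    phenotype_pca: pd.DataFrame = field(repr=False)


def validate_core(
    core_ids: Sequence[str],
    g: GenotypeMatrix,
    phen: pd.DataFrame,
    alpha: float = 0.05,
    n_pcs: int = 3,
) -> ValidationReport:
    """Compare a core against the original collection.

    Genetic diversity indices are compared by unpaired t-tests on the
    per-locus index vectors of the two sets, with two-group significance
    letters (a shared letter means no significant difference).  Each trait
    is compared on max, min, mean (t-test) and CV.  Genotype and phenotype
    PCAs are run on both sets; the phenotype PCA table mirrors the
    eigenvalue / contribution / cumulative / top-traits layout.
    """
    core_ids = [str(a) for a in core_ids]
    if not core_ids:
        raise ValueError("core is empty")
    if not set(core_ids) <= set(g.accession_ids):
        raise ValueError("core must be a subset of the collection")
    rep_core = diversity_report(g, core_ids)
    rep_full = diversity_report(g, None)
    idx_rows = []
    for name in ["Ho", "He", "PIC", "I", "J'"]:
        a = rep_core.per_locus[name].dropna().to_numpy()
        b = rep_full.per_locus[name].dropna().to_numpy()
        res = stats.ttest_ind(a, b, equal_var=False)
        p = float(res.pvalue)
        lc, lf = _letters(p, a.mean(), b.mean(), alpha)
        idx_rows.append(
            {"index": name, "core": a.mean(), "full": b.mean(), "p": p,
             "core_letter": lc, "full_letter": lf}
        )
    indices = pd.DataFrame(idx_rows)

    core_phen = phen.loc[core_ids]
    trait_rows = []
    for t in core_phen.columns:
        a = core_phen[t].dropna()
        b = phen[t].dropna()
        res = stats.ttest_ind(a, b, equal_var=False)
        trait_rows.append(
            {
                "trait": t,
                "max_core": a.max(), "max_full": b.max(),
                "min_core": a.min(), "min_full": b.min(),
                "mean_core": a.mean(), "mean_full": b.mean(),
                "cv_core": a.std(ddof=1) / abs(a.mean()),
                "cv_full": b.std(ddof=1) / abs(b.mean()),
                "p_mean": float(res.pvalue),
            }
        )
    traits = pd.DataFrame(trait_rows)

    gp_core = genotype_pca(g, core_ids, n_components=n_pcs)
    gp_full = genotype_pca(g, None, n_components=n_pcs)
    geno = pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(n_pcs)],
            "explained_core": gp_core.explained_fraction[:n_pcs],
            "explained_full": gp_full.explained_fraction[:n_pcs],
        }
    )

    pp_core = phenotype_pca(core_phen)
    pp_full = phenotype_pca(phen)
    sc = pp_core.summary(n_pcs).add_suffix("_core")
    sf_ = pp_full.summary(n_pcs).add_suffix("_full")
    pheno = pd.concat(
        [sf_.rename(columns={"component_full": "component"}), sc.drop(columns="component_core")],
        axis=1,
    )
    return ValidationReport(
        indices=indices,
        traits=traits,
        genotype_pca_explained=geno,
        phenotype_pca=pheno,
    )
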