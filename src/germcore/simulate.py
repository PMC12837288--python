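"""Synthetic clonal, structured germplasm panels with known ground truth.

The simulator emulates the salient features of a clonally propagated
forest-tree germplasm panel:

* K diverged genetic clusters whose allele frequencies follow the
  Balding-Nichols model — per locus an ancestral frequency p is drawn
  uniformly from ``ancestral_maf_range`` and each cluster's frequency from
  Beta(p (1-F)/F, (1-p) (1-F)/F), so Fst to the ancestor is F;
* a small admixed "hybrid" group whose per-accession ancestry weights are
  Dirichlet-distributed over the clusters;
* heavy clonal duplication: a fraction of each cluster's accessions are
  copies of founder genotypes, perturbed by rare somatic mutations;
* heterozygote excess: genotype class probabilities follow the
  inbreeding-coefficient parameterization P(het) = 2pq(1 - f) with f < 0,
  which preserves allele frequencies exactly while inflating Ho above He;
* phenotypes: linear combinations of top genotype principal components
  scaled so genotype explains ``trait_h2`` of each trait's variance.

A single global seed drives a hierarchical random stream (one substream
per stage), so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .io import TRAIT_NAMES, write_groups, write_phenotypes, write_vcf

HYBRID_LABEL = "hybrid"


@dataclass
class SimulationConfig:
    """Parameters of one synthetic germplasm panel.

    Defaults describe a panel with one dominant, heavily clonal cluster
    (about 80% of clustered accessions), two smaller clusters, a 7-member
    hybrid group, and heterozygote excess.  Divergence is asymmetric by
    default — the dominant cluster is the most internally diverse (lowest
    F), the small clusters are tighter and more diverged — mirroring the
    typical structure of clonal germplasm panels where the widespread
    lineage carries the most variation.  Founder inbreeding coefficients
    vary around ``het_excess`` (spread ``het_excess_sd``), mixing strongly
    heterozygous clonal lineages with more homozygous recruits.
    """

    n_clusters: int = 3
    cluster_sizes: tuple[int, ...] = (17, 12, 84)
    n_hybrids: int = 7
    n_loci: int = 1000
    fst_per_cluster: tuple[float, ...] = (0.3, 0.3, 0.12)
    clone_fraction: float | tuple[float, ...] = (0.1, 0.1, 0.7)
    somatic_mutation_rate: float = 1e-3
    het_excess: float = -0.3
    het_excess_sd: float = 0.3
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    dirichlet_alpha: float = 1.0
    n_traits: int = 15
    trait_h2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.cluster_sizes = tuple(int(s) for s in self.cluster_sizes)
        self.fst_per_cluster = tuple(float(f) for f in self.fst_per_cluster)
        if self.n_clusters < 1 or self.n_loci < 1 or self.n_traits < 1:
            raise ValueError("counts must be positive")
        if len(self.cluster_sizes) != self.n_clusters:
            raise ValueError("cluster_sizes length must equal n_clusters")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be positive")
        if len(self.fst_per_cluster) != self.n_clusters:
            raise ValueError("fst_per_cluster length must equal n_clusters")
        if any(not (0.0 < f < 1.0) for f in self.fst_per_cluster):
            raise ValueError("each Fst must lie in the open interval (0, 1)")
        if np.isscalar(self.clone_fraction):
            self.clone_fraction = (float(self.clone_fraction),) * self.n_clusters
        else:
            self.clone_fraction = tuple(float(c) for c in self.clone_fraction)
        if len(self.clone_fraction) != self.n_clusters:
            raise ValueError("clone_fraction length must equal n_clusters")
        if any(not (0.0 <= c < 1.0) for c in self.clone_fraction):
            raise ValueError("clone_fraction values must be in [0, 1)")
        if not (0.0 <= self.somatic_mutation_rate <= 0.01):
            raise ValueError("somatic_mutation_rate must be in [0, 0.01]")
        if not (-1.0 <= self.het_excess <= 0.0):
            raise ValueError("het_excess must be in [-1, 0]")
        if self.het_excess_sd < 0:
            raise ValueError("het_excess_sd must be non-negative")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        if not (0.0 <= self.trait_h2 <= 1.0):
            raise ValueError("trait_h2 must be in [0, 1]")
        if self.n_hybrids < 0:
            raise ValueError("n_hybrids must be non-negative")

    @property
    def cluster_names(self) -> list[str]:
        return [f"G{i + 1}" for i in range(self.n_clusters)]

    def streams(self) -> dict[str, np.random.Generator]:
        """One named substream per simulation stage, all from the one seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ["freqs", "genotypes", "clones", "hybrids", "phenotypes"]
        return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


def paper_like_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A preset with one dominant cluster holding ~80% of clustered accessions.

    Group sample sizes of the motivating system were not published; these
    are plausible values, not a claim about the real panel.
    """
    defaults = dict(cluster_sizes=(17, 12, 84), n_hybrids=7, seed=seed)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the simulator.

    ``table`` has one row per accession: cluster_label (cluster name or
    "hybrid"), one ancestry-proportion column per cluster (rows sum to 1),
    and clone_group (shared by clonal copies of one founder).
    ``trait_effects`` holds the PC weight vector per trait once phenotypes
    have been simulated.
    """

    table: pd.DataFrame = field(repr=False)
    trait_effects: pd.DataFrame | None = field(default=None, repr=False)


# ----------------------------------------------------------------------

def simulate_allele_frequencies(config: SimulationConfig) -> pd.DataFrame:
    """Balding-Nichols cluster allele frequencies.

    Returns a DataFrame with one column per cluster plus 'ancestral';
    all frequencies lie strictly inside (0, 1).
    """
    rng = config.streams()["freqs"]
    lo, hi = config.ancestral_maf_range
    p = rng.uniform(lo, hi, size=config.n_loci)
    out = {"ancestral": p}
    eps = 1e-9
    for name, f in zip(config.cluster_names, config.fst_per_cluster):
        a = p * (1.0 - f) / f
        b = (1.0 - p) * (1.0 - f) / f
        out[name] = np.clip(rng.beta(a, b), eps, 1.0 - eps)
    return pd.DataFrame(out)


def _genotype_probs(p: np.ndarray, f: float | np.ndarray) -> np.ndarray:
    """Genotype class probabilities under a within-individual F.

    P(0) = q^2 + f p q, P(1) = 2 p q (1 - f), P(2) = p^2 + f p q, which
    preserves the allele frequency exactly for any f.  Negative f
    (heterozygote excess) is clamped per locus to the largest magnitude
    keeping every homozygote probability non-negative.  ``f`` may be a
    scalar or a per-individual column vector of shape (n, 1), in which
    case the result is (n, L, 3).
    """
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        f_min = np.maximum(-p / np.maximum(q, 1e-300), -q / np.maximum(p, 1e-300))
    f = np.asarray(f, dtype=float)
    if np.any(f > 1.0) or np.any(f < -1.0):
        raise ValueError("inbreeding coefficients must lie in [-1, 1]")
    f_eff = np.maximum(f, f_min)
    probs = np.stack(
        [q * q + f_eff * p * q, 2.0 * p * q * (1.0 - f_eff), p * p + f_eff * p * q],
        axis=-1,
    )
    probs = np.clip(probs, 0.0, None)
    total = probs.sum(axis=-1, keepdims=True)
    if np.any(np.abs(total - 1.0) > 1e-8):
        raise ValueError("genotype class probabilities do not sum to 1")
    return probs / total


def _draw_genotypes(
    rng: np.random.Generator, p: np.ndarray, f: float | np.ndarray, n: int
) -> np.ndarray:
    """n diploid dosage rows at loci with alt frequency p and inbreeding f.

    ``f`` is a scalar shared by all individuals or an (n,)-vector of
    per-individual inbreeding coefficients.
    """
    f = np.asarray(f, dtype=float)
    if f.ndim == 1:
        if len(f) != n:
            raise ValueError("need one inbreeding coefficient per individual")
        probs = _genotype_probs(p, f[:, None])  # (n, L, 3)
        cum = np.cumsum(probs, axis=-1)
        u = rng.random((n, len(p)))
        return (u[..., None] > cum[..., :-1]).sum(axis=-1).astype(np.int8)
    probs = _genotype_probs(p, float(f))  # (L, 3)
    cum = np.cumsum(probs, axis=-1)
    u = rng.random((n, len(p)))
    return (u[..., None] > cum[None, :, :-1]).sum(axis=-1).astype(np.int8)


def _founder_inbreeding(
    rng: np.random.Generator, config: SimulationConfig, n: int
) -> np.ndarray:
    """Per-founder inbreeding coefficients around the panel mean.

    Real clonal panels mix ancient clonal lineages (strong heterozygote
    excess) with sexually recruited or partially inbred individuals
    (f near or above zero); ``het_excess_sd`` controls that spread.
    """
    if config.het_excess_sd == 0:
        return np.full(n, config.het_excess)
    f = rng.normal(config.het_excess, config.het_excess_sd, size=n)
    return np.clip(f, -1.0, 1.0)


def simulate_genotypes(
    freqs: pd.DataFrame, config: SimulationConfig
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Draw founder, clonal-copy and hybrid genotypes plus truth labels."""
    streams = config.streams()
    rng_g = streams["genotypes"]
    rng_c = streams["clones"]
    rng_h = streams["hybrids"]
    k = config.n_clusters
    rows: list[np.ndarray] = []
    ids: list[str] = []
    labels: list[str] = []
    ancestry: list[np.ndarray] = []
    clone_groups: list[str] = []

    for ci, (name, size) in enumerate(zip(config.cluster_names, config.cluster_sizes)):
        p = freqs[name].to_numpy()
        n_copies = int(round(config.clone_fraction[ci] * size))
        n_copies = min(n_copies, size - 1)  # at least one founder
        n_founders = size - n_copies
        f_ind = _founder_inbreeding(rng_g, config, n_founders)
        founders = _draw_genotypes(rng_g, p, f_ind, n_founders)
        founder_ids = [f"{name}_{i + 1:03d}" for i in range(n_founders)]
        for fid, row in zip(founder_ids, founders):
            rows.append(row)
            ids.append(fid)
            labels.append(name)
            onehot = np.zeros(k)
            onehot[ci] = 1.0
            ancestry.append(onehot)
            clone_groups.append(fid)
        # clonal copies: duplicate a random founder, then rare somatic flips
        src = rng_c.integers(0, n_founders, size=n_copies)
        for j, s in enumerate(src):
            row = founders[s].copy()
            if config.somatic_mutation_rate > 0:
                flip = rng_c.random(config.n_loci) < config.somatic_mutation_rate
                n_flip = int(flip.sum())
                if n_flip:
                    # move to a different dosage class, uniformly
                    cur = row[flip].astype(np.int64)
                    shift = rng_c.integers(1, 3, size=n_flip)
                    row[flip] = ((cur + shift) % 3).astype(np.int8)
            rows.append(row)
            ids.append(f"{name}_c{j + 1:03d}")
            labels.append(name)
            onehot = np.zeros(k)
            onehot[ci] = 1.0
            ancestry.append(onehot)
            clone_groups.append(founder_ids[s])

    cluster_freqs = freqs[config.cluster_names].to_numpy()  # (L, K)
    for h in range(config.n_hybrids):
        w = rng_h.dirichlet(np.full(k, config.dirichlet_alpha))
        p_h = cluster_freqs @ w
        f_h = _founder_inbreeding(rng_h, config, 1)
        row = _draw_genotypes(rng_h, p_h, f_h, 1)[0]
        hid = f"H_{h + 1:02d}"
        rows.append(row)
        ids.append(hid)
        labels.append(HYBRID_LABEL)
        ancestry.append(w)
        clone_groups.append(hid)

    loci = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, config.n_loci + 1) * 100,
            "ref": "A",
            "alt": "T",
            "maf": np.nan,
            "missing_rate": np.nan,
        }
    )
    g = GenotypeMatrix(accession_ids=ids, loci=loci, dosage=np.stack(rows))
    anc = np.stack(ancestry)
    table = pd.DataFrame(
        {
            "cluster_label": labels,
            **{
                f"ancestry_{n}": anc[:, i]
                for i, n in enumerate(config.cluster_names)
            },
            "clone_group": clone_groups,
        },
        index=pd.Index(ids, name="accession"),
    )
    return g, SyntheticTruth(table=table)


def simulate_phenotypes(
    g: GenotypeMatrix,
    config: SimulationConfig,
    truth: SyntheticTruth | None = None,
) -> pd.DataFrame:
    """Traits as PC combinations explaining ``trait_h2`` of variance.

    Each trait is sqrt(h2) * z + sqrt(1-h2) * noise + 10, where z is a
    standardized random linear combination of the top genotype principal
    components; the offset keeps trait means away from zero so coefficients
    of variation are well defined.  Trait columns are the 15 standard
    abbreviations (or PC-named extras beyond 15).
    """
    from .metrics import genotype_pca  # local import to avoid a cycle

    rng = config.streams()["phenotypes"]
    n = g.n_accessions
    n_pcs = min(5, n - 1, g.n_loci)
    pca = genotype_pca(g, n_components=n_pcs)
    scores = pca.scores
    scores = (scores - scores.mean(axis=0)) / np.where(
        scores.std(axis=0) > 0, scores.std(axis=0), 1.0
    )
    names = TRAIT_NAMES[: config.n_traits]
    if config.n_traits > len(TRAIT_NAMES):
        names = TRAIT_NAMES + [
            f"T{i + 1}" for i in range(config.n_traits - len(TRAIT_NAMES))
        ]
    h2 = config.trait_h2
    effects = rng.normal(size=(n_pcs, config.n_traits))
    data = {}
    for t, name in enumerate(names):
        z = scores @ effects[:, t]
        sd = z.std()
        z = z / sd if sd > 0 else z
        noise = rng.normal(size=n)
        data[name] = 10.0 + np.sqrt(h2) * z + np.sqrt(1.0 - h2) * noise
    phen = pd.DataFrame(data, index=pd.Index(g.accession_ids, name="accession"))
    if truth is not None:
        truth.trait_effects = pd.DataFrame(
            effects,
            index=[f"PC{i + 1}" for i in range(n_pcs)],
            columns=names,
        )
    return phen


def simulate_panel(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, SyntheticTruth]:
    """Convenience wrapper: frequencies -> genotypes -> phenotypes."""
    freqs = simulate_allele_frequencies(config)
    g, truth = simulate_genotypes(freqs, config)
    phen = simulate_phenotypes(g, config, truth)
    return g, phen, truth


def write_dataset(
    g: GenotypeMatrix,
    phen: pd.DataFrame,
    truth: SyntheticTruth,
    out_dir: str | os.PathLike,
) -> dict[str, Path]:
    """Write VCF, phenotype CSV, group TSV and truth TSV to a directory."""
    ids = list(g.accession_ids)
    if list(phen.index) != ids or list(truth.table.index) != ids:
        raise ValueError("accession ids differ between genotypes, phenotypes and truth")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "panel.vcf",
        "phenotypes": out / "phenotypes.csv",
        "groups": out / "groups.tsv",
        "truth": out / "truth.tsv",
    }
    write_vcf(g, paths["vcf"])
    write_phenotypes(phen, paths["phenotypes"])
    write_groups(truth.table["cluster_label"], paths["groups"])
    truth.table.to_csv(paths["truth"], sep="\t")
    return paths


def config_from_file(path: str | os.PathLike) -> SimulationConfig:
    """Load a SimulationConfig from a JSON or YAML mapping."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return SimulationConfig(**raw)
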