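"""Simulator: divergence model, clonality, heterozygote excess, phenotypes."""

import numpy as np
import pytest

from germcore.genotypes import allele_frequencies
from germcore.metrics import diversity_report, hudson_fst, mr_distance_matrix
from germcore.simulate import (
    SimulationConfig,
    simulate_allele_frequencies,
    simulate_genotypes,
    simulate_panel,
    simulate_phenotypes,
    write_dataset,
)
from germcore.io import read_vcf, read_groups, read_phenotypes


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_clusters=2, cluster_sizes=(10,))
    with pytest.raises(ValueError):
        SimulationConfig(fst_per_cluster=(0.0, 0.3, 0.3))
    with pytest.raises(ValueError):
        SimulationConfig(het_excess=0.5)
    with pytest.raises(ValueError):
        SimulationConfig(ancestral_maf_range=(0.0, 0.5))


def test_balding_nichols_low_f_concentrates_on_ancestral():
    """F -> 0 limit: cluster frequencies converge to the ancestral p."""
    cfg = SimulationConfig(
        n_clusters=1, cluster_sizes=(5,), fst_per_cluster=(1e-4,), n_loci=2000,
        clone_fraction=0.0, n_hybrids=0, seed=1,
    )
    freqs = simulate_allele_frequencies(cfg)
    assert np.max(np.abs(freqs["G1"] - freqs["ancestral"])) < 0.05


def test_balding_nichols_variance_matches_closed_form():
    """At fixed p the Beta draw has variance F p (1 - p)."""
    f, p = 0.2, 0.3
    rng = np.random.default_rng(0)
    draws = rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f, size=10_000)
    expected = f * p * (1 - p)  # 0.042
    # same model as the simulator: check the simulator draws agree too
    cfg = SimulationConfig(
        n_clusters=1, cluster_sizes=(5,), fst_per_cluster=(f,), n_loci=10_000,
        ancestral_maf_range=(p, p), clone_fraction=0.0, n_hybrids=0, seed=2,
    )
    freqs = simulate_allele_frequencies(cfg)
    for sample in (draws, freqs["G1"].to_numpy()):
        assert abs(sample.var() - expected) < 0.1 * expected


def test_two_cluster_fst_recovered():
    """Hudson Fst estimated from simulated genotypes is close to the F used."""
    cfg = SimulationConfig(
        n_clusters=2, cluster_sizes=(100, 100), fst_per_cluster=(0.5, 0.5),
        n_hybrids=0, n_loci=2000, clone_fraction=0.0, seed=3,
    )
    g, _, truth = simulate_panel(cfg)
    lab = truth.table["cluster_label"]
    fst = hudson_fst(g, list(lab.index[lab == "G1"]), list(lab.index[lab == "G2"]))
    assert abs(fst - 0.5) < 0.1


def test_het_excess_zero_gives_hardy_weinberg():
    cfg = SimulationConfig(
        het_excess=0.0, het_excess_sd=0.0, clone_fraction=0.0, n_hybrids=0,
        n_clusters=1, cluster_sizes=(300,), fst_per_cluster=(0.1,), n_loci=2000,
        seed=4,
    )
    g, _, _ = simulate_panel(cfg)
    rep = diversity_report(g)
    assert abs(rep.ho - rep.he) < 0.01


def test_het_excess_negative_inflates_ho_over_he():
    wins = 0
    for seed in range(5):
        cfg = SimulationConfig(seed=seed, n_loci=400, het_excess=-0.3)
        g, _, _ = simulate_panel(cfg)
        rep = diversity_report(g)
        wins += rep.ho > rep.he
    assert wins == 5


def test_allele_frequencies_preserved_by_het_excess():
    """The inbreeding parameterization leaves allele frequencies at p."""
    p = 0.4
    cfg = SimulationConfig(
        n_clusters=1, cluster_sizes=(2000,), fst_per_cluster=(1e-4,),
        ancestral_maf_range=(p, p), het_excess=-0.5, het_excess_sd=0.0,
        clone_fraction=0.0, n_hybrids=0, n_loci=50, seed=5,
    )
    g, _, _ = simulate_panel(cfg)
    freq = allele_frequencies(g)
    assert abs(freq.mean() - p) < 0.01


def test_clones_identical_without_somatic_mutation():
    cfg = SimulationConfig(somatic_mutation_rate=0.0, seed=6, n_loci=200)
    g, _, truth = simulate_panel(cfg)
    d = mr_distance_matrix(g)
    tab = truth.table
    pos = {a: i for i, a in enumerate(g.accession_ids)}
    n_pairs = 0
    for _, members in tab.groupby("clone_group").groups.items():
        members = list(members)
        for a in members[1:]:
            assert d.values[pos[members[0]], pos[a]] == 0.0
            n_pairs += 1
    assert n_pairs > 0
    # distinct genotype rows = clone groups (copies collapse onto founders)
    distinct = len({row.tobytes() for row in g.dosage})
    assert distinct == tab["clone_group"].nunique()


def test_somatic_mutations_stay_rare():
    rate = 0.005
    cfg = SimulationConfig(somatic_mutation_rate=rate, seed=7, n_loci=2000)
    g, _, truth = simulate_panel(cfg)
    tab = truth.table
    pos = {a: i for i, a in enumerate(g.accession_ids)}
    diffs = []
    for founder, members in tab.groupby("clone_group").groups.items():
        members = list(members)
        for a in members:
            if a != founder:
                diffs.append((g.dosage[pos[a]] != g.dosage[pos[founder]]).mean())
    assert diffs and np.mean(diffs) < 3 * rate


def test_ancestry_simplex_and_labels():
    cfg = SimulationConfig(seed=8, n_loci=50)
    _, _, truth = simulate_panel(cfg)
    anc = truth.table[[c for c in truth.table.columns if c.startswith("ancestry_")]]
    assert np.allclose(anc.sum(axis=1), 1.0, atol=1e-12)
    labels = set(truth.table["cluster_label"])
    assert labels == {"G1", "G2", "G3", "hybrid"}
    assert (truth.table["cluster_label"] == "hybrid").sum() == cfg.n_hybrids


@pytest.mark.parametrize("h2", [0.0, 1.0])
def test_phenotype_h2_extremes(h2):
    """h2=0: traits are pure noise w.r.t. the PCs; h2=1: perfectly collinear."""
    cfg = SimulationConfig(
        seed=9, n_loci=300, trait_h2=h2,
        cluster_sizes=(60, 40, 300), n_hybrids=0,
    )
    g, truth = simulate_genotypes(simulate_allele_frequencies(cfg), cfg)
    phen = simulate_phenotypes(g, cfg, truth)
    from germcore.metrics import genotype_pca

    pcs = genotype_pca(g, n_components=5).scores
    for t in phen.columns:
        y = phen[t].to_numpy()
        if h2 == 0.0:
            # per-PC correlations consistent with pure noise at n=400
            r = [abs(np.corrcoef(y, pcs[:, j])[0, 1]) for j in range(pcs.shape[1])]
            assert max(r) < 0.15
        else:
            r = np.sqrt(max(_r2_on_pcs(y, pcs), 0.0))
            assert r > 0.999


def _r2_on_pcs(y, pcs):
    x = np.column_stack([np.ones(len(y)), pcs])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return 1.0 - resid.var() / y.var()


def test_phenotype_h2_intermediate():
    """Realized R^2 of traits on the generating PCs is near trait_h2."""
    r2s = []
    for seed in range(5):
        cfg = SimulationConfig(
            seed=seed, n_loci=300, trait_h2=0.5, cluster_sizes=(60, 40, 300),
            n_hybrids=0,
        )
        g, truth = simulate_genotypes(simulate_allele_frequencies(cfg), cfg)
        phen = simulate_phenotypes(g, cfg, truth)
        from germcore.metrics import genotype_pca

        pcs = genotype_pca(g, n_components=5).scores
        r2s.extend(_r2_on_pcs(phen[t].to_numpy(), pcs) for t in phen.columns)
    assert 0.35 <= float(np.median(r2s)) <= 0.65


def test_write_dataset_round_trip(tmp_path):
    cfg = SimulationConfig(seed=10, n_loci=40)
    g, phen, truth = simulate_panel(cfg)
    # plant one missing call to check the sentinel round-trips
    g.dosage[0, 0] = -1
    paths = write_dataset(g, phen, truth, tmp_path)
    g2 = read_vcf(paths["vcf"])
    assert g2.accession_ids == g.accession_ids
    assert np.array_equal(g2.dosage, g.dosage)
    assert g2.dosage[0, 0] == -1
    phen2 = read_phenotypes(paths["phenotypes"])
    assert np.allclose(phen2.to_numpy(), phen.to_numpy())
    groups = read_groups(paths["groups"])
    assert (groups == truth.table["cluster_label"]).all()


def test_same_seed_byte_identical(tmp_path):
    cfg = SimulationConfig(seed=11, n_loci=60)
    for d in ("a", "b"):
        g, phen, truth = simulate_panel(cfg)
        write_dataset(g, phen, truth, tmp_path / d)
    for name in ("panel.vcf", "phenotypes.csv", "groups.tsv", "truth.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
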