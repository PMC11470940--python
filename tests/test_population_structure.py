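"""WC84 components vs a scalar oracle, Fst recovery, PCA, local PCA/MDS."""

import itertools

import numpy as np
import pandas as pd
import pytest

from baokit import synthetic_data as sd
from baokit.population_structure import (GenotypeMatrix, classical_mds, genotype_pca,
                                         high_fst_loci, local_pca_partition,
                                         wc84_components, weighted_fst)


def _geno(dosages, pops, ploidy=2, pos=None):
    dosages = np.asarray(dosages)
    n, m = dosages.shape
    return GenotypeMatrix(
        dosages=dosages,
        samples=[f"s{i}" for i in range(n)],
        ploidy=np.full(n, ploidy),
        populations=np.asarray(pops),
        chrom=np.array(["1"] * m),
        pos=np.arange(1, m + 1) * 10 if pos is None else np.asarray(pos),
    )


# ------------------------------------------------------------ WC84 components

def _oracle_abc(genos_by_pop):
    """Scalar implementation of the published WC84 variance components for
    one biallelic locus from diploid genotype lists."""
    r = len(genos_by_pop)
    n = [len(g) for g in genos_by_pop]
    p = [sum(g) / (2 * len(g)) for g in genos_by_pop]
    h = [sum(1 for x in g if x == 1) / len(g) for g in genos_by_pop]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def test_wc84_matches_scalar_oracle_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(100):
        r = int(rng.integers(2, 4))
        genos = [list(rng.integers(0, 3, int(rng.integers(2, 11)))) for _ in range(r)]
        if all(len(set(g)) == 1 for g in genos):
            genos[0][0] = (genos[0][0] + 1) % 3
        freqs = np.array([[sum(g) / (2 * len(g))] for g in genos])
        hets = np.array([[np.mean([x == 1 for x in g])] for g in genos])
        sizes = np.array([[float(len(g))] for g in genos])
        a, b, c = wc84_components(hets, freqs, sizes)
        ea, eb, ec = _oracle_abc(genos)
        assert a[0] == pytest.approx(ea, abs=1e-12)
        assert b[0] == pytest.approx(eb, abs=1e-12)
        assert c[0] == pytest.approx(ec, abs=1e-12)


def test_two_deme_textbook_case():
    """Frequencies 0.8 vs 0.2 in demes of 5 with HWE heterozygosity gives
    a = 0.16, b = 0.02, c = 0.16, Fst ~ 0.471."""
    a, b, c = wc84_components(np.array([[0.32], [0.32]]), np.array([[0.8], [0.2]]),
                              np.array([[5.0], [5.0]]))
    assert a[0] == pytest.approx(0.16, abs=1e-12)
    assert b[0] == pytest.approx(0.02, abs=1e-12)
    assert c[0] == pytest.approx(0.16, abs=1e-12)
    assert a[0] / (a[0] + b[0] + c[0]) == pytest.approx(0.471, abs=5e-4)


# ------------------------------------------------------------------- weighted

def test_null_case_fst_near_zero():
    """One panmictic population split arbitrarily in two: Fst ~ 0."""
    geno, _ = sd.sim_genotypes_bn(1, 100, 1000, 0.2, seed=1)
    pops = np.array(["A"] * 50 + ["B"] * 50)
    g = _geno(geno.dosages, pops)
    res = weighted_fst(g, "A", "B")
    assert abs(res.weighted_fst) <= 0.02


def test_balding_nichols_recovery():
    geno, truth = sd.sim_genotypes_bn(2, 30, 2000, 0.2, seed=2)
    res = weighted_fst(geno, "pop1", "pop2")
    assert res.weighted_fst == pytest.approx(0.2, abs=0.05)


def test_hudson_mode_agrees_on_diploids():
    geno, _ = sd.sim_genotypes_bn(2, 30, 2000, 0.3, seed=3)
    wc = weighted_fst(geno, "pop1", "pop2").weighted_fst
    hu = weighted_fst(geno, "pop1", "pop2", mode="hudson").weighted_fst
    assert hu == pytest.approx(wc, abs=0.03)


def test_tetraploid_genotypes_supported_in_both_modes():
    geno, _ = sd.sim_genotypes_bn(2, 30, 2000, 0.2, ploidy=4, seed=4)
    for mode in ("wc84", "hudson"):
        res = weighted_fst(geno, "pop1", "pop2", mode=mode)
        assert res.weighted_fst == pytest.approx(0.2, abs=0.07)


def test_monomorphic_input_is_flagged_undefined():
    g = _geno(np.zeros((8, 10), dtype=int), ["A"] * 4 + ["B"] * 4)
    res = weighted_fst(g, "A", "B")
    assert res.undefined and np.isnan(res.weighted_fst)
    assert res.n_excluded == 10


def test_single_sample_population_rejected():
    g = _geno(np.zeros((3, 5), dtype=int), ["A", "B", "B"])
    with pytest.raises(ValueError, match="at least 2"):
        weighted_fst(g, "A", "B")


# ------------------------------------------------------------- high-Fst loci

def test_planted_fixed_locus_is_the_only_high_fst_hit():
    rng = np.random.default_rng(5)
    dos = rng.binomial(2, 0.5, size=(20, 50))
    dos[:10, 7] = 2  # fixed difference at locus 7
    dos[10:, 7] = 0
    g = _geno(dos, ["A"] * 10 + ["B"] * 10)
    res = weighted_fst(g, "A", "B")
    hits = high_fst_loci(res, 0.8)
    assert list(hits["locus_index"]) == [7]


def test_high_fst_thresholds():
    geno, _ = sd.sim_genotypes_bn(2, 20, 200, 0.2, seed=6)
    res = weighted_fst(geno, "pop1", "pop2")
    defined = int(np.isfinite(res.per_locus_fst).sum())
    assert len(high_fst_loci(res, threshold=-1.1)) == defined
    null_geno, _ = sd.sim_genotypes_bn(1, 40, 200, 0.2, seed=7)
    g = _geno(null_geno.dosages, ["A"] * 20 + ["B"] * 20)
    assert len(high_fst_loci(weighted_fst(g, "A", "B"), 0.8)) == 0


# ------------------------------------------------------------------------ PCA

def test_two_identical_groups_separate_on_pc1():
    row_a = np.tile([0, 2, 1, 0, 2], 10)
    row_b = np.tile([2, 0, 1, 2, 0], 10)
    dos = np.vstack([np.tile(row_a, (4, 1)), np.tile(row_b, (4, 1))])
    g = _geno(dos, ["A"] * 4 + ["B"] * 4)
    coords, varfrac, _ = genotype_pca(g, 3)
    assert varfrac[0] == pytest.approx(1.0)
    assert (coords[:4, 0] > 0).all() != (coords[4:, 0] > 0).all()


def test_three_populations_recovered_by_clustering():
    from sklearn.cluster import KMeans

    geno, _ = sd.sim_genotypes_bn(3, 20, 2000, 0.3, seed=8)
    coords, varfrac, _ = genotype_pca(geno, 4)
    labels = KMeans(3, n_init=10, random_state=0).fit_predict(coords[:, :2])
    agree = pd.crosstab(labels, geno.populations).max(axis=1).sum() / 60
    assert agree >= 0.95
    assert varfrac.sum() <= 1.0 + 1e-9


def test_pca_is_invariant_to_locus_order():
    geno, _ = sd.sim_genotypes_bn(2, 10, 300, 0.2, seed=9)
    coords1, _, _ = genotype_pca(geno, 3)
    rng = np.random.default_rng(0)
    perm = rng.permutation(geno.n_loci)
    g2 = _geno(geno.dosages[:, perm], geno.populations)
    coords2, _, _ = genotype_pca(g2, 3)
    for j in range(coords1.shape[1]):
        assert (np.allclose(coords1[:, j], coords2[:, j], atol=1e-8)
                or np.allclose(coords1[:, j], -coords2[:, j], atol=1e-8))


def test_pca_rejects_single_sample():
    g = _geno(np.zeros((1, 10), dtype=int), ["A"])
    with pytest.raises(ValueError, match="2 samples"):
        genotype_pca(g)


# ------------------------------------------------------------------ local PCA

def test_identical_windows_have_zero_distance():
    rng = np.random.default_rng(10)
    block = rng.binomial(2, 0.4, size=(12, 30))
    dos = np.hstack([block, block])
    g = _geno(dos, ["A"] * 6 + ["B"] * 6)
    part = local_pca_partition(g, window_bp=300)
    assert part.distances.shape == (2, 2)
    assert part.distances[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_planted_permuted_windows_form_one_outlier_cluster():
    base, _ = sd.sim_genotypes_bn(2, 15, 3000, 0.1, seed=4, locus_spacing_bp=50)
    dos = base.dosages.copy()
    rng = np.random.default_rng(5)
    perm = rng.permutation(30)
    planted = (10, 11, 12)
    for w in planted:
        dos[:, w * 60 : (w + 1) * 60] = dos[perm, w * 60 : (w + 1) * 60]
    g = _geno(dos, base.populations, pos=base.pos)
    part = local_pca_partition(g, window_bp=3000)
    labels = part.windows["label"].to_numpy()
    assert set(np.flatnonzero(labels != "none")) == set(planted)
    assert len(set(labels[list(planted)])) == 1


def test_mds_of_equidistant_windows_is_equilateral():
    d = np.ones((3, 3)) - np.eye(3)
    coords = classical_mds(d, 2)
    dists = [np.linalg.norm(coords[i] - coords[j])
             for i, j in itertools.combinations(range(3), 2)]
    assert np.allclose(dists, dists[0])
    assert dists[0] == pytest.approx(1.0, abs=1e-9)


def test_mds_preserves_planar_configurations():
    rng = np.random.default_rng(13)
    pts = rng.normal(size=(12, 2))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    coords = classical_mds(d, 2)
    d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    iu = np.triu_indices(12, 1)
    corr = np.corrcoef(d[iu], d2[iu])[0, 1]
    assert corr >= 0.99


def test_windows_with_too_few_polymorphic_loci_are_skipped():
    dos = np.zeros((10, 40), dtype=int)
    dos[:, 25:] = np.random.default_rng(14).binomial(2, 0.5, size=(10, 15))
    g = _geno(dos, ["A"] * 5 + ["B"] * 5)
    # loci at 10 bp spacing: the first all-monomorphic windows are skipped
    part = local_pca_partition(g, window_bp=100)
    assert part.skipped_windows >= 1
    assert len(part.windows) >= 2
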