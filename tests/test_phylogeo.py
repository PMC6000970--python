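"""Mantel, local spatial autocorrelation, UPGMA bootstrap, divergence dating."""

import numpy as np
import pytest

from pvpopgen._util import haversine_km
from pvpopgen.phylogeo import (cophenetic_from_linkage, divergence_time,
                               genotype_sequences, group_divergence,
                               local_spatial_autocorrelation, lsa_sweep,
                               mantel, p_distance_matrix, upgma_bootstrap,
                               upgma_tree)


def _euclid(pts):
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0)
    return d


class TestMantel:
    def test_identity_r_one_min_p(self):
        rng = np.random.default_rng(0)
        d = _euclid(rng.random((10, 2)))
        res = mantel(d, d.copy(), n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        a = _euclid(rng.random((12, 2)))
        b = _euclid(rng.random((12, 2)))
        assert mantel(a, b, n_perm=0).r == pytest.approx(mantel(b, a, n_perm=0).r)

    def test_matches_reference_implementation(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as sk_mantel

        rng = np.random.default_rng(2)
        x = rng.random((12, 2))
        a, b = _euclid(x), _euclid(x + rng.normal(0, 0.2, x.shape))
        mine = mantel(a, b, n_perm=0)
        r_ref, _, _ = sk_mantel(DistanceMatrix(a), DistanceMatrix(b),
                                permutations=0)
        assert mine.r == pytest.approx(r_ref)

    def test_constant_matrix_is_error(self):
        with pytest.raises(ValueError):
            mantel(np.ones((4, 4)) - np.eye(4), np.ones((4, 4)) - np.eye(4),
                   n_perm=0)

    def test_planted_isolation_by_distance(self):
        """Spatially autocorrelated genetic distance yields significant
        positive Mantel r."""
        rng = np.random.default_rng(3)
        pts = rng.random((30, 2)) * 10
        geo = _euclid(pts)
        gen = geo * 0.1 + _euclid(rng.random((30, 2)))
        res = mantel(gen, geo, n_perm=199, seed=4)
        assert res.r > 0.3
        assert res.p <= 0.05


class TestLsa:
    def test_clone_clusters_consistently_significant(self):
        rng = np.random.default_rng(0)
        n_clone, n_bg = 8, 24
        lat = np.concatenate([np.full(n_clone, 35.0) + rng.normal(0, 0.01, n_clone),
                              rng.uniform(25, 45, n_bg)])
        lon = np.concatenate([np.full(n_clone, -90.0) + rng.normal(0, 0.01, n_clone),
                              rng.uniform(-105, -75, n_bg)])
        # clones genetically identical, background random
        g = rng.random((n_clone + n_bg, n_clone + n_bg))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0)
        g[:n_clone, :n_clone] = 0.01
        np.fill_diagonal(g, 0)
        _, consistent = lsa_sweep(g, lat, lon, n_min=5, n_max=7, n_perm=199,
                                  seed=1)
        assert consistent[:n_clone].all()

    def test_null_rejection_rate_near_alpha(self):
        """Random geography: ~5% of individuals significant at alpha=0.05."""
        rng = np.random.default_rng(1)
        rates = []
        for rep in range(15):
            n = 40
            lat = rng.uniform(25, 45, n)
            lon = rng.uniform(-105, -75, n)
            g = rng.random((n, n))
            g = (g + g.T) / 2
            np.fill_diagonal(g, 0)
            res = local_spatial_autocorrelation(g, lat, lon, n_neighbors=8,
                                                n_perm=199, seed=100 + rep)
            rates.append((res.p <= 0.05).mean())
        assert 0.01 <= np.mean(rates) <= 0.10

    def test_sweep_covers_range_and_requires_all(self):
        rng = np.random.default_rng(2)
        n = 20
        lat, lon = rng.uniform(30, 40, n), rng.uniform(-100, -90, n)
        g = rng.random((n, n))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0)
        results, consistent = lsa_sweep(g, lat, lon, n_min=7, n_max=14,
                                        n_perm=49, seed=3)
        assert [r.n_neighbors for r in results] == list(range(7, 15))
        sig = np.vstack([r.p <= 0.05 for r in results])
        assert np.array_equal(consistent, sig.all(axis=0))

    def test_neighbor_count_bounds(self):
        with pytest.raises(ValueError):
            local_spatial_autocorrelation(np.zeros((5, 5)), np.zeros(5),
                                          np.zeros(5), n_neighbors=5, n_perm=9)


class TestUpgma:
    def test_three_taxon_worked_example(self):
        """d(A,B)=2, d(A,C)=d(B,C)=4 -> ((A,B),C) with heights 1 and 2."""
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        _, clades = upgma_tree(d, ["A", "B", "C"])
        assert clades[frozenset({"A", "B"})] == pytest.approx(1.0)
        assert clades[frozenset({"A", "B", "C"})] == pytest.approx(2.0)

    def test_ultrametric_and_cophenetic_bound(self):
        rng = np.random.default_rng(0)
        pts = rng.random((8, 3))
        d = _euclid(pts)
        Z, _ = upgma_tree(d, [f"t{i}" for i in range(8)])
        coph = cophenetic_from_linkage(Z)
        offdiag = coph[np.triu_indices(8, 1)]
        assert offdiag.min() >= d[np.triu_indices(8, 1)].min() - 1e-9
        # ultrametric: three-point condition on cophenetic distances
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    m = sorted([coph[i, j], coph[i, k], coph[j, k]])
                    assert m[1] == pytest.approx(m[2])

    def test_planted_clades_high_support(self):
        """Three well-separated planted clades are recovered with >= 95%
        bootstrap support."""
        rng = np.random.default_rng(1)
        base = {c: "".join(rng.choice(list("ACGT"), 120)) for c in "XYZ"}

        def mutate(s, k):
            s = list(s)
            for i in rng.choice(len(s), k, replace=False):
                s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
            return "".join(s)

        seqs, labels = [], []
        for c in "XYZ":
            for r in range(4):
                seqs.append(mutate(base[c], 2))
                labels.append(f"{c}{r}")
        tree = upgma_bootstrap(seqs, labels, n_boot=100, seed=2)
        for c in "XYZ":
            clade = frozenset(l for l in labels if l.startswith(c))
            assert tree.supports.get(clade, 0.0) >= 95.0

    def test_newick_parses_with_reference_library(self):
        import dendropy

        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        tree = upgma_bootstrap(["AAAA", "AAAT", "TTTT"], ["A", "B", "C"],
                               n_boot=10, seed=0)
        t = dendropy.Tree.get(data=tree.newick, schema="newick")
        assert {l.taxon.label for l in t.leaf_node_iter()} == {"A", "B", "C"}

    def test_too_few_sequences_is_error(self):
        with pytest.raises(ValueError):
            upgma_bootstrap(["AA", "AT"], ["A", "B"], n_boot=5)


class TestPDistance:
    def test_fractional_ambiguity(self):
        d = p_distance_matrix(["AR", "AA", "AG"])
        # R vs A and R vs G each differ by 0.5 at one of two sites
        assert d[0, 1] == pytest.approx(0.25)
        assert d[0, 2] == pytest.approx(0.25)
        assert d[1, 2] == pytest.approx(0.5)

    def test_n_sites_excluded_pairwise(self):
        d = p_distance_matrix(["AN", "AT", "AA"])
        assert d[0, 1] == pytest.approx(0.0)   # only site 1 shared
        assert d[1, 2] == pytest.approx(0.5)


class TestDivergence:
    def test_half_distance_identity(self):
        est = divergence_time(0.05, 0.10, calibration_mya=13.0)
        assert est.t_mya == pytest.approx(6.5)

    def test_identical_groups_zero(self):
        assert divergence_time(0.0, 0.1).t_mya == 0.0

    def test_scale_invariance(self):
        t1 = divergence_time(0.03, 0.12).t_mya
        t2 = divergence_time(0.03 * 7.3, 0.12 * 7.3).t_mya
        assert t1 == pytest.approx(t2)

    def test_zero_outgroup_distance_is_error(self):
        with pytest.raises(ValueError):
            divergence_time(0.1, 0.0)

    def test_mutation_clock_simulation(self):
        """True split at 0.2x the outgroup split dates to 2.6 +- 0.3 Mya."""
        rng = np.random.default_rng(0)
        L = 4000
        anc = rng.choice(list("ACGT"), L)

        def evolve(seq, rate):
            seq = seq.copy()
            hits = rng.random(L) < rate
            for i in np.flatnonzero(hits):
                seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
            return seq

        out = evolve(anc, 0.10)          # outgroup split
        mid = evolve(anc, 0.08)          # ingroup ancestor
        a = evolve(mid, 0.02)            # the two groups split at 0.2x depth
        b = evolve(mid, 0.02)
        seqs = ["".join(s) for s in (a, b, out)]
        d = p_distance_matrix(seqs)
        labels = np.array(["ga", "gb", "out"])
        est = group_divergence(d, labels, "ga", "gb", outgroup_label="out",
                               calibration_mya=13.0)
        assert est.t_mya == pytest.approx(2.6, abs=0.3)

    def test_group_divergence_symmetry(self):
        rng = np.random.default_rng(1)
        d = _euclid(rng.random((6, 2)))
        labels = np.array(["a", "a", "b", "b", "o", "o"])
        t1 = group_divergence(d, labels, "a", "b", outgroup_label="o").t_mya
        t2 = group_divergence(d, labels, "b", "a", outgroup_label="o").t_mya
        assert t1 == pytest.approx(t2)


def test_genotype_sequences_iupac(small_sim):
    ds, _, _ = small_sim
    from pvpopgen.filtering import call_genotype_states

    called = call_genotype_states(ds)
    seqs = genotype_sequences(called)
    assert len(seqs) == ds.n_samples
    assert len(seqs[0]) == ds.n_loci
    allowed = set("ACGTRYSWKMN")
    assert set("".join(seqs)) <= allowed


def test_haversine_known_distance():
    # one degree of latitude is ~111 km
    d = haversine_km(np.array([30.0, 31.0]), np.array([-90.0, -90.0]))
    assert d[0, 1] == pytest.approx(111.19, abs=0.5)
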