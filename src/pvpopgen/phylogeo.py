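"""Spatial genetics and calibrated divergence dating.

* Mantel correlation between genetic and geographic distance matrices with
  joint row/column permutation.
* 2D local spatial autocorrelation (per-individual mean genetic similarity
  to the n nearest geographic neighbours, one-tailed permutation test,
  consistency across a neighbour sweep).
* UPGMA trees on concatenated per-genotype sequences (IUPAC ambiguity codes
  at heterozygous sites, fractional ambiguity matching) with column
  bootstrap supports.
* Relative divergence dating against an outgroup calibration (default
  13 Mya to foxtail millet).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from ._util import as_rng, check_square_symmetric, haversine_km, offdiag

log = logging.getLogger("pvpopgen")

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
_BASES = "ACGT"


# -- Mantel -------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


def mantel(dist_a: np.ndarray, dist_b: np.ndarray, n_perm: int = 999,
           seed=0, log_b: bool = False) -> MantelResult:
    """Mantel correlation of two distance matrices.

    r is the Pearson correlation of the off-diagonal entries; p comes from
    jointly permuting rows and columns of the second matrix (one-tailed on
    the observed sign side for positive r, standard IBD usage).
    """
    a = check_square_symmetric(dist_a, "dist_a")
    b = check_square_symmetric(dist_b, "dist_b")
    if a.shape != b.shape:
        raise ValueError("matrices must have the same shape")
    if log_b:
        b = np.log1p(b)
    va = offdiag(a)
    vb = offdiag(b)
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r = float(pearsonr(va, vb)[0])
    rng = as_rng(seed)
    n = a.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rp = float(np.corrcoef(va, offdiag(b[np.ix_(perm, perm)]))[0, 1])
        if rp >= r:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r, p=p, n_perm=n_perm)


# -- 2D local spatial autocorrelation ----------------------------------------

@dataclass
class LsaResult:
    sample_ids: list
    n_neighbors: int
    lr: np.ndarray
    p: np.ndarray
    neighbors: np.ndarray = field(repr=False, default=None)


def local_spatial_autocorrelation(genetic_dist: np.ndarray, latitudes, longitudes,
                                  n_neighbors: int, n_perm: int = 9999, seed=0,
                                  sample_ids=None) -> LsaResult:
    """Per-individual local autocorrelation against geographic neighbours.

    lr_i is the mean genetic similarity (1 - d/d_max over the panel) between
    i and its n nearest geographic neighbours; the one-tailed p-value is the
    probability of an equal or larger lr when individual identities are
    randomly permuted.  Coordinate ties are broken by sample order (flagged).
    """
    g = check_square_symmetric(genetic_dist, "genetic distance")
    n = g.shape[0]
    if not 0 < n_neighbors < n:
        raise ValueError("n_neighbors must be in (0, n_samples)")
    geo = haversine_km(np.asarray(latitudes), np.asarray(longitudes))
    if np.any(offdiag(geo) == 0):
        log.warning("duplicate coordinates; neighbour ties broken by sample order")
    dmax = g.max()
    sim = 1.0 - g / dmax if dmax > 0 else np.ones_like(g)
    np.fill_diagonal(sim, np.nan)

    geo_self = geo.copy()
    np.fill_diagonal(geo_self, np.inf)
    order = np.argsort(geo_self, axis=1, kind="stable")
    nbrs = order[:, :n_neighbors]
    lr = np.array([np.mean(sim[i, nbrs[i]]) for i in range(n)])

    rng = as_rng(seed)
    count = np.zeros(n)
    rows = np.arange(n)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        sp = sim[np.ix_(perm, perm)]
        lrp = sp[rows[:, None], nbrs].mean(axis=1)
        count += lrp >= lr
    p = (count + 1) / (n_perm + 1)
    ids = list(sample_ids) if sample_ids is not None else list(range(n))
    return LsaResult(sample_ids=ids, n_neighbors=n_neighbors, lr=lr, p=p,
                     neighbors=nbrs)


def lsa_sweep(genetic_dist, latitudes, longitudes, n_min: int = 7, n_max: int = 14,
              n_perm: int = 9999, seed=0, alpha: float = 0.05, sample_ids=None):
    """Run the LSA across a neighbour sweep; an individual is consistently
    significant when p <= alpha at every sweep value.  Returns
    (results per n, consistent boolean array)."""
    rng = as_rng(seed)
    results = []
    consistent = None
    for nn in range(n_min, n_max + 1):
        res = local_spatial_autocorrelation(genetic_dist, latitudes, longitudes,
                                            nn, n_perm=n_perm,
                                            seed=as_rng(rng.integers(2**31 - 1)),
                                            sample_ids=sample_ids)
        sig = res.p <= alpha
        consistent = sig if consistent is None else (consistent & sig)
        results.append(res)
    return results, consistent


# -- concatenated genotype sequences and distances ---------------------------

def genotype_sequences(dataset) -> list[str]:
    """Concatenate SNP alleles into one IUPAC-coded sequence per genotype.

    Heterozygous calls become two-base ambiguity codes; missing/ambiguous
    calls become N.  Order of sites follows the locus table.
    """
    from .dataset import HET, HOM_ALT, HOM_REF

    state = dataset.require_state()
    ref = dataset.loci["ref"].to_numpy()
    alt = dataset.loci["alt1"].to_numpy()
    seqs = []
    for i in range(dataset.n_samples):
        chars = []
        for j in range(dataset.n_loci):
            st = state[i, j]
            if st == HOM_REF:
                chars.append(ref[j])
            elif st == HOM_ALT:
                chars.append(alt[j])
            elif st == HET:
                chars.append(IUPAC.get(frozenset((ref[j], alt[j])), "N"))
            else:
                chars.append("N")
        seqs.append("".join(chars))
    return seqs


def _base_weights(seqs: list[str]) -> np.ndarray:
    """Encode sequences as (n, L, 4) base-probability weights; N -> zeros
    (site excluded from comparison)."""
    n = len(seqs)
    L = len(seqs[0])
    w = np.zeros((n, L, 4))
    amb = {code: bases for bases, code in IUPAC.items()}
    for i, s in enumerate(seqs):
        for j, c in enumerate(s):
            if c == "N":
                continue
            bases = amb.get(c, frozenset())
            for b in bases:
                w[i, j, _BASES.index(b)] = 1.0 / len(bases)
    return w


def p_distance_matrix(seqs: list[str]) -> np.ndarray:
    """Pairwise p-distance with fractional ambiguity matching.

    Match probability between two IUPAC states is the dot product of their
    base-probability vectors (e.g. R vs A scores 0.5, so the difference is
    0.5); sites with N in either sequence are excluded pairwise.
    """
    w = _base_weights(seqs)
    n, L, _ = w.shape
    flat = w.reshape(n, -1)
    match = flat @ flat.T
    obs = (w.sum(axis=2) > 0).astype(float)
    shared = obs @ obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - match / np.maximum(shared, 1)
    d[shared == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0) * 1.0


def mcl_distance_matrix(seqs: list[str]) -> np.ndarray:
    """Composite Tamura-Nei distance: transition/transversion counts pooled
    with panel-wide base frequencies (composite-likelihood style)."""
    w = _base_weights(seqs)
    freqs = w.sum(axis=(0, 1))
    freqs = freqs / freqs.sum()
    gr = freqs[_BASES.index("A")] + freqs[_BASES.index("G")]
    gy = freqs[_BASES.index("C")] + freqs[_BASES.index("T")]
    n = len(seqs)
    d = np.zeros((n, n))
    obs = (w.sum(axis=2) > 0).astype(float)
    wa, wc, wg, wt = w[..., 0], w[..., 1], w[..., 2], w[..., 3]
    for i in range(n):
        for j in range(i + 1, n):
            sh = obs[i] * obs[j]
            if sh.sum() == 0:
                continue
            match = (w[i] * w[j]).sum(axis=1)
            diff = (1 - match) * sh
            # transition probability mass: A<->G and C<->T
            ts = (wa[i] * wg[j] + wg[i] * wa[j] + wc[i] * wt[j] + wt[i] * wc[j]) * sh
            p1 = ts.sum() / sh.sum()
            q = max(diff.sum() / sh.sum() - p1, 0.0)
            # Kimura-style with unequal base classes (Tamura-Nei composite)
            with np.errstate(invalid="ignore", divide="ignore"):
                term1 = -2 * gr * gy * np.log(max(1 - p1 / (2 * gr * gy) - q, 1e-12)) \
                    if gr * gy > 0 else 0.0
                term2 = -0.5 * (1 - 2 * gr * gy) * np.log(max(1 - q / (2 * gr * gy), 1e-12)) \
                    if gr * gy > 0 else 0.0
            d[i, j] = d[j, i] = max(term1 + term2, 0.0)
    return d


# -- UPGMA with bootstrap -----------------------------------------------------

@dataclass
class PhyloTree:
    newick: str
    labels: list
    heights: dict
    supports: dict                # frozenset(leaf labels) -> bootstrap percent
    linkage: np.ndarray = field(repr=False, default=None)


def _linkage_to_clades(Z: np.ndarray, labels: list) -> dict:
    """Map each internal node of a linkage matrix to (leafset, height)."""
    n = len(labels)
    clades = {}
    members = {i: frozenset([labels[i]]) for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        node = n + k
        members[node] = members[int(a)] | members[int(b)]
        clades[members[node]] = h / 2.0  # ultrametric height of the node
    return clades, members


def _linkage_to_newick(Z: np.ndarray, labels: list, supports: dict | None = None) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    text = {i: labels[i] for i in range(n)}
    members = {i: frozenset([labels[i]]) for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + k
        hk = h / 2.0
        heights[node] = hk
        members[node] = members[a] | members[b]
        la = hk - heights[a]
        lb = hk - heights[b]
        sup = ""
        if supports is not None and k < len(Z) - 1:
            s = supports.get(members[node])
            sup = f"{s:.0f}" if s is not None else ""
        text[node] = f"({text[a]}:{la:.6f},{text[b]}:{lb:.6f}){sup}"
    return text[n + len(Z) - 1] + ";"


def upgma_tree(dist: np.ndarray, labels: list) -> tuple[np.ndarray, dict]:
    d = check_square_symmetric(dist, "distance matrix")
    Z = average(squareform(d, checks=False))
    clades, _ = _linkage_to_clades(Z, labels)
    return Z, clades


def upgma_bootstrap(seqs: list[str], labels: list, n_boot: int = 500, seed=0,
                    distance: str = "p") -> PhyloTree:
    """UPGMA tree over concatenated genotype sequences with column bootstrap.

    Supports are the percentage of bootstrap replicates (resampled alignment
    columns) whose UPGMA tree contains the same leaf set under a clade.
    """
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    if len(set(len(s) for s in seqs)) != 1:
        raise ValueError("sequences must be aligned (equal length)")
    dist_fn = p_distance_matrix if distance == "p" else mcl_distance_matrix
    d = dist_fn(seqs)
    Z, clades = upgma_tree(d, labels)
    rng = as_rng(seed)
    L = len(seqs[0])
    counts = {cl: 0 for cl in clades}
    for _ in range(n_boot):
        cols = rng.integers(0, L, size=L)
        bs = ["".join(s[c] for c in cols) for s in seqs]
        db = dist_fn(bs)
        _, bcl = upgma_tree(db, labels)
        for cl in counts:
            if cl in bcl:
                counts[cl] += 1
    supports = {cl: 100.0 * c / n_boot for cl, c in counts.items()} if n_boot else {}
    newick = _linkage_to_newick(Z, labels, supports if n_boot else None)
    heights = {cl: h for cl, h in clades.items()}
    return PhyloTree(newick=newick, labels=list(labels), heights=heights,
                     supports=supports, linkage=Z)


def cophenetic_from_linkage(Z: np.ndarray) -> np.ndarray:
    from scipy.cluster.hierarchy import cophenet
    return squareform(cophenet(Z))


# -- divergence dating --------------------------------------------------------

@dataclass
class DivergenceEstimate:
    between_group_distance: float
    outgroup_distance: float
    calibration_mya: float
    t_mya: float


def divergence_time(between_group_distance: float, outgroup_distance: float,
                    calibration_mya: float = 13.0) -> DivergenceEstimate:
    """t = calibration * d(between groups) / d(ingroup, outgroup)."""
    if outgroup_distance <= 0:
        raise ValueError("outgroup distance must be positive")
    t = calibration_mya * between_group_distance / outgroup_distance
    return DivergenceEstimate(between_group_distance=float(between_group_distance),
                              outgroup_distance=float(outgroup_distance),
                              calibration_mya=calibration_mya, t_mya=float(t))


def group_divergence(dist: np.ndarray, labels, group_a, group_b,
                     outgroup_label=None, calibration_mya: float = 13.0,
                     outgroup_distance: float | None = None,
                     net: bool = False) -> DivergenceEstimate:
    """Date the split of two groups from a pairwise distance matrix.

    The between-group distance is the mean over cross pairs; with
    ``net=True`` the mean within-group distances are subtracted
    (d_A = d_xy - (d_x + d_y)/2), removing shared ancestral polymorphism —
    the appropriate quantity when groups are polymorphic populations rather
    than single sequences.  The calibration distance is either given
    directly or taken as the mean distance from all ingroup samples to
    ``outgroup_label`` samples.
    """
    labels = np.asarray(labels)
    a = labels == group_a
    b = labels == group_b
    if not a.any() or not b.any():
        raise ValueError("empty group")

    def _within(mask):
        sub = dist[np.ix_(mask, mask)]
        k = mask.sum()
        return float(sub.sum() / (k * (k - 1))) if k > 1 else 0.0

    between = float(dist[np.ix_(a, b)].mean())
    if net:
        between = max(between - 0.5 * (_within(a) + _within(b)), 0.0)
    if outgroup_distance is None:
        if outgroup_label is None:
            raise ValueError("need outgroup_label or outgroup_distance")
        o = labels == outgroup_label
        outgroup_distance = float(dist[np.ix_(a | b, o)].mean())
    return divergence_time(between, outgroup_distance, calibration_mya)
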