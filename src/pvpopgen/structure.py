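"""Admixture-model population structure, K selection, membership rules, PCoA.

The sampler is a minimal STRUCTURE-style Gibbs chain: each of the two allele
copies per genotype carries a latent cluster of origin z; cluster allele
frequencies get independent Beta(1,1) priors, individual admixture vectors a
symmetric Dirichlet(alpha) prior.  lnP(D) is estimated from the post-burn-in
log-likelihood trace as mean(lnL) - var(lnL)/2, the same ad hoc criterion
used to choose K.  Genotypes are collapsed to biallelic alternate dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import as_rng, check_square_symmetric, spawn_seed

log = logging.getLogger("pvpopgen")


@dataclass
class AdmixtureResult:
    K: int
    Q: np.ndarray                 # samples x K posterior-mean memberships
    P: np.ndarray                 # K x loci posterior-mean allele freqs
    lnPD: float                   # of the reporting run
    lnPD_per_run: list
    chosen_run: int
    Q_per_run: list = field(repr=False, default_factory=list)


def _gibbs_run(alt_copies: np.ndarray, valid: np.ndarray, K: int, alpha: float,
               n_burnin: int, n_iter: int, rng: np.random.Generator):
    """One Gibbs chain.  ``alt_copies`` is (n, m, 2) in {0,1}; ``valid`` the
    matching observation mask."""
    n, m, _ = alt_copies.shape
    p = rng.uniform(0.1, 0.9, size=(K, m))
    q = rng.dirichlet(np.full(K, alpha), size=n)
    lnls = []
    q_sum = np.zeros((n, K))
    p_sum = np.zeros((K, m))
    kept = 0
    # flatten observed copies once: per copy its sample, locus and allele
    ii, ll, cc = np.nonzero(valid)
    aa = alt_copies[ii, ll, cc].astype(bool)
    n_obs = ii.size
    kl_idx = ll  # locus index per observed copy
    for it in range(n_burnin + n_iter):
        pT = p.T                           # (m, K)
        like = np.where(aa[:, None], pT[kl_idx], 1.0 - pT[kl_idx])
        w = like * q[ii]                   # (n_obs, K)
        tot = w.sum(axis=1)
        lnl = float(np.log(np.maximum(tot, 1e-300)).sum())
        cdf = np.cumsum(w, axis=1)
        u = rng.random(n_obs) * tot
        z = (cdf < u[:, None]).sum(axis=1)
        z = np.minimum(z, K - 1)
        # p update: alt/total copy counts per (cluster, locus)
        flat = z * m + kl_idx
        tot_k = np.bincount(flat, minlength=K * m).reshape(K, m)
        alt_k = np.bincount(flat[aa], minlength=K * m).reshape(K, m)
        p = rng.beta(1.0 + alt_k, 1.0 + tot_k - alt_k)
        # q update: cluster counts per sample
        zc = np.bincount(ii * K + z, minlength=n * K).reshape(n, K)
        gam = rng.gamma(alpha + zc)
        q = gam / gam.sum(axis=1, keepdims=True)
        if it >= n_burnin:
            lnls.append(lnl)
            q_sum += q
            p_sum += p
            kept += 1
    lnls = np.asarray(lnls)
    lnpd = float(lnls.mean() - lnls.var() / 2.0)
    return q_sum / kept, p_sum / kept, lnpd


def _align_clusters(q_ref: np.ndarray, q: np.ndarray, p: np.ndarray):
    """Greedy column matching on correlation to resolve label switching."""
    K = q.shape[1]
    used = set()
    order = np.zeros(K, dtype=int)
    corr = np.corrcoef(q_ref.T, q.T)[:K, K:]
    corr = np.nan_to_num(corr)
    for _ in range(K):
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        order[i] = j
        corr[i, :] = -np.inf
        corr[:, j] = -np.inf
        used.add(j)
    return q[:, order], p[order]


def fit_admixture(dosage: np.ndarray, K: int, n_burnin: int = 1000,
                  n_iter: int = 2000, n_runs: int = 2, alpha: float = 1.0,
                  seed=0, run_selection: str = "highest") -> AdmixtureResult:
    """Fit the admixture model at one K with multiple independent runs.

    ``dosage`` is samples x loci in {0, 0.5, 1, NaN}.  The reporting run is
    the one with the highest (default) or lowest lnP(D).
    """
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples ({n})")
    rng = as_rng(seed)

    if K == 1:
        # degenerate: Q is exactly 1; P is the posterior-mean frequency
        valid = ~np.isnan(dosage)
        copies = np.nansum(2 * np.where(valid, dosage, 0.0), axis=0)
        tot = 2 * valid.sum(axis=0)
        phat = (copies + 1.0) / (tot + 2.0)
        alt = np.round(2 * np.where(valid, dosage, 0)).astype(int)
        lnl = float(np.sum(np.where(valid,
                                    alt * np.log(phat)[None, :]
                                    + (2 - alt) * np.log1p(-phat)[None, :], 0.0)))
        return AdmixtureResult(K=1, Q=np.ones((n, 1)), P=phat[None, :],
                               lnPD=lnl, lnPD_per_run=[lnl], chosen_run=0,
                               Q_per_run=[np.ones((n, 1))])

    # expand dosages to two allele copies; ambiguous/missing are unobserved
    valid = ~np.isnan(dosage)
    alt_copies = np.zeros((n, m, 2), dtype=np.int8)
    filled = np.where(valid, dosage, 0.0)
    alt_copies[..., 0] = (filled >= 0.75)
    alt_copies[..., 1] = (filled >= 0.40)   # het contributes one alt copy
    valid2 = np.repeat(valid[..., None], 2, axis=2)

    runs = []
    for r in range(n_runs):
        child = as_rng(spawn_seed(rng))
        q, p, lnpd = _gibbs_run(alt_copies, valid2, K, alpha, n_burnin, n_iter, child)
        runs.append((q, p, lnpd))
    lnpds = [r[2] for r in runs]
    if run_selection == "lowest":
        chosen = int(np.argmin(lnpds))
    else:
        chosen = int(np.argmax(lnpds))
    q_ref = runs[chosen][0]
    aligned_q = []
    for q, p, _ in runs:
        qa, _ = _align_clusters(q_ref, q, p)
        aligned_q.append(qa)
    q, p, lnpd = runs[chosen]
    return AdmixtureResult(K=K, Q=q, P=p, lnPD=lnpd, lnPD_per_run=lnpds,
                           chosen_run=chosen, Q_per_run=aligned_q)


def select_k(lnpd_by_k: dict[int, list[float]]) -> int:
    """Choose K by mean lnP(D) with plateau detection: the smallest K whose
    mean is within one run-level standard deviation of the best mean."""
    if not lnpd_by_k:
        raise ValueError("no lnP(D) values supplied")
    ks = sorted(lnpd_by_k)
    if len(ks) == 1:
        log.warning("only one K evaluated; returning it")
        return ks[0]
    means = {k: float(np.mean(lnpd_by_k[k])) for k in ks}
    best_k = max(means, key=means.get)
    sds = [np.std(lnpd_by_k[k]) for k in ks if len(lnpd_by_k[k]) > 1]
    sd = float(np.mean(sds)) if sds else 0.0
    for k in ks:
        if means[k] >= means[best_k] - sd:
            return k
    return best_k


@dataclass
class MembershipCall:
    sample_id: str
    assigned: str          # cluster label or "admixed"
    argmax_cluster: int
    max_q: float


def classify_membership(result: AdmixtureResult, sample_ids,
                        accessions=None, threshold: float = 0.70,
                        representative_threshold: float = 0.70,
                        cluster_names=None):
    """Assign samples to clusters with the admixture threshold rule.

    Samples with max membership < threshold are "admixed".  When accession
    labels are given, an accession is representative of a cluster when more
    than ``representative_threshold`` of its genotypes are assigned there.
    Returns (calls, representative map).
    """
    K = result.K
    names = cluster_names or [f"C{i + 1}" for i in range(K)]
    calls = []
    for i, sid in enumerate(sample_ids):
        k = int(np.argmax(result.Q[i]))
        mq = float(result.Q[i, k])
        assigned = names[k] if mq >= threshold else "admixed"
        calls.append(MembershipCall(sample_id=sid, assigned=assigned,
                                    argmax_cluster=k, max_q=mq))
    representative: dict[str, list] = {name: [] for name in names}
    if accessions is not None:
        acc = pd.Series(list(accessions), index=list(sample_ids))
        assigned = pd.Series([c.assigned for c in calls], index=list(sample_ids))
        for accession, members in acc.groupby(acc).groups.items():
            sub = assigned.loc[members]
            frac = sub.value_counts(normalize=True)
            for name in names:
                if frac.get(name, 0.0) > representative_threshold:
                    representative[name].append(accession)
    return calls, representative


@dataclass
class PcoaResult:
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    pct_variance: np.ndarray


def pcoa(distance: np.ndarray, n_axes: int | None = None) -> PcoaResult:
    """Principal coordinates analysis by double-centred eigendecomposition.

    Percent variance is computed from the positive eigenvalues only; axes
    are ordered by decreasing eigenvalue.
    """
    d = check_square_symmetric(distance, "distance matrix")
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    pct = 100.0 * vals[pos] / vals[pos].sum()
    if n_axes is not None:
        coords = coords[:, :n_axes]
        pct = pct[:n_axes]
    return PcoaResult(coordinates=coords, eigenvalues=vals[pos], pct_variance=pct)


def genotype_distance(dosage: np.ndarray) -> np.ndarray:
    """Pairwise squared-dosage genetic distance (the codominant metric shared
    with the AMOVA): d_ij = sum_l 4 (g_il - g_jl)^2 over loci called in both,
    rescaled to the full locus count."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    valid = ~np.isnan(dosage)
    x = np.where(valid, dosage, 0.0)
    v = valid.astype(float)
    # sum over shared loci of (gi - gj)^2, via expansion
    x2 = x**2
    shared = v @ v.T
    cross = x @ x.T
    si = x2 @ v.T
    sj = v @ x2.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = (si + sj - 2 * cross) / np.maximum(shared, 1) * m
    d = 4.0 * d2
    np.fill_diagonal(d, 0.0)
    return d
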