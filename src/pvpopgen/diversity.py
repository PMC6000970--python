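"""Sequence diversity and neutrality statistics.

Haplotype phase over each amplicon contig is resolved with an
Excoffier-Slatkin EM over haplotype frequencies (adequate and deterministic
at amplicon SNP counts); per-contig nucleotide diversity, Watterson's theta,
haplotype diversity, Tajima's D and Fu & Li's F/F* then follow the standard
neutral-theory formulas on the phased sample of n = 2 x (individuals)
sequences.

Per-site conventions: pi uses the sample-size-corrected heterozygosity form
pi = (n/(n-1)) * sum_sites(1 - sum_a p_a^2) / L; theta_w = S / (a1 * L) with
a1 = sum_{i<n} 1/i.  Standard deviations follow the no-recombination
neutral variances (Tajima 1983/1989 for pi and S; Nei 1987 eq. 8.12 for
haplotype diversity).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger("pvpopgen")


# -- per-locus indices --------------------------------------------------------

@dataclass
class LocusDiversity:
    Ne: float          # effective allele number 1/sum(p^2)
    I: float           # Shannon information (nats)
    Ho: float          # observed heterozygosity
    He: float          # expected heterozygosity 1 - sum(p^2)
    F: float           # fixation index 1 - Ho/He (0 when He == 0)
    is_polymorphic: bool
    n_called: int


def per_locus_diversity(dosages: np.ndarray) -> LocusDiversity:
    """Diversity indices for one biallelic locus from genotype dosages
    (0 / 0.5 / 1; NaN = missing)."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("all calls missing at locus")
    p = float(np.mean(d))
    probs = np.array([1.0 - p, p])
    probs = probs[probs > 0]
    sum_sq = float(np.sum(probs**2))
    he = 1.0 - sum_sq
    ho = float(np.mean(d == 0.5))
    return LocusDiversity(
        Ne=1.0 / sum_sq,
        I=float(-np.sum(probs * np.log(probs))),
        Ho=ho,
        He=he,
        F=(1.0 - ho / he) if he > 0 else 0.0,
        is_polymorphic=he > 0,
        n_called=int(d.size),
    )


def group_diversity_summary(dataset, labels) -> "np.ndarray":
    """Per-group mean diversity indices, %P and private-allele counts.

    ``labels`` is a sequence of group labels aligned with dataset samples.
    Returns a pandas DataFrame (imported lazily to keep numpy-only callers
    light).
    """
    import pandas as pd

    dos = dataset.dosage()
    labels = np.asarray(labels)
    groups = [g for g in pd.unique(labels) if g is not None]
    # which alleles occur in which group (for private alleles)
    occ_alt = {}
    occ_ref = {}
    for g in groups:
        sub = dos[labels == g]
        with np.errstate(invalid="ignore"):
            f = np.nanmean(sub, axis=0)
        occ_alt[g] = f > 0
        occ_ref[g] = f < 1
    rows = []
    for g in groups:
        sub = dos[labels == g]
        stats = []
        poly = 0
        total = 0
        for j in range(sub.shape[1]):
            col = sub[:, j]
            if np.all(np.isnan(col)):
                continue
            ld = per_locus_diversity(col)
            stats.append(ld)
            total += 1
            poly += int(ld.is_polymorphic)
        others = [h for h in groups if h != g]
        private = int(np.sum(occ_alt[g] & ~np.any([occ_alt[h] for h in others], axis=0)))
        private += int(np.sum(occ_ref[g] & ~np.any([occ_ref[h] for h in others], axis=0)))
        rows.append({
            "group": g,
            "N": int((labels == g).sum()),
            "n_polymorphic": poly,
            "private_alleles": private,
            "pct_polymorphic": 100.0 * poly / total if total else np.nan,
            "Ne": np.mean([s.Ne for s in stats]),
            "I": np.mean([s.I for s in stats]),
            "Ho": np.mean([s.Ho for s in stats]),
            "He": np.mean([s.He for s in stats]),
            "F": np.mean([s.F for s in stats]),
        })
    return pd.DataFrame(rows).set_index("group")


# -- EM haplotype phasing -----------------------------------------------------

@dataclass
class HaplotypeSet:
    """Phased haplotypes over one contig's SNPs (0/1 strings per allele)."""

    haplotypes: list          # per sample: (hap_a, hap_b) tuples of str
    frequencies: dict         # haplotype string -> relative frequency
    log_likelihood: float
    converged: bool
    n_iter: int

    @property
    def n_sequences(self) -> int:
        return 2 * len(self.haplotypes)

    def sequences(self) -> list[str]:
        return [h for pair in self.haplotypes for h in pair]


def _resolutions(genotype: tuple) -> list[tuple[str, str]]:
    """All ordered haplotype pairs compatible with one multi-site genotype.

    Genotype entries: 0 (hom ref), 1 (het), 2 (hom alt), -1 (missing ->
    treated as reference; pairwise deletion happens downstream).
    """
    het_sites = [i for i, g in enumerate(genotype) if g == 1]
    base = ["0"] * len(genotype)
    for i, g in enumerate(genotype):
        if g == 2:
            base[i] = "1"
    if not het_sites:
        h = "".join(base)
        return [(h, h)]
    pairs = []
    # fix the first het site to break the mirror symmetry
    for bits in itertools.product("01", repeat=len(het_sites) - 1):
        a, b = base[:], base[:]
        a[het_sites[0]], b[het_sites[0]] = "0", "1"
        for site, bit in zip(het_sites[1:], bits):
            a[site] = bit
            b[site] = "1" if bit == "0" else "0"
        pairs.append(("".join(a), "".join(b)))
    return pairs


def phase_haplotypes(genotypes: np.ndarray, max_iter: int = 1000, tol: float = 1e-6,
                     n_restarts: int = 3, seed: int | np.random.Generator = 0,
                     max_het: int = 16) -> HaplotypeSet:
    """Excoffier-Slatkin EM phasing of genotypes (samples x SNPs).

    Genotype coding: 0 hom-ref, 1 het, 2 hom-alt, -1 missing.  Individuals
    with more than ``max_het`` heterozygous sites are phased on their most
    probable resolution under the final frequencies of the remaining panel
    (with a warning) to keep the enumeration bounded.
    """
    from ._util import as_rng

    rng = as_rng(seed)
    geno = np.asarray(genotypes)
    if geno.ndim != 2:
        raise ValueError("genotypes must be samples x SNPs")
    n, m = geno.shape
    het_counts = (geno == 1).sum(axis=1)
    heavy = np.flatnonzero(het_counts > max_het)
    if heavy.size:
        log.warning("%d individuals exceed %d heterozygous sites; phased greedily",
                    heavy.size, max_het)

    res_per_ind = []
    for i in range(n):
        g = tuple(geno[i])
        if het_counts[i] > max_het:
            res_per_ind.append(None)
        else:
            res_per_ind.append(_resolutions(g))

    # collect candidate haplotypes
    hap_index: dict[str, int] = {}
    for res in res_per_ind:
        if res is None:
            continue
        for a, b in res:
            for h in (a, b):
                hap_index.setdefault(h, len(hap_index))
    if not hap_index:
        raise ValueError("no phasable individuals")
    H = len(hap_index)
    ind_pairs = [None if res is None else
                 np.array([(hap_index[a], hap_index[b]) for a, b in res])
                 for res in res_per_ind]

    def run_em(freq0: np.ndarray):
        freq = freq0.copy()
        prev_ll = -np.inf
        for it in range(1, max_iter + 1):
            counts = np.zeros(H)
            ll = 0.0
            for pairs in ind_pairs:
                if pairs is None:
                    continue
                pa, pb = pairs[:, 0], pairs[:, 1]
                w = freq[pa] * freq[pb]
                mult = np.where(pa == pb, 1.0, 2.0)
                w = w * mult
                tot = w.sum()
                if tot <= 0:
                    w = mult / mult.sum()
                    tot = 1.0
                    w_norm = w
                else:
                    w_norm = w / tot
                    ll += math.log(tot)
                np.add.at(counts, pa, w_norm)
                np.add.at(counts, pb, w_norm)
            freq = counts / counts.sum()
            if abs(ll - prev_ll) < tol:
                return freq, ll, True, it
            prev_ll = ll
        return freq, prev_ll, False, max_iter

    best = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            freq0 = np.full(H, 1.0 / H)
        else:
            freq0 = rng.dirichlet(np.ones(H))
        freq, ll, conv, it = run_em(freq0)
        if best is None or ll > best[1]:
            best = (freq, ll, conv, it)
    freq, ll, conv, n_iter = best
    if not conv:
        log.warning("EM phasing did not converge after %d iterations", n_iter)

    inv = {v: k for k, v in hap_index.items()}
    out_pairs = []
    for i in range(n):
        pairs = ind_pairs[i]
        if pairs is None:
            # greedy: most probable resolution site by site
            g = geno[i]
            a = "".join("1" if x == 2 else "0" for x in g)
            b = a
            out_pairs.append((a, b))
            continue
        pa, pb = pairs[:, 0], pairs[:, 1]
        w = freq[pa] * freq[pb] * np.where(pa == pb, 1.0, 2.0)
        k = int(np.argmax(w))
        out_pairs.append((inv[pairs[k, 0]], inv[pairs[k, 1]]))
    freqs = {inv[i]: float(f) for i, f in enumerate(freq) if f > 1e-12}
    return HaplotypeSet(haplotypes=out_pairs, frequencies=freqs,
                        log_likelihood=float(ll), converged=conv, n_iter=n_iter)


# -- per-contig sequence diversity -------------------------------------------

def harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


@dataclass
class SequenceDiversity:
    L: int
    S_tot: int
    pi: float
    theta_w: float
    sd_pi: float
    sd_theta: float
    h: int
    Hd: float
    sd_Hd: float
    tajima_D: float | None
    fu_li_F: float | None
    fu_li_variant: str
    snp_density_d: float


def snp_density(S: int, L: int) -> float:
    """Percent polymorphism d = 100 * S / L."""
    if L <= 0:
        raise ValueError("alignment length must be positive")
    return 100.0 * S / L


def tajima_d(pi_per_site: float, S: int, n: int, L: int) -> float | None:
    """Tajima's D from per-site pi, segregating sites S, n sequences.

    Uses the standard constants (a1, a2, b1, b2, c1, c2, e1, e2).  None when
    S == 0 (test not applicable).
    """
    if S == 0:
        return None
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4 sequences")
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return None
    return (pi_per_site * L - S / a1) / math.sqrt(var)


def fu_li_f(n: int, S: int, pi_per_site: float, L: int, n_singletons: int,
            derived: bool = False) -> float | None:
    """Fu & Li's F (derived/external singletons, requires outgroup
    orientation) or F* (sample singletons), with the corrected constants.

    ``n_singletons`` counts derived singletons when ``derived`` is True,
    otherwise all singleton sites.  Returns None when S == 0.
    """
    if S == 0:
        return None
    if n < 4:
        raise ValueError("Fu & Li's F requires n >= 4 sequences")
    an = harmonic(n)
    bn = harmonic(n, 2)
    an1 = an + 1.0 / n  # a_{n+1}
    k = pi_per_site * L
    if derived:
        # corrected constants (Simonsen et al. 1995 erratum of Fu & Li 1993)
        cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
        v = (cn + 2 * (n * n + n + 3) / (9 * n * (n - 1)) - 2 / (n - 1)) / (an**2 + bn)
        u = (1 + (n + 1) / (3 * (n - 1)) - 4 * (n + 1) / (n - 1)**2
             * (an1 - 2 * n / (n + 1))) / an - v
        num = k - n_singletons
    else:
        vs = (2 * n**3 + 110 * n**2 - 255 * n + 153) / (9 * n**2 * (n - 1)) \
            + (2 * (n - 1) * an) / n**2 - (8 * bn) / n
        vs = vs / (an**2 + bn)
        us = (4 * n**2 + 19 * n + 3 - 12 * (n + 1) * an1) / (3 * n * (n - 1))
        us = us / an - vs
        u, v = us, vs
        num = k - (n - 1) / n * n_singletons
    var = u * S + v * S * S
    if var <= 0:
        return None
    return num / math.sqrt(var)


def sequence_diversity(haps: HaplotypeSet | list[str], L: int,
                       outgroup_states: np.ndarray | None = None) -> SequenceDiversity:
    """Diversity summary for a contig from phased 0/1 haplotype strings.

    ``outgroup_states`` optionally gives the ancestral (0/1) state per
    segregating site; when provided Fu & Li's F uses derived singletons,
    otherwise F* uses sample singletons.
    """
    seqs = haps.sequences() if isinstance(haps, HaplotypeSet) else list(haps)
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if L <= 0:
        raise ValueError("alignment length must be positive")
    mat = np.array([[int(c) for c in s] for s in seqs], dtype=float) \
        if seqs[0] else np.zeros((n, 0))
    m = mat.shape[1]

    p = mat.mean(axis=0) if m else np.zeros(0)
    seg = (p > 0) & (p < 1)
    S = int(seg.sum())
    het_sum = float(np.sum(2 * p * (1 - p)))
    pi = (n / (n - 1)) * het_sum / L
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    theta_w = S / (a1 * L)

    # neutral-model variances (per site)
    theta = theta_w * L
    var_pi = ((n + 1) / (3 * (n - 1)) * theta
              + 2 * (n * n + n + 3) / (9 * n * (n - 1)) * theta**2) / L**2
    var_theta = (theta / a1 + a2 * theta**2 / a1**2) / L**2

    counts: dict[str, int] = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    h = len(counts)
    f = np.array(list(counts.values())) / n
    hd = n / (n - 1) * (1 - float(np.sum(f**2)))
    sum2 = float(np.sum(f**2))
    sum3 = float(np.sum(f**3))
    var_hd = 2.0 / (n * (n - 1)) * (2 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2)
    var_hd = max(var_hd, 0.0)

    # singleton counts among segregating sites
    minor_count = np.minimum(mat.sum(axis=0), n - mat.sum(axis=0))
    singles_mask = seg & (minor_count == 1)
    if outgroup_states is not None:
        anc = np.asarray(outgroup_states, dtype=float)
        derived_count = np.where(anc == 0, mat.sum(axis=0), n - mat.sum(axis=0))
        singles = int(np.sum(seg & (derived_count == 1)))
        fvariant = "F"
        F = fu_li_f(n, S, pi, L, singles, derived=True) if n >= 4 else None
    else:
        singles = int(singles_mask.sum())
        fvariant = "F*"
        F = fu_li_f(n, S, pi, L, singles, derived=False) if n >= 4 else None

    D = tajima_d(pi, S, n, L) if n >= 4 else None
    return SequenceDiversity(
        L=L, S_tot=S, pi=pi, theta_w=theta_w,
        sd_pi=math.sqrt(max(var_pi, 0.0)), sd_theta=math.sqrt(max(var_theta, 0.0)),
        h=h, Hd=hd, sd_Hd=math.sqrt(var_hd),
        tajima_D=D, fu_li_F=F, fu_li_variant=fvariant,
        snp_density_d=snp_density(S, L),
    )
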