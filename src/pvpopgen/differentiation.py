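"""Population differentiation (Nei Gst / pairwise Fst / Nei distance / Nm)
and hierarchical AMOVA with permutation significance.

Gst follows Nei: Ht computed from pooled mean allele frequencies, Hs as the
mean within-group expected heterozygosity, averaged over loci as
(mean Ht - mean Hs) / mean Ht.  Pairwise Fst is Gst restricted to the pair;
Nei's standard genetic distance is D = -ln(Jxy / sqrt(Jx * Jy)) accumulated
over loci.  Gene flow Nm = 0.5 (1 - Gst) / Gst.

The AMOVA is the three-level codominant partition (among groups / among
individuals within groups / within individuals), computed as a nested
allele-level ANOVA — algebraically the squared-Euclidean distance
formulation on 0/1 allele values.  Variance components come from the
unbalanced-design expected mean squares, truncated at zero; significance
from permuting whole individuals among groups (among-group level) and
alleles among individuals (within-individual level).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import as_rng

log = logging.getLogger("pvpopgen")


# -- Nei Gst / distances ------------------------------------------------------

def _group_freqs(dosage: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, list]:
    groups = list(pd.unique(labels))
    freqs = np.full((len(groups), dosage.shape[1]), np.nan)
    for gi, g in enumerate(groups):
        sub = dosage[labels == g]
        with np.errstate(invalid="ignore"):
            freqs[gi] = np.nanmean(sub, axis=0)
    return freqs, groups


def gst_from_freqs(freqs: np.ndarray) -> float:
    """Nei Gst from a groups x loci alternate-frequency matrix."""
    freqs = np.asarray(freqs, dtype=float)
    valid = ~np.any(np.isnan(freqs), axis=0)
    p = freqs[:, valid]
    hs = np.mean(2 * p * (1 - p), axis=0)          # mean within-group He
    pbar = np.mean(p, axis=0)                      # pooled mean frequency
    ht = 2 * pbar * (1 - pbar)
    ht_mean = float(np.mean(ht))
    if ht_mean <= 0:
        raise ValueError("monomorphic across all loci: Gst undefined")
    return float((ht_mean - np.mean(hs)) / ht_mean)


def gst_overall(dosage: np.ndarray, labels, n_perm: int = 999,
                seed=0) -> tuple[float, float]:
    """Overall Gst over loci with a permutation p-value (individuals
    permuted among groups)."""
    labels = np.asarray(labels)
    if len(pd.unique(labels)) < 2:
        raise ValueError("Gst needs at least two groups")
    rng = as_rng(seed)
    obs = gst_from_freqs(_group_freqs(dosage, labels)[0])
    if n_perm <= 0:
        return obs, np.nan
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if gst_from_freqs(_group_freqs(dosage, perm)[0]) >= obs:
            count += 1
    return obs, (count + 1) / (n_perm + 1)


def gene_flow_nm(gst: float) -> float:
    """Nm = 0.5 (1 - Gst) / Gst; infinite flow flagged for gst <= 0."""
    if gst <= 0:
        log.warning("Gst <= 0: gene flow effectively infinite")
        return float("inf")
    return 0.5 * (1.0 - gst) / gst


def nei_distance(p1: np.ndarray, p2: np.ndarray, cap: float = 10.0) -> float:
    """Nei (1972) standard distance over biallelic loci.

    Jx, Jy, Jxy are summed over both alleles of every locus with defined
    frequencies in both groups; the no-shared-allele limit is capped.
    """
    valid = ~(np.isnan(p1) | np.isnan(p2))
    a1 = np.stack([1 - p1[valid], p1[valid]])
    a2 = np.stack([1 - p2[valid], p2[valid]])
    jx = float(np.sum(a1 * a1))
    jy = float(np.sum(a2 * a2))
    jxy = float(np.sum(a1 * a2))
    if jxy <= 0:
        log.warning("no shared alleles; Nei distance capped at %.1f", cap)
        return cap
    d = -np.log(jxy / np.sqrt(jx * jy))
    return float(min(max(d, 0.0), cap))


@dataclass
class DifferentiationResult:
    groups: list
    gst_overall: float
    gst_p: float
    fst_pairwise: np.ndarray
    nei_distance_pairwise: np.ndarray
    nm_pairwise: np.ndarray


def pairwise_differentiation(dosage: np.ndarray, labels, cap: float = 10.0,
                             n_perm: int = 0, seed=0) -> DifferentiationResult:
    """Pairwise Fst (pair-restricted Nei Gst) and Nei distance matrices."""
    labels = np.asarray(labels)
    freqs, groups = _group_freqs(dosage, labels)
    g = len(groups)
    if g < 2:
        raise ValueError("need at least two groups")
    for gi, grp in enumerate(groups):
        if (labels == grp).sum() < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 individuals")
    fst = np.zeros((g, g))
    nei = np.zeros((g, g))
    nm = np.full((g, g), np.inf)
    for i in range(g):
        for j in range(i + 1, g):
            pair = freqs[[i, j]]
            # skip loci monomorphic for the same allele in both groups
            with np.errstate(invalid="ignore"):
                shared_mono = (pair[0] == pair[1]) & ((pair[0] == 0) | (pair[0] == 1))
            sub = pair[:, ~shared_mono]
            f = gst_from_freqs(sub) if sub.size else 0.0
            fst[i, j] = fst[j, i] = f
            nei[i, j] = nei[j, i] = nei_distance(freqs[i], freqs[j], cap)
            if f > 0:
                nm[i, j] = nm[j, i] = gene_flow_nm(f)
    gst, gst_p = gst_overall(dosage, labels, n_perm=n_perm, seed=seed)
    return DifferentiationResult(groups=groups, gst_overall=gst, gst_p=gst_p,
                                 fst_pairwise=fst, nei_distance_pairwise=nei,
                                 nm_pairwise=nm)


# -- AMOVA --------------------------------------------------------------------

@dataclass
class AmovaResult:
    levels: list                  # dicts: label, df, SS, MS, est_var, pct
    phi_statistics: dict
    p_values: dict
    total_est_var: float

    def as_frame(self) -> pd.DataFrame:
        rows = [dict(l) for l in self.levels]
        rows.append({"label": "Total",
                     "df": sum(l["df"] for l in self.levels),
                     "SS": sum(l["SS"] for l in self.levels),
                     "MS": np.nan, "est_var": self.total_est_var, "pct": 100.0})
        return pd.DataFrame(rows)


def amova_percentages(est_vars) -> list[int]:
    """Integer percentages of total from variance components (reporting
    arithmetic used for published AMOVA tables)."""
    est_vars = np.asarray(est_vars, dtype=float)
    total = est_vars.sum()
    return [int(round(100.0 * v / total)) for v in est_vars]


def _amova_ss(alleles: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """Sums of squares for the nested design.

    ``alleles`` is (2N, loci): the two allele rows per individual are
    adjacent (2i, 2i+1).  Returns (SS among groups, SS among individuals
    within groups, SS within individuals), summed over loci.
    """
    two_n = alleles.shape[0]
    ind = np.repeat(np.arange(two_n // 2), 2)
    grand = alleles.mean(axis=0)
    ss_tot = float(np.sum((alleles - grand) ** 2))
    # within individuals
    ind_mean = alleles.reshape(-1, 2, alleles.shape[1]).mean(axis=1)
    ss_wi = float(np.sum((alleles - np.repeat(ind_mean, 2, axis=0)) ** 2))
    # among groups
    ss_ag = 0.0
    for g in np.unique(groups):
        rows = alleles[groups[ind] == g]
        ss_ag += float(rows.shape[0] * np.sum((rows.mean(axis=0) - grand) ** 2))
    ss_ai = ss_tot - ss_wi - ss_ag
    return ss_ag, ss_ai, ss_wi


def amova(dosage: np.ndarray, labels, n_perm: int = 999, seed=0,
          scale: float = 100.0) -> AmovaResult:
    """Three-level codominant AMOVA on genotype dosages.

    Missing dosages are mean-imputed per locus (as homozygous for the locus
    mean), so the design degrees of freedom depend only on sample counts.
    Groups of size 1 are merged into a residual group with a warning.
    ``scale`` multiplies the 0/1 allele values' squared distances so
    components are on a per-100-loci-like scale; percentages and Phi are
    scale-free.
    """
    labels = np.asarray(labels, dtype=object).copy()
    dosage = np.asarray(dosage, dtype=float)
    counts = pd.Series(labels).value_counts()
    singles = counts[counts < 2].index
    if len(singles):
        log.warning("merging %d singleton groups into residual", len(singles))
        labels[np.isin(labels, singles)] = "_residual"
    groups, group_idx = np.unique(labels, return_inverse=True)
    g = len(groups)
    if g < 2:
        raise ValueError("AMOVA needs at least two groups of size >= 2")
    n = dosage.shape[0]

    # allele-level matrix: expand each dosage into two 0/1 allele values
    with np.errstate(invalid="ignore"):
        locus_mean = np.nanmean(dosage, axis=0)
    filled = np.where(np.isnan(dosage), locus_mean[None, :], dosage)
    # het (0.5) -> alleles 0 and 1; hom -> equal alleles; imputed values keep
    # their fractional mean on both alleles (no within-individual variance)
    is_het = np.isclose(dosage, 0.5)
    base = np.where(is_het, 0.0, filled)
    other = np.where(is_het, 1.0, filled)
    alleles = np.empty((2 * n, dosage.shape[1]))
    alleles[0::2] = base
    alleles[1::2] = other
    alleles = alleles * np.sqrt(scale)

    n_per = np.array([(group_idx == i).sum() for i in range(g)])
    df_ag = g - 1
    df_ai = n - g
    df_wi = n
    lab_arr = np.array(groups)[group_idx]
    ss_ag, ss_ai, ss_wi = _amova_ss(alleles, lab_arr)
    ms_ag = ss_ag / df_ag
    ms_ai = ss_ai / df_ai
    ms_wi = ss_wi / df_wi
    # unbalanced nested coefficient on allele counts (2 per individual)
    a_tot = 2 * n
    a_per = 2 * n_per
    n0 = (a_tot - np.sum(a_per**2) / a_tot) / (g - 1)
    var_wi = ms_wi
    var_ai = max((ms_ai - ms_wi) / 2.0, 0.0)
    var_ag = max((ms_ag - ms_ai) / n0, 0.0)
    total = var_ag + var_ai + var_wi
    pct = [100 * var_ag / total, 100 * var_ai / total, 100 * var_wi / total] \
        if total > 0 else [0.0, 0.0, 0.0]

    phi = {
        "Phi_AG": var_ag / total if total > 0 else np.nan,          # among groups
        "Phi_IS": var_ai / (var_ai + var_wi) if var_ai + var_wi > 0 else np.nan,
        "Phi_IT": (var_ag + var_ai) / total if total > 0 else np.nan,
    }

    rng = as_rng(seed)
    p_values = {}
    # untruncated statistics so the permutation comparison is well calibrated
    raw_ag = (ms_ag - ms_ai) / n0
    raw_ai = (ms_ai - ms_wi) / 2.0
    if n_perm > 0:
        count_ag = 0
        for _ in range(n_perm):
            perm = rng.permutation(lab_arr)
            pss_ag, pss_ai, _ = _amova_ss(alleles, perm)
            pvar = (pss_ag / df_ag - pss_ai / df_ai) / n0
            if pvar >= raw_ag - 1e-12:
                count_ag += 1
        p_values["Phi_AG"] = (count_ag + 1) / (n_perm + 1)
        # within-individual level: permute alleles among individuals
        count_wi = 0
        for _ in range(n_perm):
            idx = rng.permutation(2 * n)
            pss = _amova_ss(alleles[idx], lab_arr)
            pvar_ai = (pss[1] / df_ai - pss[2] / df_wi) / 2.0
            if pvar_ai >= raw_ai - 1e-12:
                count_wi += 1
        p_values["Phi_IS"] = (count_wi + 1) / (n_perm + 1)

    levels = [
        {"label": "Among Groups", "df": df_ag, "SS": ss_ag, "MS": ms_ag,
         "est_var": var_ag, "pct": pct[0]},
        {"label": "Among Individuals", "df": df_ai, "SS": ss_ai, "MS": ms_ai,
         "est_var": var_ai, "pct": pct[1]},
        {"label": "Within Individuals", "df": df_wi, "SS": ss_wi, "MS": ms_wi,
         "est_var": var_wi, "pct": pct[2]},
    ]
    return AmovaResult(levels=levels, phi_statistics=phi, p_values=p_values,
                       total_est_var=total)


def latitude_bins(latitudes, width: float = 1.0) -> np.ndarray:
    """Group label per sample: latitude binned at ``width`` degrees."""
    lat = np.asarray(latitudes, dtype=float)
    return np.floor(lat / width).astype(int)
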