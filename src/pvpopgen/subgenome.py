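"""Homoeologous subgenome (K vs N) contrasts for allotetraploid panels.

SNP placement is profiled in fixed windows (100 bp default, anchored at
position 1 of the analysed region) per contig; homoeologous gene copies are
compared on the percentage of polymorphic loci over regions with SNP
information in both subgenomes.  Genes with mapping data in fewer than the
required fraction of accessions are excluded from the contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("pvpopgen")


@dataclass
class WindowProfile:
    contig_id: str
    window_start: int         # 1-based
    snp_count: int
    per_group_allele_freqs: dict = field(default_factory=dict)


def window_variant_profile(positions, contig_id: str = "", bin_bp: int = 100,
                           region_length: int | None = None,
                           group_freqs: dict | None = None) -> list[WindowProfile]:
    """Count SNPs per fixed-width window (1-based windows [1,100], [101,200]...).

    ``group_freqs`` optionally maps group label -> per-SNP allele-frequency
    array aligned with ``positions``.
    """
    if bin_bp <= 0:
        raise ValueError("bin size must be positive")
    positions = np.asarray(positions, dtype=int)
    if region_length is None:
        region_length = int(positions.max()) if positions.size else bin_bp
    if positions.size and positions.max() > region_length:
        raise ValueError("SNP position outside contig bounds")
    n_windows = int(np.ceil(region_length / bin_bp))
    profiles = []
    for wi in range(n_windows):
        start = wi * bin_bp + 1
        end = start + bin_bp - 1
        mask = (positions >= start) & (positions <= end)
        freqs = {}
        if group_freqs:
            freqs = {g: np.asarray(f)[mask].tolist() for g, f in group_freqs.items()}
        profiles.append(WindowProfile(contig_id=contig_id, window_start=start,
                                      snp_count=int(mask.sum()),
                                      per_group_allele_freqs=freqs))
    return profiles


@dataclass
class HomoeologContrast:
    gene: str
    pctP_K: float
    pctP_N: float
    delta: float
    shared_region_only: bool
    n_shared_windows: int = 0
    k_specific_windows: list = field(default_factory=list)
    n_specific_windows: list = field(default_factory=list)


def _pct_polymorphic(n_poly: int, n_sites: int) -> float:
    return 100.0 * n_poly / n_sites if n_sites else float("nan")


def homoeolog_contrast(gene: str,
                       profile_k: list[WindowProfile],
                       profile_n: list[WindowProfile],
                       sites_per_window: int | None = None) -> HomoeologContrast:
    """Compare %P between the K and N copies of one gene.

    Windows are paired by window_start (annotation projects homoeologous
    coordinates onto a common axis).  %P per subgenome is computed over
    shared windows — windows with SNP information in both copies — as
    100 x SNPs / analysed bp; windows polymorphic in only one copy are
    reported as subgenome-specific divergence candidates.
    """
    by_start_k = {p.window_start: p for p in profile_k}
    by_start_n = {p.window_start: p for p in profile_n}
    shared = sorted(set(by_start_k) & set(by_start_n))
    if not shared:
        log.warning("gene %s: no overlapping analysed region between subgenomes", gene)
        return HomoeologContrast(gene=gene, pctP_K=float("nan"), pctP_N=float("nan"),
                                 delta=float("nan"), shared_region_only=False)
    window_bp = sites_per_window or 100
    k_snps = sum(by_start_k[s].snp_count for s in shared)
    n_snps = sum(by_start_n[s].snp_count for s in shared)
    total_bp = window_bp * len(shared)
    pk = _pct_polymorphic(k_snps, total_bp)
    pn = _pct_polymorphic(n_snps, total_bp)
    k_only = [s for s in sorted(set(by_start_k) - set(by_start_n))
              if by_start_k[s].snp_count > 0]
    n_only = [s for s in sorted(set(by_start_n) - set(by_start_k))
              if by_start_n[s].snp_count > 0]
    return HomoeologContrast(gene=gene, pctP_K=pk, pctP_N=pn, delta=pk - pn,
                             shared_region_only=True, n_shared_windows=len(shared),
                             k_specific_windows=k_only, n_specific_windows=n_only)


def subgenome_contrasts(dataset, bin_bp: int = 100,
                        min_mapped_fraction: float = 0.80) -> pd.DataFrame:
    """Per-gene K vs N contrast table for a filtered, annotated dataset.

    A gene enters the contrast only when both subgenome copies exist and
    each copy has mapping data (any non-missing call) in more than
    ``min_mapped_fraction`` of accessions.
    """
    loci = dataset.loci
    called = dataset.called_mask()
    accessions = dataset.samples["accession_id"].to_numpy()
    rows = []
    for gene, sub in loci.groupby("gene"):
        sgs = set(sub["subgenome"]) & {"K", "N"}
        if sgs != {"K", "N"}:
            continue
        profiles = {}
        ok = True
        for sg in ("K", "N"):
            sel = (sub["subgenome"] == sg).to_numpy()
            idx = sub.index[sel]
            cols = [loci.index.get_loc(i) for i in idx]
            # mapping coverage: fraction of accessions with >=1 call
            acc_called = pd.Series(called[:, cols].any(axis=1), index=accessions)
            frac = acc_called.groupby(level=0).any().mean()
            if frac <= min_mapped_fraction:
                ok = False
                break
            contig = sub.loc[idx, "contig"].iloc[0]
            positions = sub.loc[idx, "position"].to_numpy()
            profiles[sg] = window_variant_profile(positions, contig_id=contig,
                                                  bin_bp=bin_bp)
        if not ok:
            log.info("gene %s excluded from contrast (mapping coverage)", gene)
            continue
        c = homoeolog_contrast(gene, profiles["K"], profiles["N"],
                               sites_per_window=bin_bp)
        rows.append({"gene": gene, "pctP_K": c.pctP_K, "pctP_N": c.pctP_N,
                     "delta": c.delta, "n_shared_windows": c.n_shared_windows})
    return pd.DataFrame(rows)
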