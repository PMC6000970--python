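"""Site and sample filters plus zygosity calling for amplicon SNP panels.

Zygosity is called from per-genotype alternate-read fractions: fractions
below 0.25 or above 0.75 are homozygous calls, fractions in [0.40, 0.60]
heterozygous.  The two uncovered bands ([0.25, 0.40) and (0.60, 0.75]) are
"ambiguous" and are treated as missing by every downstream frequency
computation — in tetraploid amplicon data they mostly reflect reads pooled
across homoeologs or low coverage.

Filter order is fixed and logged: INDEL removal -> adjacent-SNP removal ->
depth masking -> site missingness -> population allele frequency -> sample
missingness.  The population allele frequency is the mean alternate dosage
(hom_ref 0, het 0.5, hom_alt 1) over non-missing called genotypes, computed
after depth masking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import Config
from .dataset import (AMBIGUOUS, HET, HOM_ALT, HOM_REF, MISSING, VariantDataset)

log = logging.getLogger("pvpopgen")


@dataclass
class FilterReport:
    """Per-rule casualty counts; each removed variant is counted once, in
    the first rule that removes it."""

    n_input_variants: int = 0
    n_indels_removed: int = 0
    n_adjacent_removed: int = 0
    n_maf_removed: int = 0
    n_missingness_removed: int = 0
    n_depth_masked_calls: int = 0
    n_samples_removed: int = 0
    n_retained: int = 0
    removed_samples: list = field(default_factory=list)

    def check(self) -> None:
        removed = (self.n_indels_removed + self.n_adjacent_removed
                   + self.n_maf_removed + self.n_missingness_removed)
        if self.n_retained != self.n_input_variants - removed:
            raise AssertionError("filter report does not balance")


def call_genotype_state(alt_fraction: float, config: Config | None = None) -> int:
    """Call one genotype state from an alternate-allele fraction.

    Returns a state code (see :mod:`pvpopgen.dataset`).  NaN -> missing.
    """
    cfg = config or Config()
    if alt_fraction is None or (isinstance(alt_fraction, float) and np.isnan(alt_fraction)):
        return MISSING
    f = float(alt_fraction)
    if f < 0.0 or f > 1.0:
        raise ValueError(f"allele fraction {f} outside [0, 1]")
    if f < cfg.hom_max_fraction:
        return HOM_REF
    if f > 1.0 - cfg.hom_max_fraction:
        return HOM_ALT
    if cfg.het_lo <= f <= cfg.het_hi:
        return HET
    return AMBIGUOUS


def call_genotype_states(dataset: VariantDataset, config: Config | None = None) -> VariantDataset:
    """Vectorised zygosity calling over the whole dataset (in place on a copy)."""
    cfg = config or Config()
    frac = dataset.alt_fraction
    if np.nanmin(frac, initial=0.0) < 0 or np.nanmax(frac, initial=0.0) > 1:
        raise ValueError("allele fractions outside [0, 1]")
    state = np.full(frac.shape, AMBIGUOUS, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        state[frac < cfg.hom_max_fraction] = HOM_REF
        state[frac > 1.0 - cfg.hom_max_fraction] = HOM_ALT
        state[(frac >= cfg.het_lo) & (frac <= cfg.het_hi)] = HET
    state[np.isnan(frac)] = MISSING
    out = dataset.copy()
    out.state = state
    return out


def _adjacent_run_mask(loci) -> np.ndarray:
    """True for every member of a run of variants at immediately adjacent
    positions on the same contig (the whole run is biologically unlikely)."""
    contig = loci["contig"].to_numpy()
    pos = loci["position"].to_numpy()
    order = np.lexsort((pos, contig))
    adjacent = np.zeros(len(loci), dtype=bool)
    for a, b in zip(order[:-1], order[1:]):
        if contig[a] == contig[b] and pos[b] - pos[a] == 1:
            adjacent[a] = adjacent[b] = True
    return adjacent


def apply_site_filters(dataset: VariantDataset, config: Config | None = None
                       ) -> tuple[VariantDataset, FilterReport]:
    """Apply the site-level filters in the documented order."""
    cfg = config or Config()
    if dataset.n_loci == 0 or dataset.n_samples == 0:
        raise ValueError("empty dataset")
    report = FilterReport(n_input_variants=dataset.n_loci)
    alive = np.ones(dataset.n_loci, dtype=bool)

    # 1. INDELs
    if "is_indel" in dataset.loci.columns:
        indel = dataset.loci["is_indel"].to_numpy(dtype=bool)
    else:
        indel = np.zeros(dataset.n_loci, dtype=bool)
    report.n_indels_removed = int(indel.sum())
    alive &= ~indel

    # 2. adjacent runs (computed among surviving SNPs)
    adjacent = _adjacent_run_mask(dataset.loci[alive])
    idx_alive = np.flatnonzero(alive)
    report.n_adjacent_removed = int(adjacent.sum())
    alive[idx_alive[adjacent]] = False

    # 3. depth masking (calls, not sites)
    ds = dataset.copy()
    low = (ds.depth < cfg.min_depth) & (ds.depth > 0)
    report.n_depth_masked_calls = int(low[:, alive].sum())
    ds.depth = np.where(low, 0, ds.depth)
    ds.alt_fraction = np.where(low, np.nan, ds.alt_fraction)
    ds.alt2_fraction = np.where(low, np.nan, ds.alt2_fraction)
    ds = call_genotype_states(ds, cfg)

    # 4. site missingness (missing or ambiguous calls do not count as called)
    called = ds.called_mask()
    missing_frac = (~called).sum(axis=0) / called.shape[0]
    too_missing = alive & (missing_frac >= cfg.max_site_missing)
    report.n_missingness_removed = int(too_missing.sum())
    alive &= ~too_missing

    # 5. population allele-frequency window
    with np.errstate(invalid="ignore"):
        dos = ds.dosage()
        freq = np.nanmean(np.where(called, dos, np.nan), axis=0)
    bad_freq = alive & (np.isnan(freq) | (freq < cfg.maf_lo) | (freq > cfg.maf_hi))
    report.n_maf_removed = int(bad_freq.sum())
    alive &= ~bad_freq

    report.n_retained = int(alive.sum())
    report.check()
    out = ds.subset(locus_idx=np.flatnonzero(alive))
    if "is_indel" in out.loci.columns:
        out.loci = out.loci.drop(columns=["is_indel"])
    log.info("site filters: %d -> %d variants (indel %d, adjacent %d, "
             "missing %d, freq %d; %d calls depth-masked)",
             report.n_input_variants, report.n_retained, report.n_indels_removed,
             report.n_adjacent_removed, report.n_missingness_removed,
             report.n_maf_removed, report.n_depth_masked_calls)
    return out, report


def apply_sample_filter(dataset: VariantDataset, config: Config | None = None
                        ) -> tuple[VariantDataset, FilterReport]:
    """Drop samples with more than the allowed fraction of missing calls."""
    cfg = config or Config()
    ds = dataset if dataset.state is not None else call_genotype_states(dataset, cfg)
    called = ds.called_mask()
    missing_frac = (~called).sum(axis=1) / called.shape[1]
    keep = missing_frac <= cfg.max_sample_missing
    if not keep.any():
        raise ValueError(
            f"all {ds.n_samples} samples exceed {cfg.max_sample_missing:.0%} missingness "
            f"(median missingness {np.median(missing_frac):.0%})")
    report = FilterReport(n_input_variants=ds.n_loci, n_retained=ds.n_loci)
    report.n_samples_removed = int((~keep).sum())
    report.removed_samples = list(ds.samples.index[~keep])
    if report.n_samples_removed:
        log.info("sample filter: removed %d samples (%s)", report.n_samples_removed,
                 ", ".join(report.removed_samples[:5]))
    return ds.subset(sample_idx=np.flatnonzero(keep)), report


def filter_dataset(dataset: VariantDataset, config: Config | None = None
                   ) -> tuple[VariantDataset, FilterReport]:
    """Site filters followed by the sample filter; one combined report."""
    ds, report = apply_site_filters(dataset, config)
    ds, sample_report = apply_sample_filter(ds, config)
    report.n_samples_removed = sample_report.n_samples_removed
    report.removed_samples = sample_report.removed_samples
    return ds, report
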