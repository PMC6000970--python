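"""End-to-end pipeline: filter -> classify -> diversity -> structure ->
differentiation -> phylogeography -> subgenome contrast, plus table export.

Each stage logs its counts to stderr and the whole run is deterministic for
a given config seed.  Export layouts follow the field's standard report
tables: per-gene diversity, per-SNP classification, per-subpopulation
diversity, pairwise differentiation (Nei distance above / Fst below the
diagonal) and the AMOVA partition (df, SS, MS, Est.Var, %).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as dv
from . import phylogeo as pg
from ._util import as_rng, haversine_km, spawn_seed
from .classify import classify_dataset
from .config import Config
from .dataset import HET, HOM_ALT, HOM_REF, VariantDataset, load_dataset
from .differentiation import (AmovaResult, amova, latitude_bins,
                              pairwise_differentiation)
from .filtering import FilterReport, filter_dataset
from .structure import (AdmixtureResult, classify_membership, fit_admixture,
                        genotype_distance, pcoa, select_k)
from .subgenome import subgenome_contrasts

log = logging.getLogger("pvpopgen")


@dataclass
class ResultsBundle:
    config: Config
    filter_report: FilterReport
    dataset: VariantDataset
    classification: pd.DataFrame
    gene_diversity: pd.DataFrame
    subpop_diversity: pd.DataFrame | None
    admixture: AdmixtureResult
    lnpd_by_k: dict
    chosen_k: int
    membership: list
    representative: dict
    pcoa_pct: np.ndarray
    differentiation: object
    amova_results: dict
    mantel: object
    lsa_consistent: np.ndarray
    tree: object
    divergence: object
    subgenome: pd.DataFrame


def _stage(name):
    log.info("stage: %s", name)


def run_pipeline(dataset: VariantDataset, config: Config | None = None,
                 reference: dict[str, str] | None = None) -> ResultsBundle:
    """Run every analysis stage on a loaded dataset."""
    cfg = config or Config()
    rng = as_rng(cfg.seed)

    _stage("filter")
    ds, report = filter_dataset(dataset, cfg)
    log.info("retained %d/%d variants, %d samples", report.n_retained,
             report.n_input_variants, ds.n_samples)
    dosage = ds.dosage()

    _stage("structure")
    lnpd_by_k = {}
    fits = {}
    for k in range(cfg.k_min, cfg.k_max + 1):
        fit = fit_admixture(dosage, k, n_burnin=cfg.n_burnin, n_iter=cfg.n_iter,
                            n_runs=cfg.n_runs, alpha=cfg.admixture_alpha,
                            seed=spawn_seed(rng), run_selection=cfg.run_selection)
        lnpd_by_k[k] = fit.lnPD_per_run
        fits[k] = fit
        log.info("K=%d lnP(D)=%s", k, [f"{v:.1f}" for v in fit.lnPD_per_run])
    chosen_k = select_k(lnpd_by_k)
    admixture = fits[chosen_k]
    cluster_names = [f"C{i + 1}" for i in range(chosen_k)]
    membership, representative = classify_membership(
        admixture, ds.sample_ids, accessions=ds.samples["accession_id"],
        threshold=cfg.membership_threshold,
        representative_threshold=cfg.representative_threshold,
        cluster_names=cluster_names)
    assigned = pd.Series([c.assigned for c in membership], index=ds.sample_ids)
    subpop = assigned.where(assigned != "admixed")

    _stage("classify")
    classification = classify_dataset(ds, reference=reference,
                                      subpop_labels=subpop, config=cfg)

    _stage("diversity")
    gene_rows = []
    phased = {}
    for contig, cols in ds.loci.groupby("contig").groups.items():
        cols = np.asarray(cols)
        geno = np.full((ds.n_samples, cols.size), -1, dtype=int)
        st = ds.state[:, cols]
        geno[st == HOM_REF] = 0
        geno[st == HET] = 1
        geno[st == HOM_ALT] = 2
        haps = dv.phase_haplotypes(geno, max_iter=cfg.phase_max_iter,
                                   tol=cfg.phase_tol, n_restarts=cfg.phase_restarts,
                                   seed=spawn_seed(rng))
        phased[contig] = haps
        sub = ds.loci.iloc[cols]
        if reference is not None and contig in reference:
            L = len(reference[contig])
        else:
            L = int(sub["position"].max()) if len(sub) else 1
        sd = dv.sequence_diversity(haps, L=max(L, 1))
        cls = classification.iloc[cols]
        gene_rows.append({
            "gene": sub["gene"].iloc[0], "contig": contig,
            "chromosome": sub["chromosome"].iloc[0],
            "subgenome": sub["subgenome"].iloc[0],
            "n_samples": ds.n_samples, "n_sites": L,
            "S_tot": sd.S_tot,
            "non_coding": int((cls["effect"] == "noncoding").sum()),
            "syn": int((cls["effect"] == "synonymous").sum()),
            "con": int((cls["conservation"] == "conservative").sum()),
            "non_con": int((cls["conservation"] == "non_conservative").sum()),
            "d": sd.snp_density_d, "pi": sd.pi, "sd_pi": sd.sd_pi,
            "theta_w": sd.theta_w, "sd_theta": sd.sd_theta,
            "h": sd.h, "Hd": sd.Hd, "sd_Hd": sd.sd_Hd,
            "tajima_D": sd.tajima_D, "fu_li_F": sd.fu_li_F,
        })
    gene_diversity = pd.DataFrame(gene_rows)

    subpop_diversity = None
    if subpop.notna().sum():
        labels = subpop.fillna("admixed").to_numpy()
        subpop_diversity = dv.group_diversity_summary(ds, labels).reset_index()

    _stage("differentiation")
    have_subpops = subpop.nunique() >= 2 and (subpop.value_counts() >= 2).all()
    diff = None
    amova_results: dict[str, AmovaResult] = {}
    if have_subpops:
        mask = subpop.notna().to_numpy()
        diff = pairwise_differentiation(dosage[mask], subpop[mask].to_numpy(),
                                        cap=cfg.nei_distance_cap,
                                        n_perm=cfg.n_permutations,
                                        seed=spawn_seed(rng))
        amova_results["subpopulation"] = amova(dosage[mask], subpop[mask].to_numpy(),
                                               n_perm=cfg.n_permutations,
                                               seed=spawn_seed(rng))
    amova_results["accession"] = amova(dosage, ds.samples["accession_id"].to_numpy(),
                                       n_perm=cfg.n_permutations, seed=spawn_seed(rng))
    amova_results["latitude_bin"] = amova(
        dosage, latitude_bins(ds.samples["latitude"]),
        n_perm=cfg.n_permutations, seed=spawn_seed(rng))

    _stage("phylogeography")
    gdist = genotype_distance(dosage)
    geo = haversine_km(ds.samples["latitude"].to_numpy(),
                       ds.samples["longitude"].to_numpy())
    mantel_res = pg.mantel(gdist, geo, n_perm=cfg.n_permutations,
                           seed=spawn_seed(rng), log_b=cfg.mantel_log_distance)
    _, lsa_consistent = pg.lsa_sweep(
        gdist, ds.samples["latitude"], ds.samples["longitude"],
        n_min=cfg.lsa_neighbors_min, n_max=cfg.lsa_neighbors_max,
        n_perm=cfg.lsa_permutations, seed=spawn_seed(rng),
        sample_ids=ds.sample_ids)
    pco = pcoa(gdist)

    seqs = pg.genotype_sequences(ds)
    tree = pg.upgma_bootstrap(seqs, ds.sample_ids, n_boot=cfg.n_bootstrap,
                              seed=spawn_seed(rng), distance=cfg.tree_distance)

    divergence = None
    if have_subpops and diff is not None and len(diff.groups) >= 2:
        # date the two most differentiated subpopulations against the outgroup
        i, j = np.unravel_index(np.argmax(diff.fst_pairwise), diff.fst_pairwise.shape)
        out_d = _outgroup_p_distance(ds)
        if out_d and out_d > 0:
            pdm = pg.p_distance_matrix(seqs)
            labels = subpop.fillna("admixed").to_numpy()
            divergence = pg.group_divergence(pdm, labels, diff.groups[i],
                                             diff.groups[j],
                                             outgroup_distance=out_d,
                                             calibration_mya=cfg.calibration_mya,
                                             net=True)

    _stage("subgenome")
    sub_contrast = subgenome_contrasts(ds, bin_bp=cfg.window_bp,
                                       min_mapped_fraction=cfg.contrast_min_mapped)

    return ResultsBundle(
        config=cfg, filter_report=report, dataset=ds,
        classification=classification, gene_diversity=gene_diversity,
        subpop_diversity=subpop_diversity, admixture=admixture,
        lnpd_by_k=lnpd_by_k, chosen_k=chosen_k, membership=membership,
        representative=representative, pcoa_pct=pco.pct_variance,
        differentiation=diff, amova_results=amova_results, mantel=mantel_res,
        lsa_consistent=lsa_consistent, tree=tree, divergence=divergence,
        subgenome=sub_contrast)


def _outgroup_p_distance(ds: VariantDataset) -> float | None:
    """Mean per-SNP divergence between the panel and the outgroup alleles."""
    og = ds.loci["outgroup"]
    if og.isna().all():
        return None
    freq = ds.allele_frequency()
    d = []
    for j, allele in enumerate(og):
        if not isinstance(allele, str):
            continue
        f_alt = freq[j]
        if np.isnan(f_alt):
            continue
        if allele == ds.loci["ref"].iloc[j]:
            d.append(f_alt)
        elif allele == ds.loci["alt1"].iloc[j]:
            d.append(1 - f_alt)
        else:
            d.append(1.0)
    return float(np.mean(d)) if d else None


# -- export -------------------------------------------------------------------

def export_tables(results: ResultsBundle, out_dir) -> list[Path]:
    """Write every result table as delimited text; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, sep="\t", index=False, **kw)
        written.append(path)

    _write(results.gene_diversity, "gene_diversity.tsv")
    _write(results.classification, "snp_classification.tsv")
    if results.subpop_diversity is not None:
        _write(results.subpop_diversity, "subpopulation_diversity.tsv")
    else:
        _write(pd.DataFrame(columns=["group", "N", "n_polymorphic",
                                     "private_alleles", "pct_polymorphic",
                                     "Ne", "I", "Ho", "He", "F"]),
               "subpopulation_diversity.tsv")

    # pairwise matrix: Nei distance upper triangle, Fst lower triangle
    if results.differentiation is not None:
        diff = results.differentiation
        g = len(diff.groups)
        combo = np.zeros((g, g))
        combo[np.triu_indices(g, 1)] = diff.nei_distance_pairwise[np.triu_indices(g, 1)]
        combo[np.tril_indices(g, -1)] = diff.fst_pairwise[np.tril_indices(g, -1)]
        pair = pd.DataFrame(combo, index=diff.groups, columns=diff.groups)
        pair.insert(0, "group", diff.groups)
        _write(pair, "pairwise_differentiation.tsv")
    else:
        _write(pd.DataFrame(columns=["group"]), "pairwise_differentiation.tsv")

    amova_frames = []
    for grouping, res in results.amova_results.items():
        frame = res.as_frame()
        frame.insert(0, "grouping", grouping)
        amova_frames.append(frame)
    amova_df = pd.concat(amova_frames) if amova_frames else \
        pd.DataFrame(columns=["grouping", "label", "df", "SS", "MS", "est_var", "pct"])
    amova_df = amova_df.rename(columns={"label": "Source", "est_var": "Est.Var",
                                        "pct": "%"})
    _write(amova_df, "amova.tsv")

    (out / "upgma.nwk").write_text(results.tree.newick + "\n")
    written.append(out / "upgma.nwk")

    q = pd.DataFrame(results.admixture.Q,
                     columns=[f"q{k + 1}" for k in range(results.chosen_k)])
    q.insert(0, "sample_id", results.dataset.sample_ids)
    q["assigned"] = [c.assigned for c in results.membership]
    _write(q, "membership.tsv")
    return written


def run_from_files(vcf, metadata, annotation=None, reference=None, outgroup=None,
                   config: Config | None = None) -> ResultsBundle:
    from .dataset import load_reference

    ds = load_dataset(vcf, metadata, annotation, reference, outgroup)
    ref = load_reference(reference) if reference else None
    return run_pipeline(ds, config=config, reference=ref)
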