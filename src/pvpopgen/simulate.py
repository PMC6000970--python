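"""Synthetic allotetraploid amplicon SNP panels with known truth.

The generator emulates the study design the package targets: ~36 switchgrass
accessions (~10 genotypes each) from 3 admixed genetic subpopulations with a
geographic gradient (isolation by distance), genotyped at ~21 amplicon
contigs spread over the K and N subgenomes of 12 candidate genes.
Inheritance is disomic within each subgenome (the allotetraploid behaves as
two independent diploid genomes); per-copy ancestries follow each
individual's admixture vector, subpopulation allele frequencies follow a
Balding-Nichols model around uniform ancestral frequencies, and read support
is Poisson depth with binomial allele sampling, so alternate-read fractions
and missing data look like real amplicon output.

Everything needed by the loaders is written as plain text (VCF, metadata
TSV, BED-like annotation, FASTA, outgroup table, truth JSON).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import as_rng, haversine_km
from .dataset import VariantDataset, write_vcf
from .differentiation import gst_from_freqs

log = logging.getLogger("pvpopgen")

_BASES = np.array(list("ACGT"))

# subpopulation geographic centres (lat, lon): a northern/upland cluster and
# two lowland clusters running west -> east, mirroring the panel's geography
_CENTRES = [(44.0, -100.0), (36.0, -97.0), (29.0, -82.0)]


@dataclass
class SimulationParams:
    n_subpops: int = 3
    divergence_F: float = 0.2
    n_accessions: int = 36
    samples_per_accession: int = 10
    n_genes: int = 12
    homoeolog_pairs: int = 9          # genes with both K and N copies
    contig_length: int = 2400
    snps_per_contig: int = 12
    admixture_alpha: float = 0.2
    accession_concentration: float = 60.0   # within-accession ancestry cohesion
    spatial_range_km: float = 600.0
    spatial_jitter_deg: float = 3.0
    mean_depth: float = 60.0
    missing_rate: float = 0.05
    sequencing_error: float = 0.01
    triallelic_rate: float = 0.06
    outgroup_divergence: float = 0.08
    seed: int = 0

    def __post_init__(self):
        for name in ("divergence_F", "admixture_alpha", "missing_rate",
                     "sequencing_error", "triallelic_rate", "outgroup_divergence"):
            v = getattr(self, name)
            if name != "admixture_alpha" and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if self.snps_per_contig * 2 > self.contig_length:
            raise ValueError("more SNPs requested than contig positions")


@dataclass
class SimulationTruth:
    sample_ids: list
    subpop_names: list
    true_Q: np.ndarray                   # samples x K
    true_allele_freqs: np.ndarray        # K x loci (alt-allele frequency)
    true_haplotypes: dict                # contig -> list per sample of (str, str)
    true_fst: np.ndarray                 # K x K pairwise Nei Gst from true freqs
    planted_snps: list                   # dicts describing planted classifier truths

    def to_json(self, path) -> None:
        payload = {
            "sample_ids": self.sample_ids,
            "subpop_names": self.subpop_names,
            "true_Q": np.round(self.true_Q, 6).tolist(),
            "true_allele_freqs": np.round(self.true_allele_freqs, 6).tolist(),
            "true_haplotypes": self.true_haplotypes,
            "true_fst": np.round(self.true_fst, 6).tolist(),
            "planted_snps": self.planted_snps,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _contig_layout(params: SimulationParams) -> pd.DataFrame:
    """Gene/subgenome layout: the first ``homoeolog_pairs`` genes get K and N
    copies, the rest a single copy alternating subgenome."""
    rows = []
    for g in range(params.n_genes):
        gene = f"G{g + 1:02d}"
        if g < params.homoeolog_pairs:
            for sg in ("K", "N"):
                rows.append({"gene": gene, "subgenome": sg,
                             "contig": f"{gene}_{sg}",
                             "chromosome": f"Chr{(g % 9) + 1:02d}{sg}"})
        else:
            sg = "K" if g % 2 == 0 else "N"
            rows.append({"gene": gene, "subgenome": sg,
                         "contig": f"{gene}_{sg}",
                         "chromosome": f"Chr{(g % 9) + 1:02d}{sg}"})
    return pd.DataFrame(rows)


def _annotation_for_contig(contig: str, gene: str, subgenome: str, chromosome: str,
                           length: int) -> list[dict]:
    """Fixed gene model: 5'UTR, exon, intron, exon, 3'UTR (frames supplied)."""
    u5 = max(length // 12, 30)
    exon1 = (u5 + 1, u5 + 600)
    intron = (exon1[1] + 1, exon1[1] + max(length // 3, 200))
    exon2 = (intron[1] + 1, min(intron[1] + 600, length - u5))
    rows = []
    common = {"contig": contig, "gene": gene, "subgenome": subgenome,
              "chromosome": chromosome, "strand": "+", "homoeolog_group": gene}
    rows.append({**common, "start": 1, "end": u5, "region": "UTR5", "frame": None})
    rows.append({**common, "start": exon1[0], "end": exon1[1], "region": "exon",
                 "frame": 0})
    rows.append({**common, "start": intron[0], "end": intron[1], "region": "intron",
                 "frame": None})
    frame2 = (exon1[1] - exon1[0] + 1) % 3
    rows.append({**common, "start": exon2[0], "end": exon2[1], "region": "exon",
                 "frame": frame2})
    if exon2[1] < length:
        rows.append({**common, "start": exon2[1] + 1, "end": length,
                     "region": "UTR3", "frame": None})
    return rows


def simulate_dataset(params: SimulationParams | None = None, out_dir=None,
                     seed: int | None = None
                     ) -> tuple[VariantDataset, SimulationTruth, pd.DataFrame]:
    """Generate a dataset, its truth, and the annotation table.

    When ``out_dir`` is given, all input files are also written there
    (deterministically for a given seed): data.vcf, metadata.tsv,
    annotation.tsv, reference.fasta, outgroup.tsv, truth.json.
    """
    params = params or SimulationParams()
    if seed is not None:
        params = dataclasses.replace(params, seed=seed)
    rng = as_rng(params.seed)
    K = params.n_subpops

    # --- accessions, geography, ancestry ------------------------------------
    centres = np.array(_CENTRES[:K]) if K <= len(_CENTRES) else \
        np.column_stack([rng.uniform(28, 46, K), rng.uniform(-105, -78, K)])
    acc_centre = rng.integers(0, K, size=params.n_accessions)
    acc_lat = centres[acc_centre, 0] + rng.normal(0, params.spatial_jitter_deg,
                                                  params.n_accessions)
    acc_lon = centres[acc_centre, 1] + rng.normal(0, params.spatial_jitter_deg * 2,
                                                  params.n_accessions)
    # ancestry weights decay with distance to each subpopulation centre
    all_lat = np.concatenate([acc_lat, centres[:, 0]])
    all_lon = np.concatenate([acc_lon, centres[:, 1]])
    dists = haversine_km(all_lat, all_lon)[:params.n_accessions, params.n_accessions:]
    weights = np.exp(-dists / params.spatial_range_km)
    weights /= weights.sum(axis=1, keepdims=True)
    acc_q = np.vstack([
        rng.dirichlet(np.maximum(params.admixture_alpha * K * w, 1e-3))
        for w in weights])

    n = params.n_accessions * params.samples_per_accession
    sample_ids, accession_ids = [], []
    q = np.zeros((n, K))
    lat = np.zeros(n)
    lon = np.zeros(n)
    ecotypes, ploidies = [], []
    i = 0
    for a in range(params.n_accessions):
        upland = acc_centre[a] == 0
        for s in range(params.samples_per_accession):
            sample_ids.append(f"A{a + 1:02d}_S{s + 1:02d}")
            accession_ids.append(f"A{a + 1:02d}")
            q[i] = rng.dirichlet(params.accession_concentration * acc_q[a]
                                 + 1e-3)
            lat[i], lon[i] = acc_lat[a], acc_lon[a]
            ecotypes.append("upland" if upland else "lowland")
            ploidies.append("8x" if (upland and rng.random() < 0.8) else "4x")
            i += 1
    samples = pd.DataFrame({
        "sample_id": sample_ids, "accession_id": accession_ids,
        "ecotype": ecotypes, "ploidy": ploidies,
        "latitude": np.round(lat, 4), "longitude": np.round(lon, 4),
    }).set_index("sample_id")

    # --- contigs, reference, annotation, loci --------------------------------
    layout = _contig_layout(params)
    annotation_rows = []
    reference: dict[str, str] = {}
    loci_rows = []
    positions_by_contig: dict[str, np.ndarray] = {}
    for row in layout.itertuples(index=False):
        seq = rng.choice(_BASES, size=params.contig_length)
        ann = _annotation_for_contig(row.contig, row.gene, row.subgenome,
                                     row.chromosome, params.contig_length)
        annotation_rows.extend(ann)
        # distinct, non-adjacent positions
        cand = rng.permutation(np.arange(2, params.contig_length - 2))
        pos = []
        taken = set()
        for p in cand:
            if len(pos) == params.snps_per_contig:
                break
            if p in taken or (p - 1) in taken or (p + 1) in taken:
                continue
            taken.add(p)
            pos.append(int(p))
        pos = np.sort(np.array(pos))
        positions_by_contig[row.contig] = pos
        reference[row.contig] = seq  # mutated below for planted codons
        for p in pos:
            loci_rows.append({"contig": row.contig, "position": int(p),
                              "gene": row.gene, "chromosome": row.chromosome,
                              "subgenome": row.subgenome})

    loci = pd.DataFrame(loci_rows)
    m = len(loci)

    # annotate region/frame per locus from the annotation table
    ann_df = pd.DataFrame(annotation_rows)
    regions, frames = [], []
    for r in loci.itertuples(index=False):
        hit = ann_df[(ann_df["contig"] == r.contig) & (ann_df["start"] <= r.position)
                     & (ann_df["end"] >= r.position)].iloc[0]
        if hit["region"] == "exon":
            frames.append((int(hit["frame"]) + r.position - int(hit["start"])) % 3)
        else:
            frames.append(None)
        regions.append(hit["region"])
    loci["region"] = regions
    loci["frame"] = frames
    loci["strand"] = "+"

    # --- alleles -------------------------------------------------------------
    ref_bases, alt_bases, alt2_bases = [], [], []
    planted = []
    for idx, r in enumerate(loci.itertuples(index=False)):
        seq = reference[r.contig]
        ref_b = seq[r.position - 1]
        choices = [b for b in "ACGT" if b != ref_b]
        alt_b = choices[rng.integers(0, 3)]
        ref_bases.append(ref_b)
        alt_bases.append(alt_b)
        alt2 = None
        if rng.random() < params.triallelic_rate:
            rem = [b for b in choices if b != alt_b]
            alt2 = rem[rng.integers(0, len(rem))]
        alt2_bases.append(alt2)

    # plant two classifier truths in the first gene's first exon:
    # a non-conservative S->Y substitution (TCC -> TAC) and a synonymous
    # GGT -> GGC change, at codon-aligned exonic positions
    first_contig = layout.iloc[0]["contig"]
    exon1 = ann_df[(ann_df["contig"] == first_contig)
                   & (ann_df["region"] == "exon")].iloc[0]
    exon_start = int(exon1["start"])
    contig_pos = set(loci.loc[loci["contig"] == first_contig, "position"])
    in_exon1 = [
        j for j in loci.index[(loci["contig"] == first_contig)
                              & (loci["position"] >= exon_start)
                              & (loci["position"] <= int(exon1["end"]))]
        # keep the planted codon clear of every other simulated SNP
        if not any(p in contig_pos for p in
                   range(int(loci.at[j, "position"]) - 3,
                         int(loci.at[j, "position"]) + 4)
                   if p != int(loci.at[j, "position"]))]
    # per-codon-offset substitution designs (codon, alt base, wild aa, mutant aa)
    nonsyn_by_off = {0: ("GAT", "T", "D", "Y"),   # GAT -> TAT, Asp -> Tyr
                     1: ("TCC", "A", "S", "Y"),   # TCC -> TAC, Ser -> Tyr
                     2: ("TGC", "G", "C", "W")}   # TGC -> TGG, Cys -> Trp
    syn_by_off = {0: ("CTG", "T", "L", "L"),      # CTG -> TTG, Leu -> Leu
                  2: ("GGT", "C", "G", "G")}      # GGT -> GGC, Gly -> Gly
    want = [("nonsynonymous", "non_conservative", nonsyn_by_off),
            ("synonymous", None, syn_by_off)]
    for j in in_exon1:
        if not want:
            break
        p = int(loci.at[j, "position"])
        off = (p - exon_start) % 3
        effect, cons, table = want[0]
        if off not in table:
            continue
        want.pop(0)
        codon, alt_b, aa_w, aa_m = table[off]
        codon_start = p - 1 - off  # 0-based codon start in the contig
        loci.at[j, "frame"] = off
        seq = np.array(list(reference[first_contig])) \
            if isinstance(reference[first_contig], str) \
            else reference[first_contig]
        seq[codon_start:codon_start + 3] = list(codon)
        reference[first_contig] = seq
        ref_bases[j] = codon[off]
        alt_bases[j] = alt_b
        alt2_bases[j] = None
        planted.append({"contig": first_contig, "position": p, "effect": effect,
                        "conservation": cons, "aa_wild": aa_w, "aa_mutant": aa_m})

    loci["ref"] = ref_bases
    loci["alt1"] = alt_bases
    loci["alt2"] = alt2_bases
    reference = {c: (v if isinstance(v, str) else "".join(v))
                 for c, v in reference.items()}

    # --- subpopulation allele frequencies (Balding-Nichols) ------------------
    p0 = rng.uniform(0.05, 0.95, size=m)
    F = params.divergence_F
    if F > 0:
        shape1 = p0 * (1 - F) / F
        shape2 = (1 - p0) * (1 - F) / F
        pk = rng.beta(shape1[None, :], shape2[None, :], size=(K, m))
        pk = np.clip(pk, 1e-4, 1 - 1e-4)
    else:
        pk = np.tile(p0, (K, 1))

    # --- haplotypes (disomic per contig), genotypes --------------------------
    # per-copy, per-locus cluster of origin (the admixture model proper, so
    # the drawn Q is the identifiable truth for recovery benchmarks)
    cum_q = np.cumsum(q, axis=1)
    u = rng.random((n, 2, m))
    anc = (u[..., None] > cum_q[:, None, None, :]).sum(axis=3)  # (n, 2, m)
    anc = np.minimum(anc, K - 1)
    locus_idx = np.arange(m)
    hap_alt = (rng.random((n, 2, m)) < pk[anc, locus_idx[None, None, :]]) \
        .astype(np.int8)
    true_haps: dict[str, list] = {}
    for contig, cols in loci.groupby("contig").groups.items():
        cols = np.asarray(cols)
        true_haps[contig] = [
            ("".join(map(str, hap_alt[i, 0, cols])),
             "".join(map(str, hap_alt[i, 1, cols])))
            for i in range(n)]

    dosage_alt = hap_alt.sum(axis=1)  # 0, 1, 2 alt copies

    # --- reads: depth, alt fraction, triallelic split, missingness -----------
    depth = rng.poisson(params.mean_depth, size=(n, m))
    drop = rng.random((n, m)) < params.missing_rate
    depth[drop] = 0
    e = params.sequencing_error
    p_alt_read = dosage_alt / 2 * (1 - 2 * e) + e
    alt_reads = rng.binomial(depth, p_alt_read)
    # a small share of alt reads belongs to the second alternate allele
    has_alt2 = np.array([a is not None for a in alt2_bases])
    alt2_reads = np.zeros_like(alt_reads)
    if has_alt2.any():
        alt2_reads[:, has_alt2] = rng.binomial(alt_reads[:, has_alt2], 0.10)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, alt_reads / np.maximum(depth, 1), np.nan)
        frac[depth == 0] = np.nan
        frac2 = np.where((depth > 0) & has_alt2[None, :],
                         alt2_reads / np.maximum(depth, 1), np.nan)
        frac2[depth == 0] = np.nan

    loci["outgroup"] = _outgroup_alleles(rng, loci, p0, params.outgroup_divergence)
    # planted sites are outgroup-anchored to the reference so the wild-type
    # orientation (and hence the planted labels) is deterministic
    for plant in planted:
        j = loci.index[(loci["contig"] == plant["contig"])
                       & (loci["position"] == plant["position"])][0]
        loci.at[j, "outgroup"] = loci.at[j, "ref"]
    loci["is_indel"] = False

    dataset = VariantDataset(samples=samples, loci=loci, depth=depth,
                             alt_fraction=frac, alt2_fraction=frac2)

    true_fst = np.zeros((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            true_fst[a, b] = true_fst[b, a] = gst_from_freqs(pk[[a, b]])
    truth = SimulationTruth(
        sample_ids=list(samples.index), subpop_names=[f"C{k + 1}" for k in range(K)],
        true_Q=q, true_allele_freqs=pk, true_haplotypes=true_haps,
        true_fst=true_fst, planted_snps=planted)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(dataset, out / "data.vcf")
        samples.reset_index().to_csv(out / "metadata.tsv", sep="\t", index=False)
        ann_out = ann_df.copy()
        ann_out["frame"] = ann_out["frame"].map(
            lambda v: "." if v is None or (isinstance(v, float) and np.isnan(v))
            else int(v))
        ann_out[["contig", "start", "end", "gene", "subgenome", "region", "frame",
                 "strand", "homoeolog_group", "chromosome"]].to_csv(
            out / "annotation.tsv", sep="\t", index=False)
        with open(out / "reference.fasta", "w") as fh:
            for contig, seq in reference.items():
                fh.write(f">{contig}\n")
                for k0 in range(0, len(seq), 80):
                    fh.write(seq[k0:k0 + 80] + "\n")
        og = loci[["contig", "position", "outgroup"]].rename(
            columns={"outgroup": "allele"})
        og.to_csv(out / "outgroup.tsv", sep="\t", index=False)
        truth.to_json(out / "truth.json")
        log.info("wrote synthetic dataset (%d samples x %d loci) to %s", n, m, out)
    return dataset, truth, ann_df


def _outgroup_alleles(rng, loci: pd.DataFrame, p0: np.ndarray,
                      divergence: float) -> list[str]:
    """Outgroup allele per site: the ancestral allele, mutated to a random
    other base at the given divergence rate."""
    out = []
    for j, r in enumerate(loci.itertuples(index=False)):
        ancestral = r.alt1 if p0[j] >= 0.5 else r.ref
        if rng.random() < divergence:
            others = [b for b in "ACGT" if b != ancestral]
            out.append(others[rng.integers(0, 3)])
        else:
            out.append(ancestral)
    return out


# -- recovery metrics ---------------------------------------------------------

def match_clusters(q_true: np.ndarray, q_est: np.ndarray) -> np.ndarray:
    """Column permutation of q_est best matching q_true (greedy correlation)."""
    K = q_true.shape[1]
    corr = np.corrcoef(q_true.T, q_est.T)[:K, K:]
    corr = np.nan_to_num(corr)
    perm = np.zeros(K, dtype=int)
    c = corr.copy()
    for _ in range(K):
        i, j = np.unravel_index(np.argmax(c), c.shape)
        perm[i] = j
        c[i, :] = -np.inf
        c[:, j] = -np.inf
    return q_est[:, perm]


def truth_report(truth: SimulationTruth, q_est: np.ndarray | None = None,
                 fst_est: np.ndarray | None = None,
                 phased: dict | None = None) -> dict:
    """Recovery metrics against the simulation truth."""
    report: dict = {}
    if q_est is not None:
        if q_est.shape[0] != truth.true_Q.shape[0]:
            raise ValueError("sample sets do not match")
        if q_est.shape[1] == truth.true_Q.shape[1]:
            qm = match_clusters(truth.true_Q, q_est)
            report["q_rmse"] = float(np.sqrt(np.mean((qm - truth.true_Q) ** 2)))
    if fst_est is not None:
        iu = np.triu_indices(truth.true_fst.shape[0], 1)
        diff = np.asarray(fst_est)[iu] - truth.true_fst[iu]
        report["fst_bias"] = float(diff.mean())
        report["fst_rmse"] = float(np.sqrt((diff**2).mean()))
    if phased is not None:
        errs, tot = 0, 0
        for contig, pairs in phased.items():
            true_pairs = truth.true_haplotypes.get(contig)
            if true_pairs is None:
                continue
            for (ea, eb), (ta, tb) in zip(pairs, true_pairs):
                direct = sum(x != y for x, y in zip(ea, ta)) \
                    + sum(x != y for x, y in zip(eb, tb))
                crossed = sum(x != y for x, y in zip(ea, tb)) \
                    + sum(x != y for x, y in zip(eb, ta))
                errs += min(direct, crossed)
                tot += 2 * len(ea)
        if tot:
            report["phase_mismatch_rate"] = errs / tot
    return report
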