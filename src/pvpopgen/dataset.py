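"""Unified in-memory dataset for amplicon SNP panels and its file loaders.

The central container is :class:`VariantDataset`: sample metadata, locus
annotation, and three samples x loci matrices (read depth, alternate-allele
fraction, called genotype state).  Alternate fractions are computed from
VCF per-sample allele depths (AD); for triallelic sites ``alt_fraction`` is
the summed non-reference fraction and ``alt2_fraction`` keeps the share of
the second alternate for classification.

Coordinates are 1-based throughout (VCF convention); annotation intervals
are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

log = logging.getLogger("pvpopgen")

# genotype-state codes
MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2
AMBIGUOUS = 3

STATE_NAMES = {MISSING: "missing", HOM_REF: "hom_ref", HET: "het",
               HOM_ALT: "hom_alt", AMBIGUOUS: "ambiguous"}

ECOTYPES = ("upland", "lowland", "unknown")
PLOIDIES = ("4x", "8x", "mixed", "unknown")
REGIONS = ("exon", "intron", "UTR5", "UTR3", "intergenic")

SAMPLE_COLUMNS = ["sample_id", "accession_id", "ecotype", "ploidy", "latitude", "longitude"]
LOCUS_COLUMNS = ["contig", "position", "ref", "alt1", "alt2", "gene", "chromosome",
                 "subgenome", "region", "frame", "strand", "outgroup"]


@dataclass
class VariantDataset:
    """Samples x loci SNP calls with allele fractions and depths.

    Attributes
    ----------
    samples : DataFrame indexed by sample_id (accession_id, ecotype, ploidy,
        latitude, longitude).
    loci : DataFrame with one row per variant site (columns
        ``LOCUS_COLUMNS``); ``alt2`` is None for biallelic sites.
    depth : (n, m) int array of total read depth.
    alt_fraction : (n, m) float array, NaN where depth == 0; summed
        non-reference read fraction.
    alt2_fraction : (n, m) float array; fraction of the second alternate
        allele (NaN where absent).
    state : (n, m) int8 array of genotype-state codes, or None before
        zygosity calling.
    """

    samples: pd.DataFrame
    loci: pd.DataFrame
    depth: np.ndarray
    alt_fraction: np.ndarray
    alt2_fraction: np.ndarray
    state: np.ndarray | None = None

    def __post_init__(self):
        n, m = self.n_samples, self.n_loci
        for name in ("depth", "alt_fraction", "alt2_fraction"):
            arr = getattr(self, name)
            if arr.shape != (n, m):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, m)}")
        if self.state is not None and self.state.shape != (n, m):
            raise ValueError("state matrix shape mismatch")
        zero = self.depth == 0
        if not np.all(np.isnan(self.alt_fraction[zero])):
            raise ValueError("alt_fraction must be missing exactly where depth == 0")
        with np.errstate(invalid="ignore"):
            frac = self.alt_fraction[~np.isnan(self.alt_fraction)]
        if frac.size and (frac.min() < 0 or frac.max() > 1):
            raise ValueError("alt_fraction outside [0, 1]")
        lat = self.samples["latitude"].to_numpy(dtype=float)
        lon = self.samples["longitude"].to_numpy(dtype=float)
        if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
            raise ValueError("latitude/longitude out of range")
        if self.samples.index.duplicated().any():
            raise ValueError("duplicate sample_id")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def copy(self) -> "VariantDataset":
        return VariantDataset(
            samples=self.samples.copy(),
            loci=self.loci.copy(),
            depth=self.depth.copy(),
            alt_fraction=self.alt_fraction.copy(),
            alt2_fraction=self.alt2_fraction.copy(),
            state=None if self.state is None else self.state.copy(),
        )

    def require_state(self) -> np.ndarray:
        if self.state is None:
            raise ValueError("genotype states not called yet; run call_genotype_states first")
        return self.state

    def dosage(self) -> np.ndarray:
        """Alternate-allele dosage per genotype: hom_ref 0, het 0.5, hom_alt 1.

        Ambiguous-zone and missing calls are NaN (they are excluded from all
        downstream allele-frequency computations).
        """
        state = self.require_state()
        dos = np.full(state.shape, np.nan)
        dos[state == HOM_REF] = 0.0
        dos[state == HET] = 0.5
        dos[state == HOM_ALT] = 1.0
        return dos

    def called_mask(self) -> np.ndarray:
        """True where the genotype contributes to frequencies (hom/het call)."""
        state = self.require_state()
        return (state == HOM_REF) | (state == HET) | (state == HOM_ALT)

    def allele_frequency(self) -> np.ndarray:
        """Per-locus population alternate-allele frequency (mean dosage)."""
        dos = self.dosage()
        with np.errstate(invalid="ignore"):
            return np.nanmean(dos, axis=0)

    def subset(self, sample_idx=None, locus_idx=None) -> "VariantDataset":
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        l = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        return VariantDataset(
            samples=self.samples.iloc[s].copy(),
            loci=self.loci.iloc[l].reset_index(drop=True),
            depth=self.depth[np.ix_(s, l)],
            alt_fraction=self.alt_fraction[np.ix_(s, l)],
            alt2_fraction=self.alt2_fraction[np.ix_(s, l)],
            state=None if self.state is None else self.state[np.ix_(s, l)],
        )


def load_metadata(path) -> pd.DataFrame:
    """Read the tab-delimited sample metadata table."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "accession_id": str})
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    bad_eco = set(df["ecotype"]) - set(ECOTYPES)
    if bad_eco:
        raise ValueError(f"unknown ecotype values: {sorted(bad_eco)}")
    bad_ploidy = set(df["ploidy"]) - set(PLOIDIES)
    if bad_ploidy:
        raise ValueError(f"unknown ploidy values: {sorted(bad_ploidy)}")
    return df.set_index("sample_id")


def load_annotation(path) -> pd.DataFrame:
    """Read the BED-like annotation table (1-based inclusive intervals).

    Columns: contig, start, end, gene, subgenome, region, frame, strand,
    homoeolog_group.  ``frame`` is the 0-based position within the codon of
    ``start`` for exon intervals ('.' elsewhere).
    """
    df = pd.read_csv(path, sep="\t", na_values=".",
                     dtype={"contig": str, "gene": str, "subgenome": str,
                            "region": str, "strand": str, "homoeolog_group": str})
    required = {"contig", "start", "end", "gene", "subgenome", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if "frame" not in df.columns:
        df["frame"] = np.nan
    if "strand" not in df.columns:
        df["strand"] = "+"
    if "homoeolog_group" not in df.columns:
        df["homoeolog_group"] = df["gene"]
    if "chromosome" not in df.columns:
        df["chromosome"] = "unknown"
    return df


def load_reference(path) -> dict[str, str]:
    """Read reference contig sequences from FASTA."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_outgroup_table(path) -> dict[tuple[str, int], str]:
    """Read outgroup alleles from a tab-delimited (contig, position, allele) table."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "allele": str})
    return {(r.contig, int(r.position)): r.allele for r in df.itertuples(index=False)}


def annotate_locus(contig: str, position: int, annotation: pd.DataFrame) -> dict:
    """Look up gene/region/subgenome/frame for a 1-based position."""
    rows = annotation[(annotation["contig"] == contig)
                      & (annotation["start"] <= position)
                      & (annotation["end"] >= position)]
    if rows.empty:
        log.warning("locus %s:%d outside annotated intervals; region=intergenic",
                    contig, position)
        return {"gene": "unknown", "chromosome": "unknown", "subgenome": "unknown",
                "region": "intergenic", "frame": None, "strand": "+"}
    row = rows.iloc[0]
    frame = None
    if row["region"] == "exon" and not pd.isna(row["frame"]):
        # frame of the interval start, propagated to the locus position
        offset = position - int(row["start"])
        frame = (int(row["frame"]) + offset) % 3
    return {"gene": row["gene"], "chromosome": row.get("chromosome", "unknown"),
            "subgenome": row["subgenome"], "region": row["region"],
            "frame": frame, "strand": row.get("strand", "+")}


def load_dataset(vcf_path, metadata_path, annotation_path=None,
                 reference_path=None, outgroup_path=None) -> VariantDataset:
    """Load a per-sample-AD VCF plus metadata/annotation into a VariantDataset.

    Every VCF sample must appear in the metadata table (hard error naming the
    first absent sample).  Loci outside any annotated interval are kept with
    region='intergenic'.  INDEL records are loaded and flagged so the filter
    stage can count them.
    """
    metadata = load_metadata(metadata_path)
    annotation = load_annotation(annotation_path) if annotation_path else None
    outgroup = load_outgroup_table(outgroup_path) if outgroup_path else {}
    if reference_path:
        load_reference(reference_path)  # validated for existence/parseability

    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    for s in vcf_samples:
        if s not in metadata.index:
            raise ValueError(f"VCF sample {s!r} absent from metadata")
    samples = metadata.loc[vcf_samples].copy()

    loci_rows = []
    depth_cols, frac_cols, frac2_cols = [], [], []
    n = len(vcf_samples)
    for var in vcf:
        alts = [a for a in var.ALT if a != "<NON_REF>"]
        if len(alts) < 1 or len(alts) > 2:
            log.warning("skipping site %s:%d with %d ALT alleles",
                        var.CHROM, var.POS, len(alts))
            continue
        is_indel = len(var.REF) != 1 or any(len(a) != 1 for a in alts)
        ad = var.format("AD")
        if ad is None:
            raise ValueError(f"site {var.CHROM}:{var.POS} lacks per-sample AD")
        ad = np.asarray(ad, dtype=float)
        ad[ad < 0] = 0.0  # cyvcf2 encodes missing AD as negative
        dp = ad.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(dp > 0, ad[:, 1:].sum(axis=1) / np.maximum(dp, 1), np.nan)
            frac[dp == 0] = np.nan
            if len(alts) == 2 and ad.shape[1] >= 3:
                frac2 = np.where(dp > 0, ad[:, 2] / np.maximum(dp, 1), np.nan)
                frac2[dp == 0] = np.nan
            else:
                frac2 = np.full(n, np.nan)
        ann = (annotate_locus(var.CHROM, var.POS, annotation) if annotation is not None
               else {"gene": "unknown", "chromosome": "unknown", "subgenome": "unknown",
                     "region": "intergenic", "frame": None, "strand": "+"})
        loci_rows.append({
            "contig": var.CHROM, "position": var.POS, "ref": var.REF,
            "alt1": alts[0], "alt2": alts[1] if len(alts) == 2 else None,
            "is_indel": is_indel,
            "outgroup": outgroup.get((var.CHROM, var.POS)),
            **ann,
        })
        depth_cols.append(dp.astype(int))
        frac_cols.append(frac)
        frac2_cols.append(frac2)

    if not loci_rows:
        raise ValueError("VCF contains no usable variant records")
    loci = pd.DataFrame(loci_rows)
    return VariantDataset(
        samples=samples,
        loci=loci,
        depth=np.column_stack(depth_cols),
        alt_fraction=np.column_stack(frac_cols),
        alt2_fraction=np.column_stack(frac2_cols),
    )


def write_vcf(dataset: VariantDataset, path) -> None:
    """Write the dataset back out as an uncompressed VCF v4.2 with AD fields.

    Depths are reconstructed as ref/alt splits consistent with the stored
    alternate fractions, so a write -> load round trip reproduces the
    depth and fraction matrices.
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">']
    for contig in dict.fromkeys(dataset.loci["contig"]):
        lines.append(f"##contig=<ID={contig}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
              "FORMAT", *dataset.sample_ids]
    lines.append("\t".join(header))
    dos_state = dataset.state
    for j, locus in enumerate(dataset.loci.itertuples(index=False)):
        alt = locus.alt1 if locus.alt2 in (None, "") or pd.isna(locus.alt2) \
            else f"{locus.alt1},{locus.alt2}"
        triallelic = "," in alt
        fields = [locus.contig, str(locus.position), ".", locus.ref, alt, ".",
                  "PASS", ".", "GT:AD"]
        for i in range(dataset.n_samples):
            dp = int(dataset.depth[i, j])
            if dp == 0:
                ad = "0,0,0" if triallelic else "0,0"
                fields.append(f"./.:{ad}")
                continue
            frac = dataset.alt_fraction[i, j]
            alt_total = int(round(frac * dp))
            refd = dp - alt_total
            if triallelic:
                frac2 = dataset.alt2_fraction[i, j]
                a2 = 0 if np.isnan(frac2) else int(round(frac2 * dp))
                a1 = alt_total - a2
                ad = f"{refd},{a1},{a2}"
            else:
                ad = f"{refd},{alt_total}"
            if dos_state is not None:
                st = dos_state[i, j]
                gt = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1"}.get(int(st), "./.")
            else:
                gt = "./."
            fields.append(f"{gt}:{ad}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def write_metadata(dataset: VariantDataset, path) -> None:
    dataset.samples.reset_index().to_csv(path, sep="\t", index=False)
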