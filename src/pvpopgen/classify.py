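"""Functional / frequency / prevalence classification of retained SNPs.

Per SNP this module derives: coding effect (synonymous / non-synonymous via
the standard genetic code), amino-acid conservation class (substitution-
matrix rule: BLOSUM62 score >= +1 is a conservative change), the wild-type
(likely ancestral) allele via the outgroup with a majority fallback, a
frequency class of the wild-type allele (rare / common / balanced), and
per-subpopulation prevalence (prevalent / diagnostic) plus an ecotype
predominance call (two-proportion chi-square).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from scipy import stats

from .config import Config

log = logging.getLogger("pvpopgen")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_MATRICES: dict[str, object] = {}


def _matrix(name: str):
    if name not in _MATRICES:
        _MATRICES[name] = substitution_matrices.load(name)
    return _MATRICES[name]


@dataclass
class SnpClassification:
    """Full annotation for one SNP."""

    region: str
    effect: str                      # synonymous | nonsynonymous | noncoding
    aa_wild: str | None = None
    aa_mutants: list = field(default_factory=list)
    conservation: str = "n/a"        # conservative | non_conservative | n/a
    wild_type_allele: str | None = None
    wild_type_source: str | None = None   # outgroup | majority
    wild_type_tied: bool = False
    wildtype_freq: float | None = None
    frequency_class: str | None = None    # rare | common | balanced
    prevalence: dict = field(default_factory=dict)
    ecotype_class: str | None = None


def codon_context(contig_seq: str, position: int, frame: int, strand: str = "+"):
    """Reference codon containing a 1-based position, given the codon frame
    (0-2 = offset of this position within its codon, on the coding strand)."""
    if frame is None or (isinstance(frame, float) and np.isnan(frame)):
        raise ValueError(f"exonic locus at position {position} lacks a codon frame")
    frame = int(frame)
    i = position - 1
    if strand == "+":
        start = i - frame
        codon = contig_seq[start:start + 3]
        offset = frame
    else:
        # frame counts along the coding (reverse) strand
        end = i + frame + 1
        codon = contig_seq[end - 3:end].translate(_COMPLEMENT)[::-1]
        offset = frame
    if len(codon) != 3:
        raise ValueError(f"codon at position {position} truncated by contig edge")
    return codon.upper(), offset


def _translate(codon: str) -> str:
    return str(Seq(codon).translate(table=standard_dna_table))


def coding_effect(ref: str, alts: list[str], codon: str, offset: int,
                  strand: str = "+") -> tuple[str, str, list[str]]:
    """Coding effect of substituting each alternate base into the codon.

    ``codon`` is the reference codon on the coding strand and ``offset`` the
    position of the SNP within it.  Returns (effect, wild aa, mutant aa per
    alternate).  The effect is synonymous only when every alternate encodes
    the reference amino acid.
    """
    base_ref = ref if strand == "+" else ref.translate(_COMPLEMENT)
    if codon[offset] != base_ref.upper():
        raise ValueError(
            f"codon {codon} position {offset} is {codon[offset]}, expected ref {base_ref}")
    aa_ref = _translate(codon)
    aa_alts = []
    for alt in alts:
        base = alt if strand == "+" else alt.translate(_COMPLEMENT)
        mutated = codon[:offset] + base.upper() + codon[offset + 1:]
        aa_alts.append(_translate(mutated))
    effect = "synonymous" if all(a == aa_ref for a in aa_alts) else "nonsynonymous"
    return effect, aa_ref, aa_alts


def conservation_class(aa_wild: str, aa_mutant: str, config: Config | None = None) -> str:
    """Conservative iff the substitution-matrix score is >= the threshold
    (identical amino acids are conservative)."""
    cfg = config or Config()
    mat = _matrix(cfg.blosum_matrix)
    for aa in (aa_wild, aa_mutant):
        if aa not in mat.alphabet or aa in "BZX*":
            raise ValueError(f"nonstandard amino acid {aa!r}")
    if aa_wild == aa_mutant:
        return "conservative"
    score = mat[aa_wild][aa_mutant]
    return "conservative" if score >= cfg.conservative_min_score else "non_conservative"


def assign_wild_type(ref: str, alts: list[str], allele_freqs: dict[str, float],
                     outgroup: str | None) -> tuple[str, str, bool]:
    """Pick the wild-type allele: the outgroup allele when it is observed,
    otherwise the most frequent allele (reference wins an exact tie, flagged).

    ``allele_freqs`` maps each observed allele to its population frequency.
    Returns (allele, source, tied_flag).
    """
    observed = [ref, *alts]
    if outgroup is not None and outgroup in observed:
        return outgroup, "outgroup", False
    best = max(allele_freqs.values())
    top = [a for a in observed if np.isclose(allele_freqs.get(a, 0.0), best)]
    if len(top) > 1:
        choice = ref if ref in top else top[0]
        return choice, "majority", True
    return top[0], "majority", False


def frequency_class(wildtype_freq: float, config: Config | None = None) -> str:
    """rare (<=0.25 or >=0.75), balanced ([0.40, 0.60]), common (the rest)."""
    cfg = config or Config()
    f = float(wildtype_freq)
    if f < 0.0 or f > 1.0:
        raise ValueError(f"frequency {f} outside [0, 1]")
    if f <= cfg.rare_lo or f >= cfg.rare_hi:
        return "rare"
    if cfg.balanced_lo <= f <= cfg.balanced_hi:
        return "balanced"
    return "common"


def subpopulation_prevalence(per_subpop_freqs: dict[str, float],
                             config: Config | None = None) -> dict[str, str]:
    """Prevalent/diagnostic call per subpopulation for one allele.

    Prevalent in P: the allele is present only in P, or its frequency is
    >= 0.75 in P and < 0.25 in every other subpopulation.  Diagnostic in P:
    frequency >= 0.50 in P and < 0.05 in every other.  A SNP meeting both
    definitions is reported as diagnostic.
    """
    cfg = config or Config()
    pops = list(per_subpop_freqs)
    if len(pops) < 2:
        raise ValueError("prevalence needs at least two subpopulations")
    out = {}
    for p in pops:
        fp = per_subpop_freqs[p]
        others = [per_subpop_freqs[q] for q in pops if q != p]
        only_here = fp > 0 and all(f == 0 for f in others)
        prevalent = only_here or (fp >= cfg.prevalent_focal_min
                                  and all(f < cfg.prevalent_other_max for f in others))
        diagnostic = (fp >= cfg.diagnostic_focal_min
                      and all(f < cfg.diagnostic_other_max for f in others))
        out[p] = "diagnostic" if diagnostic else ("prevalent" if prevalent else "none")
    return out


def ecotype_class(upland_counts: tuple[int, int], lowland_counts: tuple[int, int],
                  config: Config | None = None) -> str:
    """Two-proportion chi-square on mutant-allele counts.

    ``*_counts`` are (mutant allele copies, total allele copies) per ecotype.
    Significant difference with the higher frequency in upland ->
    'upland_predominant'; in lowland -> 'lowland_predominant'; else 'shared'.
    """
    cfg = config or Config()
    (mu, nu), (ml, nl) = upland_counts, lowland_counts
    if nu == 0 or nl == 0:
        log.warning("ecotype class: an ecotype has zero called genotypes; 'shared'")
        return "shared"
    table = np.array([[mu, nu - mu], [ml, nl - ml]], dtype=float)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return "shared"  # identical (all-0 or all-1) frequencies
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    if p > cfg.ecotype_alpha:
        return "shared"
    return "upland_predominant" if mu / nu > ml / nl else "lowland_predominant"


# -- dataset-level driver -----------------------------------------------------

def classify_dataset(dataset, reference: dict[str, str] | None = None,
                     subpop_labels: pd.Series | None = None,
                     config: Config | None = None) -> pd.DataFrame:
    """Classify every locus of a filtered dataset; returns one row per SNP."""
    cfg = config or Config()
    dos = dataset.dosage()
    rows = []
    eco = dataset.samples["ecotype"].to_numpy()
    for j, locus in enumerate(dataset.loci.itertuples(index=False)):
        alts = [locus.alt1] + ([locus.alt2] if isinstance(locus.alt2, str) else [])
        d = dos[:, j]
        called = ~np.isnan(d)
        alt_freq = float(np.mean(d[called])) if called.any() else np.nan
        freqs = {locus.ref: 1.0 - alt_freq}
        if len(alts) == 1:
            freqs[alts[0]] = alt_freq
        else:
            # split the summed alternate frequency by mean read share
            with np.errstate(invalid="ignore"):
                share2 = np.nanmean(
                    np.where(dataset.alt_fraction[:, j] > 0,
                             dataset.alt2_fraction[:, j] / dataset.alt_fraction[:, j],
                             np.nan))
            share2 = 0.0 if np.isnan(share2) else float(np.clip(share2, 0, 1))
            freqs[alts[0]] = alt_freq * (1 - share2)
            freqs[alts[1]] = alt_freq * share2

        outgroup = locus.outgroup if isinstance(locus.outgroup, str) else None
        wild, source, tied = assign_wild_type(locus.ref, alts, freqs, outgroup)
        wfreq = freqs[wild]
        fclass = frequency_class(wfreq, cfg)

        effect, aa_wild, aa_mutants, conservation = "noncoding", None, [], "n/a"
        if locus.region == "exon" and reference is not None and locus.contig in reference:
            codon, offset = codon_context(reference[locus.contig], locus.position,
                                          locus.frame, locus.strand)
            effect, aa_ref, aa_alts = coding_effect(locus.ref, alts, codon, offset,
                                                    locus.strand)
            # orient to wild-type: amino acid of the wild allele vs the others
            by_allele = dict(zip([locus.ref, *alts], [aa_ref, *aa_alts]))
            aa_wild = by_allele[wild]
            mutant_alleles = sorted((a for a in by_allele if a != wild),
                                    key=lambda a: -freqs.get(a, 0.0))
            aa_mutants = [by_allele[a] for a in mutant_alleles]
            if effect == "nonsynonymous" and aa_mutants:
                if "*" in (aa_wild, aa_mutants[0]):
                    # nonsense/stop-loss changes are maximally disruptive
                    conservation = "non_conservative"
                else:
                    conservation = conservation_class(aa_wild, aa_mutants[0], cfg)

        prevalence: dict[str, str] = {}
        if subpop_labels is not None:
            labels = subpop_labels.reindex(dataset.samples.index)
            per_pop = {}
            for pop, idx in labels.groupby(labels).groups.items():
                sel = dataset.samples.index.isin(idx)
                dsel = d[sel]
                dsel = dsel[~np.isnan(dsel)]
                if dsel.size:
                    af = float(np.mean(dsel))
                    per_pop[pop] = af if wild != locus.ref else 1.0 - af
            if len(per_pop) >= 2:
                # prevalence refers to the mutant (non-wild-type) allele
                mut = {p: 1.0 - f for p, f in per_pop.items()}
                prevalence = subpopulation_prevalence(mut, cfg)

        up = called & (eco == "upland")
        lo = called & (eco == "lowland")
        mut_freq = (1.0 - wfreq)

        def _counts(mask):
            # mutant allele copies: dosage counts alt copies; flip if wild is alt
            vals = d[mask]
            copies = np.round(2 * vals).sum() if wild == locus.ref \
                else np.round(2 * (1 - vals)).sum()
            return int(copies), int(2 * mask.sum())

        eclass = ecotype_class(_counts(up), _counts(lo), cfg) \
            if up.any() or lo.any() else None

        rows.append({
            "gene": locus.gene, "contig": locus.contig, "position": locus.position,
            "chromosome": locus.chromosome, "subgenome": locus.subgenome,
            "region": locus.region, "effect": effect,
            "aa_wild": aa_wild, "aa_mutants": "/".join(aa_mutants) or None,
            "conservation": conservation,
            "wild_type_allele": wild, "wild_type_source": source,
            "wild_type_tied": tied, "wildtype_freq": wfreq,
            "frequency_class": fclass,
            "prevalence": ";".join(f"{p}:{v}" for p, v in sorted(prevalence.items()))
                          or None,
            "ecotype_class": eclass,
            "mutant_freq": mut_freq,
        })
    return pd.DataFrame(rows)
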