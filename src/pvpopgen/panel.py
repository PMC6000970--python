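"""Bundled worked-example data: a published 12-gene switchgrass amplicon panel.

These small tables summarise a candidate-gene survey of 372 switchgrass
(Panicum virgatum) genotypes: 251 retained SNPs across 21 amplicon contigs in
the two homoeologous subgenomes (K/N).  They serve as frozen inputs for the
package's worked examples and validation suite — the classifier and the
reporting arithmetic can be exercised against printed values without any
external download.

Three tables are provided:

* ``nonsynonymous_substitutions()`` — the 49 non-synonymous SNPs with the
  reference/alternate/outgroup (Setaria italica) amino acids, the wild-type
  and mutant allele frequencies (percent), and the published
  conservative / non-conservative call for each substitution.
* ``gene_summary()`` — per-contig polymorphism and diversity summary
  (segregating sites, site-category counts, SNP density, pi, Watterson's
  theta, haplotype counts, Tajima's D).
* ``amova_components()`` — estimated variance components of three published
  hierarchical AMOVA layouts (latitude bins, accessions, subpopulations).
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

# gene contig chromosome aa_pos region ref_aa alt1_aa alt2_aa outgroup_aa
# freq_wild freq_mut1 freq_mut2 published_class
_SUBSTITUTIONS_TSV = """\
gene	contig	chromosome	aa_pos	region	ref_aa	alt1_aa	alt2_aa	outgroup_aa	freq_wild	freq_mut1	freq_mut2	published_class
GI	contig15400	Chr05K	155	Exon7	E	K	.	E	91.59	8.41	.	Con
GI	contig15400	Chr05K	175	Exon7	S	Y	.	S	80.32	19.68	.	Non Con
GI	contig15400	Chr05K	177	Exon7	G	D	.	D	32.80	67.20	.	Non Con
GI	contig15400	Chr05K	180	Exon7	G	R	.	G	92.79	7.21	.	Non Con
GI	contig15400	Chr05K	234	Exon9	C	F	Y	C	79.82	19.59	0.58	Non Con
GI	contig01489	Chr05N	63	Exon5	W	S	.	S	37.50	62.50	.	Non Con
GI	contig01489	Chr05N	185	Exon7	R	Q	.	R	65.84	34.16	.	Con
GI	contig01489	Chr05N	960	Exon14	F	L	.	L	35.83	64.17	.	Non Con
PHYB	contig13571	Chr09N	661	Exon2	S	C	.	S	63.64	36.36	.	Non Con
PHYB	contig13571	Chr09N	702	Exon2	V	I	.	V	79.13	20.87	.	Con
PHYB	contig13571	Chr09N	713	Exon2	Y	D	.	D	50.30	49.70	.	Non Con
HD1	contig03275	Chr04K	11	Exon1	E	M	.	E	85.98	14.02	.	Non Con
HD1	contig03275	Chr04K	32	Exon1	A	T	.	A	94.56	5.44	.	Non Con
HD1	contig03275	Chr04K	35	Exon1	G	S	.	S	60.63	39.37	.	Non Con
PGM	contig17299	Chr09K	351	Exon6	A	V	.	A	73.21	26.79	.	Non Con
TB1	contig06045	Chr09K	57	Exon1	G	D	.	G	91.61	8.39	.	Non Con
TB1	contig06045	Chr09K	213	Exon1	G	D	.	G	89.76	10.24	.	Non Con
TB1	contig06045	Chr09K	337	Exon1	I	V	.	L	56.64	43.36	.	Con
TB1	contig76312	Chr09N	51	Exon1	H	Y	.	H	88.06	11.94	.	Con
TB1	contig76312	Chr09N	89	Exon1	A	P	.	A	92.42	7.58	.	Non Con
TB1	contig76312	Chr09N	137	Exon1	S	P	.	S	92.77	7.23	.	Non Con
TB1	contig76312	Chr09N	193	Exon1	I	V	.	V	60.26	39.74	.	Con
TB1	contig76312	Chr09N	321	Exon1	N	S	.	N	91.87	8.13	.	Con
PHYC	contig03093	Chr09N	422	Exon1	V	L	.	L	45.71	54.29	.	Con
PHYC	contig03093	Chr09N	966	Exon3	E	V	.	V	42.90	57.10	.	Non Con
PHYC	contig03093	Chr09N	1029	Exon3	P	A	.	P	81.03	18.97	.	Non Con
PHYC	contig03093	Chr09N	1031	Exon3	K	E	.	K	76.66	23.34	.	Con
PHYC	contig03093	Chr09N	1041	Exon3	K	N	.	K	83.44	16.56	.	Non Con
PHYC	contig03093	Chr09N	1069	Exon1	L	W	.	L	94.26	5.74	.	Non Con
PHYC	contig03093	Chr09N	1104	Exon1	L	H	.	L	67.70	32.30	.	Non Con
VRN3	contig07490	Chr03N	238	Exon2	E	D	.	E	89.78	10.22	.	Con
VRN3	contig07490	Chr03N	286	Exon3	L	M	.	L	93.11	6.89	.	Con
VRN3	contig07490	Chr03N	295	Exon3	T	A	.	T	90.10	9.90	.	Non Con
VRN3	contig07490	Chr03N	412	Exon4	P	R	.	P	91.53	8.47	.	Non Con
VRN3	contig07490	Chr03N	493	Exon4	L	S	.	S	84.26	15.74	.	Non Con
VRN3	contig07490	Chr03N	511	Exon4	N	K	.	N	93.63	6.37	.	Non Con
VRN3	contig07490	Chr03N	600	Exon4	G	V	.	E	88.59	11.41	.	Non Con
VRN3	contig16433	Chr03K	144	Exon2	P	A	.	P	90.45	9.55	.	Non Con
VRN3	contig16433	Chr03K	398	Exon4	V	I	.	A	93.98	6.02	.	Con
VRN3	contig16433	Chr03K	409	Exon4	S	N	.	S	89.42	10.58	.	Con
VRN3	contig16433	Chr03K	450	Exon4	D	G	.	G	43.61	56.39	.	Non Con
VRN3	contig16433	Chr03K	569	Exon4	Q	E	.	R	88.36	11.64	.	Con
VRN3	contig16433	Chr03K	682	Exon4	L	Q	.	Q	28.61	71.39	.	Non Con
DW3	contig26301	Chr06K	672	Exon3	E	G	.	E	94.29	5.71	.	Non Con
DW3	contig26301	Chr06K	751	Exon3	M	V	.	M	21.22	78.78	.	Con
DW3	contig117938	Chr06N	713	Exon3	I	M	.	M	87.84	12.16	.	Con
DW3	contig26301	Chr06N	897	Exon3	I	V	.	V	82.96	17.04	.	Con
DW3	contig117938	Chr06N	872	Exon3	T	A	S	A	78.04	21.96	0.30	Non Con
FLD	contig01920	Chr07N	511	Exon1	S	G	.	G	76.70	23.30	.	Non Con
"""

# gene contig chromosome n_samples n_sites coding_len S_tot non_coding syn
# con non_con d pi sd_pi theta_w sd_theta h Hd sd_Hd tajima_D
# pi/theta are per-site values x 1e-3 as published; d is percent = 100*S/L.
_GENE_SUMMARY_TSV = """\
gene	contig	chromosome	n_samples	n_sites	coding_len	S_tot	non_coding	syn	con	non_con	d	pi	sd_pi	theta_w	sd_theta	h	Hd	sd_Hd	tajima_D
PHYC	contig03093	Chr09N	353	3224	2279	20	7	6	2	5	0.620	1.68	0.04	0.87	0.25	91	0.963	0.002	0.362
TE	contig99597	Chr05K	351	2088	278	21	21	0	0	0	1.006	3.43	0.08	1.40	0.31	84	0.883	0.010	0.138
TE	contig04674	Chr05N	334	2088	278	21	20	1	0	0	1.006	3.78	0.09	1.58	0.34	110	0.959	0.003	0.316
VRN3	contig07490	Chr03N	337	2258	1771	12	1	4	2	5	0.531	1.30	0.05	0.74	0.21	22	0.759	0.013	0.723
VRN3	contig16433	Chr03K	356	2258	1773	10	3	1	3	3	0.443	0.95	0.03	0.62	0.19	30	0.728	0.016	0.62
DW3	contig26301	Chr06K	327	2207	2207	5	2	0	2	1	0.227	0.56	0.02	0.32	0.14	10	0.629	0.018	1.267
DW3	contig117938	Chr06N	337	2198	2198	4	2	0	1	1	0.182	0.55	0.02	0.25	0.13	14	0.714	0.010	0.793
FLD	contig102960	Chr07K	346	2329	1395	3	2	1	0	0	0.129	0.10	0.01	0.18	0.10	5	0.207	0.020	-0.588
FLD	contig01920	Chr07N	339	2330	1395	1	0	0	0	1	0.043	0.15	0.01	0.06	0.06	2	0.346	0.017	1.253
GI	contig15400	Chr05K	342	3456	1185	20	13	2	1	4	0.608	1.71	0.06	0.81	0.18	83	0.904	0.006	-0.264
GI	contig01489	Chr05N	312	3464	1185	10	7	0	1	2	0.289	1.05	0.03	0.40	0.13	22	0.757	0.013	1.655
FLT	contig09545	Chr07K	365	1826	195	17	17	0	0	0	0.931	1.97	0.05	1.30	0.31	64	0.931	0.005	-0.103
FLT	contig08422	Chr07N	339	2181	195	21	21	0	0	0	0.963	2.85	0.04	1.34	0.29	62	0.899	0.006	0.63
PHYB	contig13571	Chr09N	350	3198	2758	4	1	0	1	2	0.125	0.55	0.01	0.17	0.09	7	0.697	0.009	3.265
PHYB	contig21054	Chr09K	342	3194	2758	7	6	1	0	0	0.219	0.49	0.01	0.30	0.12	12	0.666	0.012	0.771
HD1	contig03275	Chr04K	306	2220	1104	7	2	2	0	3	0.360	0.93	0.44	0.44	0.17	8	0.776	0.008	2.082
HD1	contig05584	Chr04N	363	2140	1113	17	17	0	0	0	0.280	1.66	0.04	1.11	0.27	30	0.901	0.005	-0.142
PGM	contig17299	Chr09K	343	3120	1634	8	5	2	0	1	0.256	0.59	0.36	0.36	0.13	28	0.848	0.008	1.27
PGM	contig200892	Chr09N	315	696	391	7	4	3	0	0	1.006	3.3	0.05	1.40	0.53	13	0.780	0.007	1.328
TB1	contig06045	Chr09K	339	2428	1109	10	2	5	1	2	0.412	1.42	0.03	0.59	0.21	38	0.817	0.010	1.625
TB1	contig76312	Chr09N	314	2597	1115	26	16	5	3	2	1.001	2.53	0.07	1.41	0.37	84	0.926	0.005	0.037
"""

# Published hierarchical AMOVA variance components (among groups, among
# individuals within groups, within individuals) and the printed percentages.
_AMOVA_COMPONENTS = {
    "latitude_bin": {"est_var": (8.09, 39.32, 7.20), "published_pct": (15, 72, 13)},
    "accession": {"est_var": (14.92, 31.98, 7.20), "published_pct": (28, 59, 13)},
    "subpopulation": {"est_var": (22.69, 32.61, 6.96), "published_pct": (37, 52, 11)},
}


def nonsynonymous_substitutions() -> pd.DataFrame:
    """The 49 non-synonymous substitutions of the bundled panel.

    Columns include the reference (``ref_aa``), alternate (``alt1_aa``,
    ``alt2_aa``) and outgroup (``outgroup_aa``) amino acids, allele
    frequencies in percent, and the published conservation call.
    Missing alternates are NaN.
    """
    df = pd.read_csv(StringIO(_SUBSTITUTIONS_TSV), sep="\t", na_values=".")
    return df


def gene_summary() -> pd.DataFrame:
    """Per-contig polymorphism/diversity summary of the bundled panel."""
    return pd.read_csv(StringIO(_GENE_SUMMARY_TSV), sep="\t")


def amova_components() -> dict:
    """Published AMOVA variance components keyed by grouping factor."""
    return {k: dict(v) for k, v in _AMOVA_COMPONENTS.items()}


def substitution_pairs(df: pd.DataFrame | None = None) -> list[tuple[str, str]]:
    """(wild-type, primary mutant) amino-acid pairs for the bundled panel.

    The wild-type amino acid is the outgroup state when it is observed among
    the reference/alternate amino acids; otherwise the majority amino acid is
    wild-type (orientation then defaults to the reference amino acid, which
    never changes a symmetric substitution-matrix score).  The primary mutant
    is the highest-frequency observed amino acid that is not wild-type.
    """
    if df is None:
        df = nonsynonymous_substitutions()
    pairs: list[tuple[str, str]] = []
    for row in df.itertuples(index=False):
        observed = [row.ref_aa, row.alt1_aa]
        if isinstance(row.alt2_aa, str):
            observed.append(row.alt2_aa)
        if row.outgroup_aa in observed:
            wild = row.outgroup_aa
        else:
            wild = row.ref_aa  # majority fallback; scores are symmetric
        mutants = [a for a in observed if a != wild]
        pairs.append((wild, mutants[0]))
    return pairs
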