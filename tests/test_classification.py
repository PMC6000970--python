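"""Coding effect, conservation, wild-type, frequency class, prevalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvpopgen import panel
from pvpopgen.classify import (assign_wild_type, coding_effect,
                               conservation_class, ecotype_class,
                               frequency_class, subpopulation_prevalence)


class TestCodingEffect:
    def test_synonymous_third_position(self):
        effect, aa_ref, aa_alts = coding_effect("T", ["C"], "GGT", 2)
        assert effect == "synonymous"
        assert aa_ref == "G" and aa_alts == ["G"]

    def test_nonsynonymous_g_to_d(self):
        # GGT (Gly) -> GAT (Asp) at the second codon position
        effect, aa_ref, aa_alts = coding_effect("G", ["A"], "GGT", 1)
        assert effect == "nonsynonymous"
        assert (aa_ref, aa_alts) == ("G", ["D"])

    def test_triallelic_two_mutant_amino_acids(self):
        # TGC (Cys) -> TTC (Phe) / TAC (Tyr): both mutants reported
        effect, aa_ref, aa_alts = coding_effect("G", ["T", "A"], "TGC", 1)
        assert effect == "nonsynonymous"
        assert aa_ref == "C" and aa_alts == ["F", "Y"]

    def test_reverse_strand(self):
        # coding codon ATG on the reverse strand; the forward-strand ref C
        # complements to the codon's third base G, and C->T gives ATA (Ile)
        effect, aa_ref, aa_alts = coding_effect("C", ["T"], "ATG", 2, "-")
        assert effect == "nonsynonymous"
        assert aa_ref == "M" and aa_alts == ["I"]

    def test_codon_ref_mismatch_is_error(self):
        with pytest.raises(ValueError, match="expected ref"):
            coding_effect("A", ["G"], "GGT", 0)


class TestConservation:
    @pytest.mark.parametrize("wild,mutant,expected", [
        ("S", "Y", "non_conservative"),
        ("V", "I", "conservative"),
        ("A", "A", "conservative"),
        ("K", "E", "conservative"),
        ("A", "T", "non_conservative"),   # BLOSUM62 score 0 is non-conservative
        ("L", "F", "non_conservative"),
    ])
    def test_pairs(self, wild, mutant, expected):
        assert conservation_class(wild, mutant) == expected

    def test_nonstandard_symbol_is_error(self):
        with pytest.raises(ValueError):
            conservation_class("S", "X")

    def test_bundled_panel_reproduced_exactly(self):
        """The substitution-matrix rule reproduces every published
        conservation label of the bundled 49-substitution panel."""
        df = panel.nonsynonymous_substitutions()
        pairs = panel.substitution_pairs(df)
        calls = [conservation_class(w, m) for w, m in pairs]
        expected = ["non_conservative" if lab == "Non Con" else "conservative"
                    for lab in df["published_class"]]
        assert calls == expected

    def test_symmetry(self):
        for w, m in [("S", "Y"), ("K", "E"), ("G", "D")]:
            assert conservation_class(w, m) == conservation_class(m, w)


class TestWildType:
    def test_outgroup_match(self):
        allele, source, tied = assign_wild_type("G", ["A"], {"G": 0.6, "A": 0.4}, "G")
        assert (allele, source, tied) == ("G", "outgroup", False)

    def test_outgroup_matches_alternate(self):
        allele, source, _ = assign_wild_type("G", ["A"], {"G": 0.6, "A": 0.4}, "A")
        assert (allele, source) == ("A", "outgroup")

    def test_majority_fallback(self):
        allele, source, _ = assign_wild_type("G", ["A"], {"G": 0.7, "A": 0.3}, "C")
        assert (allele, source) == ("G", "majority")

    def test_exact_tie_prefers_reference_and_flags(self):
        allele, source, tied = assign_wild_type("G", ["A"], {"G": 0.5, "A": 0.5}, None)
        assert allele == "G" and tied


class TestFrequencyClass:
    @pytest.mark.parametrize("freq,expected", [
        (0.9179, "rare"), (0.10, "rare"), (0.25, "rare"), (0.75, "rare"),
        (0.33, "common"), (0.70, "common"),
        (0.50, "balanced"), (0.40, "balanced"), (0.60, "balanced"),
    ])
    def test_examples(self, freq, expected):
        assert frequency_class(freq) == expected

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            frequency_class(1.5)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(deadline=None, max_examples=300)
    def test_partition_complete_and_disjoint(self, f):
        cls = frequency_class(f)
        matches = [
            f <= 0.25 or f >= 0.75,                      # rare
            0.40 <= f <= 0.60,                           # balanced
            (0.25 < f < 0.40) or (0.60 < f < 0.75),      # common
        ]
        assert sum(matches) == 1
        assert cls == ["rare", "balanced", "common"][matches.index(True)]


class TestPrevalence:
    def test_prevalent(self):
        out = subpopulation_prevalence({"C1": 0.80, "C2": 0.10, "C3": 0.20})
        assert out == {"C1": "prevalent", "C2": "none", "C3": "none"}

    def test_diagnostic(self):
        out = subpopulation_prevalence({"C1": 0.60, "C2": 0.02, "C3": 0.04})
        assert out["C1"] == "diagnostic"

    def test_diagnostic_wins_over_prevalent(self):
        out = subpopulation_prevalence({"C1": 0.90, "C2": 0.0, "C3": 0.0})
        assert out["C1"] == "diagnostic"

    def test_symmetric_case_none(self):
        out = subpopulation_prevalence({"C1": 0.5, "C2": 0.5, "C3": 0.5})
        assert set(out.values()) == {"none"}

    def test_single_subpopulation_is_error(self):
        with pytest.raises(ValueError):
            subpopulation_prevalence({"C1": 0.9})

    def test_relabeling_invariance(self):
        freqs = {"C1": 0.80, "C2": 0.10, "C3": 0.20}
        renamed = {"X": 0.80, "Y": 0.10, "Z": 0.20}
        out1 = subpopulation_prevalence(freqs)
        out2 = subpopulation_prevalence(renamed)
        assert [out1[k] for k in ("C1", "C2", "C3")] == \
            [out2[k] for k in ("X", "Y", "Z")]


class TestEcotypeClass:
    def test_strong_difference_upland(self):
        # chi-square on 80/100 vs 5/100: p << 0.05
        assert ecotype_class((80, 100), (5, 100)) == "upland_predominant"

    def test_identical_frequencies_shared(self):
        assert ecotype_class((30, 100), (30, 100)) == "shared"

    def test_empty_ecotype_shared(self):
        assert ecotype_class((0, 0), (30, 100)) == "shared"

    def test_planted_differential_snps_recovered(self):
        """Simulated ecotype-differential SNPs at a large effect size are
        detected with >= 95% sensitivity."""
        rng = np.random.default_rng(1)
        n_each = 150
        hits = 0
        trials = 200
        for _ in range(trials):
            up = rng.binomial(2 * n_each, 0.55)
            lo = rng.binomial(2 * n_each, 0.15)
            if ecotype_class((up, 2 * n_each), (lo, 2 * n_each)) == \
                    "upland_predominant":
                hits += 1
        assert hits / trials >= 0.95
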