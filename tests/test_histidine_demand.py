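import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spacerhis.errors import ConsistencyError, UndefinedValueError
from spacerhis.genome_io import Proteome
from spacerhis.histidine_demand import (
    GenomeHisSummary,
    demand_curve,
    fraction_min_demand,
    fraction_min_his,
    harmonic_mean,
    high_demand_genes,
    his_count_curve,
    histidine_profile,
    proteome_summary,
)

pos_int_lists = st.lists(st.integers(min_value=1, max_value=500),
                         min_size=1, max_size=30)


class TestHarmonicMean:
    @pytest.mark.parametrize("d,expected", [
        ([1, 1], 1.0),
        ([2, 4], 8 / 3),          # 2 / (1/2 + 1/4)
        ([5], 5.0),
    ])
    def test_examples(self, d, expected):
        assert harmonic_mean(d) == pytest.approx(expected)

    def test_empty_list_undefined(self):
        with pytest.raises(UndefinedValueError):
            harmonic_mean([])

    def test_nonpositive_rejected(self):
        with pytest.raises(UndefinedValueError):
            harmonic_mean([3, 0])

    @settings(derandomize=True, max_examples=300)
    @given(pos_int_lists)
    def test_am_hm_inequality(self, d):
        hm = harmonic_mean(d)
        am = sum(d) / len(d)
        assert hm <= am + 1e-9
        if len(set(d)) > 1:
            assert hm < am
        assert min(d) - 1e-9 <= hm <= max(d) + 1e-9


class TestHistidineProfile:
    def test_adjacent_pair(self):
        p = histidine_profile("g", "MHH")
        assert (p.h, p.positions, p.distances) == (2, (1, 2), (1,))
        assert p.H_harm == pytest.approx(1.0)
        assert p.D == pytest.approx(2.0)

    def test_spaced_triple(self):
        protein = "A" * 10 + "H" + "A" + "H" + "A" * 3 + "H" + "A" * 4
        p = histidine_profile("g", protein)
        assert p.positions == (10, 12, 16)
        assert p.distances == (2, 4)
        assert p.H_harm == pytest.approx(8 / 3)
        assert p.D == pytest.approx(1.125)

    def test_no_histidines_leaves_stats_undefined(self):
        p = histidine_profile("g", "MAAA")
        assert p.h == 0 and p.H_harm is None and p.D is None

    def test_single_histidine_has_no_demand(self):
        p = histidine_profile("g", "MAHAA")
        assert p.h == 1 and p.D is None

    def test_all_pairs_mode(self):
        p = histidine_profile("g", "HHH", mode="all_pairs")
        assert sorted(p.distances) == [1, 1, 2]

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet="AH", min_size=2, max_size=120))
    def test_demand_identity_and_cluster_value(self, protein):
        p = histidine_profile("g", protein)
        if p.h >= 2:
            # algebraic identity: D = h * sum(1/d) / (h - 1)
            brute = p.h * sum(1 / d for d in p.distances) / (p.h - 1)
            assert p.D == pytest.approx(brute)
            if all(d == 1 for d in p.distances):
                assert p.D == pytest.approx(p.h)

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet="AH", min_size=2, max_size=80))
    def test_appending_adjacent_histidine_never_decreases_D(self, protein):
        p = histidine_profile("g", protein)
        if p.h >= 2:
            grown = (protein[:p.positions[-1] + 1] + "H"
                     + protein[p.positions[-1] + 1:])
            assert histidine_profile("g", grown).D >= p.D - 1e-9


def _summary_from(proteins, cds):
    proteome = Proteome(genome_id="G",
                        proteins=[(f"g{i}", p) for i, p in enumerate(proteins)])
    return proteome_summary(proteome,
                            {f"g{i}": c for i, c in enumerate(cds)})


class TestProteomeSummary:
    def test_small_example_frequency(self):
        # 6 non-stop codons, of which 2 are His codons
        s = _summary_from(["MHH", "MAA"], ["ATGCATCACTAA", "ATGGCAGCATAA"])
        assert s.total_codons == 6
        assert s.total_his_codons == 2
        assert s.his_codon_freq_per_thousand == pytest.approx(1000 / 3)

    def test_exact_arithmetic_45_in_2000(self):
        # 45 His codons among exactly 2000 non-stop codons => 22.50/1000
        codons = ["ATG"] + ["CAT"] * 23 + ["CAC"] * 22 + ["GCA"] * 1954
        assert len(codons) == 2000
        cds = "".join(codons) + "TAA"
        protein = "M" + "H" * 45 + "A" * 1954
        s = _summary_from([protein], [cds])
        assert s.his_codon_freq_per_thousand == pytest.approx(22.50, abs=1e-12)

    def test_empty_proteome_rejected(self):
        with pytest.raises(ConsistencyError):
            proteome_summary(Proteome(genome_id="G"), {})

    def test_mismatched_gene_ids_rejected(self):
        proteome = Proteome(genome_id="G", proteins=[("a", "MHH")])
        with pytest.raises(ConsistencyError, match="disagree"):
            proteome_summary(proteome, {"b": "ATGCATCACTAA"})

    def test_stop_codons_excluded_by_default(self):
        s = _summary_from(["M"], ["ATGTAA"])
        assert s.total_codons == 1
        proteome = Proteome(genome_id="G", proteins=[("g0", "M")])
        s2 = proteome_summary(proteome, {"g0": "ATGTAA"},
                              include_stop_codons=True)
        assert s2.total_codons == 2

    def test_protein_his_count_matches_cds_his_codons(self, rng):
        # counting H residues and counting CAT/CAC codons must agree
        from spacerhis.synthetic_data import SynthConfig, synth_proteome
        bundle = synth_proteome(SynthConfig(seed=4), genome_id="X")
        for gid, protein in bundle.proteome.proteins:
            cds = bundle.cds_seqs[gid]
            n_codons = sum(cds[i:i + 3] in {"CAT", "CAC"}
                           for i in range(0, len(cds), 3))
            assert protein.count("H") == n_codons


class TestCurves:
    def _summary(self):
        proteins = ["MAAA", "M" + "H" * 3, "M" + ("H" + "A") * 40,
                    "M" + "H" * 50]
        cds = None
        proteome = Proteome(genome_id="G",
                            proteins=[(f"g{i}", p)
                                      for i, p in enumerate(proteins)])
        from spacerhis.synthetic_data import _CODONS_BY_AA
        cds = {f"g{i}": "".join(_CODONS_BY_AA[aa][0] for aa in p) + "TAA"
               for i, p in enumerate(proteins)}
        return proteome_summary(proteome, cds)

    def test_fraction_min_his(self):
        s = self._summary()  # h values: 0, 3, 40, 50
        assert fraction_min_his(s, 0) == 1.0
        assert fraction_min_his(s, 35) == 0.5

    def test_fraction_min_his_monotone(self):
        s = self._summary()
        fracs = [fraction_min_his(s, m) for m in range(0, 60)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_fraction_min_demand(self):
        s = self._summary()  # D values among h>=2: 3, ~2.05?, 50
        assert fraction_min_demand(s, 0) == 1.0

    def test_fraction_min_demand_direct_count(self):
        profiles = [
            histidine_profile("a", "HH"),                    # D = 2
            histidine_profile("b", "H" * 6),                 # D = 6
            histidine_profile("c", "H" * 11),                # D = 11
        ]
        s = GenomeHisSummary(genome_id="G", profiles=profiles, n_proteins=3,
                             total_codons=1, total_his_codons=0,
                             his_codon_freq_per_thousand=0.0)
        assert fraction_min_demand(s, 5.0) == pytest.approx(2 / 3)

    def test_fraction_min_demand_undefined_without_pairs(self):
        profiles = [histidine_profile("a", "MAH")]
        s = GenomeHisSummary(genome_id="G", profiles=profiles, n_proteins=1,
                             total_codons=1, total_his_codons=0,
                             his_codon_freq_per_thousand=0.0)
        with pytest.raises(UndefinedValueError):
            fraction_min_demand(s, 1.0)

    def test_engineered_max_demand_below_threshold(self):
        # every protein has D < 10 => the fraction at 10.0 is exactly zero
        profiles = [histidine_profile("a", "H" * 9),   # D = 9
                    histidine_profile("b", "HH")]      # D = 2
        s = GenomeHisSummary(genome_id="G", profiles=profiles, n_proteins=2,
                             total_codons=1, total_his_codons=0,
                             his_codon_freq_per_thousand=0.0)
        assert fraction_min_demand(s, 10.0) == 0.0


class TestHighDemandGenes:
    def _summary(self, proteins):
        proteome = Proteome(
            genome_id="G",
            proteins=[(f"g{i}", p) for i, p in enumerate(proteins)])
        from spacerhis.synthetic_data import _CODONS_BY_AA
        cds = {f"g{i}": "".join(_CODONS_BY_AA[aa][0] for aa in p) + "TAA"
               for i, p in enumerate(proteins)}
        return proteome_summary(proteome, cds)

    def test_count_boundary_inclusive(self):
        # 35 histidines, widely spaced (D ~ 1) => listed by count
        protein = "M" + ("H" + "A" * 34) * 35
        s = self._summary([protein])
        hits = high_demand_genes(s)
        assert len(hits) == 1 and hits[0].by_count and not hits[0].by_demand

    def test_demand_boundary_exclusive(self):
        # D = 5.0 exactly (five adjacent histidines) is NOT above 5.0
        s = self._summary(["MA" + "H" * 5 + "AA"])
        assert high_demand_genes(s) == []

    def test_tight_cluster_listed_by_demand(self):
        # h = 6 adjacent => D = 6.0 > 5.0
        s = self._summary(["MA" + "H" * 6 + "AA"])
        hits = high_demand_genes(s)
        assert len(hits) == 1 and hits[0].by_demand and not hits[0].by_count

    def test_h34_below_both_cutoffs(self):
        protein = "M" + ("H" + "A" * 40) * 34
        s = self._summary([protein])
        assert high_demand_genes(s) == []


def test_codon_frequency_conservation(rng):
    """sum over genomes of freq * total / 1000 recovers the His codon count."""
    from spacerhis.synthetic_data import SynthConfig, synth_proteome
    total_his = 0
    back = 0.0
    for gid in ["a", "b", "c"]:
        bundle = synth_proteome(SynthConfig(seed=6), genome_id=gid)
        s = proteome_summary(bundle.proteome, bundle.cds_seqs)
        total_his += s.total_his_codons
        back += s.his_codon_freq_per_thousand * s.total_codons / 1000.0
    assert back == pytest.approx(total_his)


def test_curve_exports_shapes():
    profiles = [histidine_profile("a", "MHH"), histidine_profile("b", "MA")]
    s = GenomeHisSummary(genome_id="G", profiles=profiles, n_proteins=2,
                         total_codons=10, total_his_codons=2,
                         his_codon_freq_per_thousand=200.0)
    assert his_count_curve(s)[0] == (0, 1.0)
    assert demand_curve(s, [0.0, 5.0]) == [(0.0, 1.0), (5.0, 0.0)]
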