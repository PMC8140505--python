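"""Genome-level metrics against generator ground truth and brute-force
oracles: ANI recovery, Mash closed form, POCP, dDDH monotonicity, N50 and
the quality score."""

import math

import numpy as np
import pytest

import polytax as pt
from polytax.genome import _fragments
from _oracles import mash_distance_oracle, n50_oracle, pocp_oracle


def _pair(ani, length=50_000, seed=7, **kw):
    return pt.make_genome_pair(
        pt.GenomePairDesign(ancestor_length=length, target_ani=ani, seed=seed, **kw)
    )


class TestGC:
    @pytest.mark.parametrize(
        "seq,expected", [("ATGC", 50.0), ("GGCC", 100.0), ("AATT", 0.0)]
    )
    def test_simple_compositions(self, seq, expected):
        assert pt.gc_content(pt.GenomeAssembly("g", [seq])) == expected

    def test_ambiguous_bases_excluded(self):
        g = pt.GenomeAssembly("g", ["ATGCNNNN"])
        assert pt.gc_content(g) == 50.0

    def test_all_ambiguous_rejected(self):
        with pytest.raises(pt.UndefinedResultError):
            pt.gc_content(pt.GenomeAssembly("g", ["NNNN"]))

    def test_known_composition_genome(self):
        # 6359 G/C + 3641 A/T -> 63.59 mol%
        rng = np.random.default_rng(0)
        seq = "".join(
            rng.permutation(list("G" * 3180 + "C" * 3179 + "A" * 1821 + "T" * 1820))
        )
        assert pt.gc_content(pt.GenomeAssembly("g", [seq])) == 63.59


class TestOrthoANI:
    def test_self_comparison_is_100(self):
        g, _, _ = _pair(0.95)
        assert pt.orthoani(g, g).ani == 100.0

    @pytest.mark.parametrize("ani,tol", [(0.95, 1.0), (0.80, 1.5)])
    def test_recovers_target(self, ani, tol):
        g1, g2, truth = _pair(ani, length=100_000)
        res = pt.orthoani(g1, g2)
        assert res.ani == pytest.approx(100 * truth, abs=tol)
        assert res.n_fragments_used >= 1

    def test_symmetry(self):
        g1, g2, _ = _pair(0.90)
        a = pt.orthoani(g1, g2).ani
        b = pt.orthoani(g2, g1).ani
        assert a == pytest.approx(b, abs=0.2)

    def test_monotone_in_divergence(self):
        anis = []
        for target in (0.80, 0.90, 0.95, 0.99):
            g1, g2, _ = _pair(target, seed=13)
            anis.append(pt.orthoani(g1, g2).ani)
        assert anis == sorted(anis)

    def test_fragmentation_discards_remainder(self):
        g = pt.GenomeAssembly("g", ["A" * 2500])
        frags = _fragments(g, 1020)
        assert [len(f) for f in frags] == [1020, 1020]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            g1, g2, _ = _pair(0.95)
            short = pt.GenomeAssembly("s", ["ACGT" * 400])
            pt.orthoani(g1, short)

    def test_unrelated_genomes_undefined(self):
        g1, _, _ = _pair(1.0, seed=1, length=10_000)
        g2, _, _ = _pair(1.0, seed=999, length=10_000)
        with pytest.raises(pt.UndefinedResultError):
            pt.orthoani(g1, g2)

    def test_indel_tolerance(self):
        g1, g2, truth = pt.make_genome_pair(
            pt.GenomePairDesign(ancestor_length=50_000, target_ani=0.95,
                                indel_rate=0.0005, seed=3)
        )
        assert pt.orthoani(g1, g2).ani == pytest.approx(100 * truth, abs=2.0)


class TestMash:
    def test_identical_genomes_distance_zero(self):
        g, _, _ = _pair(0.95)
        s = pt.sketch(g)
        assert pt.mash_distance(s, s) == 0.0

    def test_closed_form_third_jaccard(self):
        # hand-built sketches with jaccard exactly 1/3 over the merged bottom
        s1 = pt.MashSketch(k=21, sketch_size=3, min_hashes=(1, 2, 3))
        s2 = pt.MashSketch(k=21, sketch_size=3, min_hashes=(1, 5, 6))
        d = pt.mash_distance(s1, s2)
        assert d == pytest.approx(math.log(2) / 21, abs=1e-12)
        assert d == pytest.approx(mash_distance_oracle(1 / 3, 21), abs=1e-12)

    def test_disjoint_sketches_sentinel(self):
        s1 = pt.MashSketch(k=21, sketch_size=2, min_hashes=(1, 2))
        s2 = pt.MashSketch(k=21, sketch_size=2, min_hashes=(5, 6))
        assert pt.mash_distance(s1, s2) == 1.0

    def test_k_mismatch_rejected(self):
        s1 = pt.MashSketch(k=21, sketch_size=2, min_hashes=(1, 2))
        s2 = pt.MashSketch(k=17, sketch_size=2, min_hashes=(1, 2))
        with pytest.raises(ValueError):
            pt.mash_distance(s1, s2)

    def test_distance_grows_with_divergence(self):
        dists = []
        for target in (0.99, 0.95, 0.90, 0.80):
            g1, g2, _ = _pair(target, seed=17)
            dists.append(pt.mash_distance(pt.sketch(g1), pt.sketch(g2)))
        assert dists == sorted(dists)

    def test_canonical_kmers_make_strands_equal(self):
        g1, _, _ = _pair(1.0, seed=5, length=10_000)
        rc = g1.contigs[0].translate(str.maketrans("ACGT", "TGCA"))[::-1]
        g_rc = pt.GenomeAssembly("rc", [rc])
        assert pt.mash_distance(pt.sketch(g1), pt.sketch(g_rc)) == 0.0


class TestMatchReferenceSpecies:
    def test_identical_reference_matches_at_zero(self):
        g, _, _ = _pair(0.95, length=20_000)
        matches = pt.match_reference_species(
            g, [pt.GenomeAssembly("ref", g.contigs)]
        )
        assert matches == [("ref", 0.0)]

    def test_same_species_pair_matches(self):
        g1, g2, _ = _pair(0.97, seed=19)
        assert [m[0] for m in pt.match_reference_species(g1, [g2])] == [g2.name]

    def test_distant_pair_is_dark_taxon_candidate(self):
        g1, g2, _ = _pair(0.80, seed=19)
        assert pt.match_reference_species(g1, [g2]) == []


class TestPOCP:
    def test_identical_proteomes(self, small_proteome_pair):
        p1, _, _ = small_proteome_pair
        assert pt.pocp(p1, p1) == 100.0

    def test_matches_design_truth_and_oracle(self, small_proteome_pair):
        p1, p2, truth = small_proteome_pair
        value = pt.pocp(p1, p2)
        assert value == truth
        assert value == pocp_oracle(p1, p2)

    def test_unrelated_proteomes_zero(self):
        rng = np.random.default_rng(33)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        p1 = [(f"a{i}", "".join(rng.choice(aa, 80))) for i in range(6)]
        p2 = [(f"b{i}", "".join(rng.choice(aa, 80))) for i in range(6)]
        value = pt.pocp(p1, p2)
        assert value == pocp_oracle(p1, p2)
        assert value == 0.0

    def test_empty_proteome_rejected(self, small_proteome_pair):
        p1, _, _ = small_proteome_pair
        with pytest.raises(ValueError):
            pt.pocp(p1, [])


class TestDdh:
    def test_identical_genomes_at_logistic_maximum(self):
        g, _, _ = _pair(0.95, length=20_000)
        res = pt.ddh_estimate(g, g)
        cfg = pt.DdhConfig()
        assert res["distance_f2"] == 0.0
        assert res["ddh"] == pytest.approx(100 / (1 + math.exp(cfg.a)), abs=1e-9)

    def test_monotone_in_divergence(self):
        g1, g2, _ = _pair(0.99, seed=23)
        h1, h2, _ = _pair(0.85, seed=23)
        assert pt.ddh_estimate(h1, h2)["ddh"] < pt.ddh_estimate(g1, g2)["ddh"]

    def test_species_boundary_separation(self):
        """Clearly conspecific pairs sit above 70% dDDH, clearly distinct
        species sit below."""
        g1, g2, _ = _pair(0.99, seed=29)
        h1, h2, _ = _pair(0.90, seed=29)
        assert pt.ddh_estimate(g1, g2)["ddh"] > 70.0
        assert pt.ddh_estimate(h1, h2)["ddh"] < 70.0

    def test_symmetry(self):
        g1, g2, _ = _pair(0.95, seed=31)
        a = pt.ddh_estimate(g1, g2)
        b = pt.ddh_estimate(g2, g1)
        assert a["distance_f2"] == pytest.approx(b["distance_f2"], abs=1e-6)


class TestAssemblyStats:
    def test_n50_brute_force(self):
        lengths = [5000, 4000, 3000, 2000, 1000]
        assert pt.n50(lengths) == 4000
        assert pt.n50(lengths) == n50_oracle(lengths)

    def test_single_contig(self):
        assert pt.n50([1_000_000]) == 1_000_000

    @pytest.mark.parametrize("seed", range(5))
    def test_n50_random_agreement(self, seed):
        rng = np.random.default_rng(seed)
        lengths = rng.integers(500, 100_000, size=rng.integers(2, 30)).tolist()
        assert pt.n50(lengths) == n50_oracle(lengths)

    def test_quality_score_formula(self):
        assert pt.quality_score(97.65, 0.63) == pytest.approx(94.50, abs=1e-9)

    def test_quality_score_linearity(self):
        """Mean of scores equals score of mean inputs (machine precision)."""
        rng = np.random.default_rng(42)
        comp = rng.uniform(50, 100, 200)
        cont = rng.uniform(0, 5, 200)
        scores = [pt.quality_score(c, x) for c, x in zip(comp, cont)]
        assert np.mean(scores) == pytest.approx(
            pt.quality_score(np.mean(comp), np.mean(cont)), abs=1e-9
        )

    def test_assembly_stats_bundle(self):
        g = pt.GenomeAssembly("g", ["A" * 5000, "C" * 3000, "G" * 2000])
        qc = pt.assembly_stats(g, completeness=98.0, contamination=0.4)
        assert qc.n_contigs == 3
        assert qc.n50 == 5000
        assert qc.quality_score == pytest.approx(96.0)

    def test_invalid_inputs_rejected(self):
        g = pt.GenomeAssembly("g", ["ACGT" * 100])
        with pytest.raises(ValueError):
            pt.assembly_stats(g, completeness=120, contamination=0)
        with pytest.raises(ValueError):
            pt.assembly_stats(g, completeness=90, contamination=-1)
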