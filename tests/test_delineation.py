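"""Rank decision engine: forced examples, the boundary-grid truth table,
and structural properties (rank nesting, monotonicity in 16S identity)."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polytax as pt
from polytax.delineation import Rank


def _ev(id16s=0.96, ddh=35.0, ani=88.0, pocp=60.0, clade=False,
        nfam=0, ph_sp=False, ph_gen=False, ph_fam=False):
    return pt.TaxonEvidence(
        id16s_best=id16s, ddh=ddh, ani=ani, pocp=pocp,
        independent_clade=clade, neighbor_families_count=nfam,
        phenotype_distinct_species=ph_sp, phenotype_distinct_genus=ph_gen,
        phenotype_distinct_family=ph_fam,
    )


def oracle_rank(e: pt.TaxonEvidence) -> str:
    """Literal transcription of the published rules, evaluated rank by rank
    as full conjunctions (independent of the engine's clause structure)."""
    if e.id16s_best > 0.987:
        return "known_species"
    species = (
        e.id16s_best < 0.987
        and e.ddh < 70
        and (e.ani < 95 or (95 <= e.ani <= 96 and e.phenotype_distinct_species))
    )
    genus = (
        species
        and e.id16s_best < 0.95
        and e.pocp < 50
        and e.phenotype_distinct_genus
        and e.independent_clade
    )
    family = (
        genus
        and e.id16s_best < 0.90
        and e.neighbor_families_count >= 2
        and e.phenotype_distinct_family
    )
    if family:
        return "new_family"
    if genus:
        return "new_genus"
    if species:
        return "new_species"
    return "ambiguous"


class TestForcedExamples:
    def test_known_species(self):
        assert pt.delineate(_ev(id16s=0.992)).rank == Rank.KNOWN_SPECIES

    def test_new_species_not_genus(self):
        d = pt.delineate(_ev(id16s=0.96, ddh=35, ani=88, pocp=60))
        assert d.rank == Rank.NEW_SPECIES

    def test_new_genus_not_family(self):
        d = pt.delineate(
            _ev(id16s=0.93, ddh=25, ani=78, pocp=42, clade=True,
                ph_sp=True, ph_gen=True, nfam=1)
        )
        assert d.rank == Rank.NEW_GENUS

    def test_new_family(self):
        d = pt.delineate(
            _ev(id16s=0.89, ddh=20, ani=72, pocp=35, clade=True,
                ph_sp=True, ph_gen=True, ph_fam=True, nfam=2)
        )
        assert d.rank == Rank.NEW_FAMILY

    def test_ani_window_exception(self):
        """ANI in [95, 96] with distinct phenotype still permits a new
        species call."""
        d = pt.delineate(_ev(id16s=0.97, ddh=60, ani=95.5, ph_sp=True))
        assert d.rank == Rank.NEW_SPECIES

    def test_ani_window_without_phenotype_fails(self):
        d = pt.delineate(_ev(id16s=0.97, ddh=60, ani=95.5, ph_sp=False))
        assert d.rank == Rank.AMBIGUOUS

    def test_boundary_987_is_ambiguous(self):
        d = pt.delineate(_ev(id16s=0.987))
        assert d.rank == Rank.AMBIGUOUS

    def test_missing_field_raises(self):
        with pytest.raises(pt.IncompleteEvidenceError):
            _ev(id16s=None)

    def test_clause_audit_trail(self):
        d = pt.delineate(_ev(id16s=0.96, ddh=35, ani=88, pocp=60))
        assert "species.id16s" in d.satisfied_clauses
        assert "genus.pocp" in d.failed_clauses


class TestTruthTable:
    def test_boundary_grid_matches_oracle(self):
        """Every combination of boundary-straddling values agrees with the
        enumerated-conjunction oracle (>4,000 cases)."""
        grid = itertools.product(
            (0.899, 0.90, 0.949, 0.95, 0.986, 0.987, 0.988),
            (69.0, 70.0),
            (94.0, 95.0, 95.5, 96.0, 97.0),
            (49.0, 50.0),
            (False, True),       # independent_clade
            (1, 2),              # neighbor_families_count
            (False, True),       # phenotype flags, moved together
        )
        n = 0
        for id16s, ddh, ani, pocp_v, clade, nfam, pheno in grid:
            e = _ev(id16s=id16s, ddh=ddh, ani=ani, pocp=pocp_v, clade=clade,
                    nfam=nfam, ph_sp=pheno, ph_gen=pheno, ph_fam=pheno)
            assert pt.delineate(e).rank.value == oracle_rank(e), vars(e)
            n += 1
        assert n >= 500

    @given(
        id16s=st.floats(0.85, 1.0),
        ddh=st.floats(0, 100),
        ani=st.floats(70, 100),
        pocp_v=st.floats(0, 100),
        clade=st.booleans(),
        nfam=st.integers(0, 3),
        ph_sp=st.booleans(),
        ph_gen=st.booleans(),
        ph_fam=st.booleans(),
    )
    @settings(max_examples=400, deadline=None, derandomize=True)
    def test_rank_nesting_property(self, id16s, ddh, ani, pocp_v, clade, nfam,
                                   ph_sp, ph_gen, ph_fam):
        """A family call implies the genus clauses hold, which imply the
        species clauses hold; known_species excludes novelty."""
        e = _ev(id16s=id16s, ddh=ddh, ani=ani, pocp=pocp_v, clade=clade,
                nfam=nfam, ph_sp=ph_sp, ph_gen=ph_gen, ph_fam=ph_fam)
        d = pt.delineate(e)
        assert d.rank.value == oracle_rank(e)
        sat = set(d.satisfied_clauses)
        species_clauses = {"species.id16s", "species.ddh", "species.ani"}
        genus_clauses = species_clauses | {
            "genus.id16s", "genus.pocp", "genus.phenotype", "genus.clade"
        }
        if d.rank == Rank.NEW_FAMILY:
            assert genus_clauses <= sat
        if d.rank in (Rank.NEW_FAMILY, Rank.NEW_GENUS):
            assert species_clauses <= sat
        if d.rank == Rank.KNOWN_SPECIES:
            assert "known.id16s" in sat

    @given(
        id16s_hi=st.floats(0.85, 0.986),
        delta=st.floats(0.001, 0.05),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_16s_identity(self, id16s_hi, delta):
        """Lowering the best 16S identity, everything else fixed and
        passing, never demotes the rank."""
        order = ["ambiguous", "known_species", "new_species", "new_genus",
                 "new_family"]
        kwargs = dict(ddh=20.0, ani=80.0, pocp=30.0, clade=True, nfam=2,
                      ph_sp=True, ph_gen=True, ph_fam=True)
        hi = pt.delineate(_ev(id16s=id16s_hi, **kwargs)).rank.value
        lo = pt.delineate(_ev(id16s=max(0.0, id16s_hi - delta), **kwargs)).rank.value
        assert order.index(lo) >= order.index(hi)


class TestBatch:
    def test_all_known(self):
        df = pd.DataFrame([vars(_ev(id16s=0.99))] * 10)
        _, counts = pt.delineate_batch(df)
        assert counts["known_species"] == 10

    def test_planted_panel_counts(self):
        """A constructed panel with 5/3/1 planted species/genus/family
        novelties yields exactly those counts."""
        rows = []
        for i in range(5):
            rows.append(_ev(id16s=0.96 + 0.001 * i, ddh=40, ani=90, pocp=70))
        for i in range(3):
            rows.append(_ev(id16s=0.92 + 0.002 * i, ddh=30, ani=82, pocp=40,
                            clade=True, ph_gen=True, nfam=1))
        rows.append(_ev(id16s=0.88, ddh=20, ani=75, pocp=30, clade=True,
                        ph_sp=True, ph_gen=True, ph_fam=True, nfam=2))
        frame, counts = pt.delineate_batch(rows)
        assert counts["new_species"] == 5
        assert counts["new_genus"] == 3
        assert counts["new_family"] == 1
        assert counts["known_species"] == 0
        assert len(frame) == 9

    def test_empty_table_all_zero(self):
        frame, counts = pt.delineate_batch([])
        assert len(frame) == 0
        assert all(v == 0 for v in counts.values())

    def test_row_errors_carry_identity(self):
        df = pd.DataFrame([vars(_ev())])
        df.loc[0, "ddh"] = None
        with pytest.raises(pt.IncompleteEvidenceError, match="row 0"):
            pt.delineate_batch(df)

    def test_batch_consistent_with_single(self):
        rows = [_ev(id16s=v) for v in (0.99, 0.96, 0.93, 0.987)]
        frame, counts = pt.delineate_batch(rows)
        singles = [pt.delineate(e).rank.value for e in rows]
        assert list(frame["rank"]) == singles
        assert sum(counts.values()) == len(rows)
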