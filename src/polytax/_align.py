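"""Shared pairwise-alignment machinery.

All nucleotide identities in this package are defined the same way:
matches / compared_sites, where compared_sites counts alignment columns
that are ungapped on both sides and unambiguous (A/C/G/T) on both sides.
Terminal gaps are never penalized, so a short sequence aligned inside a
longer one is scored only over the overlap.

Protein comparisons use local (Smith-Waterman) alignment with BLOSUM62
and affine gaps (-11/-1), the classic protein-search parameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import UndefinedResultError

_ACGT = frozenset("ACGT")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
# IUPAC nucleotide one-letter codes (U accepted and treated as ambiguous-free T)
_IUPAC_NUC = frozenset("ACGTURYSWKMBDHVN")

# Karlin-Altschul parameters for gapped BLOSUM62 with open 11 / extend 1,
# as reported by blastp; used for the approximate E-value of a local hit.
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass(frozen=True)
class NucAlignment:
    """A scored global nucleotide alignment with site-pattern counts.

    ``transitions`` and ``transversions`` partition the mismatches;
    ``compared_sites`` = matches + mismatches counts only columns that are
    ungapped and unambiguous on both sequences.
    """

    aligned_a: str
    aligned_b: str
    matches: int
    mismatches: int
    transitions: int
    transversions: int
    compared_sites: int

    @property
    def identity(self) -> float:
        if self.compared_sites == 0:
            raise UndefinedResultError("alignment has no comparable sites")
        return self.matches / self.compared_sites


@dataclass(frozen=True)
class ProteinHit:
    """A local protein alignment summarized BLAST-style."""

    score: float
    matches: int
    columns: int           # alignment length, gap columns included
    query_span: int        # residues of the query inside the alignment
    subject_span: int
    evalue: float

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _check_nucleotide(seq: str, label: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"{label} is empty")
    s = seq.upper().replace("U", "T")
    bad = set(s) - _IUPAC_NUC
    if bad:
        raise ValueError(f"{label} contains non-IUPAC characters: {sorted(bad)}")
    return s


@lru_cache(maxsize=1)
def _nuc_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    # terminal gaps free: overlap-style global alignment
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


@lru_cache(maxsize=1)
def _prot_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def count_site_patterns(aligned_a: str, aligned_b: str) -> NucAlignment:
    """Tally matches/transitions/transversions over a gapped sequence pair."""
    matches = transitions = transversions = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-" or x not in _ACGT or y not in _ACGT:
            continue
        if x == y:
            matches += 1
        elif (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    mismatches = transitions + transversions
    return NucAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        matches=matches,
        mismatches=mismatches,
        transitions=transitions,
        transversions=transversions,
        compared_sites=matches + mismatches,
    )


def align_nucleotides(a: str, b: str) -> NucAlignment:
    """Globally align two nucleotide sequences (terminal gaps free) and
    return per-column counts."""
    a = _check_nucleotide(a, "first sequence")
    b = _check_nucleotide(b, "second sequence")
    aln = _nuc_aligner().align(a, b)[0]
    return count_site_patterns(str(aln[0]), str(aln[1]))


def align_proteins(query: str, subject: str) -> ProteinHit | None:
    """Best local alignment of two proteins, or None when no positive-scoring
    alignment exists."""
    if not query or not subject:
        raise ValueError("empty protein sequence")
    aligner = _prot_aligner()
    score = aligner.score(query, subject)
    if score <= 0:
        return None
    aln = aligner.align(query, subject)[0]
    # in local mode the rendered strings cover only the aligned region
    qa, sa = str(aln[0]), str(aln[1])
    columns = len(qa)
    matches = sum(1 for x, y in zip(qa, sa) if x == y and x != "-")
    qstart, qend = aln.aligned[0][0][0], aln.aligned[0][-1][1]
    sstart, send = aln.aligned[1][0][0], aln.aligned[1][-1][1]
    evalue = _KA_K * len(query) * len(subject) * math.exp(-_KA_LAMBDA * score)
    return ProteinHit(
        score=score,
        matches=matches,
        columns=columns,
        query_span=int(qend - qstart),
        subject_span=int(send - sstart),
        evalue=evalue,
    )
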