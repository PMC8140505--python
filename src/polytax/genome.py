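"""Whole-genome comparison and assembly QC metrics.

Implements the genome-level evidence used for taxon delineation:

* fragment-based ANI (OrthoANI-style): both genomes are cut into
  non-overlapping 1,020-bp windows, fragments are matched across genomes
  by seed-and-extend alignment, and the ANI is the mean identity over
  reciprocal best fragment pairs — <95% conventionally separates species;
* a digital DNA-DNA hybridization (dDDH) ESTIMATE mapped from the
  fragment-alignment distance through a configurable logistic — <70%
  separates species;
* POCP, the percentage of conserved proteins — <50% suggests distinct
  genera;
* MinHash sketch (Mash) distance — <0.05 is used for same-species
  matching against reference genome sets;
* G+C content, N50, and the composite assembly quality score
  completeness - 5 x contamination.
"""

from __future__ import annotations

import hashlib
import math
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from ._align import align_nucleotides, align_proteins
from .errors import UndefinedResultError

_SEED_K = 13  # seeding word size for fragment matching; 0.8^13 ~ 5.5% of
              # 13-mers survive at the lowest supported divergence


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class GenomeAssembly:
    """A named set of nucleotide contigs."""

    name: str
    contigs: tuple[str, ...]

    def __init__(self, name: str, contigs):
        contigs = tuple(c.upper() for c in contigs)
        if not contigs or sum(len(c) for c in contigs) == 0:
            raise ValueError("assembly must contain at least one non-empty contig")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "contigs", contigs)

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass(frozen=True)
class ANIResult:
    ani: float                 # percent
    n_fragments_used: int
    reciprocal: bool = True


@dataclass(frozen=True)
class AssemblyQC:
    name: str
    n_contigs: int
    n50: int
    completeness: float        # percent, an input (e.g. CheckM)
    contamination: float       # percent, an input
    quality_score: float       # completeness - 5 x contamination


@dataclass(frozen=True)
class MashSketch:
    k: int
    sketch_size: int
    min_hashes: tuple[int, ...]   # sorted ascending, at most sketch_size


@dataclass(frozen=True)
class DdhConfig:
    """Logistic map from fragment-alignment distance to a dDDH-like percent.

    ddh = 100 / (1 + exp(a + b * d)). The defaults are calibrated so that
    the conventional 70% dDDH species boundary falls at a fragment distance
    of ~0.045, i.e. alongside the 95-96% ANI species boundary; they are NOT
    the coefficients of any published regression and the result is an
    estimate, not a reimplementation of GGDC.
    """

    a: float = -7.0
    b: float = 137.0


# ---------------------------------------------------------------------------
# simple per-assembly metrics


def gc_content(genome: GenomeAssembly) -> float:
    """G+C mol%, ambiguous bases excluded from numerator and denominator,
    rounded to 2 decimals."""
    counts = Counter()
    for contig in genome.contigs:
        counts.update(contig)
    unambiguous = sum(counts[b] for b in "ACGT")
    if unambiguous == 0:
        raise UndefinedResultError("assembly contains no unambiguous bases")
    return round(100.0 * (counts["G"] + counts["C"]) / unambiguous, 2)


def n50(contig_lengths) -> int:
    """Largest length L such that contigs of length >= L cover at least
    half the assembly."""
    lengths = sorted((int(x) for x in contig_lengths), reverse=True)
    if not lengths or lengths[0] <= 0:
        raise ValueError("contig lengths must be positive")
    half = sum(lengths) / 2.0
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def quality_score(completeness: float, contamination: float) -> float:
    """Composite assembly quality: completeness - 5 x contamination."""
    return completeness - 5.0 * contamination


def assembly_stats(
    genome: GenomeAssembly, completeness: float, contamination: float
) -> AssemblyQC:
    if not 0 <= completeness <= 100:
        raise ValueError("completeness must be a percent in [0, 100]")
    if contamination < 0:
        raise ValueError("contamination cannot be negative")
    return AssemblyQC(
        name=genome.name,
        n_contigs=len(genome.contigs),
        n50=n50(len(c) for c in genome.contigs),
        completeness=completeness,
        contamination=contamination,
        quality_score=quality_score(completeness, contamination),
    )


def mean_depth(depths) -> float:
    """Mean per-base coverage depth from a per-position depth vector."""
    arr = np.asarray(list(depths), dtype=float)
    if arr.size == 0:
        raise ValueError("no depth values")
    return float(arr.mean())


# ---------------------------------------------------------------------------
# fragment-based ANI and the dDDH estimate


def _fragments(genome: GenomeAssembly, fragment_len: int) -> list[str]:
    """Consecutive non-overlapping windows per contig; trailing remainder
    shorter than fragment_len is discarded."""
    frags = []
    for contig in genome.contigs:
        for start in range(0, len(contig) - fragment_len + 1, fragment_len):
            frags.append(contig[start: start + fragment_len])
    return frags


def _kmer_index(frags: list[str], k: int) -> dict:
    index: dict = defaultdict(list)
    for idx, frag in enumerate(frags):
        for pos in range(len(frag) - k + 1):
            index[frag[pos: pos + k]].append((idx, pos))
    return index


@dataclass(frozen=True)
class _FragmentHit:
    subject: int
    identity: float
    matches: int
    compared: int
    coverage: float


def _compare_on_diagonal(a: str, b: str, shift: int) -> tuple[int, int]:
    """Ungapped comparison of a against b offset by ``shift`` (b position =
    a position + shift). Returns (matches, compared_sites)."""
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    a_lo = max(0, -shift)
    b_lo = max(0, shift)
    n = min(len(a_arr) - a_lo, len(b_arr) - b_lo)
    if n <= 0:
        return 0, 0
    x = a_arr[a_lo: a_lo + n]
    y = b_arr[b_lo: b_lo + n]
    valid = np.isin(x, np.frombuffer(b"ACGT", dtype=np.uint8)) & np.isin(
        y, np.frombuffer(b"ACGT", dtype=np.uint8)
    )
    matches = int(((x == y) & valid).sum())
    return matches, int(valid.sum())


def _best_hit(
    frag: str,
    index: dict,
    subject_frags: list[str],
    k: int = _SEED_K,
    max_candidates: int = 3,
) -> _FragmentHit | None:
    """Best-matching subject fragment for ``frag`` via k-mer seeding.

    Shared k-mers vote for (subject fragment, diagonal); the dominant
    diagonal is scored by ungapped comparison, falling back to a full
    gapped alignment when the seeds disagree on a single diagonal
    (i.e. indels inside the fragment).
    """
    votes: Counter = Counter()          # (subject, diag) -> seed count
    per_subject: Counter = Counter()
    for pos in range(len(frag) - k + 1):
        for idx, spos in index.get(frag[pos: pos + k], ()):
            votes[(idx, spos - pos)] += 1
            per_subject[idx] += 1
    if not per_subject:
        return None
    best: _FragmentHit | None = None
    for subject, n_seeds in per_subject.most_common(max_candidates):
        diag_votes = {d: c for (s, d), c in votes.items() if s == subject}
        diag, diag_count = max(diag_votes.items(), key=lambda kv: (kv[1], -abs(kv[0])))
        if diag_count >= 0.8 * n_seeds:
            matches, compared = _compare_on_diagonal(
                frag, subject_frags[subject], diag
            )
        else:  # seeds split across diagonals: likely indels, do a real alignment
            aln = align_nucleotides(frag, subject_frags[subject])
            matches, compared = aln.matches, aln.compared_sites
        if compared == 0:
            continue
        hit = _FragmentHit(
            subject=subject,
            identity=matches / compared,
            matches=matches,
            compared=compared,
            coverage=compared / len(frag),
        )
        if (
            best is None
            or (hit.identity, -hit.subject) > (best.identity, -best.subject)
        ):
            best = hit
    return best


def _reciprocal_fragment_pairs(
    g1: GenomeAssembly,
    g2: GenomeAssembly,
    fragment_len: int = 1020,
    min_coverage: float = 0.7,
) -> list[tuple[int, int, int, int, float]]:
    """Reciprocal best fragment pairs passing the coverage cutoff.

    Returns tuples (i, j, matches, compared_sites, identity) for fragment
    i of g1 matched with fragment j of g2.
    """
    for g in (g1, g2):
        if g.total_length < 2 * fragment_len:
            raise ValueError(
                f"genome {g.name} is shorter than two fragments "
                f"({g.total_length} < {2 * fragment_len} bp)"
            )
    frags1 = _fragments(g1, fragment_len)
    frags2 = _fragments(g2, fragment_len)
    index2 = _kmer_index(frags2, _SEED_K)
    index1 = _kmer_index(frags1, _SEED_K)
    best12 = {i: _best_hit(f, index2, frags2) for i, f in enumerate(frags1)}
    best21 = {j: _best_hit(f, index1, frags1) for j, f in enumerate(frags2)}
    pairs = []
    for i, hit in best12.items():
        if hit is None or hit.coverage < min_coverage:
            continue
        back = best21.get(hit.subject)
        if back is None or back.subject != i or back.coverage < min_coverage:
            continue
        pairs.append((i, hit.subject, hit.matches, hit.compared, hit.identity))
    return pairs


def orthoani(
    g1: GenomeAssembly,
    g2: GenomeAssembly,
    fragment_len: int = 1020,
    min_coverage: float = 0.7,
) -> ANIResult:
    """Fragment-based average nucleotide identity (percent).

    Mean alignment identity over reciprocal best 1,020-bp fragment pairs
    with alignment coverage >= 70% of the fragment. Raises
    UndefinedResultError when no fragment pair qualifies (distinct from an
    ANI of 0).
    """
    pairs = _reciprocal_fragment_pairs(g1, g2, fragment_len, min_coverage)
    if not pairs:
        raise UndefinedResultError(
            f"no reciprocal fragment pairs between {g1.name} and {g2.name}"
        )
    identities = [p[4] for p in pairs]
    return ANIResult(
        ani=100.0 * float(np.mean(identities)),
        n_fragments_used=len(pairs),
        reciprocal=True,
    )


def ddh_estimate(
    g1: GenomeAssembly,
    g2: GenomeAssembly,
    fragment_len: int = 1020,
    min_coverage: float = 0.7,
    config: DdhConfig = DdhConfig(),
) -> dict:
    """dDDH-style estimate from pooled fragment alignments.

    distance = 1 - (total identical sites / total aligned sites) over all
    retained reciprocal fragment pairs; ddh = 100 / (1 + exp(a + b*d)).
    Symmetric in its arguments and strictly decreasing in the distance.
    """
    pairs = _reciprocal_fragment_pairs(g1, g2, fragment_len, min_coverage)
    if not pairs:
        raise UndefinedResultError(
            f"no alignable fragments between {g1.name} and {g2.name}"
        )
    total_matches = sum(p[2] for p in pairs)
    total_sites = sum(p[3] for p in pairs)
    distance = 1.0 - total_matches / total_sites
    ddh = 100.0 / (1.0 + math.exp(config.a + config.b * distance))
    return {"distance_f2": distance, "ddh": ddh}


# ---------------------------------------------------------------------------
# POCP


def pocp(
    proteome1,
    proteome2,
    evalue_max: float = 1e-5,
    identity_min: float = 0.4,
    coverage_min: float = 0.5,
) -> float:
    """Percentage of conserved proteins between two proteomes.

    A protein is conserved when some protein of the other proteome aligns
    to it with E-value < 1e-5, identity > 40%, and an alignable region
    covering > 50% of the query length. POCP = 100 * (C1 + C2) / (T1 + T2);
    values below 50% conventionally indicate distinct genera.

    Proteomes are sequences of (id, amino-acid sequence) pairs.
    """
    seqs1 = [s for _, s in proteome1]
    seqs2 = [s for _, s in proteome2]
    if not seqs1 or not seqs2:
        raise ValueError("both proteomes must be non-empty")

    def conserved_count(queries, subjects) -> int:
        count = 0
        for q in queries:
            for s in subjects:
                hit = align_proteins(q, s)
                if hit is None:
                    continue
                if (
                    hit.evalue < evalue_max
                    and hit.identity > identity_min
                    and hit.query_span > coverage_min * len(q)
                ):
                    count += 1
                    break
        return count

    c1 = conserved_count(seqs1, seqs2)
    c2 = conserved_count(seqs2, seqs1)
    return 100.0 * (c1 + c2) / (len(seqs1) + len(seqs2))


# ---------------------------------------------------------------------------
# MinHash (Mash) sketching


def _hash_kmer(kmer: str) -> int:
    return int.from_bytes(
        hashlib.blake2b(kmer.encode(), digest_size=8).digest(), "little"
    )


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def sketch(
    genome: GenomeAssembly, k: int = 21, sketch_size: int = 1000
) -> MashSketch:
    """Bottom-s MinHash sketch over canonical k-mers.

    Canonical form is the lexicographic minimum of a k-mer and its reverse
    complement; k-mers containing ambiguous bases are skipped.
    """
    hashes: set[int] = set()
    for contig in genome.contigs:
        for pos in range(len(contig) - k + 1):
            kmer = contig[pos: pos + k]
            if any(c not in "ACGT" for c in kmer):
                continue
            rc = kmer.translate(_COMPLEMENT)[::-1]
            hashes.add(_hash_kmer(min(kmer, rc)))
    bottom = sorted(hashes)[:sketch_size]
    return MashSketch(k=k, sketch_size=sketch_size, min_hashes=tuple(bottom))


def mash_distance(s1: MashSketch, s2: MashSketch) -> float:
    """Mash distance between two sketches.

    The Jaccard index j is estimated over the merged bottom sketch;
    d = -(1/k) * ln(2j / (1+j)); disjoint sketches give the sentinel 1.0.
    """
    if s1.k != s2.k:
        raise ValueError(f"sketch k mismatch: {s1.k} != {s2.k}")
    h1, h2 = set(s1.min_hashes), set(s2.min_hashes)
    size = min(s1.sketch_size, s2.sketch_size)
    merged = sorted(h1 | h2)[:size]
    shared = sum(1 for h in merged if h in h1 and h in h2)
    if not merged:
        raise UndefinedResultError("empty sketches")
    j = shared / len(merged)
    if j == 0:
        return 1.0
    return -math.log(2 * j / (1 + j)) / s1.k


def match_reference_species(
    query: GenomeAssembly,
    refs,
    threshold: float = 0.05,
    k: int = 21,
    sketch_size: int = 1000,
) -> list[tuple[str, float]]:
    """Reference genomes within a Mash distance (< threshold, strict) of the
    query, sorted by ascending distance.

    An empty list is a meaningful result: the query matches no reference
    species and is a candidate "dark" taxon.
    """
    qs = sketch(query, k=k, sketch_size=sketch_size)
    matches = []
    for ref in refs:
        d = mash_distance(qs, sketch(ref, k=k, sketch_size=sketch_size))
        if d < threshold:
            matches.append((ref.name, d))
    return sorted(matches, key=lambda t: (t[1], t[0]))
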