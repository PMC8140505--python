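"""Pairwise 16S rRNA gene comparison, clustering, and species assignment.

Identity is defined once for the whole package: matching sites over the
ungapped, unambiguous columns of a global alignment with free terminal
gaps (see ``polytax._align``). The 98.7% identity threshold separates
known species from candidate novel taxa; the Kimura 2-parameter (K2P)
distance corrects observed transition (P) and transversion (Q) fractions
for multiple substitutions:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Greedy centroid clustering reproduces the usual species-level
dereplication at 98.7% identity: sequences are processed longest-first
and each joins the first centroid it matches, else founds a new cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._align import NucAlignment, align_nucleotides
from .errors import SaturationError

KNOWN_SPECIES_IDENTITY = 0.987


@dataclass(frozen=True)
class Cluster:
    centroid: str               # id of the founding (centroid) sequence
    members: tuple[str, ...]    # ids, centroid included


@dataclass(frozen=True)
class ClusterSet:
    clusters: tuple[Cluster, ...]
    threshold: float

    def __len__(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, str]:
        """Map member id -> centroid id."""
        return {m: c.centroid for c in self.clusters for m in c.members}


@dataclass(frozen=True)
class SpeciesAssignment:
    best_name: str
    identity: float
    status: str     # "known" | "novel_candidate"


def align_identity(a: str, b: str) -> float:
    """Global alignment identity of two nucleotide sequences.

    Symmetric; ambiguous bases and gap columns are excluded from the
    comparison. Orientation is the caller's responsibility.
    """
    return align_nucleotides(a, b).identity


def k2p_distance(aln: NucAlignment) -> float:
    """Kimura 2-parameter distance (substitutions/site) from site counts.

    Raises SaturationError when the observed P and Q place the pair
    outside the model's domain (log argument <= 0).
    """
    if aln.compared_sites <= 0:
        raise ValueError("alignment has no comparable sites")
    p = aln.transitions / aln.compared_sites
    q = aln.transversions / aln.compared_sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"substitution fractions P={p:.3f}, Q={q:.3f} saturate the "
            "Kimura 2-parameter correction"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance_between(a: str, b: str) -> float:
    """Convenience: align two sequences and return their K2P distance."""
    return k2p_distance(align_nucleotides(a, b))


def greedy_cluster(
    seqs: list[tuple[str, str]], threshold: float = KNOWN_SPECIES_IDENTITY
) -> ClusterSet:
    """Greedy centroid clustering of (id, sequence) pairs.

    Sequences are processed in decreasing length order (ties keep input
    order); each joins the FIRST existing centroid with identity >=
    threshold, else founds a new cluster. Deterministic by construction.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    order = sorted(
        range(len(seqs)), key=lambda i: (-len(seqs[i][1]), i)
    )
    centroids: list[tuple[str, str]] = []       # (id, sequence)
    members: list[list[str]] = []
    for i in order:
        name, seq = seqs[i]
        for c_idx, (_, c_seq) in enumerate(centroids):
            if align_identity(seq, c_seq) >= threshold:
                members[c_idx].append(name)
                break
        else:
            centroids.append((name, seq))
            members.append([name])
    return ClusterSet(
        clusters=tuple(
            Cluster(centroid=c[0], members=tuple(m))
            for c, m in zip(centroids, members)
        ),
        threshold=threshold,
    )


def assign_known_species(
    query: str, refs: list[tuple[str, str]]
) -> SpeciesAssignment:
    """Assign a query 16S gene against named reference sequences.

    status = "known" iff the best identity is strictly > 98.7%; exactly
    98.7% (or below) makes the query a candidate novel taxon.
    """
    if not refs:
        raise ValueError("reference set is empty")
    best_name, best_identity = None, -1.0
    for name, seq in refs:
        ident = align_identity(query, seq)
        if ident > best_identity:
            best_name, best_identity = name, ident
    status = "known" if best_identity > KNOWN_SPECIES_IDENTITY else "novel_candidate"
    return SpeciesAssignment(
        best_name=best_name, identity=best_identity, status=status
    )
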