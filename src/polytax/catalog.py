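"""Nonredundant protein catalogs and catalog-vs-catalog coverage.

A gene catalog collapses near-identical predicted proteins into
representatives (the usual build uses 95% identity with the alignment
covering 90% of the shorter sequence) and then asks how much of another
catalog those representatives cover at looser homology cutoffs — 60%
identity for a functional match, 40% for a structural (fold-level)
match, both with the alignment spanning at least 70% of the query.

Protein identity here is matches / alignment length, gap columns
included in the length; this differs subtly from BLAST's local identity
and is applied uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import align_proteins


@dataclass(frozen=True)
class ProteinCatalog:
    """An ordered set of (id, amino-acid sequence) entries with an optional
    member -> representative cluster map."""

    entries: tuple[tuple[str, str], ...]
    cluster_map: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate protein ids in catalog")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def sequence(self, pid: str) -> str:
        for eid, seq in self.entries:
            if eid == pid:
                return seq
        raise KeyError(pid)


@dataclass(frozen=True)
class CoverageReport:
    subject_size: int
    n_hit: int
    identity_cutoff: float
    qcov_cutoff: float

    @property
    def coverage(self) -> float:
        return 100.0 * self.n_hit / self.subject_size


def _pair_stats(a: str, b: str) -> tuple[float, float, float]:
    """(identity, coverage of shorter, coverage of a) for one local
    alignment; zeros when nothing aligns."""
    hit = align_proteins(a, b)
    if hit is None:
        return 0.0, 0.0, 0.0
    shorter_span = hit.query_span if len(a) <= len(b) else hit.subject_span
    cov_short = shorter_span / min(len(a), len(b))
    cov_a = hit.query_span / len(a)
    return hit.identity, cov_short, cov_a


def build_catalog(
    proteins,
    identity: float = 0.95,
    cov_short: float = 0.90,
) -> ProteinCatalog:
    """Greedy incremental clustering into a nonredundant catalog.

    Sequences are sorted by decreasing length (input order breaks ties);
    each joins the first representative it matches at >= ``identity`` with
    the alignment covering >= ``cov_short`` of the SHORTER sequence, else
    becomes a representative itself. Building from the representatives of
    a built catalog returns them unchanged (idempotence).
    """
    proteins = list(proteins)
    if not proteins:
        raise ValueError("no input proteins")
    for pid, seq in proteins:
        if not seq or any(c not in "ACDEFGHIKLMNPQRSTVWYBXZJUO*" for c in seq):
            raise ValueError(f"protein {pid}: invalid amino-acid sequence")
    order = sorted(range(len(proteins)), key=lambda i: (-len(proteins[i][1]), i))
    reps: list[tuple[str, str]] = []
    cluster_map: dict[str, str] = {}
    for i in order:
        pid, seq = proteins[i]
        for rep_id, rep_seq in reps:
            ident, cov, _ = _pair_stats(seq, rep_seq)
            if ident >= identity and cov >= cov_short:
                cluster_map[pid] = rep_id
                break
        else:
            reps.append((pid, seq))
            cluster_map[pid] = pid
    return ProteinCatalog(entries=tuple(reps), cluster_map=cluster_map)


def _hit_subject_ids(
    query: ProteinCatalog,
    subject: ProteinCatalog,
    id_cutoff: float,
    qcov: float,
) -> set[str]:
    """Subject entries hit by at least one query at the given cutoffs.

    A subject is hit when some query aligns to it with identity >=
    id_cutoff and the alignment spanning >= qcov of the QUERY length.
    """
    hits: set[str] = set()
    for s_id, s_seq in subject.entries:
        for _, q_seq in query.entries:
            ident, _, cov_q = _pair_stats(q_seq, s_seq)
            if ident >= id_cutoff and cov_q >= qcov:
                hits.add(s_id)
                break
    return hits


def coverage_against(
    query: ProteinCatalog,
    subject: ProteinCatalog,
    id_cutoff: float = 0.40,
    qcov: float = 0.70,
) -> CoverageReport:
    """Fraction of subject entries covered by the query catalog."""
    if not len(subject):
        raise ValueError("subject catalog is empty")
    hits = _hit_subject_ids(query, subject, id_cutoff, qcov)
    return CoverageReport(
        subject_size=len(subject),
        n_hit=len(hits),
        identity_cutoff=id_cutoff,
        qcov_cutoff=qcov,
    )


def cumulative_coverage(
    genome_proteomes,
    subject: ProteinCatalog,
    id_cutoff: float = 0.40,
    qcov: float = 0.70,
    n_perm: int = 100,
    seed: int = 0,
):
    """Permutation curve of subject coverage as genomes accumulate.

    ``genome_proteomes`` is a list of per-genome protein lists. The value
    at k is the mean, over random genome orderings, of the percent of
    subject entries hit by the union of the first k genomes' hit sets;
    the endpoint equals the all-genome coverage exactly.

    Returns a DataFrame with columns k, mean, sd.
    """
    import pandas as pd

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    hit_sets = [
        frozenset(
            _hit_subject_ids(
                ProteinCatalog(entries=tuple(prot)), subject, id_cutoff, qcov
            )
        )
        for prot in genome_proteomes
    ]
    n = len(hit_sets)
    rng = np.random.default_rng(seed)
    curve = np.empty((n_perm, n), dtype=float)
    for p in range(n_perm):
        order = rng.permutation(n)
        seen: set = set()
        for k, idx in enumerate(order):
            seen |= hit_sets[idx]
            curve[p, k] = 100.0 * len(seen) / len(subject)
    return pd.DataFrame(
        {
            "k": np.arange(1, n + 1),
            "mean": curve.mean(axis=0),
            "sd": curve.std(axis=0, ddof=0),
        }
    )


def partition_by_annotation(
    subject: ProteinCatalog, labels: dict
) -> tuple[ProteinCatalog, ProteinCatalog]:
    """Split a catalog into (annotated, unannotated) sub-catalogs.

    ``labels`` maps every entry id to "annotated" or "unannotated"; a
    missing or unknown label raises. Entry order is preserved.
    """
    annotated, unannotated = [], []
    for pid, seq in subject.entries:
        if pid not in labels:
            raise KeyError(f"no annotation label for {pid}")
        label = labels[pid]
        if label == "annotated":
            annotated.append((pid, seq))
        elif label == "unannotated":
            unannotated.append((pid, seq))
        else:
            raise ValueError(f"unknown label {label!r} for {pid}")
    return (
        ProteinCatalog(entries=tuple(annotated)),
        ProteinCatalog(entries=tuple(unannotated)),
    )
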