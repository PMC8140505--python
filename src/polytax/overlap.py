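"""Cross-collection comparison of novel-taxon inventories.

Culture collections publish 16S rRNA gene sequences for their novel
isolates; comparing collections asks which novel taxa are shared and
which are unique to one effort. Within a collection, near-identical
sequences are first dereplicated at 98.7% identity. Across collections,
representatives closer than a K2P distance of 0.013 are considered the
same species; shared-species grouping is single-linkage over that
relation (connected components of the < 0.013 graph), so non-transitive
triples collapse into one taxon component — a deliberate, documented
choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import SaturationError
from .ssu import greedy_cluster, align_identity, k2p_distance_between

MIN_SSU_LENGTH = 1000      # genome-derived 16S genes shorter than ~1 kb are dropped
SHARED_SPECIES_K2P = 0.013


@dataclass(frozen=True)
class Collection:
    """A named culture collection: (id, 16S sequence) members."""

    name: str
    members: tuple[tuple[str, str], ...]

    def __post_init__(self):
        ids = [m[0] for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"collection {self.name}: duplicate member ids")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class OverlapMatrix:
    """Connected-component membership of taxa across collections.

    ``membership`` has one row per taxon component with a boolean column
    per collection; ``component_members`` lists the representative ids per
    component and collection.
    """

    membership: pd.DataFrame
    component_members: dict[int, dict[str, tuple[str, ...]]]

    @property
    def n_taxa(self) -> int:
        return len(self.membership)

    def shared_counts(self) -> dict[int, int]:
        """Number of taxon components spanning exactly k collections."""
        spans = self.membership.sum(axis=1)
        return spans.value_counts().sort_index().to_dict()

    def unique_counts(self) -> dict[str, int]:
        """Per collection, the number of taxa found only in it."""
        unique = self.membership[self.membership.sum(axis=1) == 1]
        return {c: int(unique[c].sum()) for c in self.membership.columns}

    def venn_counts(self) -> dict[str, int]:
        """Count of taxon components per membership region (collection
        names joined by '&')."""
        regions: dict[str, int] = {}
        for _, row in self.membership.iterrows():
            key = "&".join(c for c in self.membership.columns if row[c])
            regions[key] = regions.get(key, 0) + 1
        return regions


def dereplicate(
    collection: Collection, threshold: float = 0.987
) -> Collection:
    """Species-level dereplication of one collection.

    Members shorter than 1 kb are dropped with a warning; the remainder is
    greedily clustered at 98.7% identity and the centroids are returned.
    """
    kept = [(i, s) for i, s in collection.members if len(s) >= MIN_SSU_LENGTH]
    n_dropped = len(collection.members) - len(kept)
    if n_dropped:
        warnings.warn(
            f"collection {collection.name}: dropped {n_dropped} sequence(s) "
            f"shorter than {MIN_SSU_LENGTH} bp"
        )
    if not kept:
        raise ValueError(
            f"collection {collection.name}: no sequences of >= "
            f"{MIN_SSU_LENGTH} bp remain"
        )
    clusters = greedy_cluster(kept, threshold=threshold)
    seq_of = dict(kept)
    reps = tuple((c.centroid, seq_of[c.centroid]) for c in clusters.clusters)
    return Collection(name=collection.name, members=reps)


def cross_overlap(
    collections: list[Collection],
    max_distance: float = SHARED_SPECIES_K2P,
) -> OverlapMatrix:
    """Shared/unique taxon structure across dereplicated collections.

    Builds a graph over all representatives with an edge wherever the K2P
    distance is < max_distance (strict); connected components are taxa. A
    pair whose K2P correction saturates is treated as unambiguously
    distant (no edge), with a warning.
    """
    nodes = [
        (f"{c.name}:{mid}", c.name, mid, seq)
        for c in collections
        for mid, seq in c.members
    ]
    graph = nx.Graph()
    graph.add_nodes_from(n[0] for n in nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            try:
                d = k2p_distance_between(nodes[i][3], nodes[j][3])
            except SaturationError:
                warnings.warn(
                    f"K2P saturation between {nodes[i][0]} and {nodes[j][0]}; "
                    "treating the pair as distant"
                )
                continue
            if d < max_distance:
                graph.add_edge(nodes[i][0], nodes[j][0])
    by_key = {n[0]: n for n in nodes}
    names = [c.name for c in collections]
    rows = []
    component_members: dict[int, dict[str, tuple[str, ...]]] = {}
    components = sorted(nx.connected_components(graph), key=min)
    for comp_id, comp in enumerate(components):
        present = {name: [] for name in names}
        for key in sorted(comp):
            _, cname, mid, _ = by_key[key]
            present[cname].append(mid)
        component_members[comp_id] = {
            name: tuple(v) for name, v in present.items() if v
        }
        rows.append({name: bool(present[name]) for name in names})
    membership = pd.DataFrame(rows, columns=names, dtype=bool)
    membership.index.name = "component"
    return OverlapMatrix(
        membership=membership, component_members=component_members
    )


def wanted_coverage(
    queries: Collection,
    targets: Collection,
    threshold: float = 0.987,
) -> pd.DataFrame:
    """Which target taxa are covered by the query collection.

    For every target sequence (e.g. a "most wanted" OTU), find the best
    query identity; covered iff strictly > 98.7%. Returns a DataFrame with
    columns target, best_query, identity, covered.
    """
    if not len(queries) or not len(targets):
        raise ValueError("both collections must be non-empty")
    rows = []
    for t_id, t_seq in targets.members:
        best_q, best_ident = None, -1.0
        for q_id, q_seq in queries.members:
            ident = align_identity(t_seq, q_seq)
            if ident > best_ident:
                best_q, best_ident = q_id, ident
        rows.append(
            {
                "target": t_id,
                "best_query": best_q,
                "identity": best_ident,
                "covered": best_ident > threshold,
            }
        )
    return pd.DataFrame(rows, columns=["target", "best_query", "identity", "covered"])
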