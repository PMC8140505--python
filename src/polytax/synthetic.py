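"""Synthetic genomes, 16S genes, proteomes, and multi-study OTU tables.

Every generator is seeded and fully deterministic: the same design always
yields bit-identical sequences and tables. Divergence is introduced by
point substitution sampled WITHOUT replacement, so the realized identity
of a generated pair is exact, not approximate — parameter-recovery tests
downstream can therefore be sharp.

The generators emulate structure, not biology: no codon usage, no rRNA
secondary structure, no realistic gene content. Abundances follow a
lognormal law as a generic heavy-tailed stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeAssembly
from .prevalence import StudyTable

_NUC = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


# ---------------------------------------------------------------------------
# designs


@dataclass(frozen=True)
class GenomePairDesign:
    """A pair of genomes diverged from a common ancestor to a target ANI."""

    ancestor_length: int = 100_000
    target_ani: float = 0.95
    indel_rate: float = 0.0
    n_contigs: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.ancestor_length < 10_000:
            raise ValueError("ancestor_length must be >= 10,000 bp")
        if not 0.5 < self.target_ani <= 1.0:
            raise ValueError(
                "target_ani must lie in (0.5, 1.0]; identities below 50% are "
                "outside the validity range of fragment-based ANI"
            )
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")


@dataclass(frozen=True)
class ProteomePairDesign:
    """Two proteomes with a designed number of conserved homolog pairs."""

    n1: int = 20
    n2: int = 20
    conserved_pairs: int = 10
    conserved_identity: float = 0.9
    protein_length: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.conserved_pairs > min(self.n1, self.n2):
            raise ValueError("conserved_pairs cannot exceed min(n1, n2)")
        if self.conserved_pairs < 0 or self.n1 < 1 or self.n2 < 1:
            raise ValueError("protein counts must be positive")
        if not 0 < self.conserved_identity <= 1.0:
            raise ValueError("conserved_identity must lie in (0, 1]")
        if self.conserved_identity <= 0.4:
            raise ValueError(
                "conserved_identity <= 0.4 would place designed homologs below "
                "the 40% conserved-protein hit criterion, leaving the truth "
                "POCP undefined"
            )


@dataclass(frozen=True)
class CommunityDesign:
    """Multi-study community layout with per-study taxon presence
    probabilities and lognormal abundances."""

    n_studies: int
    samples_per_study: tuple[int, ...]
    taxon_pool: tuple[str, ...]
    presence_prob: tuple[tuple[float, ...], ...]  # study x taxon
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if len(self.samples_per_study) != self.n_studies:
            raise ValueError("samples_per_study length must equal n_studies")
        pp = np.asarray(self.presence_prob, dtype=float)
        if pp.shape != (self.n_studies, len(self.taxon_pool)):
            raise ValueError("presence_prob must be n_studies x n_taxa")
        if ((pp < 0) | (pp > 1)).any():
            raise ValueError("presence probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# sequence helpers


def _random_nuc(rng: np.random.Generator, length: int) -> np.ndarray:
    return _NUC[rng.integers(0, 4, size=length)]


def _substitute(
    rng: np.random.Generator,
    seq: np.ndarray,
    n_sub: int,
    alphabet: np.ndarray = _NUC,
) -> np.ndarray:
    """Substitute exactly n_sub distinct positions to a different base/residue."""
    out = seq.copy()
    if n_sub == 0:
        return out
    k = len(alphabet)
    lookup = {c: i for i, c in enumerate(alphabet)}
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    current = np.array([lookup[c] for c in out[positions]])
    # a uniform nonzero offset modulo k always lands on a different letter
    offsets = rng.integers(1, k, size=n_sub)
    out[positions] = alphabet[(current + offsets) % k]
    return out


def _apply_indels(
    rng: np.random.Generator, seq: np.ndarray, indel_rate: float
) -> np.ndarray:
    n_indels = rng.poisson(indel_rate * len(seq))
    s = seq
    for _ in range(n_indels):
        pos = int(rng.integers(0, len(s)))
        size = int(rng.integers(1, 6))
        if rng.random() < 0.5:
            s = np.concatenate([s[:pos], _random_nuc(rng, size), s[pos:]])
        else:
            s = np.concatenate([s[:pos], s[pos + size:]])
    return s


def _split_contigs(seq: str, n_contigs: int) -> list[str]:
    bounds = np.linspace(0, len(seq), n_contigs + 1).astype(int)
    return [seq[bounds[i]: bounds[i + 1]] for i in range(n_contigs)]


# ---------------------------------------------------------------------------
# generators


def make_genome_pair(
    design: GenomePairDesign,
) -> tuple[GenomeAssembly, GenomeAssembly, float]:
    """Generate two genomes diverged by uniform point substitution.

    Returns (genome_a, genome_b, truth_ani) where truth_ani is the exact
    site-wise identity of the known ancestral alignment:
    1 - round(L * (1 - target_ani)) / L.
    """
    rng = np.random.default_rng(design.seed)
    ancestor = _random_nuc(rng, design.ancestor_length)
    n_sub = round(design.ancestor_length * (1.0 - design.target_ani))
    derived = _substitute(rng, ancestor, n_sub)
    truth_ani = 1.0 - n_sub / design.ancestor_length
    if design.indel_rate > 0:
        derived = _apply_indels(rng, derived, design.indel_rate)
    g1 = GenomeAssembly(
        name=f"synth_a_seed{design.seed}",
        contigs=_split_contigs("".join(ancestor), design.n_contigs),
    )
    g2 = GenomeAssembly(
        name=f"synth_b_seed{design.seed}",
        contigs=_split_contigs("".join(derived), design.n_contigs),
    )
    return g1, g2, truth_ani


def make_16s_pair(
    length: int, target_identity: float, seed: int = 0
) -> tuple[str, str]:
    """A pair of 16S-scale gene sequences at an exact ungapped identity.

    The realized number of mismatching sites is round(length * (1 -
    target_identity)), placed uniformly without replacement.
    """
    if length < 1200:
        raise ValueError("full-length 16S genes are >= 1,200 bp")
    if not 0 < target_identity <= 1.0:
        raise ValueError("target_identity must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    a = _random_nuc(rng, length)
    n_sub = round(length * (1.0 - target_identity))
    b = _substitute(rng, a, n_sub)
    return "".join(a), "".join(b)


def make_proteome_pair(
    design: ProteomePairDesign,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], float]:
    """Two proteomes sharing exactly ``conserved_pairs`` designed homologs.

    Conserved partners are full-length copies mutated to
    ``conserved_identity``; the remaining proteins are independent random
    sequences. Returns (proteome_1, proteome_2, truth_pocp) with
    truth_pocp = 100 * (C1 + C2) / (T1 + T2) = 100 * 2c / (n1 + n2).
    """
    rng = np.random.default_rng(design.seed)
    length = design.protein_length

    def random_protein() -> np.ndarray:
        return _AA[rng.integers(0, len(_AA), size=length)]

    p1 = [random_protein() for _ in range(design.n1)]
    p2: list[np.ndarray] = []
    n_sub = round(length * (1.0 - design.conserved_identity))
    for i in range(design.conserved_pairs):
        p2.append(_substitute(rng, p1[i], n_sub, alphabet=_AA))
    for _ in range(design.n2 - design.conserved_pairs):
        p2.append(random_protein())
    truth_pocp = (
        100.0 * 2 * design.conserved_pairs / (design.n1 + design.n2)
    )
    prot1 = [(f"a_{i}", "".join(s)) for i, s in enumerate(p1)]
    prot2 = [(f"b_{i}", "".join(s)) for i, s in enumerate(p2)]
    return prot1, prot2, truth_pocp


def make_otu_tables(design: CommunityDesign) -> list[StudyTable]:
    """Simulate one relative-abundance table per study.

    Per sample, each taxon is present with its study's presence
    probability; present taxa receive lognormal abundances normalized to
    sum to 1. A sample where no taxon of the pool was drawn stays all-zero
    (its reads would belong to taxa outside the pool), so row sums are
    either 1 or 0.
    """
    rng = np.random.default_rng(design.seed)
    pp = np.asarray(design.presence_prob, dtype=float)
    tables = []
    for s in range(design.n_studies):
        n = design.samples_per_study[s]
        present = rng.random((n, pp.shape[1])) < pp[s]
        raw = rng.lognormal(
            design.abundance_mu, design.abundance_sigma, size=present.shape
        )
        raw *= present
        sums = raw.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.where(sums > 0, raw / np.where(sums == 0, 1, sums), 0.0)
        df = pd.DataFrame(
            mat,
            index=[f"s{s}_sample{i}" for i in range(n)],
            columns=list(design.taxon_pool),
        )
        tables.append(StudyTable(study_id=f"study_{s}", abundances=df))
    return tables


def corrupt_with_ambiguity(
    seq: str, fraction: float, seed: int = 0
) -> str:
    """Replace a fraction of positions with 'N' (explicit ambiguity
    injection for robustness tests)."""
    rng = np.random.default_rng(seed)
    arr = np.array(list(seq))
    n = round(len(arr) * fraction)
    if n:
        pos = rng.choice(len(arr), size=n, replace=False)
        arr[pos] = "N"
    return "".join(arr)
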