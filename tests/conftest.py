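import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import polytax as pt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def two_group_ssu():
    """Ten 16S-scale sequences in two groups: within-group identity >= 0.99,
    between-group <= 0.95. Returns (records, group_of) with group labels."""
    rng = np.random.default_rng(11)
    base1 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1500)])
    # second base diverged well below the between-group ceiling
    _, base2 = pt.make_16s_pair(1500, 0.90, seed=12)
    base2_seq = base2
    records, group_of = [], {}

    def variants(base, prefix, n, seed0):
        out = []
        for v in range(n):
            _, var = _mutate(base, 0.9975, seed0 + v)
            out.append((f"{prefix}{v}", var))
        return out

    def _mutate(base, identity, seed):
        arr = np.array(list(base))
        local = np.random.default_rng(seed)
        n_sub = round(len(arr) * (1 - identity))
        pos = local.choice(len(arr), n_sub, replace=False)
        nuc = np.array(list("ACGT"))
        lookup = {c: i for i, c in enumerate(nuc)}
        for p in pos:
            arr[p] = nuc[(lookup[arr[p]] + local.integers(1, 4)) % 4]
        return base, "".join(arr)

    for name, seq in variants(base1, "g1_", 5, 100):
        records.append((name, seq))
        group_of[name] = 1
    for name, seq in variants(base2_seq, "g2_", 5, 200):
        records.append((name, seq))
        group_of[name] = 2
    return records, group_of


@pytest.fixture(scope="session")
def small_proteome_pair():
    """A 5x5 proteome pair with 3 designed conserved homolog pairs, small
    enough for the brute-force Smith-Waterman oracle."""
    design = pt.ProteomePairDesign(
        n1=5, n2=5, conserved_pairs=3, conserved_identity=0.8,
        protein_length=70, seed=4,
    )
    return pt.make_proteome_pair(design)
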