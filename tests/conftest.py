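import itertools
import math

import pytest

from mirextra.io_model import MiRNARecord
from mirextra.synthetic import SyntheticSpec, generate_dataset

MIR1 = MiRNARecord("hsa-miR-1", "UGGAAUGUAAAGAAGUAUGUAU")


def brute_force_one_sided_p(x, y):
    """Enumerate all C(n1+n2, n1) group labelings of the pooled data and
    return P(rank-sum of the first group >= observed). Midranks handle ties.
    Independent of the package's shift-algorithm implementation."""
    pooled = list(x) + list(y)
    n = len(pooled)
    n1 = len(x)
    # midranks
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    observed = sum(ranks[:n1])
    hits = total = 0
    for subset in itertools.combinations(range(n), n1):
        total += 1
        if sum(ranks[i] for i in subset) >= observed - 1e-9:
            hits += 1
    return hits / total


def brute_force_max_disjoint(sequence, motif):
    """Maximum number of mutually disjoint occurrences of a motif, by
    exhaustive search over occurrence subsets (fixtures kept short)."""
    positions = [
        i for i in range(len(sequence) - len(motif) + 1)
        if sequence[i : i + len(motif)] == motif
    ]
    best = 0
    for r in range(len(positions), 0, -1):
        for combo in itertools.combinations(positions, r):
            if all(b - a >= len(motif) for a, b in zip(combo, combo[1:])):
                return r
    return best


@pytest.fixture(scope="session")
def small_dataset():
    """One small planted-signal dataset shared across tests."""
    spec = SyntheticSpec(
        n_changed=30,
        n_unchanged=120,
        utr_length_range=(200, 400),
        n_decoy_mirnas=10,
        seed=42,
    )
    return generate_dataset(spec)


def rna_rc_to_dna(rna):
    """Independent reverse-complement oracle: RNA window -> DNA hexamer."""
    comp = {"A": "T", "C": "G", "G": "C", "U": "A"}
    return "".join(comp[b] for b in reversed(rna))
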