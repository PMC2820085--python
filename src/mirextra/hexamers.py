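"""miRNA seed-region hexamers and non-overlapping motif counting.

A miRNA recognises its targets mainly through its first eight nucleotides.
Three 6-nt windows of that region define three "hexamers" on the mRNA: the
reverse complements of miRNA positions 1-6, 2-7 and 3-8 (1-based, 5'->3' on
the miRNA), written 5'->3' on the mRNA strand in DNA alphabet. Hexamer 2 is
the classical seed match (miRNA positions 2-7).

Occurrences of a hexamer on a 3'UTR are counted *non-overlapping* with a
greedy 5'->3' scan, and normalised by the full UTR length to give
hexamers-per-nucleotide values in [0, 1/6]. An optional per-position
conservation mask restricts counting to windows whose six positions are all
conserved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_model import MiRNARecord, UTRRecord

_RNA_TO_DNA_RC = str.maketrans("ACGU", "TGCA")
_DNA_RC = str.maketrans("ACGT", "TGCA")
_VALID_HEX = frozenset("ACGT")


@dataclass(frozen=True)
class MiRNAHexamers:
    """The three 3'UTR hexamers complementary to a miRNA's 5' region."""

    mirna_id: str
    hex1: str  # reverse complement of miRNA positions 1-6
    hex2: str  # positions 2-7: the seed match
    hex3: str  # positions 3-8

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.hex1, self.hex2, self.hex3)


def reverse_complement_dna(seq: str) -> str:
    return seq.translate(_DNA_RC)[::-1]


def mirna_to_hexamers(mirna: MiRNARecord) -> MiRNAHexamers:
    """Derive hexamers 1/2/3 from a mature miRNA sequence.

    hex_i is the DNA reverse complement of miRNA positions i..i+5. Requires
    the miRNA to be at least 8 nt long so that positions 1-8 exist.
    """
    seq = mirna.sequence
    if len(seq) < 8:
        raise ValueError(
            f"miRNA {mirna.mirna_id!r} is too short ({len(seq)} nt < 8)"
        )
    hexes = [seq[i : i + 6].translate(_RNA_TO_DNA_RC)[::-1] for i in range(3)]
    return MiRNAHexamers(mirna.mirna_id, *hexes)


def all_hexamers() -> list[str]:
    """All 4096 DNA 6-mers in lexicographic order."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=6)]


def _check_hexamer(hexamer: str) -> None:
    if len(hexamer) != 6 or set(hexamer) - _VALID_HEX:
        raise ValueError(f"invalid hexamer {hexamer!r}: need 6 characters over ACGT")


def count_nonoverlapping(
    sequence: str, hexamer: str, mask: str | None = None
) -> int:
    """Greedy 5'->3' count of non-overlapping hexamer occurrences.

    At each position: if the 6-mer matches (and, with a mask, all six mask
    positions are '1'), count it and jump 6 nt; otherwise advance 1 nt.
    Windows containing N never match. The greedy count equals the maximum
    number of mutually disjoint occurrences of a fixed-length motif.
    """
    _check_hexamer(hexamer)
    if mask is not None and len(mask) != len(sequence):
        raise ValueError("mask length differs from sequence length")
    count = 0
    pos = 0
    while True:
        hit = sequence.find(hexamer, pos)
        if hit < 0:
            break
        if mask is None or mask[hit : hit + 6] == "111111":
            count += 1
            pos = hit + 6
        else:
            pos = hit + 1
    return count


def normalized_count(sequence: str, hexamer: str, mask: str | None = None) -> float:
    """Non-overlapping count divided by the full UTR length (hexamers/nt).

    The denominator is the full sequence length even when a conservation
    mask restricts which occurrences are counted.
    """
    if len(sequence) == 0:
        raise ValueError("cannot normalise a count over an empty sequence")
    return count_nonoverlapping(sequence, hexamer, mask) / len(sequence)


def hexamers_for_mirnas(
    mirnas: Iterable[MiRNARecord],
) -> tuple[list[MiRNAHexamers], list[str]]:
    """Map miRNAs to hexamer triples and collect the distinct hexamers.

    The same hexamer may belong to several miRNAs; it appears once in the
    returned hexamer list (first-seen order) and every owning miRNA shares
    its single test result downstream.
    """
    mapping = [mirna_to_hexamers(m) for m in mirnas]
    seen: dict[str, None] = {}
    for mh in mapping:
        for h in mh.triple:
            seen.setdefault(h)
    return mapping, list(seen)


def _count_all_against_index(
    sequence: str, hexamers: Sequence[str], mask: str | None
) -> np.ndarray:
    """Count every requested hexamer in one pass over the sequence.

    Builds an occurrence index (positions of each distinct 6-mer) in a
    single scan, then resolves the greedy non-overlap rule per hexamer by
    walking its position list. Used when the hexamer panel is large (e.g.
    all 4096); equivalent to `count_nonoverlapping` per hexamer.
    """
    index: dict[str, list[int]] = {}
    wanted = set(hexamers)
    for i in range(len(sequence) - 5):
        window = sequence[i : i + 6]
        if window in wanted:
            index.setdefault(window, []).append(i)
    counts = np.zeros(len(hexamers), dtype=np.float64)
    for j, h in enumerate(hexamers):
        positions = index.get(h)
        if not positions:
            continue
        count = 0
        next_free = 0
        for pos in positions:
            if pos < next_free:
                continue
            if mask is None or mask[pos : pos + 6] == "111111":
                count += 1
                next_free = pos + 6
        counts[j] = count
    return counts


def build_count_matrix(
    utrs: Sequence[UTRRecord],
    hexamers: Sequence[str] | None = None,
    use_masks: bool = False,
) -> pd.DataFrame:
    """Normalized-count matrix: genes (rows, input order) x hexamers (columns).

    ``hexamers=None`` counts all 4096 6-mers. With ``use_masks`` every UTR
    must carry a conservation mask. Values are non-overlapping counts
    divided by full UTR length, hence in [0, 1/6]. Genes with empty
    sequences are rejected (they must be filtered upstream).
    """
    if hexamers is None:
        hexamers = all_hexamers()
    hexamers = list(dict.fromkeys(hexamers))
    if not hexamers:
        raise ValueError("no hexamers to count")
    for h in hexamers:
        _check_hexamer(h)
    if use_masks:
        missing = [u.gene_id for u in utrs if u.mask is None]
        if missing:
            raise ValueError(
                f"{len(missing)} UTRs lack a conservation mask: "
                f"{missing[:5]}{' ...' if len(missing) > 5 else ''}"
            )
    empty = [u.gene_id for u in utrs if len(u.sequence) == 0]
    if empty:
        raise ValueError(f"zero-length UTRs cannot be counted: {empty[:5]}")

    values = np.empty((len(utrs), len(hexamers)), dtype=np.float64)
    use_index = len(hexamers) > 48
    for i, utr in enumerate(utrs):
        mask = utr.mask if use_masks else None
        if use_index:
            row = _count_all_against_index(utr.sequence, hexamers, mask)
        else:
            row = np.array(
                [count_nonoverlapping(utr.sequence, h, mask) for h in hexamers],
                dtype=np.float64,
            )
        values[i] = row / len(utr.sequence)
    return pd.DataFrame(values, index=[u.gene_id for u in utrs], columns=hexamers)


def alignment_to_mask(seq_a: str, seq_b: str) -> str:
    """Convert a pairwise alignment of a UTR to a conservation mask.

    ``seq_a`` is the gapped reference (e.g. human) sequence, ``seq_b`` the
    gapped orthologue (e.g. mouse); both equal length. The mask covers the
    ungapped reference and marks a position 1 iff the aligned bases are
    identical and neither is a gap.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    bits = []
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a == "-":
            continue
        bits.append("1" if (b != "-" and a == b) else "0")
    return "".join(bits)
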