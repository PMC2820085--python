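"""Input parsing and gene-set assembly.

Reads the external file formats the pipeline consumes -- 3'UTR and mature
miRNA FASTA, one-ID-per-line gene lists, gene->metric TSV tables, alias->ID
maps, per-position conservation masks and per-(gene, miRNA) score tables --
and builds the changed/unchanged gene partition that the rank statistics
operate on.

Conventions
-----------
* 3'UTR sequences are stored in DNA space: uppercased, ``U`` converted to
  ``T`` at read time, so that all downstream motif work happens on the mRNA
  strand written as DNA (the convention of genome-browser reference files).
* When a gene has several annotated 3'UTR isoforms, only the longest is
  kept (first occurrence wins on exact length ties).
* Alias mapping is many-to-one and never silent: unmapped aliases are
  returned to the caller alongside the mapped set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_UTR = frozenset("ACGTN")
_VALID_MIRNA = frozenset("ACGU")


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA input; carries the line number."""


@dataclass
class UTRRecord:
    """One gene's 3'UTR sequence plus optional per-position conservation mask.

    ``mask`` is a string of ``0``/``1`` with ``1`` marking a position whose
    base is conserved (e.g. identical between human and mouse); it must have
    the same length as ``sequence``.
    """

    gene_id: str
    sequence: str
    mask: str | None = None

    def __post_init__(self) -> None:
        if self.mask is not None and len(self.mask) != len(self.sequence):
            raise ValueError(
                f"mask length {len(self.mask)} != sequence length "
                f"{len(self.sequence)} for gene {self.gene_id!r}"
            )


@dataclass
class MiRNARecord:
    """A mature miRNA sequence in RNA alphabet, 5'->3'."""

    mirna_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_MIRNA
        if bad:
            raise ValueError(
                f"miRNA {self.mirna_id!r} contains non-RNA characters {sorted(bad)}"
            )
        if len(self.sequence) < 8:
            raise ValueError(
                f"miRNA {self.mirna_id!r} is {len(self.sequence)} nt long; "
                "at least 8 nt (positions 1-8) are required"
            )


@dataclass
class ExpressionInput:
    """The changed/unchanged partition of the gene universe.

    Either supplied directly as two lists, or derived from a fold-change-like
    metric by taking the ``n_changed`` most extreme genes as changed.
    """

    changed: set[str]
    unchanged: set[str]
    metric: dict[str, float] | None = None
    n_changed: int | None = None

    def __post_init__(self) -> None:
        overlap = self.changed & self.unchanged
        if overlap:
            raise ValueError(
                f"changed and unchanged sets overlap: {sorted(overlap)[:5]} ..."
            )


@dataclass
class IDMap:
    """Many-to-one alias -> canonical gene ID lookup."""

    mapping: dict[str, str] = field(default_factory=dict)

    def translate(self, aliases: Iterable[str]) -> tuple[list[str], list[str]]:
        """Map aliases to canonical IDs; returns (mapped, unmapped aliases)."""
        mapped: list[str] = []
        unmapped: list[str] = []
        for alias in aliases:
            target = self.mapping.get(alias)
            if target is None:
                unmapped.append(alias)
            else:
                mapped.append(target)
        return mapped, unmapped


def _iter_fasta(path: str | Path) -> Iterable[tuple[str, str]]:
    """Yield (first header token, sequence) pairs; validates structure.

    Hand-rolled only to the extent of tracking line numbers for error
    reporting; the format handled is plain multi-line FASTA.
    """
    path = Path(path)
    header: str | None = None
    chunks: list[str] = []
    n_records = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
                n_records += 1
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                chunks.append(line)
    if header is not None:
        yield header, "".join(chunks)
    if n_records == 0:
        raise FastaParseError(f"{path}: no FASTA records found")


def read_utr_fasta(path: str | Path) -> list[UTRRecord]:
    """Read 3'UTR sequences, keeping the longest UTR per gene ID.

    Sequences are uppercased and U->T converted. Among multiple entries for
    one gene the longest is retained; equal lengths keep the first seen.
    Record order follows first occurrence of each gene in the file.
    """
    best: dict[str, str] = {}
    order: list[str] = []
    for gene_id, seq in _iter_fasta(path):
        seq = seq.upper().replace("U", "T")
        bad = set(seq) - _VALID_UTR
        if bad:
            raise FastaParseError(
                f"{path}: gene {gene_id!r} contains invalid characters {sorted(bad)}"
            )
        if gene_id not in best:
            best[gene_id] = seq
            order.append(gene_id)
        elif len(seq) > len(best[gene_id]):
            best[gene_id] = seq
    return [UTRRecord(g, best[g]) for g in order]


def write_utr_fasta(records: Iterable[UTRRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def read_mirna_fasta(path: str | Path) -> list[MiRNARecord]:
    """Read mature miRNA sequences (miRBase style); T is accepted and read as U."""
    records = []
    for mirna_id, seq in _iter_fasta(path):
        seq = seq.upper().replace("T", "U")
        records.append(MiRNARecord(mirna_id, seq))
    return records


def read_mask_fasta(path: str | Path) -> dict[str, str]:
    """Read per-gene conservation masks (FASTA-like, sequence of 0/1)."""
    masks: dict[str, str] = {}
    for gene_id, mask in _iter_fasta(path):
        bad = set(mask) - {"0", "1"}
        if bad:
            raise FastaParseError(
                f"{path}: mask for {gene_id!r} contains characters {sorted(bad)}; "
                "expected only 0/1"
            )
        masks[gene_id] = mask
    return masks


def attach_masks(utrs: list[UTRRecord], masks: Mapping[str, str]) -> list[UTRRecord]:
    """Return UTR records with masks attached; errors if lengths disagree."""
    out = []
    for rec in utrs:
        mask = masks.get(rec.gene_id)
        out.append(UTRRecord(rec.gene_id, rec.sequence, mask))
    return out


def read_id_map(path: str | Path) -> IDMap:
    """Read a two-column TSV of alias -> canonical gene ID."""
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            mapping[parts[0]] = parts[1]
    return IDMap(mapping)


def read_gene_list(
    path: str | Path, id_map: IDMap | None = None
) -> tuple[set[str], list[str]]:
    """Read a one-ID-per-line gene list, optionally translating aliases.

    Returns the deduplicated set of (canonical) IDs and the list of aliases
    that could not be translated. An empty resulting set is an error.
    """
    aliases: list[str] = []
    with open(path) as handle:
        for raw in handle:
            line = raw.strip()
            if line:
                aliases.append(line)
    if id_map is not None:
        mapped, unmapped = id_map.translate(aliases)
    else:
        mapped, unmapped = aliases, []
    genes = set(mapped)
    if unmapped:
        logger.warning(
            "%d aliases in %s could not be mapped to canonical IDs: %s%s",
            len(unmapped), path, unmapped[:5], " ..." if len(unmapped) > 5 else "",
        )
    if not genes:
        raise ValueError(f"{path}: gene list is empty after ID mapping")
    return genes, unmapped


def read_metric_tsv(
    path: str | Path, id_map: IDMap | None = None
) -> tuple[dict[str, float], list[str]]:
    """Read a two-column TSV of gene ID and fold-change-like metric.

    A non-numeric second field on the first line is treated as a header.
    Duplicate gene IDs keep the first value. Returns (metric map, unmapped
    aliases).
    """
    table: dict[str, float] = {}
    unmapped: list[str] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            gene, value = parts[0].strip(), parts[1].strip()
            try:
                metric = float(value)
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise ValueError(f"{path}:{lineno}: non-numeric metric {value!r}")
            if id_map is not None:
                canonical = id_map.mapping.get(gene)
                if canonical is None:
                    unmapped.append(gene)
                    continue
                gene = canonical
            table.setdefault(gene, metric)
    if not table:
        raise ValueError(f"{path}: no metric rows parsed")
    if unmapped:
        logger.warning("%d metric rows dropped (unmapped aliases)", len(unmapped))
    return table, unmapped


def read_score_table(path: str | Path) -> dict[tuple[str, str], float]:
    """Read a three-column TSV of (gene_id, mirna_id, target-prediction score)."""
    scores: dict[tuple[str, str], float] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            try:
                value = float(parts[2])
            except ValueError:
                if lineno == 1:
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric score {parts[2]!r}")
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative score {value}")
            scores[(parts[0].strip(), parts[1].strip())] = value
    if not scores:
        raise ValueError(f"{path}: no score rows parsed")
    return scores


def split_by_metric(
    table: Mapping[str, float], n_changed: int, direction: str = "up"
) -> ExpressionInput:
    """Partition genes into changed/unchanged by sorting on the metric.

    ``direction='up'`` takes the ``n_changed`` genes with the highest metric
    as changed; ``'down'`` the lowest. Ties at the boundary are broken by
    gene-ID lexicographic order so the split is deterministic.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if not 1 <= n_changed < len(table):
        raise ValueError(
            f"n_changed={n_changed} out of range for {len(table)} genes "
            "(need at least one gene on each side)"
        )
    sign = -1.0 if direction == "up" else 1.0
    ordered = sorted(table, key=lambda g: (sign * table[g], g))
    changed = set(ordered[:n_changed])
    unchanged = set(ordered[n_changed:])
    return ExpressionInput(changed, unchanged, metric=dict(table), n_changed=n_changed)


def complement_background(changed: set[str], universe: set[str]) -> ExpressionInput:
    """Use every universe gene not in ``changed`` as the unchanged background.

    Changed genes missing from the universe are dropped with a warning; an
    empty changed set (before or after dropping) is an error.
    """
    if not changed:
        raise ValueError("changed gene set is empty")
    missing = changed - universe
    if missing:
        logger.warning(
            "%d changed genes absent from the UTR universe were dropped: %s%s",
            len(missing), sorted(missing)[:5], " ..." if len(missing) > 5 else "",
        )
    kept = changed & universe
    if not kept:
        raise ValueError("no changed gene has a 3'UTR record")
    return ExpressionInput(kept, universe - kept)


def restrict_to_universe(
    expression: ExpressionInput, universe: set[str]
) -> ExpressionInput:
    """Drop genes without a UTR record from both sides of the partition."""
    changed = expression.changed & universe
    unchanged = expression.unchanged & universe
    dropped = (len(expression.changed) - len(changed)) + (
        len(expression.unchanged) - len(unchanged)
    )
    if dropped:
        logger.info("%d expression-input genes lack a 3'UTR and were dropped", dropped)
    if not changed or not unchanged:
        raise ValueError("changed or unchanged set empty after UTR filtering")
    return ExpressionInput(
        changed, unchanged, metric=expression.metric, n_changed=expression.n_changed
    )
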