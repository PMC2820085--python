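"""Per-miRNA scoring, ranking, weight calibration and score-table mode.

Each miRNA owns three hexamer enrichment values (-lnp of hexamers 1, 2
and 3). The combined score weights them

    combined = w1 * lnp1 + 1 * lnp2 + w3 * lnp3

with defaults w1 = 0.6 and w3 = 0: the seed-match hexamer carries full
weight, the 5'-shifted flanking hexamer 1 helps discriminate miRNAs that
share a seed, and hexamer 3 is reported but does not enter the score.

The weight defaults come from a grid calibration: on datasets where the
truly perturbed miRNA is known, the normalized margin between the correct
miRNA's score and its best competitor with a different hexamer triple is
summed across datasets and maximised over a 101 x 101 lattice of
(w1, w3) in [0, 1] at 0.01 steps. :func:`optimize_weights` re-runs that
search on caller-supplied calibration data.

Score-table mode replaces hexamer counts by externally computed per-(gene,
miRNA) target-prediction scores and applies the same one-sided rank-sum
test per miRNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hexamers import MiRNAHexamers
from .io_model import ExpressionInput
from .rank_stats import (
    HexamerResult,
    display_2dp,
    floor_and_lnp,
    wilcoxon_one_sided,
)

logger = logging.getLogger(__name__)

DEFAULT_W1 = 0.6
DEFAULT_W3 = 0.0
GRID_STEP = 0.01


@dataclass(frozen=True)
class MiRNAScore:
    """A miRNA's three hexamer -lnp values and combined score."""

    mirna_id: str
    lnp1: float
    lnp2: float
    lnp3: float
    combined: float
    hexamers: MiRNAHexamers | None = None


@dataclass
class WeightGrid:
    """Full audit record of the weight-calibration objective surface."""

    w1_values: np.ndarray
    w3_values: np.ndarray
    objective: np.ndarray  # shape (len(w1_values), len(w3_values))

    @property
    def n_points(self) -> int:
        return self.objective.size


def combined_score(
    lnp1: float,
    lnp2: float,
    lnp3: float,
    w1: float = DEFAULT_W1,
    w3: float = DEFAULT_W3,
) -> float:
    """Weighted hexamer score: w1*lnp1 + lnp2 + w3*lnp3 (seed weight fixed at 1)."""
    if lnp1 < 0 or lnp2 < 0 or lnp3 < 0:
        raise ValueError("-lnp values must be non-negative")
    return w1 * lnp1 + lnp2 + w3 * lnp3


def rank_mirnas(
    results: Sequence[HexamerResult],
    mapping: Sequence[MiRNAHexamers],
    mirna_filter: set[str] | None = None,
    w1: float = DEFAULT_W1,
    w3: float = DEFAULT_W3,
) -> list[MiRNAScore]:
    """Score and rank miRNAs by combined hexamer enrichment.

    Every hexamer of every mapped miRNA must carry a test result; miRNAs
    sharing a hexamer each receive its -lnp independently. Output is
    sorted by combined score descending, ties broken by lnp2 then by
    miRNA ID. Filter names that match no miRNA are warned about and
    skipped.
    """
    lnp_by_hex = {r.hexamer: r.lnp for r in results}
    if mirna_filter is not None:
        known = {m.mirna_id for m in mapping}
        for name in sorted(mirna_filter - known):
            logger.warning("miRNA filter entry %r matches no known miRNA", name)
        mapping = [m for m in mapping if m.mirna_id in mirna_filter]
    scores = []
    for mh in mapping:
        try:
            lnp1, lnp2, lnp3 = (lnp_by_hex[h] for h in mh.triple)
        except KeyError as exc:
            raise ValueError(
                f"no test result for hexamer {exc.args[0]!r} of miRNA {mh.mirna_id!r}"
            ) from None
        scores.append(
            MiRNAScore(
                mh.mirna_id, lnp1, lnp2, lnp3,
                combined_score(lnp1, lnp2, lnp3, w1, w3),
                hexamers=mh,
            )
        )
    scores.sort(key=lambda s: (-s.combined, -s.lnp2, s.mirna_id))
    return scores


def normalized_margin(
    scores: Sequence[MiRNAScore], correct: str
) -> float:
    """Relative lead of the correct miRNA over its best distinct competitor.

    ``(score(correct) - score(best other)) / score(correct)``, where
    competitors sharing *all three* hexamers with the correct miRNA are
    excluded (they are indistinguishable by construction). Negative when
    the correct miRNA is outranked; 1.0 when no distinct competitor
    exists. Undefined (error) when the correct miRNA scores 0.
    """
    by_id = {s.mirna_id: s for s in scores}
    if correct not in by_id:
        raise ValueError(f"correct miRNA {correct!r} not among the scores")
    target = by_id[correct]
    if target.combined == 0:
        raise ValueError(f"correct miRNA {correct!r} has combined score 0")
    target_triple = target.hexamers.triple if target.hexamers else None
    competitors = [
        s.combined
        for s in scores
        if s.mirna_id != correct
        and not (
            target_triple is not None
            and s.hexamers is not None
            and s.hexamers.triple == target_triple
        )
    ]
    best = max(competitors, default=0.0)
    return (target.combined - best) / target.combined


def _calibration_arrays(
    results: Sequence[HexamerResult],
    mapping: Sequence[MiRNAHexamers],
    correct: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    lnp_by_hex = {r.hexamer: r.lnp for r in results}
    ids = [m.mirna_id for m in mapping]
    if correct not in ids:
        raise ValueError(f"correct miRNA {correct!r} absent from mapping")
    l1, l2, l3 = (
        np.array([lnp_by_hex[m.triple[i]] for m in mapping]) for i in range(3)
    )
    idx = ids.index(correct)
    triple = mapping[idx].triple
    competitor = np.array(
        [i != idx and m.triple != triple for i, m in enumerate(mapping)]
    )
    return l1, l2, l3, competitor, idx


def optimize_weights(
    calibration: Sequence[tuple[Sequence[HexamerResult], Sequence[MiRNAHexamers], str]],
) -> tuple[float, float, WeightGrid]:
    """Grid-search (w1, w3) maximising the summed normalized margin.

    Each calibration dataset is a (hexamer results, miRNA->hexamer mapping,
    correct miRNA id) triple. The objective at each of the 101 x 101
    lattice points (0.01 steps on [0,1]^2, seed weight fixed at 1) is the
    sum over datasets of the normalized margin of the correct miRNA. Grid
    points where a dataset's correct miRNA scores 0 receive that dataset's
    worst observed margin (logged) rather than aborting the search. Ties
    are broken by the smallest w1, then the smallest w3.
    """
    if not calibration:
        raise ValueError("need at least one calibration dataset")
    w1_values = np.round(np.arange(0, 101) * GRID_STEP, 2)
    w3_values = np.round(np.arange(0, 101) * GRID_STEP, 2)
    W1 = w1_values[:, None, None]
    W3 = w3_values[None, :, None]
    objective = np.zeros((101, 101))
    for results, mapping, correct in calibration:
        l1, l2, l3, competitor, idx = _calibration_arrays(results, mapping, correct)
        scores = W1 * l1 + l2 + W3 * l3  # (101, 101, n_mirnas)
        sc = scores[:, :, idx]
        if competitor.any():
            best = scores[:, :, competitor].max(axis=2)
        else:
            best = np.zeros_like(sc)
        with np.errstate(divide="ignore", invalid="ignore"):
            margin = (sc - best) / sc
        degenerate = sc == 0
        if degenerate.any():
            finite = margin[~degenerate]
            worst = finite.min() if finite.size else -1.0
            logger.warning(
                "correct miRNA %r scores 0 at %d grid points; using worst "
                "observed margin %.4f there",
                correct, int(degenerate.sum()), worst,
            )
            margin = np.where(degenerate, worst, margin)
        objective += margin
    # lexicographic argmax: smallest w1 then w3 among ties; points within a
    # tiny relative band of the maximum count as tied (float jitter from
    # algebraically identical objectives evaluated at different weights)
    peak = objective.max()
    tol = 1e-9 * max(1.0, abs(peak))
    best_flat = np.flatnonzero(objective >= peak - tol)[0]
    i, j = np.unravel_index(best_flat, objective.shape)
    grid = WeightGrid(w1_values, w3_values, objective)
    return float(w1_values[i]), float(w3_values[j]), grid


def score_table_enrichment(
    table: Mapping[tuple[str, str], float],
    expression: ExpressionInput,
    mirna_filter: set[str] | None = None,
    absent: str = "zero",
) -> list[tuple[str, float, float]]:
    """Rank-sum test on target-prediction scores, per miRNA.

    For each miRNA the scores of changed genes are tested against those of
    unchanged genes (one-sided, changed greater). Genes absent from the
    table score 0 by default (``absent='zero'``, the no-predicted-site
    reading) or are dropped (``absent='drop'``). miRNAs with fewer than
    two scored genes on either side are skipped with a warning. Returns
    (mirna_id, p, -lnp) sorted by p ascending, ties by miRNA ID.
    """
    if absent not in ("zero", "drop"):
        raise ValueError("absent must be 'zero' or 'drop'")
    mirnas = sorted({m for (_, m) in table})
    if mirna_filter is not None:
        mirnas = [m for m in mirnas if m in mirna_filter]
    changed = sorted(expression.changed)
    unchanged = sorted(expression.unchanged)
    out = []
    for mirna in mirnas:
        def gather(genes: list[str]) -> list[float]:
            if absent == "zero":
                return [table.get((g, mirna), 0.0) for g in genes]
            return [table[(g, mirna)] for g in genes if (g, mirna) in table]

        x, y = gather(changed), gather(unchanged)
        if len(x) < 2 or len(y) < 2:
            logger.warning(
                "miRNA %r has too few scored genes (%d changed / %d unchanged); skipped",
                mirna, len(x), len(y),
            )
            continue
        p = wilcoxon_one_sided(x, y)
        p, lnp = floor_and_lnp(p)
        out.append((mirna, p, lnp))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def scores_to_frame(scores: Sequence[MiRNAScore]) -> pd.DataFrame:
    """Per-miRNA report table with hexamers, -lnp values and rank."""
    frame = pd.DataFrame(
        {
            "mirna_id": [s.mirna_id for s in scores],
            "hex1": [s.hexamers.hex1 if s.hexamers else "" for s in scores],
            "lnp1": [s.lnp1 for s in scores],
            "hex2": [s.hexamers.hex2 if s.hexamers else "" for s in scores],
            "lnp2": [s.lnp2 for s in scores],
            "hex3": [s.hexamers.hex3 if s.hexamers else "" for s in scores],
            "lnp3": [s.lnp3 for s in scores],
            "combined": [s.combined for s in scores],
            "combined_2dp": [display_2dp(s.combined) for s in scores],
        }
    )
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame
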