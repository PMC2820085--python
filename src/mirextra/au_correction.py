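"""AU-composition bias correction of fold-change metrics.

Microarray fold changes can correlate with the single-nucleotide A+U
content of a transcript's 3'UTR for purely technical reasons. Because
miRNA seed matches are themselves AU-rich, such a bias masquerades as
miRNA signal. The correction regresses the metric on the UTR AU fraction
with robust locally weighted regression (lowess, smoother span 2/3, three
robustifying iterations -- the classical defaults) and replaces each
metric by its residual from the fitted trend. It runs on the full
gene x metric table, before the changed/unchanged split.

The robustifying iterations matter: genuinely deregulated genes are
outliers relative to the stable majority, so the fitted trend tracks the
stable genes' baseline and bias-free data are left essentially untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

LOWESS_SPAN = 2.0 / 3.0
LOWESS_ITERATIONS = 3


@dataclass
class AUProfile:
    """Per-gene AU content and (corrected) expression metric."""

    gene_id: str
    au_fraction: float
    metric: float
    fitted: float = float("nan")
    corrected_metric: float = float("nan")


def au_fraction(sequence: str) -> float:
    """Fraction of A or T/U bases in a 3'UTR.

    N bases count toward the denominator only, so ambiguous positions
    dilute rather than inflate the AU estimate.
    """
    if not sequence:
        raise ValueError("cannot compute AU fraction of an empty sequence")
    seq = sequence.upper()
    return (seq.count("A") + seq.count("T") + seq.count("U")) / len(seq)


def correct_au_bias(profiles: list[AUProfile]) -> list[AUProfile]:
    """Residualize each gene's metric on the lowess trend over AU fraction.

    Returns new profiles with ``fitted`` (trend value at the gene's AU
    fraction) and ``corrected_metric = metric - fitted`` filled in. Needs
    at least 10 genes with finite values. If every AU fraction is
    identical the trend degenerates to the plain mean (with a warning).
    """
    if len(profiles) < 10:
        raise ValueError(f"need >= 10 genes for the lowess fit, got {len(profiles)}")
    au = np.array([p.au_fraction for p in profiles], dtype=np.float64)
    metric = np.array([p.metric for p in profiles], dtype=np.float64)
    if not (np.all(np.isfinite(au)) and np.all(np.isfinite(metric))):
        raise ValueError("non-finite AU fraction or metric")

    if np.all(au == au[0]):
        logger.warning(
            "all AU fractions identical; correcting by the plain mean metric"
        )
        fitted = np.full_like(metric, metric.mean())
    else:
        fitted = lowess(
            metric,
            au,
            frac=LOWESS_SPAN,
            it=LOWESS_ITERATIONS,
            return_sorted=False,
        )
    corrected = metric - fitted
    return [
        AUProfile(p.gene_id, p.au_fraction, p.metric, float(f), float(c))
        for p, f, c in zip(profiles, fitted, corrected)
    ]


def profiles_from_inputs(
    metric: dict[str, float], utr_sequences: dict[str, str]
) -> list[AUProfile]:
    """Pair each gene's metric with the AU fraction of its UTR.

    Genes without a UTR record are skipped (they cannot enter hexamer
    counting either); order follows sorted gene ID for determinism.
    """
    profiles = []
    for gene in sorted(metric):
        seq = utr_sequences.get(gene)
        if seq:
            profiles.append(AUProfile(gene, au_fraction(seq), metric[gene]))
    if not profiles:
        raise ValueError("no metric gene has a UTR sequence")
    return profiles
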