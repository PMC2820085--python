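"""End-to-end orchestration: inputs -> enrichment reports.

The flow is: load and deduplicate 3'UTRs -> (optionally) AU-correct the
fold-change metric -> derive the changed/unchanged split -> map miRNAs to
their three hexamers (restricted by an optional miRNA filter) -> build the
normalized count matrix (optionally conservation-masked) -> one-sided
rank-sum test per hexamer -> per-miRNA combined scores -> TSV reports plus
a -lnp histogram. In score-table mode the hexamer counting is replaced by
externally supplied per-(gene, miRNA) target-prediction scores.

Given identical inputs and configuration the run is fully deterministic,
down to the bytes of the report files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .au_correction import correct_au_bias, profiles_from_inputs
from .hexamers import build_count_matrix, hexamers_for_mirnas
from .io_model import (
    ExpressionInput,
    attach_masks,
    complement_background,
    read_gene_list,
    read_id_map,
    read_mask_fasta,
    read_metric_tsv,
    read_mirna_fasta,
    read_score_table,
    read_utr_fasta,
    restrict_to_universe,
    split_by_metric,
)
from .mirna_scoring import (
    rank_mirnas,
    score_table_enrichment,
    scores_to_frame,
)
from .rank_stats import (
    display_2dp,
    lnp_histogram,
    results_to_frame,
    test_all_hexamers,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one analysis run depends on."""

    utr_fasta: Path
    mirna_fasta: Path
    outdir: Path
    changed_list: Path | None = None
    unchanged_list: Path | None = None
    metric_tsv: Path | None = None
    n_changed: int | None = None
    direction: str = "up"
    id_map: Path | None = None
    masks: Path | None = None
    score_table: Path | None = None
    mirna_filter: Path | None = None
    mode: str = "hexamer"  # or "score_table"
    au_correct: bool = False
    use_conservation: bool = False
    all_hexamers: bool = False

    def to_json(self) -> str:
        payload = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        payload["version"] = __version__
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class ReportBundle:
    """Paths of the files a run produced."""

    outdir: Path
    hexamer_results: Path | None
    mirna_scores: Path
    histogram: Path | None
    config_echo: Path


def validate_config(config: RunConfig) -> list[str]:
    """Collect *all* configuration problems instead of failing on the first."""
    issues = []
    for label, path in (
        ("UTR FASTA", config.utr_fasta),
        ("miRNA FASTA", config.mirna_fasta),
    ):
        if path is None or not Path(path).is_file():
            issues.append(f"{label} missing: {path}")
    has_lists = config.changed_list is not None
    has_metric = config.metric_tsv is not None
    if not has_lists and not has_metric:
        issues.append("need either a changed gene list or a metric TSV")
    if has_lists and has_metric:
        issues.append("changed gene list and metric TSV are mutually exclusive")
    if has_metric and config.n_changed is None:
        issues.append("metric TSV input requires n_changed")
    if config.direction not in ("up", "down"):
        issues.append(f"direction must be 'up' or 'down', got {config.direction!r}")
    if config.mode not in ("hexamer", "score_table"):
        issues.append(f"unknown mode {config.mode!r}")
    if config.mode == "score_table" and config.score_table is None:
        issues.append("mode=score_table requires a score-table TSV")
    if config.use_conservation and config.masks is None:
        issues.append("use_conservation requires a mask file")
    if config.au_correct and not has_metric:
        issues.append("AU correction applies to metric input only")
    for label, path in (
        ("changed list", config.changed_list),
        ("unchanged list", config.unchanged_list),
        ("metric TSV", config.metric_tsv),
        ("ID map", config.id_map),
        ("mask file", config.masks),
        ("score table", config.score_table),
        ("miRNA filter", config.mirna_filter),
    ):
        if path is not None and not Path(path).is_file():
            issues.append(f"{label} not found: {path}")
    return issues


def _derive_expression(config: RunConfig, universe: set[str]) -> ExpressionInput:
    id_map = read_id_map(config.id_map) if config.id_map else None
    if config.metric_tsv is not None:
        metric, _ = read_metric_tsv(config.metric_tsv, id_map)
        if config.au_correct:
            raise RuntimeError("AU correction must run before the split")
        return split_by_metric(metric, config.n_changed, config.direction)
    changed, _ = read_gene_list(config.changed_list, id_map)
    if config.unchanged_list is not None:
        unchanged, _ = read_gene_list(config.unchanged_list, id_map)
        overlap = changed & unchanged
        if overlap:
            raise ValueError(
                f"{len(overlap)} genes occur in both lists: {sorted(overlap)[:5]}"
            )
        return ExpressionInput(changed, unchanged)
    return complement_background(changed, universe)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis described by ``config``.

    Raises with the failing stage named; partially written outputs are
    removed on failure so an output directory is either complete or absent.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid configuration: " + "; ".join(issues))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_stages(config, outdir, written)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _write_tsv(frame: pd.DataFrame, path: Path, written: list[Path]) -> Path:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    written.append(path)
    return path


def _run_stages(
    config: RunConfig, outdir: Path, written: list[Path]
) -> ReportBundle:
    stage = "load UTRs"
    try:
        utrs = read_utr_fasta(config.utr_fasta)
        if config.use_conservation:
            masks = read_mask_fasta(config.masks)
            utrs = attach_masks(utrs, masks)
        universe = {u.gene_id for u in utrs}
        utr_seqs = {u.gene_id: u.sequence for u in utrs}

        stage = "load miRNAs"
        mirnas = read_mirna_fasta(config.mirna_fasta)
        mirna_filter = None
        if config.mirna_filter is not None:
            mirna_filter, _ = read_gene_list(config.mirna_filter)

        stage = "AU correction"
        if config.au_correct:
            metric, _ = read_metric_tsv(
                config.metric_tsv,
                read_id_map(config.id_map) if config.id_map else None,
            )
            profiles = profiles_from_inputs(metric, utr_seqs)
            corrected = correct_au_bias(profiles)
            diag = pd.DataFrame(
                {
                    "gene_id": [p.gene_id for p in corrected],
                    "au_fraction": [p.au_fraction for p in corrected],
                    "metric": [p.metric for p in corrected],
                    "fitted": [p.fitted for p in corrected],
                    "corrected": [p.corrected_metric for p in corrected],
                }
            )
            _write_tsv(diag, outdir / "au_diagnostics.tsv", written)
            stage = "changed/unchanged split"
            expression = split_by_metric(
                {p.gene_id: p.corrected_metric for p in corrected},
                config.n_changed,
                config.direction,
            )
        else:
            stage = "changed/unchanged split"
            expression = _derive_expression(config, universe)
        expression = restrict_to_universe(expression, universe)

        config_echo = outdir / "run_config.json"
        config_echo.write_text(config.to_json() + "\n")
        written.append(config_echo)

        if config.mode == "score_table":
            stage = "score-table enrichment"
            table = read_score_table(config.score_table)
            rows = score_table_enrichment(table, expression, mirna_filter)
            frame = pd.DataFrame(rows, columns=["mirna_id", "p_value", "lnp"])
            frame["lnp_2dp"] = frame["lnp"].map(display_2dp)
            frame["rank"] = range(1, len(frame) + 1)
            scores_path = _write_tsv(frame, outdir / "mirna_scores.tsv", written)
            return ReportBundle(outdir, None, scores_path, None, config_echo)

        stage = "hexamer mapping"
        mapping, hexes = hexamers_for_mirnas(mirnas)
        if mirna_filter is not None:
            mapping = [m for m in mapping if m.mirna_id in mirna_filter]
            hexes = list(dict.fromkeys(h for m in mapping for h in m.triple))
        panel = None if config.all_hexamers else hexes

        stage = "count matrix"
        matrix = build_count_matrix(utrs, panel, use_masks=config.use_conservation)

        stage = "rank-sum tests"
        results = test_all_hexamers(matrix, expression)
        results_path = _write_tsv(
            results_to_frame(results), outdir / "hexamer_results.tsv", written
        )

        stage = "histogram"
        hist = lnp_histogram(results)
        hist_frame = pd.DataFrame(
            {
                "bin_start": hist.bin_edges[:-1],
                "bin_end": hist.bin_edges[1:],
                "count": hist.counts,
            }
        )
        hist_path = _write_tsv(hist_frame, outdir / "lnp_histogram.tsv", written)

        stage = "miRNA scoring"
        scores = rank_mirnas(results, mapping, None)
        scores_path = _write_tsv(
            scores_to_frame(scores), outdir / "mirna_scores.tsv", written
        )
        return ReportBundle(outdir, results_path, scores_path, hist_path, config_echo)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
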