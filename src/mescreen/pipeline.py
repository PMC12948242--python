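"""End-to-end orchestration of the mutual-exclusion screen.

matrix -> percentile ranks -> plasticity -> virtual sort -> three-way ME
filter -> optional reciprocal check, with TSV/JSON outputs and a run log.
Results are written to files, never to stdout, so the tool composes in
pipelines; logging goes to stderr and, when an output directory is set,
to ``run.log`` inside it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import exclusion, plasticity, sorting
from .matrix import ExpressionMatrix, read_expression_matrix, write_results_table

logger = logging.getLogger("mescreen")


def configure_logging(level: str = "INFO", logfile: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=getattr(logging, level.upper()), handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


@dataclass
class ScreenConfig:
    """Configuration of one screen run (CLI flag > config file > default)."""

    matrix_path: str | Path | None = None
    sources: list[str] = field(default_factory=list)
    cos_max: float = exclusion.DEFAULT_COS_MAX
    delta_max: float = exclusion.DEFAULT_DELTA_MAX
    padj_max: float = exclusion.DEFAULT_PADJ_MAX
    min_group: int = sorting.DEFAULT_MIN_GROUP
    gp_threshold: float | None = None  # None -> matrix-wide mean GP
    reciprocal: bool = False
    out_dir: str | Path | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 <= self.cos_max <= 1.0:
            raise ValueError(f"cos_max must be in [0, 1], got {self.cos_max}")
        if not -100.0 <= self.delta_max <= 100.0:
            raise ValueError(f"delta_max must be in [-100, 100], got {self.delta_max}")
        if not 0.0 < self.padj_max <= 1.0:
            raise ValueError(f"padj_max must be in (0, 1], got {self.padj_max}")


@dataclass
class ScreenResult:
    """In-memory result of one source gene's screen."""

    source: str
    rank_matrix: plasticity.RankMatrix
    plasticity_profile: pd.DataFrame
    sorting_table: pd.DataFrame
    candidate_table: pd.DataFrame
    venn_counts: dict
    analyzable: bool = True
    reason: str | None = None

    @property
    def candidates(self) -> list[str]:
        return list(self.candidate_table.index[self.candidate_table["is_candidate"]])


def venn_counts(candidate_table: pd.DataFrame) -> dict:
    """Counts of genes passing each filter condition and their intersection."""
    t = candidate_table
    return {
        "n_genes": int(len(t)),
        "pass_cosine": int(t["pass_cosine"].sum()),
        "pass_delta": int(t["pass_delta"].sum()),
        "pass_padj": int(t["pass_padj"].sum()),
        "pass_all_three": int((t["pass_cosine"] & t["pass_delta"] & t["pass_padj"]).sum()),
        "candidates": int(t["is_candidate"].sum()),
    }


def screen_one_source(
    m: ExpressionMatrix,
    source: str,
    config: ScreenConfig,
    rank_matrix: plasticity.RankMatrix | None = None,
    profile: pd.DataFrame | None = None,
) -> ScreenResult:
    """Run the full screen for a single source gene on an in-memory matrix."""
    if source not in m.data.index:
        raise ValueError(f"source gene {source!r} not present in the matrix")
    r = rank_matrix if rank_matrix is not None else plasticity.compute_rank_matrix(m)
    prof = profile if profile is not None else plasticity.gene_plasticity(r, class_threshold=config.gp_threshold)
    sort_table = sorting.virtual_sort(r, source, min_group=config.min_group)
    logger.info(
        "source %s: high=%d low=%d boundary=%.2f", source,
        sort_table.attrs["n_high"], sort_table.attrs["n_low"], sort_table.attrs["boundary"],
    )
    cosines = exclusion.cosine_to_source(m, source)
    cand = exclusion.screen_me(
        sort_table,
        cosines,
        cos_max=config.cos_max,
        delta_max=config.delta_max,
        padj_max=config.padj_max,
        plasticity=prof,
        gp_threshold=config.gp_threshold,
    )
    counts = venn_counts(cand)
    logger.info("source %s: %d candidates of %d genes", source, counts["candidates"], counts["n_genes"])
    result = ScreenResult(source, r, prof, sort_table, cand, counts)
    if config.reciprocal:
        recip = exclusion.reciprocal_check(
            r, result.candidates, source,
            delta_max=config.delta_max, padj_max=config.padj_max, min_group=config.min_group,
        )
        cand["reciprocal_ok"] = recip.reindex(cand.index)
    return result


def run_screen(config: ScreenConfig, m: ExpressionMatrix | None = None) -> ScreenResult:
    """Run one screen from a config, writing output tables when out_dir is set.

    A source gene with zero plasticity yields a structured not-analyzable
    result (and a ``not_analyzable.json`` report) instead of a crash.
    """
    if m is None:
        if config.matrix_path is None:
            raise ValueError("config.matrix_path is required when no matrix is given")
        m = read_expression_matrix(config.matrix_path)
    if not config.sources:
        raise ValueError("at least one source gene is required")
    source = config.sources[0]
    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        configure_logging(config.log_level, out_dir / "run.log")
    try:
        result = screen_one_source(m, source, config)
    except sorting.ZeroPlasticityError as err:
        logger.warning("source %s not analyzable: %s", source, err)
        r = plasticity.compute_rank_matrix(m)
        prof = plasticity.gene_plasticity(r, class_threshold=config.gp_threshold)
        result = ScreenResult(source, r, prof, pd.DataFrame(), pd.DataFrame(), {}, analyzable=False, reason=str(err))
        if out_dir is not None:
            (out_dir / "not_analyzable.json").write_text(json.dumps({"source": source, "reason": str(err)}, indent=2))
        return result
    if out_dir is not None:
        write_results_table(result.plasticity_profile.reset_index(), out_dir / "plasticity.tsv")
        write_results_table(result.sorting_table.reset_index(), out_dir / f"sorting_{source}.tsv")
        write_results_table(result.candidate_table.reset_index(), out_dir / f"candidates_{source}.tsv")
        write_results_table(
            sorting.volcano_table(result.sorting_table).reset_index(), out_dir / f"volcano_{source}.tsv"
        )
        (out_dir / f"venn_{source}.json").write_text(json.dumps(result.venn_counts, indent=2))
        logger.info("wrote results for %s to %s", source, out_dir)
    return result


def run_multi_source(config: ScreenConfig, m: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Screen several source genes (or all genes with sources=["all"]).

    Sources whose plasticity is below the high-plasticity threshold are
    skipped with a logged reason (low-plasticity sources make ME analysis
    one-sided).  Per-source BH families.  Returns a long-format
    source x target candidate table.
    """
    if m is None:
        if config.matrix_path is None:
            raise ValueError("config.matrix_path is required when no matrix is given")
        m = read_expression_matrix(config.matrix_path)
    if not config.sources:
        raise ValueError("at least one source gene is required")
    sources = list(m.data.index) if config.sources == ["all"] else config.sources
    r = plasticity.compute_rank_matrix(m)
    prof = plasticity.gene_plasticity(r, class_threshold=config.gp_threshold)
    gp_threshold = prof.attrs["class_threshold"]
    frames = []
    for source in sources:
        if source not in m.data.index:
            raise ValueError(f"source gene {source!r} not present in the matrix")
        gp = float(prof.loc[source, "gp"])
        if gp < gp_threshold:
            logger.info("skipping source %s: zero/low plasticity (GP %.2f < %.2f)", source, gp, gp_threshold)
            continue
        try:
            res = screen_one_source(m, source, config, rank_matrix=r, profile=prof)
        except sorting.ZeroPlasticityError as err:
            logger.info("skipping source %s: %s", source, err)
            continue
        cand = res.candidate_table[res.candidate_table["is_candidate"]]
        if len(cand):
            sub = cand.reset_index().rename(columns={"gene_id": "target"})
            sub.insert(0, "source", source)
            frames.append(sub)
    if frames:
        combined = pd.concat(frames, ignore_index=True)
    else:
        combined = pd.DataFrame(columns=["source", "target", "delta", "p_adj", "cosine"])
    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_results_table(combined, out_dir / "multi_source_candidates.tsv")
    return combined
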