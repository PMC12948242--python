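"""Mutual-exclusion screening: cosine filter, candidate calls, patterns.

Two genes are mutually exclusive (ME) when at most one of them is highly
expressed in any sample — their TPM vectors have (near-)disjoint support,
so the angle between them approaches 90 degrees and the cosine similarity

    cos(x, y) = sum(x_i y_i) / (||x|| ||y||)

approaches 0.  On nonnegative TPM vectors the cosine lives in [0, 1].
Cosine alone is not a sufficient ME test: near-silent genes produce
spurious near-zero cosines (noise orthogonality), and linearly
anti-correlated genes that co-express at intermediate levels keep a high
cosine despite a strongly negative correlation.  The screen therefore
requires all three of

    cosine <= cos_max,  delta <= delta_max,  p_adj <= padj_max

(defaults 0.05, -15, 0.01) where delta and p_adj come from the virtual
sorting of samples by the source gene.

Exclusion patterns: bilateral ME needs both genes highly plastic;
if either side has low plasticity the evidence is one-sided ("unilateral"
exclusion) and the screen is insensitive around that gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .plasticity import RankMatrix
from .sorting import DEFAULT_MIN_GROUP, ZeroPlasticityError, virtual_sort

DEFAULT_COS_MAX = 0.05
DEFAULT_DELTA_MAX = -15.0
DEFAULT_PADJ_MAX = 0.01

PATTERNS = ("bilateral_ME", "unilateral_source_low", "unilateral_target_low", "co_existing", "none")


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine of the angle between two nonnegative expression vectors.

    Returns NaN (undefined) if either vector is all-zero: a never-expressed
    gene carries no exclusion evidence and must not masquerade as
    orthogonal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must be 1-D and equal length, got {x.shape} vs {y.shape}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("vectors must be finite")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        return float("nan")
    return float(np.dot(x, y) / (nx * ny))


def cosine_to_source(m: ExpressionMatrix, source: str, log1p: bool = False) -> pd.Series:
    """Cosine similarity of every gene's TPM vector to the source gene's.

    The source's own value is 1; all-zero genes get NaN (undefined).
    ``log1p=True`` computes the cosine on log1p-compressed TPM instead of
    the raw scale (off by default; the raw scale is the defined filter).
    """
    if source not in m.data.index:
        raise ValueError(f"source gene {source!r} not present in the matrix")
    values = np.log1p(m.values) if log1p else m.values
    src = values[m.data.index.get_loc(source)]
    src_norm = np.linalg.norm(src)
    if src_norm == 0.0:
        raise ValueError(f"source gene {source!r} has an all-zero TPM vector")
    norms = np.linalg.norm(values, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = values @ src / (norms * src_norm)
    cos = np.where(norms == 0.0, np.nan, cos)
    out = pd.Series(cos, index=m.data.index, name="cosine")
    out.loc[source] = 1.0
    return out


def _validate_thresholds(cos_max: float, delta_max: float, padj_max: float) -> None:
    if not 0.0 <= cos_max <= 1.0:
        raise ValueError(f"cos_max must be in [0, 1], got {cos_max}")
    if not -100.0 <= delta_max <= 100.0:
        raise ValueError(f"delta_max must be in [-100, 100], got {delta_max}")
    if not 0.0 < padj_max <= 1.0:
        raise ValueError(f"padj_max must be in (0, 1], got {padj_max}")


def screen_me(
    sorting: pd.DataFrame,
    cosines: pd.Series,
    cos_max: float = DEFAULT_COS_MAX,
    delta_max: float = DEFAULT_DELTA_MAX,
    padj_max: float = DEFAULT_PADJ_MAX,
    plasticity: pd.DataFrame | None = None,
    gp_threshold: float | None = None,
) -> pd.DataFrame:
    """Apply the three-way ME filter for one source-gene screen.

    `sorting` is the :func:`mescreen.sorting.virtual_sort` table and
    `cosines` the :func:`cosine_to_source` series over the same genes.
    A gene is a candidate iff it passes all three conditions (inclusive
    boundaries); genes with undefined cosine fail the cosine condition and
    the source gene is never its own candidate.

    If a plasticity profile is supplied, each gene additionally gets an
    exclusion-pattern label (see :func:`classify_exclusion_pattern`).
    """
    _validate_thresholds(cos_max, delta_max, padj_max)
    source = sorting.attrs.get("source_gene")
    if set(sorting.index) != set(cosines.index):
        raise ValueError("sorting table and cosine series cover different gene sets")
    cosines = cosines.reindex(sorting.index)
    table = sorting.copy()
    table["cosine"] = cosines
    table["pass_cosine"] = (cosines <= cos_max) & cosines.notna()
    table["pass_delta"] = table["delta"] <= delta_max
    table["pass_padj"] = table["p_adj"] <= padj_max
    table["is_candidate"] = table["pass_cosine"] & table["pass_delta"] & table["pass_padj"]
    if source is not None and source in table.index:
        table.loc[source, "is_candidate"] = False
    if plasticity is not None:
        if gp_threshold is None:
            gp_threshold = float(plasticity.attrs.get("class_threshold", plasticity["gp"].mean()))
        gp = plasticity["gp"].reindex(table.index)
        gp_source = float(plasticity.loc[source, "gp"]) if source in plasticity.index else float("nan")
        table["pattern"] = [
            classify_exclusion_pattern(gp_source, float(gp_t), float(d), gp_threshold, delta_max=delta_max)
            for gp_t, d in zip(gp, table["delta"])
        ]
    table.attrs.update(sorting.attrs)
    table.attrs["thresholds"] = {"cos_max": cos_max, "delta_max": delta_max, "padj_max": padj_max}
    return table


def classify_exclusion_pattern(
    gp_source: float,
    gp_target: float,
    delta: float,
    gp_threshold: float,
    delta_max: float = DEFAULT_DELTA_MAX,
) -> str:
    """Label a source/target pair's exclusion pattern.

    bilateral_ME — both genes highly plastic and delta at or below the ME
    cutoff; unilateral_source_low / unilateral_target_low — one side's
    plasticity is below threshold, so exclusion evidence is one-sided
    regardless of delta; co_existing — both plastic with delta at or above
    the mirrored (positive) cutoff; otherwise none.
    """
    source_high = gp_source >= gp_threshold
    target_high = gp_target >= gp_threshold
    if not source_high and target_high:
        return "unilateral_source_low"
    if not target_high and source_high:
        return "unilateral_target_low"
    if source_high and target_high:
        if delta <= delta_max:
            return "bilateral_ME"
        if delta >= -delta_max:
            return "co_existing"
    return "none"


def reciprocal_check(
    r: RankMatrix,
    candidates: list[str],
    source: str,
    delta_max: float = DEFAULT_DELTA_MAX,
    padj_max: float = DEFAULT_PADJ_MAX,
    min_group: int = DEFAULT_MIN_GROUP,
) -> pd.Series:
    """Confirm candidates by reversing the roles of source and target.

    For each candidate c the screen is rerun with c as the source gene; the
    check passes when the original source gene itself satisfies
    delta <= delta_max and p_adj <= padj_max in that reversed screen.
    Candidates whose rank vector is constant (zero plasticity) — or whose
    partition leaves a group below `min_group` — cannot be evaluated and
    get a missing value rather than a failure.

    Returns a boolean Series (pandas nullable) indexed by candidate.
    """
    results: dict[str, object] = {}
    for c in candidates:
        try:
            rev = virtual_sort(r, c, min_group=min_group)
        except (ZeroPlasticityError, ValueError):
            results[c] = pd.NA
            continue
        row = rev.loc[source]
        results[c] = bool(row["delta"] <= delta_max and row["p_adj"] <= padj_max)
    return pd.Series(results, dtype="boolean", name="reciprocal_ok")
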