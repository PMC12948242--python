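"""Percentile-rank transformation and gene-plasticity (GP) statistics.

Within each sample, every gene with nonzero TPM receives a percentile rank
score P = n/N x 100, where N is the number of nonzero-TPM genes in that
sample and n is the gene's ascending ordinal rank among those N (ties get
the average ordinal rank).  A zero-TPM gene receives P = 0.  Scores
therefore live in [0, 100], low to high expression, and are comparable
across samples regardless of sequencing depth or TPM scale.

Per gene, across a set of samples:

* ARS (average rank score) — the mean percentile rank, a rank-based
  expression-level summary;
* GP (gene plasticity, Delta_95/5) — the 95th minus the 5th percentile of
  the gene's rank scores, the dynamic range of its expression rank.  A gene
  that is near the top of some samples and silent in others has GP near
  100; a gene whose rank never moves has GP near 0.

Genes are called high-plasticity when GP reaches a threshold; by default
the threshold is the matrix-wide mean GP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix


class UninformativeSampleWarning(UserWarning):
    """A sample whose TPM vector is all zero carries no rank information."""


class SmallSampleWarning(UserWarning):
    """Quantile-based plasticity is interpolation-dominated below ~20 samples."""


@dataclass(frozen=True)
class RankMatrix:
    """Per-sample percentile-rank scores, genes x samples, values in [0, 100]."""

    data: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def percentile_rank_sample(tpm: np.ndarray) -> np.ndarray:
    """Percentile-rank one sample's TPM vector.

    Zero entries map to 0.  Nonzero entries are ranked ascending among the
    N nonzero entries only (tie-averaged), giving P = n/N x 100; the
    sample's unique maximum always scores 100.

    An all-zero vector returns all zeros and emits
    :class:`UninformativeSampleWarning`.
    """
    tpm = np.asarray(tpm, dtype=float)
    if tpm.ndim != 1:
        raise ValueError("expected a 1-D TPM vector")
    if not np.all(np.isfinite(tpm)) or (tpm < 0).any():
        raise ValueError("TPM vector must be finite and nonnegative")
    out = np.zeros_like(tpm)
    nonzero = tpm > 0
    n_nonzero = int(nonzero.sum())
    if n_nonzero == 0:
        warnings.warn("all-zero sample: percentile ranks uninformative", UninformativeSampleWarning)
        return out
    ranks = rankdata(tpm[nonzero], method="average")
    out[nonzero] = ranks / n_nonzero * 100.0
    return out


def compute_rank_matrix(m: ExpressionMatrix) -> RankMatrix:
    """Apply :func:`percentile_rank_sample` to every sample (column) of `m`."""
    values = m.values
    ranks = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks[:, j] = percentile_rank_sample(values[:, j])
    return RankMatrix(pd.DataFrame(ranks, index=m.data.index.copy(), columns=m.data.columns.copy()))


def average_rank_score(r: RankMatrix, samples: list[str] | None = None) -> pd.Series:
    """Per-gene mean percentile rank (ARS) over a sample subset.

    ``samples=None`` uses every sample; an empty subset is an error.
    """
    if samples is None:
        sub = r.data
    else:
        samples = list(samples)
        if len(samples) == 0:
            raise ValueError("ARS requires a non-empty sample subset")
        sub = r.data[samples]
    return sub.mean(axis=1).rename("ars")


def gene_plasticity(r: RankMatrix, class_threshold: float | None = None) -> pd.DataFrame:
    """Per-gene plasticity profile: ARS, 5th/95th rank quantiles, GP, class.

    Quantiles use linear interpolation between order statistics; GP is
    q95 - q05 (Delta_95/5).  ``plasticity_class`` is "high" where
    GP >= `class_threshold`, which defaults to the matrix-wide mean GP.

    Returns a DataFrame indexed by gene with columns
    ``ars, q05, q95, gp, plasticity_class``.
    """
    values = r.values
    if values.shape[1] < 20:
        warnings.warn(
            f"only {values.shape[1]} samples: 5th/95th percentiles are interpolation-dominated",
            SmallSampleWarning,
        )
    q05 = np.quantile(values, 0.05, axis=1)
    q95 = np.quantile(values, 0.95, axis=1)
    gp = q95 - q05
    ars = values.mean(axis=1)
    if class_threshold is None:
        class_threshold = float(gp.mean())
    profile = pd.DataFrame(
        {
            "ars": ars,
            "q05": q05,
            "q95": q95,
            "gp": gp,
            "plasticity_class": np.where(gp >= class_threshold, "high", "low"),
        },
        index=r.data.index.copy(),
    )
    profile.attrs["class_threshold"] = float(class_threshold)
    return profile
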