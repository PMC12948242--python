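"""Synthetic mixed-phenotype TPM matrices with planted gene-pair archetypes.

The generator emulates a pooled bulk RNA-seq design: samples drawn from
several latent cell phenotypes, genes whose expression is restricted to a
phenotype subset (plastic genes), and exact zeros for undetected
transcripts.  Expression is lognormal on the TPM scale with explicit
zero-dropout in the inactive state — the simplest model that reproduces
phenotype-restricted expression, the heavy right tail of TPM, and the
exact zeros the percentile-rank rule depends on.

Planted archetypes, each with ground-truth labels:

* one ME *hub* gene, active in half the phenotypes (high plasticity; the
  natural source gene for a screen);
* bilateral ME pairs — gene A active in a subset of the hub's phenotypes,
  gene B in a disjoint subset of the remaining ones, so A/B (and hub/B)
  have near-disjoint expression support;
* co-existing pairs — both genes share one active phenotype subset;
* linear negative-correlation pairs — two strictly positive mid-level
  genes with y = c - x + noise, the x side tracking the hub's phenotypes:
  anti-correlated with the source yet never silent, the confounder a
  cosine threshold must reject;
* housekeeping genes — stable high expression everywhere (low plasticity);
* near-silent genes — zero in >= 95% of samples, the confounder that
  yields spurious near-zero cosines;
* background genes — active in an independent random phenotype subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the mixed-phenotype generator (defaults = study conditions)."""

    n_samples: int = 600
    n_phenotypes: int = 8
    phenotype_weights: tuple[float, ...] | None = None  # None -> uniform
    n_background_genes: int = 1849
    n_me_pairs: int = 20
    n_coexist_pairs: int = 10
    n_linear_neg_pairs: int = 10
    n_housekeeping: int = 20
    n_silent: int = 50
    mu_hi: float = math.log(100.0)  # log-scale mean of active-state TPM
    mu_lo: float = math.log(0.5)  # log-scale mean of inactive-state leak
    sigma: float = 1.0  # log-scale sd of plastic-gene expression
    dropout_off: float = 0.85  # P(exact zero | inactive state)
    seed: int = 1

    #: per-phenotype activity probability of phenotype-restricted background
    #: genes; most genes in pooled bulk data are broadly expressed
    background_activity: float = 0.75
    #: fraction of background genes that are stably expressed in every
    #: phenotype (rank-stable, low GP); the rest are phenotype-restricted.
    #: The mixture reproduces a pooled-compendium GP landscape whose mean
    #: sits mid-scale rather than near 100
    background_stable: float = 0.6
    #: fraction of samples in which a near-silent gene is (barely) detected
    silent_detect_rate: float = 0.03
    #: log-scale sd of housekeeping per-sample jitter (rank-stable expression)
    housekeeping_jitter: float = 0.2

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_phenotypes <= 0:
            raise ValueError("n_samples and n_phenotypes must be positive")
        if self.n_phenotypes < 2:
            raise ValueError("need at least 2 phenotypes to plant exclusion structure")
        if self.phenotype_weights is not None:
            w = np.asarray(self.phenotype_weights, dtype=float)
            if w.size != self.n_phenotypes or (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError("phenotype_weights must be a probability vector of length n_phenotypes")
        for name in ("n_background_genes", "n_me_pairs", "n_coexist_pairs", "n_linear_neg_pairs", "n_housekeeping", "n_silent"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.dropout_off <= 1.0:
            raise ValueError("dropout_off must be in [0, 1]")
        if self.mu_hi <= self.mu_lo:
            raise ValueError("mu_hi must exceed mu_lo")

    @property
    def n_genes(self) -> int:
        return (
            1
            + 2 * self.n_me_pairs
            + 2 * self.n_coexist_pairs
            + 2 * self.n_linear_neg_pairs
            + self.n_housekeeping
            + self.n_silent
            + self.n_background_genes
        )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "GeneratorSpec":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown generator parameters: {sorted(unknown)}")
        if "phenotype_weights" in mapping and mapping["phenotype_weights"] is not None:
            mapping = dict(mapping)
            mapping["phenotype_weights"] = tuple(mapping["phenotype_weights"])
        return cls(**mapping)

    def with_seed(self, seed: int) -> "GeneratorSpec":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class TruthLabels:
    """Ground truth for one generated matrix."""

    table: pd.DataFrame  # index gene_id; columns archetype, partner_id, active_phenotypes
    hub_gene: str
    hub_phenotypes: tuple[int, ...]
    sample_phenotypes: pd.Series  # per-sample latent phenotype index

    def genes_of(self, archetype: str) -> list[str]:
        return list(self.table.index[self.table["archetype"] == archetype])

    @property
    def hub_me_partners(self) -> list[str]:
        """Planted ME genes whose active phenotypes are disjoint from the hub's."""
        hub = set(self.hub_phenotypes)
        out = []
        for gene in self.genes_of("me_partner"):
            active = self.table.loc[gene, "active_phenotypes"]
            if active and hub.isdisjoint(int(p) for p in active.split(",")):
                out.append(gene)
        return out


def _gated_row(rng: np.random.Generator, active: np.ndarray, spec: GeneratorSpec) -> np.ndarray:
    """One phenotype-gated gene: lognormal high where active, dropout/leak elsewhere."""
    n = active.size
    hi = rng.lognormal(spec.mu_hi, spec.sigma, size=n)
    lo = rng.lognormal(spec.mu_lo, spec.sigma, size=n)
    dropped = rng.random(n) < spec.dropout_off
    off = np.where(dropped, 0.0, lo)
    return np.where(active, hi, off)


def _subset(rng: np.random.Generator, pool: np.ndarray, min_size: int, max_size: int) -> np.ndarray:
    size = int(rng.integers(min_size, max_size + 1))
    return np.sort(rng.choice(pool, size=size, replace=False))


def _pheno_str(phenos: np.ndarray | tuple) -> str:
    return ",".join(str(int(p)) for p in phenos)


def generate(spec: GeneratorSpec) -> tuple[ExpressionMatrix, TruthLabels]:
    """Generate a TPM matrix and its ground-truth labels.

    Deterministic for a fixed spec (a single pseudo-random stream consumed
    in fixed gene order).  The first half of the phenotype indices forms
    the hub's active set.
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids = [f"S{i:04d}" for i in range(spec.n_samples)]
    weights = (
        np.full(spec.n_phenotypes, 1.0 / spec.n_phenotypes)
        if spec.phenotype_weights is None
        else np.asarray(spec.phenotype_weights, dtype=float)
    )
    phenos = rng.choice(spec.n_phenotypes, size=spec.n_samples, p=weights)

    half = spec.n_phenotypes // 2
    hub_set = np.arange(half)
    other_set = np.arange(half, spec.n_phenotypes)
    in_hub = np.isin(phenos, hub_set)

    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    records: list[tuple[str, str, str]] = []  # archetype, partner, active phenotypes

    def add(gene_id: str, row: np.ndarray, archetype: str, partner: str = "", active: str = "") -> None:
        gene_ids.append(gene_id)
        rows.append(row)
        records.append((archetype, partner, active))

    # ME hub: active in half the phenotypes -> high plasticity source
    add("ME_HUB", _gated_row(rng, in_hub, spec), "me_hub", active=_pheno_str(hub_set))

    def side_subset(pool: np.ndarray) -> np.ndarray:
        # breadth >= half the side: a single-phenotype partner is the
        # low-breadth confounder, modelled by background genes instead
        lo = max(1, math.ceil(pool.size / 2))
        return _subset(rng, pool, lo, pool.size)

    for i in range(spec.n_me_pairs):
        s_a = side_subset(hub_set)
        s_b = side_subset(other_set)
        a_id, b_id = f"ME{i:03d}_A", f"ME{i:03d}_B"
        add(a_id, _gated_row(rng, np.isin(phenos, s_a), spec), "me_partner", b_id, _pheno_str(s_a))
        add(b_id, _gated_row(rng, np.isin(phenos, s_b), spec), "me_partner", a_id, _pheno_str(s_b))

    for i in range(spec.n_coexist_pairs):
        shared = _subset(rng, np.arange(spec.n_phenotypes), 2, max(2, spec.n_phenotypes // 2))
        a_id, b_id = f"COEX{i:03d}_A", f"COEX{i:03d}_B"
        mask = np.isin(phenos, shared)
        add(a_id, _gated_row(rng, mask, spec), "coexist_partner", b_id, _pheno_str(shared))
        add(b_id, _gated_row(rng, mask, spec), "coexist_partner", a_id, _pheno_str(shared))

    for i in range(spec.n_linear_neg_pairs):
        # strictly positive mid-level anti-correlated pair; x tracks the
        # hub's phenotypes so the pair confounds the hub screen the way a
        # linearly anti-correlated gene confounds a real source
        x = np.where(in_hub, rng.uniform(65.0, 95.0, spec.n_samples), rng.uniform(5.0, 35.0, spec.n_samples))
        y = np.clip(100.0 - x + rng.normal(0.0, 3.0, spec.n_samples), 1.0, None)
        x_id, y_id = f"LNEG{i:03d}_X", f"LNEG{i:03d}_Y"
        add(x_id, x, "linear_neg_partner", y_id)
        add(y_id, y, "linear_neg_partner", x_id)

    for i in range(spec.n_housekeeping):
        # fixed gene-level log-mean + small jitter: stable rank, low GP
        mu_g = rng.normal(spec.mu_hi, spec.sigma)
        add(f"HK{i:03d}", np.exp(mu_g + rng.normal(0.0, spec.housekeeping_jitter, spec.n_samples)), "housekeeping")

    for i in range(spec.n_silent):
        detected = rng.random(spec.n_samples) < spec.silent_detect_rate
        vals = rng.lognormal(spec.mu_lo * 0.1, spec.sigma, spec.n_samples)
        add(f"SILENT{i:03d}", np.where(detected, vals, 0.0), "silent")

    all_phenos = np.arange(spec.n_phenotypes)
    min_per_side = min(2, half, spec.n_phenotypes - half)
    for i in range(spec.n_background_genes):
        if rng.random() < spec.background_stable:
            # broadly expressed, rank-stable gene: fixed gene-level mean,
            # small per-sample jitter
            mu_g = rng.normal(spec.mu_hi - 1.0, spec.sigma)
            row = np.exp(mu_g + rng.normal(0.0, spec.housekeeping_jitter, spec.n_samples))
            add(f"BG{i:04d}", row, "background", active=_pheno_str(all_phenos))
            continue
        # phenotype-restricted gene.  The "background" truth label asserts no
        # exclusion structure with the planted hub, so the draw is
        # conditioned to stay active on both sides of the hub's phenotype
        # split; an unconditioned draw occasionally produces a bona fide
        # (but unlabelled) ME partner
        while True:
            active_set = np.flatnonzero(rng.random(spec.n_phenotypes) < spec.background_activity)
            if (
                np.isin(active_set, hub_set).sum() >= min_per_side
                and np.isin(active_set, other_set).sum() >= min_per_side
            ):
                break
        add(f"BG{i:04d}", _gated_row(rng, np.isin(phenos, active_set), spec), "background", active=_pheno_str(active_set))

    matrix = ExpressionMatrix(pd.DataFrame(np.vstack(rows), index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids))
    truth_table = pd.DataFrame(records, index=matrix.data.index.copy(), columns=["archetype", "partner_id", "active_phenotypes"])
    truth = TruthLabels(
        table=truth_table,
        hub_gene="ME_HUB",
        hub_phenotypes=tuple(int(p) for p in hub_set),
        sample_phenotypes=pd.Series(phenos, index=sample_ids, name="phenotype"),
    )
    return matrix, truth


def write_truth(truth: TruthLabels, path) -> None:
    """Write ground-truth labels as a TSV (gene_id, archetype, partner_id, active_phenotypes)."""
    truth.table.to_csv(path, sep="\t", index_label="gene_id")
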