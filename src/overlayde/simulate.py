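"""Synthetic count matrices with known DE structure.

The generator emulates the statistical shape of bulk RNA-seq input to
the overlay caller: a lognormal transcriptome, an optional spike of
weakly expressed noisy genes, multiplicative lognormal replicate noise
with a fixed coefficient of variation, injected between-condition fold
changes for a chosen subset of genes, and multinomial read sampling to
a fixed library size (adding realistic counting noise at low
expression).  Gene-length weighting in the read sampling makes TPM
recovery unbiased.  Every draw comes from one seeded generator, so a
configuration determines its output bit for bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .io import CountMatrix, GeneLengthTable, SampleDesign

__all__ = ["SynthConfig", "TruthTable", "generate_counts", "truth_evaluation"]

#: spike genes sit this many natural-log units below the bulk mean
_SPIKE_LOG_OFFSET = 4.0
_SPIKE_SIGMA = 0.8


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic dataset.

    ``baseline`` is the (mu, sigma) of the bulk lognormal expression
    (natural-log units); ``replicate_cv`` the fractional CV of the
    multiplicative replicate noise; ``condition_cv`` a sub-threshold
    biological drift applied to every gene coherently across the
    replicates of a condition (real conditions perturb the whole
    transcriptome a little, not only the strongly regulated genes);
    ``fold_range`` the injected between-condition fold-change interval
    for the ``n_de`` DE genes; ``spike_frac`` the fraction of genes
    drawn from a weakly expressed noise component (off by default);
    ``library_size`` the multinomial read depth, chosen so reads per
    gene match bacterial bulk RNA-seq; ``time_points`` turns the
    two-condition design into a series whose DE fold changes ramp
    geometrically from 1 at the first time point to the full fold at
    the last.
    """

    m: int = 2000
    baseline: tuple[float, float] = (2.0, 1.5)
    replicate_cv: float = 0.15
    condition_cv: float = 0.05
    n_de: int = 200
    fold_range: tuple[float, float] = (4.0, 8.0)
    direction_prob: float = 0.5
    spike_frac: float = 0.10
    lengths_range: tuple[int, int] = (500, 5000)
    library_size: int = 8_000_000
    n_reps: int = 2
    time_points: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise DataError("m must be >= 1")
        if not 0 <= self.n_de <= self.m:
            raise DataError("n_de must lie in [0, m]")
        if self.fold_range[0] < 1 or self.fold_range[1] < self.fold_range[0]:
            raise DataError("fold_range must satisfy 1 <= min <= max")
        if self.replicate_cv < 0:
            raise DataError("replicate_cv must be >= 0")
        if self.condition_cv < 0:
            raise DataError("condition_cv must be >= 0")
        if not 0 <= self.direction_prob <= 1:
            raise DataError("direction_prob must lie in [0, 1]")
        if not 0 <= self.spike_frac < 1:
            raise DataError("spike_frac must lie in [0, 1)")
        if self.lengths_range[0] < 1 or self.lengths_range[1] < self.lengths_range[0]:
            raise DataError("lengths_range must satisfy 1 <= min <= max")
        if self.library_size < 1:
            raise DataError("library_size must be >= 1")
        if self.n_reps < 2:
            raise DataError("n_reps must be >= 2")
        if self.time_points is not None and len(self.time_points) < 2:
            raise DataError("time_points needs >= 2 labels")
        if self.seed is None:
            raise DataError("seed is mandatory")


@dataclass(frozen=True)
class TruthTable:
    """Ground truth per gene: DE status and injected fold change."""

    table: pd.DataFrame  # index gene_id, columns is_de (bool), true_fold (float)

    @property
    def de_genes(self) -> set[str]:
        return set(self.table.index[self.table["is_de"]])


def generate_counts(
    cfg: SynthConfig,
) -> tuple[CountMatrix, GeneLengthTable, SampleDesign, TruthTable]:
    """Draw one dataset under ``cfg``; fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m
    width = max(4, len(str(m)))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(m)]

    lengths = rng.integers(cfg.lengths_range[0], cfg.lengths_range[1] + 1, size=m)

    mu, sigma = cfg.baseline
    n_spike = int(round(cfg.spike_frac * m))
    is_spike = np.zeros(m, dtype=bool)
    if n_spike:
        is_spike[rng.choice(m, size=n_spike, replace=False)] = True
    base = np.where(
        is_spike,
        rng.lognormal(mu - _SPIKE_LOG_OFFSET, _SPIKE_SIGMA, size=m),
        rng.lognormal(mu, sigma, size=m),
    )

    # DE genes come from the lower three quartiles of bulk expression:
    # regulated genes are rarely the top-mass transcripts, and keeping
    # the injected mass small preserves sample composition so that
    # non-DE genes really are non-DE after TPM renormalization.
    is_de = np.zeros(m, dtype=bool)
    bulk_idx = np.flatnonzero(~is_spike)
    q75 = np.quantile(base[bulk_idx], 0.75)
    de_pool = bulk_idx[base[bulk_idx] < q75]
    if cfg.n_de > de_pool.size:  # fall back when most of the bulk is DE
        de_pool = bulk_idx
    if cfg.n_de > de_pool.size:
        raise DataError("n_de exceeds the number of non-spike genes")
    if cfg.n_de:
        is_de[rng.choice(de_pool, size=cfg.n_de, replace=False)] = True
    folds = np.ones(m)
    folds[is_de] = rng.uniform(*cfg.fold_range, size=cfg.n_de)
    up = rng.random(m) < cfg.direction_prob
    signed_fold = np.where(up, folds, 1.0 / folds)

    conditions = (
        list(cfg.time_points) if cfg.time_points is not None else ["cond1", "cond2"]
    )
    n_cond = len(conditions)

    # per-condition expected expression; DE folds ramp geometrically over time
    cond_means = np.empty((m, n_cond))
    sigma_c = np.sqrt(np.log1p(cfg.condition_cv**2))
    for t in range(n_cond):
        frac = t / (n_cond - 1)
        cond_means[:, t] = base * np.where(is_de, signed_fold**frac, 1.0)
        if sigma_c > 0:
            # sub-threshold biological response: every gene shifts a
            # little between conditions, coherently across replicates
            cond_means[:, t] *= rng.lognormal(-(sigma_c**2) / 2, sigma_c, size=m)

    sigma_n = np.sqrt(np.log1p(cfg.replicate_cv**2))
    sample_ids, cond_col, rep_col = [], [], []
    counts = np.empty((m, n_cond * cfg.n_reps), dtype=np.int64)
    col = 0
    for t, cond in enumerate(conditions):
        for r in range(1, cfg.n_reps + 1):
            expr = cond_means[:, t]
            if sigma_n > 0:
                noise = rng.lognormal(-(sigma_n**2) / 2, sigma_n, size=m)
                expr = expr * noise
            weights = expr * lengths
            counts[:, col] = rng.multinomial(cfg.library_size, weights / weights.sum())
            sample_ids.append(f"{cond}_r{r}")
            cond_col.append(cond)
            rep_col.append(f"r{r}")
            col += 1

    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))
    gl = GeneLengthTable(pd.Series(lengths.astype(float), index=gene_ids))
    design = SampleDesign(
        pd.DataFrame(
            {"condition": cond_col, "replicate": rep_col}, index=sample_ids
        )
    )
    truth = TruthTable(
        pd.DataFrame(
            {"is_de": is_de, "true_fold": signed_fold}, index=gene_ids
        )
    )
    return cm, gl, design, truth


def truth_evaluation(called, truth: TruthTable) -> dict[str, float]:
    """Sensitivity, FDR and precision of a DE call against ground truth.

    ``called`` is an iterable of gene ids, or any object exposing
    ``de_genes`` / ``de_final_genes``.  Genes the caller dropped (e.g.
    by the expression filter) simply count as not called; calling a
    gene unknown to the truth table is an error.  With no calls at all,
    FDR is 0 by convention and precision 1.
    """
    if hasattr(called, "de_final_genes"):
        called = called.de_final_genes
    elif hasattr(called, "de_genes"):
        called = called.de_genes
    called = set(called)
    known = set(truth.table.index)
    unknown = called - known
    if unknown:
        raise DataError(f"called genes absent from truth table: {sorted(unknown)[:5]}")
    positives = truth.de_genes
    tp = len(called & positives)
    fp = len(called - positives)
    sensitivity = tp / len(positives) if positives else 1.0
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    return {"sensitivity": sensitivity, "fdr": fdr, "precision": 1.0 - fdr}
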