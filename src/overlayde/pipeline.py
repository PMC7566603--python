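"""End-to-end analysis: counts -> TPM -> filter -> noise baseline ->
dot-size sweep -> overlay DE call -> KDE p-values -> reports.

`analyze` is the in-memory engine; `run_pipeline` wraps it with file
input and a fully materialized output directory (tables, fit summary,
manifest, overlay plot).  Identical inputs and configuration produce
byte-identical tabular outputs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import filtering, kde, noise, overlay
from .errors import DataError
from .io import (
    CountMatrix,
    ExpressionMatrix,
    GeneLengthTable,
    SampleDesign,
    log10_transform,
    read_count_matrix,
    read_gene_lengths,
    read_sample_design,
    select_replicate_pair,
    tpm_normalize,
)

__all__ = ["RunConfig", "AnalysisResult", "analyze", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one run needs; serialized into the output manifest."""

    counts: str
    lengths: str
    design: str
    out_dir: str
    comparison: tuple[str, str] | None = None
    families: tuple[str, ...] = tuple(sorted(filtering.FAMILIES))
    filter_threshold: float | None = None  # None -> density-crossing rule
    filter_rule: str = "mean"
    dot_size_grid: tuple[float, ...] = overlay.DEFAULT_DOT_SIZE_GRID
    metric: str = "euclidean"
    noise_mode: str = "mean"
    bandwidth_method: str = "silverman"
    p_mode: str = "cdf"
    p_cutoff: float | None = None
    fold_cutoff: float | None = None
    floor: float = 1e-3
    seed: int = 0
    make_plot: bool = True


@dataclass
class AnalysisResult:
    """All intermediate and final products of one comparison."""

    comparison: tuple[str, str]
    fit: filtering.FitResult
    all_fits: list[filtering.FitResult]
    filter_spec: filtering.FilterSpec
    n_genes_input: int
    em: ExpressionMatrix  # filtered, linear TPM
    pairs: dict[str, tuple[str, str]]
    baseline: float
    sweep: overlay.SweepTable
    selection: overlay.DotSizeSelection
    overlay_result: overlay.OverlayResult
    kde_model: kde.KdeModel
    report: kde.DEReport

    @property
    def de_genes(self) -> list[str]:
        return self.report.de_final_genes


def _drop_unobserved(
    em: ExpressionMatrix,
    pairs: dict[str, tuple[str, str]],
    comparison: tuple[str, str],
) -> ExpressionMatrix:
    """Drop genes with zero TPM in both samples of any pair the
    comparison uses (within-condition pairs and the four combinations);
    eta2 is undefined for such pairs and the gene is unobserved there."""
    cond1, cond2 = comparison
    p1, p2 = pairs[cond1], pairs[cond2]
    used_pairs = [p1, p2] + [(a, b) for a in p1 for b in p2]
    vals = em.values
    keep = pd.Series(True, index=vals.index)
    for a, b in used_pairs:
        keep &= (vals[a] + vals[b]) > 0
    if not keep.all():
        em = ExpressionMatrix(vals.loc[keep].copy(), em.scale, em.design)
    return em


def analyze(
    cm: CountMatrix,
    gl: GeneLengthTable,
    design: SampleDesign,
    comparison: tuple[str, str] | None = None,
    families=None,
    filter_threshold: float | None = None,
    filter_rule: str = "mean",
    dot_size_grid=overlay.DEFAULT_DOT_SIZE_GRID,
    metric: str = "euclidean",
    noise_mode: str = "mean",
    bandwidth_method: str = "silverman",
    p_mode: str = "cdf",
    p_cutoff: float | None = None,
    fold_cutoff: float | None = None,
    floor: float = 1e-3,
    seed: int = 0,
) -> AnalysisResult:
    """Run the whole overlay analysis for one condition pair."""
    em = tpm_normalize(cm, gl)
    em.design = design
    if comparison is None:
        conds = design.conditions
        if len(conds) < 2:
            raise DataError("need at least two conditions")
        comparison = (conds[0], conds[-1])

    # transcriptome-wide distribution fit on pooled non-zero TPM
    pooled = em.values.to_numpy().ravel()
    pooled = pooled[pooled > 0]
    families = list(families) if families is not None else sorted(filtering.FAMILIES)
    all_fits = []
    for fam in families:
        try:
            all_fits.append(filtering.fit_family(pooled, fam))
        except filtering.FitError:
            continue
    fit = filtering.select_best_family(pooled, families)
    if filter_threshold is None:
        spec = filtering.lower_tail_threshold(pooled, fit)
        spec = filtering.FilterSpec(spec.threshold, filter_rule)
    else:
        spec = filtering.FilterSpec(filter_threshold, filter_rule)
    em_f = filtering.filter_low_expression(em, spec)

    pairs = {c: select_replicate_pair(em_f, c, floor=floor) for c in comparison}
    em_f = _drop_unobserved(em_f, pairs, comparison)
    baseline = noise.replicate_noise_baseline(em_f, comparison, pairs, noise_mode)
    sweep = overlay.sweep_dot_sizes(
        em_f, comparison, dot_size_grid, metric, pairs, floor=floor
    )
    selection = overlay.select_dot_size(sweep, baseline)

    em_log = log10_transform(em_f, floor=floor)
    rep_clouds = (
        overlay.build_replicate_cloud(em_log, comparison[0], pairs[comparison[0]]),
        overlay.build_replicate_cloud(em_log, comparison[1], pairs[comparison[1]]),
    )
    combo_clouds = overlay.build_condition_points(em_log, *comparison, pairs)
    result = overlay.call_de(combo_clouds, rep_clouds, selection.dot_size, metric)

    model = kde.build_kde_model(em_log, comparison, pairs, method=bandwidth_method)
    report = kde.DEReport.from_overlay(result, em_f, comparison)
    report = kde.de_pvalues(
        report, model, em_log, comparison, mode=p_mode, pairs=pairs, seed=seed
    )
    report = kde.apply_cutoffs(report, p_cutoff=p_cutoff, fold_cutoff=fold_cutoff)
    report.meta.update(
        {
            "comparison": list(comparison),
            "metric": metric,
            "noise_mode": noise_mode,
            "baseline": baseline,
            "selected_dot_size": selection.dot_size,
            "dot_size_qualified": selection.qualified,
            "filter_threshold_tpm": spec.threshold,
            "filter_rule": spec.rule,
            "fit_family": fit.family,
        }
    )
    return AnalysisResult(
        comparison=comparison,
        fit=fit,
        all_fits=all_fits,
        filter_spec=spec,
        n_genes_input=len(cm.gene_ids),
        em=em_f,
        pairs=pairs,
        baseline=baseline,
        sweep=sweep,
        selection=selection,
        overlay_result=result,
        kde_model=model,
        report=report,
    )


def _write_noise_table(res: AnalysisResult, path: Path) -> None:
    rows = []
    for cond in res.comparison:
        pair = res.pairs[cond]
        summary = noise.pair_noise_summary(res.em, pair)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": summary.per_gene.index,
                    "pair": f"{pair[0]}|{pair[1]}",
                    "eta2": summary.per_gene.to_numpy(),
                }
            )
        )
    pd.concat(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full analysis from files and write the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm = read_count_matrix(cfg.counts)
    gl = read_gene_lengths(cfg.lengths)
    design = read_sample_design(cfg.design)
    res = analyze(
        cm,
        gl,
        design,
        comparison=cfg.comparison,
        families=cfg.families,
        filter_threshold=cfg.filter_threshold,
        filter_rule=cfg.filter_rule,
        dot_size_grid=cfg.dot_size_grid,
        metric=cfg.metric,
        noise_mode=cfg.noise_mode,
        bandwidth_method=cfg.bandwidth_method,
        p_mode=cfg.p_mode,
        p_cutoff=cfg.p_cutoff,
        fold_cutoff=cfg.fold_cutoff,
        floor=cfg.floor,
        seed=cfg.seed,
    )

    de = res.report.table.copy()
    flags = res.overlay_result.table.drop(columns="de")
    de = flags.join(de)
    de.insert(0, "gene_id", de.index)
    de.to_csv(out / "de_genes.tsv", sep="\t", index=False, float_format="%.8g")

    res.sweep.rows.to_csv(
        out / "sweep.tsv", sep="\t", index=False, float_format="%.8g"
    )
    _write_noise_table(res, out / "noise.tsv")

    fit_json = {
        "chosen_family": res.fit.family,
        "threshold_tpm": res.filter_spec.threshold,
        "fits": [
            {
                "family": f.family,
                "params": f.params,
                "loglik": f.loglik,
                "aic": f.aic,
                "n": f.n,
            }
            for f in res.all_fits
        ],
    }
    (out / "fit.json").write_text(json.dumps(fit_json, indent=2, sort_keys=True))

    manifest = {
        "config": asdict(cfg),
        "comparison": list(res.comparison),
        "replicate_pairs": {c: list(p) for c, p in res.pairs.items()},
        "genes_input": res.n_genes_input,
        "genes_retained": len(res.em.gene_ids),
        "replicate_noise_baseline": res.baseline,
        "selected_dot_size": res.selection.dot_size,
        "dot_size_qualified": res.selection.qualified,
        "de_overlay_count": res.overlay_result.de_count,
        "de_final_count": len(res.de_genes),
        "report_meta": {
            k: v for k, v in res.report.meta.items() if not isinstance(v, pd.Series)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    if cfg.make_plot:
        from .plotting import render_overlay
        from .io import log10_transform as _log10

        em_log = _log10(res.em, floor=cfg.floor)
        rep_clouds = (
            overlay.build_replicate_cloud(
                em_log, res.comparison[0], res.pairs[res.comparison[0]]
            ),
            overlay.build_replicate_cloud(
                em_log, res.comparison[1], res.pairs[res.comparison[1]]
            ),
        )
        combo_clouds = overlay.build_condition_points(
            em_log, *res.comparison, res.pairs
        )
        render_overlay(
            rep_clouds,
            combo_clouds,
            res.overlay_result,
            res.selection.dot_size,
            out / "overlay.svg",
        )
    return out
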