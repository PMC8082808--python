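"""End-to-end orchestration: filter → rarefy → CLR → screens → tables.

Each stage's settings and outcomes are logged to a :class:`RunReport`;
outputs are long-format TSVs so result surfaces diff cleanly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import compositional, delta, diversity, models
from .io_config import (
    MARKERS,
    CountTable,
    RunConfig,
    RunReport,
    apply_marker_limits,
    filter_prevalence,
)
from .rmcorr import rmcorr_screen, rmcorr_screen_clr


def prepare(
    counts: CountTable, config: RunConfig, report: RunReport
) -> tuple[CountTable, compositional.RarefiedSet, compositional.ClrInstanceSet]:
    """Prevalence filter, rarefaction and the Dirichlet Monte-Carlo CLR stack.

    The CLR transform runs on the filtered, *non-rarefied* counts; the
    rarefied tables feed diversity only. Samples dropped at rarefaction are
    removed from the CLR stack so every downstream surface covers one sample
    set.
    """
    filtered = filter_prevalence(
        counts, config.prevalence_min, config.pathway_min_count, report
    )
    depth = (
        compositional.auto_depth(filtered)
        if config.rarefaction_depth == "auto"
        else int(config.rarefaction_depth)
    )
    rare = compositional.rarefy(
        filtered, depth, config.rarefaction_cycles, seed=config.rng_seed
    )
    report.log(
        "rarefy", depth=depth, cycles=config.rarefaction_cycles,
        dropped=list(rare.dropped_samples),
    )
    retained = filtered.select_samples(list(rare.sample_ids))
    clr = compositional.dirichlet_clr(
        retained, config.n_instances, seed=config.rng_seed
    )
    report.log("dirichlet_clr", n_instances=config.n_instances, prior=clr.prior)
    return retained, rare, clr


def run_pipeline(
    counts: CountTable,
    design: pd.DataFrame,
    config: RunConfig,
    out_dir: str | Path,
    markers: tuple[str, ...] = MARKERS,
) -> RunReport:
    """Run every analysis surface and write one TSV per result table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict(), seed=config.rng_seed)
    covs = list(config.covariates)

    retained, rare, clr = prepare(counts, config, report)
    design = apply_marker_limits(
        design.loc[list(rare.sample_ids)], config.clip_marker_limits
    )

    alpha = diversity.alpha_diversity(rare)
    _write(alpha.reset_index(names="sample_id"), out / "alpha_diversity.tsv", report)

    bc = diversity.bray_curtis(rare.canonical)
    ord_ = diversity.pcoa(bc, n_axes=2)

    marker_rows, contrast_frames = [], []
    for m in markers:
        y = models.rank_transform(design[m])
        _, res, contr = models.timecourse_lrt(y, design, covs, response=m)
        marker_rows.append(
            {"marker": m, "lrt_stat": res.statistic, "lrt_df": res.df, "lrt_p": res.p}
        )
        contr.insert(0, "marker", m)
        contrast_frames.append(contr)
    _write(pd.DataFrame(marker_rows), out / "marker_timecourse_lrt.tsv", report)
    _write(pd.concat(contrast_frames), out / "marker_timecourse_contrasts.tsv", report)

    overall, contrasts = models.per_feature_timecourse(
        clr, design, covs, config.fdr_alpha
    )
    _write(overall.reset_index(), out / "feature_timecourse_overall.tsv", report)
    _write(contrasts, out / "feature_timecourse_contrasts.tsv", report)

    quant = pd.DataFrame(
        {
            "shannon": alpha["shannon"],
            "PCo1": ord_.scores(0),
            "PCo2": ord_.scores(1),
        }
    )
    screen_alpha = rmcorr_screen(quant, design, list(markers))
    _write(screen_alpha, out / "rmcorr_diversity.tsv", report)
    screen_feat = rmcorr_screen_clr(clr, design, list(markers))
    _write(screen_feat, out / "rmcorr_features.tsv", report)

    dt = delta.build_deltas(rare.canonical, clr, design, list(markers), covs)
    for m in markers:
        scr = delta.delta_screen(dt, m, covariates=covs, alpha=config.fdr_alpha)
        _write(scr.reset_index(), out / f"delta_screen_{m}.tsv", report)

    report.write(out / "run_report.json")
    return report


def _write(frame: pd.DataFrame, path: Path, report: RunReport) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    report.outputs[path.stem] = str(path)
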