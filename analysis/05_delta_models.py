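#!/usr/bin/env python
"""Change-vs-change analysis: marker changes over all within-subject visit
pairs modelled on genus CLR changes (common-slope vs interaction LRTs),
the Bray–Curtis distance variant, the zonulin-vs-calprotectin convenience
model, and the directional interval-overlap report. Writes results/delta/."""

from pathlib import Path

import pandas as pd

from microperm import delta as dmod, models
from microperm.io_config import RunConfig, RunReport, read_cohort, read_count_table
from microperm.pipeline import prepare

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
TIMEPOINTS = ["P2", "P3", "P4", "P5", "P6"]
MARKERS = ["zonulin", "calprotectin"]
COVS = ["delivery_mode", "breastfeeding_weeks"]
N_INSTANCES = 4


def main() -> None:
    out = ROOT / "delta"
    out.mkdir(parents=True, exist_ok=True)
    counts = read_count_table(ROOT / "cohort" / "counts.tsv")
    design = read_cohort(ROOT / "cohort" / "metadata.tsv", TIMEPOINTS)
    config = RunConfig(n_instances=N_INSTANCES, rng_seed=SEED)
    _, rare, clr = prepare(counts, config, RunReport())
    design = design.loc[list(rare.sample_ids)]

    dt = dmod.build_deltas(rare.canonical, clr, design, MARKERS, COVS)
    print(f"delta table: {dt.n_rows} within-subject visit pairs "
          f"({design['subject_id'].nunique()} subjects)")

    for marker in MARKERS:
        scr = dmod.delta_screen(dt, marker, covariates=COVS)
        scr.reset_index().to_csv(out / f"genus_screen_{marker}.tsv", sep="\t", index=False)
        flagged = scr[scr["decision"] != "none"]
        print(f"\nΔ{marker} ~ Δgenus screen: {len(flagged)} flagged")
        if len(flagged):
            print(flagged[["beta", "se", "lrt1_q", "lrt2_q", "decision"]]
                  .round(4).to_string())

    bc = dmod.fit_delta_model(dt, "calprotectin", "bray_curtis", COVS)
    print(f"\nΔcalprotectin ~ Bray–Curtis distance: beta={bc.beta:.2f} "
          f"(SE {bc.se:.2f}), common-slope p={bc.lrt1_p:.3f}, decision={bc.decision}")

    zc = dmod.fit_delta_model(dt, "calprotectin", "d_zonulin", COVS)
    print(f"Δcalprotectin ~ Δzonulin: beta={zc.beta:.2f} (SE {zc.se:.2f}), "
          f"common-slope p={zc.lrt1_p:.3f}, interaction p={zc.lrt2_p:.3f}")

    # directional co-occurrence of significant interval changes
    y = models.rank_transform(design["calprotectin"])
    _, _, marker_contr = models.timecourse_lrt(y, design, COVS)
    _, feat_contr = models.per_feature_timecourse(clr, design, COVS)
    overlap = dmod.interval_overlap(marker_contr, feat_contr)
    overlap.to_csv(out / "interval_overlap_calprotectin.tsv", sep="\t", index=False)
    labelled = overlap[overlap["label"] != ""]
    print(f"\ninterval overlap with calprotectin changes: "
          f"{len(labelled)} genera labelled")
    if len(labelled):
        print(labelled.to_string(index=False))


if __name__ == "__main__":
    main()
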