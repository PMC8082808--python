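#!/usr/bin/env python
"""Time-course mixed models: marker trajectories (rank-transformed, adjusted
for delivery mode and breastfeeding time) and the per-genus CLR screen over
Dirichlet Monte-Carlo instances. Writes results/timecourse/."""

from pathlib import Path

import pandas as pd

from microperm import models
from microperm.io_config import RunConfig, RunReport, read_cohort, read_count_table
from microperm.pipeline import prepare

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
TIMEPOINTS = ["P2", "P3", "P4", "P5", "P6"]
COVS = ["delivery_mode", "breastfeeding_weeks"]
N_INSTANCES = 8  # Monte-Carlo instances for the per-genus screen


def main() -> None:
    out = ROOT / "timecourse"
    out.mkdir(parents=True, exist_ok=True)
    counts = read_count_table(ROOT / "cohort" / "counts.tsv")
    design = read_cohort(ROOT / "cohort" / "metadata.tsv", TIMEPOINTS)
    config = RunConfig(n_instances=N_INSTANCES, rng_seed=SEED)
    _, rare, clr = prepare(counts, config, RunReport())
    design = design.loc[list(rare.sample_ids)]

    rows, frames = [], []
    for marker in ("zonulin", "calprotectin"):
        y = models.rank_transform(design[marker])
        _, res, contr = models.timecourse_lrt(y, design, COVS, response=marker)
        rows.append({"marker": marker, "lrt_stat": res.statistic,
                     "lrt_df": res.df, "lrt_p": res.p})
        contr.insert(0, "marker", marker)
        frames.append(contr)
        sig = contr[contr["q"] < 0.05]["pair"].tolist()
        print(f"{marker}: time LRT df={res.df}, p={res.p:.2e}; "
              f"significant visit pairs: {sig}")
    pd.DataFrame(rows).to_csv(out / "marker_lrt.tsv", sep="\t", index=False)
    pd.concat(frames).to_csv(out / "marker_contrasts.tsv", sep="\t", index=False)

    overall, contrasts = models.per_feature_timecourse(clr, design, COVS)
    overall.reset_index().to_csv(out / "genus_overall.tsv", sep="\t", index=False)
    contrasts.to_csv(out / "genus_contrasts.tsv", sep="\t", index=False)
    hits = overall[overall["significant"]].index.tolist()
    print(f"genera changing over time (averaged q<0.05, {N_INSTANCES} instances): {hits}")


if __name__ == "__main__":
    main()
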