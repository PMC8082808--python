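#!/usr/bin/env python
"""Repeated-measures correlation screens: markers vs alpha diversity and
PCo scores, and markers vs per-genus CLR values (instance-averaged).
Writes results/rmcorr/."""

from pathlib import Path

import pandas as pd

from microperm import diversity as div
from microperm.io_config import RunConfig, RunReport, read_cohort, read_count_table
from microperm.rmcorr import rmcorr_screen, rmcorr_screen_clr
from microperm.pipeline import prepare

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
TIMEPOINTS = ["P2", "P3", "P4", "P5", "P6"]
MARKERS = ["zonulin", "calprotectin"]


def main() -> None:
    out = ROOT / "rmcorr"
    out.mkdir(parents=True, exist_ok=True)
    counts = read_count_table(ROOT / "cohort" / "counts.tsv")
    design = read_cohort(ROOT / "cohort" / "metadata.tsv", TIMEPOINTS)
    config = RunConfig(n_instances=8, rng_seed=SEED)
    _, rare, clr = prepare(counts, config, RunReport())
    design = design.loc[list(rare.sample_ids)]

    alpha = div.alpha_diversity(rare)
    ordn = div.pcoa(div.bray_curtis(rare.canonical), n_axes=2)
    quantities = pd.DataFrame(
        {
            "shannon": alpha["shannon"],
            "simpson": alpha["simpson"],
            "chao1": alpha["chao1"],
            "evenness": alpha["evenness"],
            "PCo1": ordn.scores(0),
            "PCo2": ordn.scores(1),
        }
    )
    scr_div = rmcorr_screen(quantities, design, MARKERS, rank=True)
    scr_div.to_csv(out / "diversity_rmcorr.tsv", sep="\t", index=False)
    print("marker vs diversity/ordination (rank-transformed markers):")
    print(scr_div[["marker", "feature", "r", "p", "q"]].round(4).to_string(index=False))

    scr_gen = rmcorr_screen_clr(clr, design, MARKERS, rank=True)
    scr_gen.to_csv(out / "genus_rmcorr.tsv", sep="\t", index=False)
    hits = scr_gen[scr_gen["q"] < 0.05]
    print(f"\n{len(hits)} genus–marker rmcorr associations at averaged q<0.05; strongest:")
    print(hits.sort_values("q")[["marker", "feature", "r", "q"]].head(8).round(4)
          .to_string(index=False))


if __name__ == "__main__":
    main()
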