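#!/usr/bin/env python
"""Multiply impute the cohort's missing items and covariates under MAR.

Runs the two-stage multilevel latent-normal sampler (Q1 pattern: pre-op
items + incomplete covariates with provider-level auxiliaries; Q2
pattern: post-op items with patient-level auxiliaries, fitted on pre-op
responders) and writes the M completed datasets plus a manifest under
results/imputations/.

Desk-scale sampler settings (M = 10, 400 post-burn-in iterations thinned
every 40th after 300 burn-in) keep this run under a few minutes; the
published configuration (M = 100, 10,000 iterations, thinning 100) is a
parameter choice away.
"""

import time
from pathlib import Path

import pandas as pd

from promperf.imputation import impute_pipeline

SEED = 2026
COHORT = Path("results/cohort")
OUT = Path("results/imputations")


def main() -> None:
    patients = pd.read_csv(COHORT / "cohort.csv")
    providers = pd.read_csv(COHORT / "providers.csv")

    t0 = time.time()
    imp = impute_pipeline(patients, providers, m=10,
                          iterations=400, thinning=40, burnin=300, seed=SEED)
    imp.save(OUT)

    complete = all(
        not d[[c for c in d.columns if "item" in c] + ["nonwhite", "symptom_duration"]]
        .isna().any().any() for d in imp.datasets)
    print(f"M = {imp.m} completed datasets in {time.time() - t0:.0f}s; "
          f"all modelled cells complete: {complete}")
    obs_mean = patients["y2_total"].mean()
    mi_mean = sum(d["y2_total"].mean() for d in imp.datasets) / imp.m
    print(f"observed post-op mean {obs_mean:.2f} -> completed-data mean {mi_mean:.2f} "
          "(missing patients carry a poorer observed profile)")
    print(f"written to {OUT}/")


if __name__ == "__main__":
    main()
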