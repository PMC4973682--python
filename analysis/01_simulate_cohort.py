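#!/usr/bin/env python
"""Generate the desk-scale synthetic PROM cohort the later stages analyse.

50 providers with lognormal volumes (mean ~200 patients), case-mix
covariates at the published category frequencies, pre/post-op OHS items
from the latent threshold model, and MAR questionnaire-level missingness
(delta = 0).  Writes the cohort, the pre-deletion truth, the provider
frame and the config under results/cohort/ and prints the descriptive
statistics the generator is calibrated to emulate.
"""

import json
from pathlib import Path

from promperf.cohort import CohortConfig, generate_cohort

SEED = 2026
OUT = Path("results/cohort")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = CohortConfig(seed=SEED)
    providers, patients, truth = generate_cohort(config)

    providers.to_csv(OUT / "providers.csv", index=False)
    patients.to_csv(OUT / "cohort.csv", index=False)
    truth.to_csv(OUT / "truth.csv", index=False)
    config.save_yaml(OUT / "config.yaml")
    (OUT / "meta.json").write_text(json.dumps({"seed": SEED}, indent=2))

    r1, r2 = patients["R1"].mean(), patients["R2"].mean()
    print(f"cohort: {len(patients)} patients in {len(providers)} providers")
    print(f"pre-op OHS  (truth): mean {truth['y1_total'].mean():5.2f}  SD {truth['y1_total'].std():5.2f}")
    print(f"post-op OHS (truth): mean {truth['y2_total'].mean():5.2f}  SD {truth['y2_total'].std():5.2f}")
    print(f"response: Q1 {r1:.1%}, Q2 {r2:.1%} "
          f"(observed post-op mean {patients['y2_total'].mean():.2f})")
    print(f"covariate missingness: ethnicity {patients['nonwhite'].isna().mean():.1%}, "
          f"symptom duration {patients['symptom_duration'].isna().mean():.1%}")
    print(f"written to {OUT}/")


if __name__ == "__main__":
    main()
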