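#!/usr/bin/env python
"""Generate the synthetic study populations used by the downstream steps.

Two datasets are written under results/data/:

* ``recalls_2d.csv`` — 500 women x 2 recall days, log-scale usual intakes
  (zinc-like units, population mean ~11 mg/d), true WIV:total = 2/3, a
  weekend effect and a small second-recall effect.  This is the repeat-day
  dataset the 2-d workflow decomposes.
* ``survey_1d.csv`` — 480 women x 1 day on a 24-strata x 2-cluster design
  with unequal weights and cluster-level intake tilts, for the design-based
  uncertainty step.

Each CSV gets a ``.truth.json`` sidecar with the generating parameters.
"""

from pathlib import Path

from intakevar import SyntheticConfig, generate
from intakevar.simulate import write_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20260101


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cfg_2d = SyntheticConfig(
        n_subjects=500, n_days=2, mu=2.0, s_b2=0.25, s_w2=0.50,
        lambda_true=0.0, weekend_effect=0.15, sequence_effects=(-0.05,),
        seed=SEED)
    data, truth = generate(cfg_2d)
    write_dataset(data, truth, OUT / "recalls_2d.csv")
    print(f"recalls_2d.csv: {len(data)} rows, "
          f"true WIV:total = {truth['beta_true']:.4f}, "
          f"median intake = {data['intake'].median():.2f}")

    day1 = data[data["sequence"] == 1]
    day1.to_csv(OUT / "recalls_day1.csv", index=False)
    print(f"recalls_day1.csv: {len(day1)} rows (first recall only)")

    cfg_survey = SyntheticConfig(
        n_subjects=480, n_days=1, mu=2.0, s_b2=0.25, s_w2=0.50,
        lambda_true=0.0,
        design={"n_strata": 24, "clusters_per_stratum": 2,
                "weight_model": "variable", "cluster_effect_sd": 0.15},
        seed=SEED + 1)
    survey, struth = generate(cfg_survey)
    write_dataset(survey, struth, OUT / "survey_1d.csv")
    print(f"survey_1d.csv: {len(survey)} rows, "
          f"{survey['stratum'].nunique()} strata, "
          f"weights {survey['weight'].min():.2f}-{survey['weight'].max():.2f}")


if __name__ == "__main__":
    main()
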