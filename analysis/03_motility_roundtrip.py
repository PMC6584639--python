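#!/usr/bin/env python
"""Single-molecule motility: kymograph round trip and condition contrasts.

1. Simulates wild-type motors (0.45 µm/s, 8.6 µm exponential runs) landing
   on 60 microtubules, renders noisy kymographs, traces them and summarises
   speed, run length (censoring-corrected) and landing rate.
2. Contrasts landing-rate estimates between three simulated conditions:
   motor alone, motor + activator (1.4x true rate) and a hyperactive
   stalk-deletion mutant (20x true rate), with a t-test on per-microtubule
   rates.

Writes results/motility_summary.csv and results/landing_rates.csv.
"""

import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from kifquant import synthgen as sg
from kifquant.motility import MTObservation, landing_rate, summarize, trace_kymograph
from kifquant.stats import group_compare

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def roundtrip(n_mt: int = 60):
    observations = []
    for m in range(n_mt):
        tracks, _ = sg.sim_motility(15.0, 3.0, sg.WILD_TYPE_MOTILITY,
                                    seed=SEED + m)
        kymo = sg.render_kymograph(tracks, 15.0, 180.0, seed=SEED + 500_000 + m)
        observations.append(MTObservation(15.0, 3.0, trace_kymograph(kymo)))
    return summarize(observations, min_duration_s=1.0)


def condition_rates(n_mt: int = 40):
    conditions = {
        "KIF1C alone": sg.WILD_TYPE_MOTILITY,
        "+ activator FERM": replace(sg.WILD_TYPE_MOTILITY,
                                    landing_rate_true=0.15 * 1.4),
        "stalk deletion": replace(sg.WILD_TYPE_MOTILITY,
                                  landing_rate_true=0.15 * 20),
    }
    rows, groups = [], {}
    for i, (name, truth) in enumerate(conditions.items()):
        rates = []
        for m in range(n_mt):
            _, events = sg.sim_motility(10.0, 3.0, truth,
                                        seed=SEED + 900_000 + i * n_mt + m)
            rates.append(landing_rate(MTObservation(10.0, 3.0, events)))
        groups[name] = rates
        rows.append({"condition": name, "true_rate": truth.landing_rate_true,
                     "estimated_rate": round(float(np.mean(rates)), 4)})
    return pd.DataFrame(rows), groups


def main() -> None:
    out = Path("results")
    out.mkdir(exist_ok=True)
    s = roundtrip()
    pd.DataFrame([{
        "mean_speed_um_s": s.mean_speed_um_s,
        "mean_run_length_um": s.mean_run_length_um,
        "run_length_corrected_um": s.run_length_corrected_um,
        "landing_rate_per_um_min": s.landing_rate,
        "running_frequency_per_um_min": s.running_frequency,
        "n_events": s.n_events,
    }]).round(4).to_csv(out / "motility_summary.csv", index=False)
    print(f"round trip over 60 microtubules: mean speed "
          f"{s.mean_speed_um_s:.3f} µm/s (generative 0.45), corrected run "
          f"length {s.run_length_corrected_um:.2f} µm (generative 8.6), "
          f"landing rate {s.landing_rate:.3f} /(µm·min) (generative 0.15)")

    df, groups = condition_rates()
    df.to_csv(out / "landing_rates.csv", index=False)
    print("\n" + df.to_string(index=False))
    base = df.loc[0, "estimated_rate"]
    print(f"activator increase: {100 * (df.loc[1, 'estimated_rate'] / base - 1):.0f}% "
          f"(simulated 40%); stalk-deletion fold-change: "
          f"{df.loc[2, 'estimated_rate'] / base:.1f}x (simulated 20x)")
    cmp = group_compare(groups, test="t", correction="bonferroni")
    print("\npairwise t-tests (Bonferroni):")
    print(cmp.to_string(index=False))


if __name__ == "__main__":
    main()
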