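"""Can age redistribution alone explain a persistent MCV rise?  No.

Runs the age-structured red-cell conveyor under a 3-week doubling of
production (the reticulocyte response to Epo), followed by a below-baseline
production dip (the post-treatment reticulocyte undershoot seen in the
human data), under two scenarios:

* null — cells are born at the normal 106 fL regardless of Epo: MCV rises
  only because young (large) cells are over-represented, returns toward
  baseline once production normalises, and dips *below* baseline during the
  undershoot;
* alternative — cells born during treatment are 8% larger: MCV stays
  elevated as long as any treatment-born cohort survives (~ pulse + one
  120-day lifespan), matching the persistence seen in vivo.

Writes both CBC time series and a comparison summary to results/.
"""

import argparse
import json
from pathlib import Path

from erythrokit import mcv_sim as sim

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int) -> None:  # deterministic model; seed kept for interface parity
    RESULTS.mkdir(parents=True, exist_ok=True)
    model = sim.VolumeAgeModel()  # 106 → 74 fL over 120 d: steady MCV 90 fL
    schedule = sim.ProductionSchedule(
        fold_breakpoints=(
            (0.0, 1.0), (2.0, 2.0), (21.0, 2.0),
            (23.0, 0.6), (42.0, 0.6), (49.0, 1.0),
        )
    )
    effect = sim.SizeEffect(((0.0, 1.0), (2.0, 1.08), (21.0, 1.08), (23.0, 1.0)))
    cfg = sim.SimConfig(dt=0.25, horizon=200.0, retic_age=2.0, burn_in=120.0)

    res = sim.epo_scenario_compare(model, schedule, effect, cfg)
    res["null"].table.to_csv(RESULTS / "mcv_null_scenario.csv", index=False)
    res["alternative"].table.to_csv(RESULTS / "mcv_alt_scenario.csv", index=False)
    summary = {"baseline_mcv_fl": res["baseline_mcv"], **res["summary"]}
    (RESULTS / "mcv_scenarios.json").write_text(json.dumps(summary, indent=2))

    ssn = sim.steady_state_cbc(model, cfg)
    print(f"steady state: MCV {ssn['mcv']:.1f} fL, RDW-SD {ssn['rdw_sd']:.2f} fL, "
          f"retic fraction {ssn['retic_frac']:.4f}")
    for name in ("null", "alternative"):
        s = res["summary"][name]
        print(f"{name:12s}: peak ΔMCV {100 * s['peak_fractional_mcv']:.2f}%, "
              f"{s['days_above_threshold']:.0f} days above +0.5%, "
              f"final ΔMCV {100 * s['final_fractional_mcv']:.2f}%")
    print("conclusion: the production pulse alone is transient and bounded; "
          "only a birth-size effect sustains the MCV elevation")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
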