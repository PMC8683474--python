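"""Generate every synthetic fixture the downstream analyses consume.

Writes CSV tables plus a sidecar JSON of generator parameters to
results/fixtures/.  All generators are seeded; re-running with the same seed
reproduces the files bit for bit.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from erythrokit import synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"


def main(seed: int) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = {"seed": seed}

    spec = syn.BeadSpec(area_cv=0.05, rim_bias=0.5, outlier_frac=0.01)
    syn.gen_bead_events(spec, seed).to_csv(OUT / "beads.csv", index=False)
    params["beads"] = {"diameters": list(spec.diameters), "area_cv": spec.area_cv,
                       "rim_bias": spec.rim_bias, "outlier_frac": spec.outlier_frac}

    stages = syn.default_stage_panel()
    events = syn.gen_erythroid_events(stages, 50_000, seed + 1)
    events.to_csv(OUT / "erythroid_events.csv", index=False)
    params["erythroid"] = {s.name: s.mean_diameter for s in stages}

    for name, td in (("epor", 6.1), ("bclxl", 8.6)):
        truth = syn.GrowthTruth(n0=1.0, doubling_time=td, count_cv=0.05)
        df = syn.gen_growth_series(truth, np.linspace(0, 26, 10), seed + 2)
        df.to_csv(OUT / f"growth_{name}.csv", index=False)
    params["growth"] = {"doubling_times_h": [6.1, 8.6], "count_cv": 0.05}

    syn.gen_brdu_dna((0.3, 0.5, 0.2), 1.0, 20_000, seed + 3).to_csv(
        OUT / "brdu_reference.csv", index=False)
    syn.gen_brdu_dna((0.3, 0.5, 0.2), 1.5, 20_000, seed + 4).to_csv(
        OUT / "brdu_fast.csv", index=False)
    params["brdu"] = {"fractions": [0.3, 0.5, 0.2], "speed_ratio": 1.5}

    for name, T in (("T6", 6.0), ("T12", 12.0)):
        df = syn.gen_ft_events(syn.FTTruth(T=T, tau=1.5), 30_000, seed + 5)
        df.to_csv(OUT / f"ft_{name}.csv", index=False)
    params["ft"] = {"T_h": [6.0, 12.0], "tau_h": 1.5}

    panel = syn.gen_cbc_panel(syn.study1_design(), seed + 6)
    panel.to_csv(OUT / "cbc_panel.csv", index=False)
    params["cbc"] = {"n_treated": 25, "n_placebo": 9}

    (OUT / "params.json").write_text(json.dumps(params, indent=2))
    print(f"wrote fixtures for seed {seed} to {OUT}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
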