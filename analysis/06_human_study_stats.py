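"""Intervention-study statistics on a simulated study-#1-shaped CBC panel.

Simulates 25 Epo-treated and 9 placebo subjects (4 baseline weeks, 3
treatment weeks, 5 follow-up weeks, weekly sampling) and runs the full
statistical pipeline: subject-level baseline correction, fractional change,
per-timepoint Welch contrasts with Benjamini–Hochberg adjustment, pooled
correlations (MCV vs RDW-SD, MCV vs reticulocytes), and the Welch test on
the published colony-area summaries.
"""

import argparse
import json
from pathlib import Path

from erythrokit import study_stats as ss
from erythrokit import synthetic as syn

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int) -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    out = {}
    panel = syn.gen_cbc_panel(syn.study1_design(), seed)

    corrected = ss.baseline_correct(panel)
    frac = ss.fractional_change(panel)
    hgb = frac[(frac["analyte"] == "hemoglobin") & (frac["group"] == "treated")]
    in_window = hgb[(hgb["time_days"] >= 7) & (hgb["time_days"] <= 21)]
    out["hemoglobin_fractional_change"] = float(in_window["value"].mean())
    print(f"hemoglobin in treatment window: {100 * out['hemoglobin_fractional_change']:.1f}% "
          "over baseline (truth +5%)")

    contrasts = ss.per_timepoint_contrasts(panel, "MCV")
    contrasts.to_csv(RESULTS / "mcv_contrasts.csv", index=False)
    out["mcv_significant_timepoints"] = int(contrasts["significant"].sum())
    out["mcv_timepoints_total"] = len(contrasts)
    print("MCV treated-vs-placebo contrasts (baseline-corrected, BH-adjusted):")
    print(contrasts[["time_days", "estimate", "p_adj", "significant"]]
          .round(4).to_string(index=False))

    r_rdw = ss.correlate(corrected, "MCV", "RDW_SD", scope="pooled")
    r_retic = ss.correlate(corrected, "MCV", "retic", scope="pooled")
    out["pooled_r_mcv_rdw"] = r_rdw.r
    out["pooled_r_mcv_retic"] = r_retic.r
    print(f"pooled Pearson r: MCV–RDW-SD {r_rdw.r:.2f} (p {r_rdw.p:.2g}); "
          f"MCV–retic {r_retic.r:.2f} — the diverging retic time course "
          "decouples it from MCV")

    colony = ss.welch_t_summary(439, 208, 75, 217, 106, 75)
    out["colony_welch"] = {"t": colony.statistic, "df": colony.df, "p": colony.p}
    print(f"colony-area Welch test: t = {colony.statistic:.2f}, "
          f"df = {colony.df:.0f}, p = {colony.p:.2g}")

    (RESULTS / "human_study_stats.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
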