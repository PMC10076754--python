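"""Biomonitoring analysis of the synthetic study.

Derives midpoint-assigned urinary deposition rates, fractions of ingested
dose excreted per metabolite (FUE), the adipic-acid background, and the
absorption bounds, per volunteer. Requires 05_synthesise_study.py first.
Outputs: results/biomonitoring/.
"""

import json
from pathlib import Path

import pandas as pd

from deha_pbk import biomonitoring as bm
from deha_pbk.parameters import default_parameters

ROOT = Path(__file__).resolve().parents[1] / "results"
STUDY = ROOT / "study"
OUT = ROOT / "biomonitoring"
OUT.mkdir(parents=True, exist_ok=True)

meta = json.loads((STUDY / "truth.json").read_text())
df = pd.read_csv(STUDY / "study_voids.csv")
molar = default_parameters().molar

rows = []
for v in meta["volunteers"]:
    ds = bm.VolunteerDataset.from_frame(df, v["volunteer_id"], BW=v["BW"],
                                        dose=v["dose_mg_per_kg"])
    rates = {a: bm.deposition_rates(ds, a) for a in bm.ANALYTES}
    rec = pd.concat([
        pd.DataFrame({"volunteer": ds.id, "analyte": a,
                      "midpoint_h": s.midpoints, "rate_mg_per_h": s.rates})
        for a, s in rates.items()], ignore_index=True)
    rec.to_csv(OUT / f"deposition_rates_{ds.id}.csv", index=False)

    # adipic-acid background: automatic washout selection, falling back to
    # the last AA voids when the specific metabolite has not washed out
    try:
        bg_total, bg_rate = bm.aa_background(ds)
        bg_mode = "automatic"
    except ValueError:
        aa_times = [u.t for u in ds.voids if "AA" in u.conc][-3:]
        bg_total, bg_rate = bm.aa_background(ds, select_times=aa_times)
        bg_mode = "manual (last 3 AA voids)"

    fues = {}
    for a in bm.ANALYTES:
        background = bg_total if a == "AA" else 0.0
        fues[a] = bm.fue(ds, a, molar, background_total_mg=background)
    lower, pairs = bm.absorption_bounds(fues)
    rows.append({
        "volunteer": ds.id,
        "aa_background_rate_mg_per_h": bg_rate, "aa_background_mode": bg_mode,
        **{f"FUE_{a}": f for a, f in fues.items()},
        "FracAbsorbed_lower_bound": lower,
        "true_FracAbsorbed": v["local_params"]["FracAbsorbed"],
        "true_aa_background": v["aa_background_rate"]})

summary = pd.DataFrame(rows)
summary.to_csv(OUT / "summary.csv", index=False)
print(summary.to_string(index=False))
print("\nThe FUE of the specific metabolites are of order 1e-3 (the "
      "specifics account for well under 1% of the ingested dose); the "
      "absorbed-fraction lower bound is dominated by adipic acid.")
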