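#!/usr/bin/env python
"""Stage 3 — fit the 120-member SDM ensemble and classify suitability.

Draws 3 sets of 500 pseudo-absences, fits GLM / GAM / GBM / RF over
3 pseudo-absence replicates x 10 cross-validation runs (75/25 splits),
evaluates every member with AUC and TSS, mixes all members by Committee
Averaging and AUC-weighted mean, scores permutation variable importance,
and cuts the weighted-mean map into four Jenks suitability levels.

Writes the member table, ensemble maps, importance table and
classification under results/sdm/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from phylosdm import sdm
from phylosdm.occurrences import read_occurrences
from phylosdm.rasters import RasterStack, read_ascii_grid, write_ascii_grid

IN = Path("results/inputs")
PREP = Path("results/prep")
OUT = Path("results/sdm")
SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    kept = json.loads((PREP / "variables.json").read_text())["kept"]
    stack = RasterStack([read_ascii_grid(IN / f"layer_{n}.asc", name=n)
                         for n in kept])
    records = read_occurrences(PREP / "occurrences_thinned.csv")
    presences = np.array([r.point for r in records])

    pa_sets = sdm.gen_pseudo_absences(stack, presences, n=500, n_sets=3,
                                      seed=SEED)
    runs = sdm.fit_model_grid(stack, presences, pa_sets, cv_runs=10,
                              seed=SEED + 1)
    stats = sdm.member_stats(runs)
    pd.DataFrame([{"algorithm": r.algorithm, "pa": r.pa_replicate,
                   "cv": r.cv_run, "auc": r.auc, "tss": r.tss,
                   "threshold": r.threshold, "passes_qc": r.passes_qc,
                   "ok": r.ok} for r in runs]) \
        .to_csv(OUT / "members.csv", index=False)
    print(f"{stats['n_members']} members fitted "
          f"({stats['n_usable']} usable, {stats['n_passes_qc']} pass QC); "
          f"AUC {stats['auc_mean']:.3f} +/- {stats['auc_sd']:.3f}, "
          f"TSS {stats['tss_mean']:.3f} +/- {stats['tss_sd']:.3f}")

    pre = sdm.member_scores(runs, stack)
    ca = sdm.ensemble_ca(runs, stack, precomputed=pre)
    wm = sdm.ensemble_wm(runs, stack, precomputed=pre)
    write_ascii_grid(ca, OUT / "ensemble_ca.asc")
    write_ascii_grid(wm, OUT / "ensemble_wm.asc")
    all_pa = np.vstack(pa_sets)
    for name, layer in (("CA", ca), ("WM", wm)):
        auc, tss = sdm.evaluate_ensemble(layer, presences, all_pa)
        print(f"{name} ensemble: AUC {auc:.3f}, TSS {tss:.3f} "
              f"(pooled evaluation)")

    imp = sdm.variable_importance(runs, stack, seed=SEED + 2)
    pd.Series(imp, name="importance").rename_axis("variable") \
        .to_csv(OUT / "importance.csv")
    ranked = sorted(imp.items(), key=lambda kv: -kv[1])
    print("variable importance:",
          ", ".join(f"{k} {v:.2f}" for k, v in ranked))

    breaks = sdm.jenks_breaks(wm.valid_values(), 4)
    classification = sdm.classify_suitability(wm, breaks)
    write_ascii_grid(classification.class_map, OUT / "suitability_class.asc")
    (OUT / "classification.json").write_text(json.dumps(
        {"breaks": classification.breaks,
         "class_areas_km2": {str(c): a for c, (a, _)
                             in classification.class_areas.items()},
         "class_percent": {str(c): p for c, (_, p)
                           in classification.class_areas.items()}},
        indent=2))
    print(f"Jenks breaks: {[round(b, 3) for b in breaks]}")
    for c, (area, pct) in classification.class_areas.items():
        print(f"  class {c}: {area:,.0f} km2 ({pct:.1f}%)")


if __name__ == "__main__":
    main()
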