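#!/usr/bin/env python
"""Stage 2 — thin occurrences and filter collinear variables.

Applies the 10-km spatial thinning rule (records closer than 10 km are
replicates; one survives) and the |r| > 0.8 Pearson collinearity filter
over the environmental layers.  Writes the thinned records and the
variable decision log under results/prep/.
"""

import json
from pathlib import Path

from phylosdm.occurrences import (collinearity_filter, read_occurrences,
                                  thin_occurrences, write_occurrences)
from phylosdm.rasters import RasterStack, read_ascii_grid

IN = Path("results/inputs")
OUT = Path("results/prep")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = read_occurrences(IN / "occurrences.csv")
    retained, dropped = thin_occurrences(records, 10.0, metric="planar")
    write_occurrences(retained, OUT / "occurrences_thinned.csv")
    print(f"thinning: {len(retained)} of {len(records)} records retained "
          f"({len(dropped)} replicates within 10 km dropped)")

    stack = RasterStack([read_ascii_grid(p, name=p.stem.removeprefix("layer_"))
                         for p in sorted(IN.glob("layer_*.asc"))])
    kept, dropped_vars = collinearity_filter(stack, 0.8)
    (OUT / "variables.json").write_text(json.dumps(
        {"kept": kept,
         "dropped": [{"dropped": d, "kept_partner": p, "r": r}
                     for d, p, r in dropped_vars]}, indent=2))
    print(f"collinearity filter: kept {kept}")
    for d, p, r in dropped_vars:
        print(f"  dropped {d} (|r| = {abs(r):.3f} with {p})")


if __name__ == "__main__":
    main()
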