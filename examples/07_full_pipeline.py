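"""The complete four-group phantom study, end to end.

Generates one placenta phantom per litter with the configured group effects
(+14% volume and +20% capillary surface under hypoxia, +15% maternal blood
space under hypoxia + antioxidant), runs the full stereology, densitometry
and statistics, and writes a results tree with a reproducibility manifest.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from stereoplacenta import PipelineConfig, run_pipeline

out = Path("example_run")
cfg = PipelineConfig.from_dict({
    "study": {"litters_per_group": {"N": 6, "H": 6, "HM": 6, "NM": 6}},
    "seed": 7,
})
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    manifest = run_pipeline(cfg, out)

print("stages:", ", ".join(f"{s} ({r['seconds']}s)"
                           for s, r in manifest.stages.items()))
fits = json.loads((out / "stats.json").read_text())["fits"]
rows = []
for outcome in ("volume_mm3", "fc_surface_cm2", "mbs_surface_cm2",
                "tau_h_um", "relative"):
    e = fits[outcome]["effects"]
    rows.append({"outcome": outcome,
                 "p_hypoxia": round(e["hypoxia"]["p"], 4),
                 "p_mitoq": round(e["mitoq"]["p"], 4)})
print(pd.DataFrame(rows).to_string(index=False))
print("Low hypoxia p-values on volume and capillary surface reflect the "
      "programmed morphological adaptation; the membrane thickness stays "
      "null, as configured.")
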