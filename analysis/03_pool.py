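#!/usr/bin/env python
"""Second stage: pool per-IQR community estimates with ML random effects.

Pools the first-stage log effects (per community-specific IQR of TV) within
countries and within climate zones (quartiles of annual mean temperature),
for every TV window and season. Writes results/pooled_country.csv and
results/pooled_zone.csv.
"""

from pathlib import Path

import pandas as pd

from tvmort.io import read_metadata_csv, write_results_csv
from tvmort.meta import assign_climate_zones, pool_by_group

ROOT = Path(__file__).resolve().parents[1]
metadata = read_metadata_csv(ROOT / "results" / "metadata.csv")
fs = pd.read_csv(ROOT / "results" / "first_stage.csv")

per_iqr = fs.copy()
per_iqr["coefficient"] *= per_iqr["iqr"]
per_iqr["se"] *= per_iqr["iqr"]
per_iqr = per_iqr[["community_id", "tv_window", "season", "coefficient", "se"]]

for grouping, labels in (
    ("country", metadata.set_index("community_id")["country"]),
    ("zone", assign_climate_zones(metadata)),
):
    pooled = pool_by_group(per_iqr, labels)
    write_results_csv(pooled, ROOT / "results" / f"pooled_{grouping}.csv")
    head = pooled[(pooled["season"] == "all") & (pooled["tv_window"] == 1)]
    print(f"\npooled by {grouping} (window 0-1, all seasons):")
    print(head[["group", "n_communities", "percent_change", "ci_low",
                "ci_high", "I2"]].round(3).to_string(index=False))
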