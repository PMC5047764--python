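#!/usr/bin/env python
"""Quick Monte-Carlo validation of the estimators (reduced replicate counts).

Runs scaled-down versions of the validation studies — parameter recovery,
type-I error, confounding-adjustment ordering, ML pooling recovery, and the
climate-zone pattern — and writes results/validation_summary.json. The
full-size runs live in scripts/acceptance.py.
"""

import json
from pathlib import Path

from tvmort import studies

ROOT = Path(__file__).resolve().parents[1]
seed = 20260925

summary = {
    "recovery": studies.recovery_study(n_reps=50, seed=seed),
    "type1_error": studies.type1_error_study(n_reps=100, seed=seed + 1),
    "confounding": studies.confounding_adjustment_study(n_reps=50, seed=seed + 2),
    "meta_recovery": studies.meta_recovery_study(n_reps=100, seed=seed + 3),
}
zone = studies.zone_pattern_study(seed=seed + 4)
summary["zone_pattern"] = {k: v for k, v in zone.items() if k != "pooled"}

out = ROOT / "results"
out.mkdir(exist_ok=True)
(out / "validation_summary.json").write_text(json.dumps(summary, indent=2))

r = summary["recovery"]
print(f"recovery: mean pct/IQR {r['mean_pct_change']:.3f} "
      f"vs truth {r['mean_truth_pct']:.3f}, coverage {r['coverage_pct']:.0f}%")
print(f"type-I error: {summary['type1_error']['rejection_rate_pct']:.1f}% "
      f"(nominal 5%)")
c = summary["confounding"]
print(f"confounding: unadjusted {c['mean_unadjusted_coef']:.5f} -> "
      f"adjusted {c['mean_adjusted_coef']:.5f} (shrinks toward 0)")
m = summary["meta_recovery"]
print(f"ML pooling: mu {m['mu_hat_mean']:.3f} (true {m['true_mu']}), "
      f"tau {m['tau_hat_mean']:.3f} (true {m['true_tau']})")
z = summary["zone_pattern"]
print(f"zone pattern: window 0-1 hot {z['short_hot']:.2f}% > others; "
      f"window 0-7 moderate {z['long_moderate_min']:.2f}% > hot/cold")
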