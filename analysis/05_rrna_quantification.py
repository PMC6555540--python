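#!/usr/bin/env python
"""rRNA synthesis fold changes: pulse labelling, northern, TRO.

Three internal-control-normalised quantifications, each simulated at
its measured effect size and recovered by the ratio-of-medians
estimator:

  * pulse labelling — the truncation mutant synthesises rRNA at one
    fifth the WT rate (fold 0.2 against a loading control);
  * northern — the suppressor x exosome double mutant accumulates
    35S/23S pre-rRNA 2-fold over the exosome single mutant (SCR1
    control);
  * TRO — the suppressor strain shows a 3-fold increase of the Pol I
    probe group relative to the 5S internal control.
"""

import json
from pathlib import Path

from sgrmap import (
    POL_I_GROUP,
    fold_change,
    normalize_to_control,
    probe_group_mean,
    simulate_signal_table,
)
from sgrmap.io import write_table

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20240905
out = {}

# pulse labelling: 5-fold reduction in the truncation mutant
pulse = simulate_signal_table(
    {"WT": {"preRNA": 1.0, "loading": 1.0},
     "truncation": {"preRNA": 0.2, "loading": 1.0}},
    control_probe="loading", n_replicates=3, noise_cv=0.2, seed=SEED,
)
f = fold_change(normalize_to_control(pulse, "loading"), "WT", seed=SEED)[0]
out["pulse_fold"] = {"fold": f.fold, "ci": [f.ci_low, f.ci_high], "true": 0.2}
print(f"pulse labelling, truncation/WT: {f.fold:.2f} [{f.ci_low:.2f}, {f.ci_high:.2f}] "
      f"(true 0.2 = five-fold reduction)")

# northern: 2-fold 35S/23S accumulation in suppressor x rrp6 double
northern = simulate_signal_table(
    {"rrp6d": {"35S": 1.0, "23S": 1.0, "SCR1": 1.0},
     "F301S_rrp6d": {"35S": 2.0, "23S": 2.0, "SCR1": 1.0}},
    control_probe="SCR1", n_replicates=3, noise_cv=0.2, seed=SEED + 1,
)
write_table(northern, RESULTS / "northern_signals.tsv", {"seed": SEED + 1, "control": "SCR1"})
folds = {e.probe: e for e in fold_change(normalize_to_control(northern, "SCR1"), "rrp6d", seed=SEED)}
out["northern_folds"] = {p: {"fold": e.fold, "ci": [e.ci_low, e.ci_high]}
                         for p, e in folds.items()}
for p in ("35S", "23S"):
    e = folds[p]
    print(f"northern {p}, double/rrp6d: {e.fold:.2f} [{e.ci_low:.2f}, {e.ci_high:.2f}] (true 2)")

# TRO: 3-fold increase of the Pol I probe group relative to 5S
tro = simulate_signal_table(
    {"WT": {**dict.fromkeys(POL_I_GROUP, 1.0), "NTS2": 1.0, "5S": 1.0},
     "F301S": {**dict.fromkeys(POL_I_GROUP, 3.0), "NTS2": 1.0, "5S": 1.0}},
    control_probe="5S", n_replicates=3, noise_cv=0.2, seed=SEED + 2,
)
ns = probe_group_mean(normalize_to_control(tro, "5S"), list(POL_I_GROUP), name="PolI")
e = {x.probe: x for x in fold_change(ns, "WT", seed=SEED)}["PolI"]
out["tro_pol_i_fold"] = {"fold": e.fold, "ci": [e.ci_low, e.ci_high], "true": 3.0}
print(f"TRO Pol I group, F301S/WT: {e.fold:.2f} [{e.ci_low:.2f}, {e.ci_high:.2f}] (true 3)")

RESULTS.mkdir(exist_ok=True)
with open(RESULTS / "rrna_quantification.json", "w") as fh:
    json.dump(out, fh, indent=1)
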