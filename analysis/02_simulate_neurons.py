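#!/usr/bin/env python
"""Generate the per-session synthetic populations used by analyses 03-06.

Follows the default selectivity schedules: non-match coding ramps from 5%
to 25% of units during the first phase; after the rule switch, cue-identity
coding ramps identically while a residual 10% of units keep (weaker)
non-match coding — but only in the rule-switching group.  Controls carry
cue-identity coding alone.

Writes results/neural/rates_<group>_<session>.csv (trials x units, with a
sidecar labels table) and a units.csv manifest with each unit's programmed
tuning (the ground truth downstream analyses are checked against).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from schemapop.neuro_synth import (
    CONTROL, RULE_SWITCHING, PopulationSpec, balanced_type_trials,
    schedule_selectivity, synth_rate_matrix,
)
from schemapop.taskgen import CUE_ID, NON_MATCH

OUT = Path(__file__).resolve().parents[1] / "results" / "neural"
SEED = 21
N_UNITS = 80
N_PER_TYPE = 12


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    trials = balanced_type_trials(N_PER_TYPE)
    trials.to_csv(OUT / "trial_labels.csv", index=False)
    manifest = []
    schedule = (
        [(RULE_SWITCHING, NON_MATCH, s) for s in range(5)]
        + [(RULE_SWITCHING, CUE_ID, s) for s in range(5)]
        + [(CONTROL, CUE_ID, s) for s in range(5)]
    )
    for group, phase, s in schedule:
        spec = schedule_selectivity(s, phase, group)
        spec = PopulationSpec(**{**spec.__dict__, "n_units": N_UNITS})
        rm = synth_rate_matrix(spec, trials, seed=int(rng.integers(2**31)))
        tag = f"{group}_{phase}_s{s}"
        pd.DataFrame(rm.rates).to_csv(OUT / f"rates_{tag}.csv", index=False)
        units = rm.units.assign(group=group, phase=phase, session=s)
        manifest.append(units)
        n_nm = int((units.delta_nm != 0).sum())
        n_ci = int((units.delta_ci != 0).sum())
        print(f"{tag}: {n_nm} non-match-coding units, {n_ci} cue-identity-coding")
    pd.concat(manifest, ignore_index=True).to_csv(OUT / "units.csv", index=False)
    print(f"\nWrote {len(schedule)} session populations under {OUT}")


if __name__ == "__main__":
    main()
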