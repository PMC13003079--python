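#!/usr/bin/env python
"""Single-unit rule selectivity across the curriculum.

For every session population from analysis 02, runs the permutation
selectivity test for both rules on each unit and tabulates the proportions
of non-match-only, cue-identity-only, and dual-selective units.

Expected pattern: the non-match-selective proportion ramps toward ~25%
during non-match training, cue-identity selectivity ramps after the switch,
and a residual non-match-selective fraction persists only in the
rule-switching group.

Writes results/units/selectivity.csv and proportions.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from schemapop import unit_metrics
from schemapop.taskgen import CUE_ID, NON_MATCH

NEURAL = Path(__file__).resolve().parents[1] / "results" / "neural"
OUT = Path(__file__).resolve().parents[1] / "results" / "units"
SEED = 22
N_PERM = 500


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    trials = pd.read_csv(NEURAL / "trial_labels.csv")
    labels = {NON_MATCH: trials.rewarded_nm.to_numpy(),
              CUE_ID: trials.rewarded_ci.to_numpy()}
    rng = np.random.default_rng(SEED)
    unit_rows, prop_rows = [], []
    for path in sorted(NEURAL.glob("rates_*.csv")):
        tag = path.stem.removeprefix("rates_")
        rates = pd.read_csv(path).to_numpy()
        results = {}
        for rule in (NON_MATCH, CUE_ID):
            results[rule] = [
                unit_metrics.selectivity_test_rates(
                    rates[:, u], labels[rule], n_perm=N_PERM,
                    seed=int(rng.integers(2**31)), unit_id=u, rule=rule,
                )
                for u in range(rates.shape[1])
            ]
            unit_rows += [
                dict(session=tag, unit_id=r.unit_id, rule=r.rule,
                     stat=r.statistic, p=r.p, selective=r.selective)
                for r in results[rule]
            ]
        prop = unit_metrics.selective_proportion(results)
        prop_rows.append(dict(session=tag, **prop))
        print(f"{tag}: non-match {prop[NON_MATCH]:.0%}, "
              f"cue-id {prop[CUE_ID]:.0%}, both {prop['both']:.0%}")
    pd.DataFrame(unit_rows).to_csv(OUT / "selectivity.csv", index=False)
    pd.DataFrame(prop_rows).to_csv(OUT / "proportions.csv", index=False)


if __name__ == "__main__":
    main()
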