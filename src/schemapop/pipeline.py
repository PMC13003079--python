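"""End-to-end pipeline driver, run configuration, fixtures, and file I/O.

The pipeline chains simulate -> single-unit metrics -> population geometry ->
decoding -> decoder-behavior linkage on fully synthetic data and writes
plain-text tables (CSV) plus a machine-readable ``summary.json``.  All
randomness flows from the seeds named in :class:`RunConfig`; identical
configurations produce byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import decoding, geometry, linkage, neuro_synth, taskgen, unit_metrics
from .neuro_synth import (
    CONTROL, RULE_SWITCHING, PopulationSpec, balanced_type_trials,
    schedule_selectivity, split_by_rat, synth_rate_matrix,
)
from .taskgen import CUE_ID, NON_MATCH, AgentPolicy, BehaviorSession, TaskConfig


@dataclass
class RunConfig:
    """All pipeline parameters with their canonical defaults.

    Statistical defaults (50 ms bins, 5-bin smoothing, 500 ms response
    window, 1 s baseline, 80%/30-trial criterion, 1000 permutations, 1000
    bootstraps, 500 CCGP partitions) are the analysis conventions; the
    simulation sizes are tunable for quick demonstration runs.
    """

    seed: int = 0
    n_rats: int = 5
    n_control_rats: int = 4
    n_units: int = 60
    n_trials: int = 300
    sessions_per_phase: int = 5
    repeat_prob: float = 0.49
    bin_width: float = 0.05
    smooth_bins: int = 5
    response_window: float = 0.5
    baseline_window: float = 1.0
    criterion_threshold: float = 0.80
    criterion_window: int = 30
    alpha: float = 0.05
    n_perm: int = 1000
    n_boot: int = 1000
    n_partitions: int = 500
    n_trials_per_type: int = 8
    embedding_backend: str = "linear"

    def __post_init__(self):
        for name in ("n_perm", "n_boot", "n_partitions", "n_trials",
                     "n_units", "n_rats", "sessions_per_phase"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def demo_config(seed: int = 0) -> RunConfig:
    """A small configuration that exercises every stage in well under a minute."""
    return RunConfig(
        seed=seed, n_rats=3, n_control_rats=3, n_units=24, n_trials=120,
        sessions_per_phase=2, n_perm=60, n_boot=30, n_partitions=40,
        n_trials_per_type=4,
    )


def behavior_policy(session_index: int, phase: str, group: str,
                    sessions_per_phase: int = 5) -> AgentPolicy:
    """Default behavioral-agent schedule emulating learning dynamics.

    In the rule-switching group the non-match weight ramps up during the
    first phase; after the rule switch the cue-identity weight ramps up
    while a decaying non-match weight biases early errors toward the old
    rule.  Controls learn cue identity with no old-rule bias.  The first
    session starts with a go bias (naive animals respond on every trial).
    """
    frac = session_index / max(sessions_per_phase - 1, 1)
    frac = min(frac, 1.0)
    bias = max(1.5 * (1.0 - 2 * frac), 0.0)
    if phase == NON_MATCH:
        return AgentPolicy(w_nm=2.5 * frac, w_ci=0.0, go_bias=bias, lapse=0.1)
    if group == RULE_SWITCHING:
        return AgentPolicy(w_nm=1.5 * (1.0 - frac), w_ci=2.5 * frac,
                           go_bias=0.0, lapse=0.1)
    return AgentPolicy(w_nm=0.0, w_ci=2.5 * frac, go_bias=bias, lapse=0.1)


def simulate_group(group: str, rat_ids, config: RunConfig, seed) -> list:
    """Simulate every session of one group's curriculum."""
    phases = ([NON_MATCH, CUE_ID] if group == RULE_SWITCHING else [CUE_ID])
    rng = np.random.default_rng(seed)
    sessions = []
    for phase in phases:
        for s in range(config.sessions_per_phase):
            policy = behavior_policy(s, phase, group, config.sessions_per_phase)
            for rat in rat_ids:
                cfg = TaskConfig(
                    active_rule=phase, n_trials=config.n_trials,
                    repeat_prob=config.repeat_prob,
                    seed=int(rng.integers(2**31)),
                )
                trials = taskgen.generate_trial_sequence(cfg)
                trials = taskgen.simulate_agent(
                    trials, policy, seed=int(rng.integers(2**31))
                )
                sessions.append(
                    BehaviorSession(
                        rat_id=rat, session_id=f"{phase}_s{s}", phase=phase,
                        group=group, trials=trials,
                    )
                )
    return sessions


# ------------------------------------------------------------ fixtures ---

FIXTURE_SPECS = {
    "nm_only": PopulationSpec(n_units=40, frac_nm_selective=0.5,
                              frac_untuned=0.5, effect_nm=8.0, n_rats=4),
    "ci_only": PopulationSpec(n_units=40, frac_ci_selective=0.5,
                              frac_untuned=0.5, effect_ci=8.0, n_rats=4),
    "dual": PopulationSpec(n_units=40, frac_nm_selective=0.3,
                           frac_ci_selective=0.3, frac_untuned=0.4,
                           effect_nm=8.0, effect_ci=8.0, n_rats=4),
    "memorization": PopulationSpec(n_units=40, frac_untuned=1.0,
                                   odor_gain_sd=6.0, n_rats=4),
    "null": PopulationSpec(n_units=40, frac_untuned=1.0, n_rats=4),
}


def generate_fixtures(seed: int = 0, n_per_type: int = 8) -> dict:
    """Small canonical datasets with ground-truth metadata.

    Returns ``name -> dict(rates, type_index, units, by_rat, truth)`` for
    the five coding regimes: non-match only, cue-identity only, dual,
    memorization (per-type idiosyncratic tuning, no abstract axis), and
    null (no tuning at all).
    """
    rng = np.random.default_rng(seed)
    trials = balanced_type_trials(n_per_type)
    out = {}
    for name, spec in FIXTURE_SPECS.items():
        rm = synth_rate_matrix(spec, trials, seed=int(rng.integers(2**31)))
        out[name] = dict(
            rates=rm.rates,
            type_index=rm.trials.type_index.to_numpy(),
            units=rm.units,
            by_rat=split_by_rat(rm),
            truth=dict(
                nm_coding=spec.frac_nm_selective + spec.frac_both > 0,
                ci_coding=spec.frac_ci_selective + spec.frac_both > 0,
                memorization=spec.odor_gain_sd > 0,
            ),
        )
    return out


# ------------------------------------------------------------ pipeline ---

def _behavior_stage(sessions, config):
    rows = []
    for s in sessions:
        rows.append(
            dict(
                rat_id=s.rat_id, session_id=s.session_id, phase=s.phase,
                group=s.group,
                acc_nm=taskgen.accuracy_by_rule(s, NON_MATCH),
                acc_ci=taskgen.accuracy_by_rule(s, CUE_ID),
                trials_to_criterion=taskgen.trials_to_criterion(
                    s, config.criterion_threshold, config.criterion_window
                ),
                n_trials=len(s.trials),
            )
        )
    return pd.DataFrame(rows)


def _session_key(s):
    return (s.group, s.session_id)


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Execute the full synthetic analysis and return (and optionally write)
    all stage outputs.

    Stages: behavior simulation for the rule-switching and control groups;
    per-session synthetic populations following the selectivity schedules;
    single-unit selectivity proportions; LOSO rule separations with
    permutation nulls; CCGP, axis cosine, confusion/template and
    diagonal-ratio decoding; per-rat rule decoders and decoder-behavior
    linkage with the ignore-go statistic.
    """
    rng = np.random.default_rng(config.seed)
    summary = {"config": asdict(config)}

    switch_rats = [f"rat{i}" for i in range(config.n_rats)]
    control_rats = [f"crat{i}" for i in range(config.n_control_rats)]
    sessions = simulate_group(RULE_SWITCHING, switch_rats, config,
                              int(rng.integers(2**31)))
    sessions += simulate_group(CONTROL, control_rats, config,
                               int(rng.integers(2**31)))
    behavior = _behavior_stage(sessions, config)

    # one synthetic population per (group, session); units partitioned over rats
    session_keys = sorted({_session_key(s) for s in sessions})
    pops = {}
    for group, sid in session_keys:
        phase, s_idx = sid.rsplit("_s", 1)
        spec = schedule_selectivity(int(s_idx), phase, group)
        n_rats = config.n_rats if group == RULE_SWITCHING else config.n_control_rats
        spec = PopulationSpec(**{**asdict(spec), "n_units": config.n_units,
                                 "n_rats": n_rats})
        trials = balanced_type_trials(config.n_trials_per_type)
        pops[(group, sid)] = synth_rate_matrix(
            spec, trials, seed=int(rng.integers(2**31))
        )

    # single-unit selectivity proportions per session
    unit_rows = []
    for (group, sid), rm in pops.items():
        results = {}
        for rule, col in ((NON_MATCH, "rewarded_nm"), (CUE_ID, "rewarded_ci")):
            labels = rm.trials[col].to_numpy()
            results[rule] = [
                unit_metrics.selectivity_test_rates(
                    rm.rates[:, u], labels, n_perm=config.n_perm,
                    alpha=config.alpha, seed=int(rng.integers(2**31)),
                    unit_id=u, rule=rule,
                )
                for u in range(rm.rates.shape[1])
            ]
        prop = unit_metrics.selective_proportion(results)
        unit_rows.append(dict(group=group, session_id=sid, **{
            k: v for k, v in prop.items()
        }))
    units_df = pd.DataFrame(unit_rows)

    # geometry: LOSO separation per session and rule
    geom_rows, nulls_by_rule = [], {NON_MATCH: {}, CUE_ID: {}}
    for (group, sid), rm in pops.items():
        by_rat = split_by_rat(rm)
        for rule in (NON_MATCH, CUE_ID):
            obs, null = geometry.loso_rule_separation(
                by_rat, rule, n_perm=config.n_perm,
                backend=config.embedding_backend,
                seed=int(rng.integers(2**31)),
            )
            nulls_by_rule[rule][(group, sid)] = null
            geom_rows.append(dict(group=group, session_id=sid, rule=rule,
                                  separation=obs, p=null.p_two_tailed))
    geom_df = pd.DataFrame(geom_rows)
    for rule in (NON_MATCH, CUE_ID):
        sub = geom_df[geom_df.rule == rule]
        geom_df.loc[sub.index, "p_holm"] = geometry.holm_bonferroni(sub.p)

    # decoding per session
    dec_rows, confusions = [], {}
    for (group, sid), rm in pops.items():
        types = rm.trials.type_index.to_numpy()
        row = dict(group=group, session_id=sid)
        for rule in (NON_MATCH, CUE_ID):
            res = decoding.ccgp(rm.rates, types, rule,
                                n_partitions=config.n_partitions,
                                seed=int(rng.integers(2**31)))
            row[f"ccgp_{rule}"] = res.accuracy
            row[f"ccgp_{rule}_p"] = res.p
        cosines, cos_sum = decoding.bootstrap_axis_cosine(
            rm.rates, types, n_boot=config.n_boot,
            seed=int(rng.integers(2**31)),
        )
        row["cosine_mean"] = cos_sum["mean"]
        row["cosine_ci_low"], row["cosine_ci_high"] = (
            cos_sum["ci_low"], cos_sum["ci_high"],
        )
        cm, kept = decoding.fit_confusion_matrix(
            rm.rates, types, seed=int(rng.integers(2**31))
        )
        confusions[(group, sid)] = cm
        if len(kept) == taskgen.N_TYPES:
            for kind in (decoding.NM_TEMPLATE, decoding.CI_TEMPLATE,
                         decoding.BOTH_TEMPLATE):
                ts = decoding.template_permutation_test(
                    cm, decoding.make_template(kind), n_perm=config.n_perm,
                    seed=int(rng.integers(2**31)), kind=kind,
                )
                row[f"template_{kind}"] = ts.score
                row[f"template_{kind}_p"] = ts.p
            row["diagonal_ratio"] = decoding.diagonal_ratio(cm)
        dec_rows.append(row)
    dec_df = pd.DataFrame(dec_rows)

    # per-rat rule decoders + linkage to behavior
    link_rows = []
    for (group, sid), rm in pops.items():
        by_rat = split_by_rat(rm)
        types = rm.trials.type_index.to_numpy()
        for rat, (rates, _) in by_rat.items():
            row = dict(group=group, session_id=sid, rat_pop=rat)
            for rule in (NON_MATCH, CUE_ID):
                acc, p, _n = decoding.rule_decoder(
                    rates, types, rule, n_perm=0 if config.n_perm < 1 else 19,
                    seed=int(rng.integers(2**31)),
                )
                row[f"decoder_{rule}"] = acc
            link_rows.append(row)
    link_df = pd.DataFrame(link_rows)
    # attach behavioral accuracy: population "rats" map onto behavioral rats
    beh_key = behavior.set_index(["group", "session_id", "rat_id"])
    acc_nm, acc_ci = [], []
    for r in link_df.itertuples():
        rat_index = int(str(r.rat_pop).lstrip("rat"))
        rats = switch_rats if r.group == RULE_SWITCHING else control_rats
        beh_rat = rats[rat_index % len(rats)]
        rec = beh_key.loc[(r.group, r.session_id, beh_rat)]
        acc_nm.append(float(rec.acc_nm))
        acc_ci.append(float(rec.acc_ci))
    link_df["acc_nm"], link_df["acc_ci"] = acc_nm, acc_ci

    link_summary = {}
    cue_mask = link_df.session_id.str.startswith(CUE_ID)
    exp_cue = link_df[(link_df.group == RULE_SWITCHING) & cue_mask]
    if len(exp_cue) >= 3:
        reg = linkage.decoder_behavior_regression(
            exp_cue[f"decoder_{CUE_ID}"], exp_cue["acc_ci"]
        )
        link_summary["ci_decoder_vs_ci_behavior"] = dict(
            slope=reg.slope, r_squared=reg.r_squared, p=reg.p, n=reg.n
        )
        slopes = linkage.per_session_slopes(
            exp_cue, x=f"decoder_{NON_MATCH}", y="acc_nm"
        )
        link_summary["per_session_slopes_nm"] = slopes.to_dict("records")

    summary["behavior"] = dict(
        mean_acc_active_final=float(
            behavior.groupby("session_id").acc_nm.mean().iloc[-1]
        )
    )
    result = dict(
        summary=summary, behavior=behavior, units=units_df, geometry=geom_df,
        decoding=dec_df, linkage=link_df, link_summary=link_summary,
        confusions=confusions, sessions=sessions,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: dict, out_dir) -> None:
    """Write all stage tables as CSV plus summary.json under ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    taskgen.sessions_to_frame(result["sessions"]).to_csv(
        out / "trials.csv", index=False
    )
    for name in ("behavior", "units", "geometry", "decoding", "linkage"):
        result[name].to_csv(out / f"{name}.csv", index=False)
    (out / "confusion").mkdir(exist_ok=True)
    for (group, sid), cm in result["confusions"].items():
        np.savetxt(out / "confusion" / f"{group}_{sid}.csv", cm, delimiter=",")
    payload = dict(result["summary"], link_summary=result["link_summary"])
    with open(out / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=float)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
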