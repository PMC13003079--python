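"""Single-unit analyses: PSTHs, baseline-normalized z-scores, rule selectivity.

Conventions follow the recording analyses they mirror: spike counts binned
at 50 ms, PSTHs smoothed with a 5-bin uniform moving average, the response
window is the 500 ms preceding odor-port withdrawal ("un-poke"), and the
baseline is the 1 s preceding trial initiation.  Rule selectivity is tested
with a permutation procedure: the observed statistic combines (a) the
maximum absolute deviation between the two conditions' cumulative
normalized spike-time profiles within the sampling window and (b) the
absolute firing-rate difference, each standardized against its own
permutation null, and the empirical p-value uses the add-one convention
(1 + k) / (1 + n_perm), so p = 0 is never reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

BIN_WIDTH = 0.05          # s
SMOOTH_BINS = 5
RESPONSE_WINDOW = 0.5     # s before un-poke
BASELINE_WINDOW = 1.0     # s before trial initiation
MIN_TRIALS_PER_CONDITION = 5


class UndefinedZError(ValueError):
    """Raised when the baseline SD is zero and z-scores are undefined."""


@dataclass
class PSTH:
    bin_edges: np.ndarray            # relative to alignment event (s)
    rates: dict                      # condition -> smoothed mean rate per bin (Hz)
    raw_rates: dict                  # condition -> unsmoothed mean rate per bin
    align_event: str = "t_unpoke"


@dataclass
class UnitWindowStats:
    z_rewarded: float
    z_nonrewarded: float

    @property
    def delta_z(self) -> float:
        return self.z_rewarded - self.z_nonrewarded


@dataclass
class SelectivityResult:
    unit_id: int
    rule: str
    statistic: float
    p: float
    selective: bool
    testable: bool = True


def _counts_in_windows(spike_times, starts, stops):
    """Spike count per trial window via searchsorted on sorted spike times."""
    spike_times = np.asarray(spike_times)
    return (
        np.searchsorted(spike_times, stops) - np.searchsorted(spike_times, starts)
    ).astype(float)


def compute_psth(
    spike_times,
    event_times,
    condition_labels=None,
    window=(-2.0, 1.0),
    bin_width: float = BIN_WIDTH,
    smooth_bins: int = SMOOTH_BINS,
    align_event: str = "t_unpoke",
    conditions=None,
) -> PSTH:
    """Per-condition PSTH aligned to an event, 50 ms bins, 5-bin smoothing.

    ``condition_labels`` assigns each trial to a condition; None pools all
    trials under the condition ``"all"``.  ``conditions`` optionally names
    the conditions to compute; a requested condition with no trials is
    omitted with a warning.  Smoothing uses edge-replicated padding so the
    trace's total mass is conserved up to edge effects.
    """
    event_times = np.asarray(event_times, dtype=float)
    if condition_labels is None:
        condition_labels = np.array(["all"] * len(event_times))
    else:
        condition_labels = np.asarray(condition_labels)
    edges = np.arange(window[0], window[1] + bin_width / 2, bin_width)
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    rates, raw = {}, {}
    if conditions is None:
        conditions = pd.unique(condition_labels)
    for cond in conditions:
        ev = event_times[condition_labels == cond]
        if len(ev) == 0:
            import warnings

            warnings.warn(f"condition {cond!r} has no trials; omitted")
            continue
        counts = np.zeros(len(edges) - 1)
        for e in ev:
            rel = spike_times[
                np.searchsorted(spike_times, e + window[0]):
                np.searchsorted(spike_times, e + window[1])
            ] - e
            counts += np.histogram(rel, bins=edges)[0]
        mean_rate = counts / len(ev) / bin_width
        raw[cond] = mean_rate
        rates[cond] = uniform_filter1d(mean_rate, size=smooth_bins, mode="nearest")
    return PSTH(bin_edges=edges, rates=rates, raw_rates=raw, align_event=align_event)


def window_rates(spike_times, trials: pd.DataFrame):
    """Per-trial response-window and baseline rates (Hz) for one unit."""
    t_unpoke = trials.t_unpoke.to_numpy(dtype=float)
    t_start = trials.t_start.to_numpy(dtype=float)
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    resp = _counts_in_windows(spike_times, t_unpoke - RESPONSE_WINDOW, t_unpoke)
    base = _counts_in_windows(spike_times, t_start - BASELINE_WINDOW, t_start)
    return resp / RESPONSE_WINDOW, base / BASELINE_WINDOW


def zscore_window(resp_rates, base_rates, condition_mask=None) -> float:
    """z = (mean response rate over condition trials - mean baseline rate over
    all trials) / SD of per-trial baseline rates."""
    resp_rates = np.asarray(resp_rates, dtype=float)
    base_rates = np.asarray(base_rates, dtype=float)
    if len(base_rates) < 2:
        raise UndefinedZError("need >=2 trials for a baseline SD")
    sd = base_rates.std(ddof=1)
    if sd == 0:
        raise UndefinedZError("zero baseline SD")
    if condition_mask is None:
        condition_mask = np.ones(len(resp_rates), dtype=bool)
    return float((resp_rates[condition_mask].mean() - base_rates.mean()) / sd)


def delta_zscore(resp_rates, base_rates, rewarded_mask) -> UnitWindowStats:
    """z(rewarded) - z(non-rewarded) for one unit under one rule's split."""
    rewarded_mask = np.asarray(rewarded_mask, dtype=bool)
    z_r = zscore_window(resp_rates, base_rates, rewarded_mask)
    z_nr = zscore_window(resp_rates, base_rates, ~rewarded_mask)
    return UnitWindowStats(z_rewarded=z_r, z_nonrewarded=z_nr)


def sampling_window_counts(spike_times, trials, n_bins=10):
    """trials x n_bins spike-count matrix over the odor sampling window
    (odor onset to un-poke), the input to :func:`selectivity_test`."""
    t_on = trials.t_odor_on.to_numpy(dtype=float)
    t_off = trials.t_unpoke.to_numpy(dtype=float)
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    out = np.zeros((len(trials), n_bins))
    for i, (a, b) in enumerate(zip(t_on, t_off)):
        rel = spike_times[
            np.searchsorted(spike_times, a):np.searchsorted(spike_times, b)
        ]
        out[i] = np.histogram(rel, bins=np.linspace(a, b, n_bins + 1))[0]
    return out


def _deviation_and_rate_stats(counts, labels_matrix):
    """Vectorized statistic components for many label assignments at once.

    ``counts`` is (n_trials, n_bins); ``labels_matrix`` is (n_assign,
    n_trials) boolean (True = condition A).  Returns (dev, rate_diff), each
    of length n_assign: dev is the max absolute difference between the two
    conditions' cumulative normalized spike-time profiles; rate_diff is the
    absolute per-trial mean-count difference.
    """
    L = labels_matrix.astype(float)
    nA = L.sum(axis=1)
    nB = L.shape[1] - nA
    sumA = L @ counts                       # (n_assign, n_bins)
    sumB = counts.sum(axis=0)[None, :] - sumA
    totA = sumA.sum(axis=1, keepdims=True)
    totB = sumB.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cumA = np.cumsum(sumA, axis=1) / np.where(totA > 0, totA, 1.0)
        cumB = np.cumsum(sumB, axis=1) / np.where(totB > 0, totB, 1.0)
    dev = np.abs(cumA - cumB).max(axis=1)
    rate_diff = np.abs(sumA.sum(axis=1) / nA - sumB.sum(axis=1) / nB)
    return dev, rate_diff


def selectivity_test(
    spike_counts,
    condition_labels,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
    unit_id: int = -1,
    rule: str = "",
) -> SelectivityResult:
    """Permutation test for condition-dependent firing in the sampling window.

    ``spike_counts`` is a trials x bins count matrix over the poke-to-un-poke
    window (see :func:`sampling_window_counts`); ``condition_labels`` is boolean.
    The statistic is the larger of the two standardized components
    (cumulative-profile deviation, absolute rate difference), standardized
    by the permutation null's mean and SD.
    """
    counts = np.asarray(spike_counts, dtype=float)
    labels = np.asarray(condition_labels, dtype=bool)
    nA = int(labels.sum())
    nB = len(labels) - nA
    if nA < MIN_TRIALS_PER_CONDITION or nB < MIN_TRIALS_PER_CONDITION:
        return SelectivityResult(unit_id, rule, np.nan, np.nan, False, testable=False)
    rng = np.random.default_rng(seed)
    perm = np.empty((n_perm, len(labels)), dtype=bool)
    for i in range(n_perm):
        perm[i] = rng.permutation(labels)
    all_labels = np.vstack([labels[None, :], perm])
    dev, rdiff = _deviation_and_rate_stats(counts, all_labels)

    def _standardize(x):
        mu, sd = x[1:].mean(), x[1:].std(ddof=1)
        return (x - mu) / (sd if sd > 0 else 1.0)

    z = np.maximum(_standardize(dev), _standardize(rdiff))
    obs, null = z[0], z[1:]
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)
    return SelectivityResult(
        unit_id=unit_id, rule=rule, statistic=float(obs), p=float(p),
        selective=bool(p <= alpha), testable=True,
    )


def selectivity_test_rates(
    rates, condition_labels, n_perm=1000, alpha=0.05, seed=None,
    unit_id=-1, rule="",
) -> SelectivityResult:
    """Selectivity test from a single per-trial rate (one 'bin') per trial.

    Convenience entry point for rate-matrix data without spike times; the
    deviation component degenerates and the test reduces to a permutation
    test on the rate difference.
    """
    rates = np.asarray(rates, dtype=float)
    return selectivity_test(
        rates[:, None], condition_labels, n_perm=n_perm, alpha=alpha,
        seed=seed, unit_id=unit_id, rule=rule,
    )


def selective_proportion(results_by_rule: dict) -> dict:
    """Population proportions from per-rule SelectivityResult lists.

    ``results_by_rule`` maps rule name -> list of SelectivityResult over a
    common unit set (aligned by position).  Returns fractions over testable
    units: per-rule-only, both, and any, plus counts.
    """
    rules = list(results_by_rule)
    if not rules or not results_by_rule[rules[0]]:
        raise ValueError("empty result set")
    n = len(results_by_rule[rules[0]])
    testable = np.ones(n, dtype=bool)
    flags = {}
    for r in rules:
        res = results_by_rule[r]
        if len(res) != n:
            raise ValueError("rules must cover the same unit set")
        testable &= np.array([x.testable for x in res])
        flags[r] = np.array([x.selective for x in res])
    n_testable = int(testable.sum())
    if n_testable == 0:
        raise ValueError("no testable units")
    out = {"n_testable": n_testable}
    if len(rules) == 2:
        a, b = rules
        both = flags[a] & flags[b] & testable
        out["both"] = both.sum() / n_testable
        out[f"{a}_only"] = (flags[a] & ~flags[b] & testable).sum() / n_testable
        out[f"{b}_only"] = (flags[b] & ~flags[a] & testable).sum() / n_testable
    for r in rules:
        out[r] = (flags[r] & testable).sum() / n_testable
    return out
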