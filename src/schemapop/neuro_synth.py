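"""Synthetic spiking populations with configurable rule coding.

Every downstream analysis (selectivity tests, population geometry, decoding)
is exercised against populations generated here, where the ground truth —
which units carry non-match coding, cue-identity coding, both, or none — is
known by construction.

A unit's firing rate in the odor-sampling window is

    rate = baseline + (delta_nm / 2) * s_nm + (delta_ci / 2) * s_ci + gain[type]

with rule codes s in {+1, -1}, so ``delta_nm`` is the non-match-minus-match
rate difference in Hz (and likewise ``delta_ci`` for the cue-identity
contrast).  Outside the odor window the unit fires at its baseline rate, so
baseline epochs carry no rule signal.  Spike counts are Poisson in each
epoch; spike times are placed uniformly within their epoch (a
piecewise-constant inhomogeneous Poisson process).

Per-type ``gain`` terms are zero by default; a "memorization" population
draws idiosyncratic gains for each of the 16 trial types, producing
decodable structure inside each condition without any abstract rule axis —
the dissociation that cross-condition generalization is designed to detect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .taskgen import N_TYPES, NON_MATCH, CUE_ID, BehaviorSession

RESPONSE_WINDOW = 0.5   # s, odor-on -> un-poke
BASELINE_WINDOW = 1.0   # s, preceding trial initiation


@dataclass(frozen=True)
class PopulationSpec:
    """Composition and effect sizes of a synthetic population.

    Fractions must sum to 1.  ``effect_nm`` / ``effect_ci`` are rate
    differences (Hz) between the preferred and non-preferred condition of
    the respective rule.  ``odor_gain_sd`` > 0 adds per-trial-type
    idiosyncratic tuning (the memorization regime).
    """

    n_units: int = 100
    frac_nm_selective: float = 0.0
    frac_ci_selective: float = 0.0
    frac_both: float = 0.0
    frac_untuned: float = 1.0
    effect_nm: float = 5.0
    effect_ci: float = 5.0
    baseline_rate_range: tuple = (5.0, 15.0)
    odor_gain_sd: float = 0.0
    n_rats: int = 5

    def __post_init__(self):
        fr = (self.frac_nm_selective, self.frac_ci_selective,
              self.frac_both, self.frac_untuned)
        if any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("population fractions must be nonnegative and sum to 1")
        lo, hi = self.baseline_rate_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid baseline_rate_range")
        if not (np.isfinite(self.effect_nm) and np.isfinite(self.effect_ci)):
            raise ValueError("effect sizes must be finite")
        if self.n_units < 1 or self.n_rats < 1:
            raise ValueError("n_units and n_rats must be positive")


@dataclass
class UnitTuning:
    unit_id: int
    rat_id: str
    baseline_rate: float
    delta_nm: float = 0.0
    delta_ci: float = 0.0
    odor_gains: np.ndarray | None = None  # length N_TYPES, Hz


@dataclass
class SpikeData:
    """Spike timestamps per unit, on the session's common clock."""

    spikes: dict            # unit_id -> 1-D nondecreasing array of times (s)
    units: pd.DataFrame     # unit_id, rat_id, baseline_rate, delta_nm, delta_ci

    def to_frame(self) -> pd.DataFrame:
        rows = []
        rat = dict(zip(self.units.unit_id, self.units.rat_id))
        for uid, times in self.spikes.items():
            for t in times:
                rows.append((uid, rat[uid], t))
        return pd.DataFrame(rows, columns=["unit_id", "rat_id", "timestamp_s"])


@dataclass
class RateMatrix:
    """trials x units firing-rate matrix over the response window."""

    rates: np.ndarray       # (n_trials, n_units), Hz
    trials: pd.DataFrame    # trial_index, odor, is_match, type_index, rewarded_nm, rewarded_ci, response
    units: pd.DataFrame     # unit_id, rat_id


def build_tuning(spec: PopulationSpec, rng: np.random.Generator) -> list:
    """Assign tuning classes to units (shuffled), partition rats round-robin."""
    n = spec.n_units
    n_nm = int(round(spec.frac_nm_selective * n))
    n_ci = int(round(spec.frac_ci_selective * n))
    n_both = int(round(spec.frac_both * n))
    classes = (["nm"] * n_nm + ["ci"] * n_ci + ["both"] * n_both)
    classes += ["none"] * (n - len(classes))
    order = rng.permutation(n)
    lo, hi = spec.baseline_rate_range
    tunings = []
    for u in range(n):
        cls = classes[order[u]]
        base = float(rng.uniform(lo, hi))
        d_nm = spec.effect_nm if cls in ("nm", "both") else 0.0
        d_ci = spec.effect_ci if cls in ("ci", "both") else 0.0
        gains = None
        if spec.odor_gain_sd > 0:
            gains = rng.normal(0.0, spec.odor_gain_sd, size=N_TYPES)
        tunings.append(
            UnitTuning(
                unit_id=u, rat_id=f"rat{u % spec.n_rats}",
                baseline_rate=base, delta_nm=d_nm, delta_ci=d_ci,
                odor_gains=gains,
            )
        )
    return tunings


def _window_rates(tunings, trials_df) -> np.ndarray:
    """Programmed odor-window rate per (trial, unit), clipped at 0."""
    s_nm = np.where(trials_df.rewarded_nm.to_numpy(), 1.0, -1.0)
    s_ci = np.where(trials_df.rewarded_ci.to_numpy(), 1.0, -1.0)
    types = trials_df.type_index.to_numpy()
    out = np.empty((len(trials_df), len(tunings)))
    for j, tu in enumerate(tunings):
        r = tu.baseline_rate + 0.5 * tu.delta_nm * s_nm + 0.5 * tu.delta_ci * s_ci
        if tu.odor_gains is not None:
            r = r + tu.odor_gains[types]
        out[:, j] = r
    if (out < 0).any():
        warnings.warn("negative implied firing rate clipped at 0")
        out = np.clip(out, 0.0, None)
    return out


def trials_table(session: BehaviorSession) -> pd.DataFrame:
    rows = [
        dict(
            trial_index=t.index, odor=t.odor, is_match=t.is_match,
            type_index=t.type_index, rewarded_nm=t.rewarded_nm,
            rewarded_ci=t.rewarded_ci,
            response="" if t.response is None else t.response,
            t_start=t.t_start, t_odor_on=t.t_odor_on, t_unpoke=t.t_unpoke,
        )
        for t in session.trials
    ]
    return pd.DataFrame(rows)


def synth_population(
    spec: PopulationSpec,
    session: BehaviorSession,
    seed=None,
    with_spikes: bool = False,
):
    """Simulate one session's population activity.

    Returns ``(rate_matrix, spike_data)``; ``spike_data`` is None unless
    ``with_spikes``.  When spikes are generated, the rate matrix is computed
    from the same spike counts, so the two views are consistent.
    """
    rng = np.random.default_rng(seed)
    tunings = build_tuning(spec, rng)
    tdf = trials_table(session)
    rates_hz = _window_rates(tunings, tdf)
    units_df = pd.DataFrame(
        dict(
            unit_id=[t.unit_id for t in tunings],
            rat_id=[t.rat_id for t in tunings],
            baseline_rate=[t.baseline_rate for t in tunings],
            delta_nm=[t.delta_nm for t in tunings],
            delta_ci=[t.delta_ci for t in tunings],
        )
    )

    counts = rng.poisson(rates_hz * RESPONSE_WINDOW)
    spike_data = None
    if with_spikes:
        spikes = {t.unit_id: [] for t in tunings}
        t_start = tdf.t_start.to_numpy()
        t_odor = tdf.t_odor_on.to_numpy()
        t_unpoke = tdf.t_unpoke.to_numpy()
        for j, tu in enumerate(tunings):
            # baseline epoch: 1 s before trial start up to odor onset, plus a
            # 1 s tail after un-poke, all at the baseline rate
            for i in range(len(tdf)):
                seg = [
                    (t_start[i] - BASELINE_WINDOW, t_odor[i], tu.baseline_rate),
                    (t_unpoke[i], t_unpoke[i] + 1.0, tu.baseline_rate),
                ]
                ts = [
                    rng.uniform(a, b, size=rng.poisson(r * (b - a)))
                    for a, b, r in seg
                ]
                # odor window spikes reuse the Poisson count drawn above
                ts.append(rng.uniform(t_odor[i], t_unpoke[i], size=counts[i, j]))
                spikes[tu.unit_id].append(np.concatenate(ts))
            spikes[tu.unit_id] = np.sort(np.concatenate(spikes[tu.unit_id]))
        spike_data = SpikeData(spikes=spikes, units=units_df)

    rm = RateMatrix(rates=counts / RESPONSE_WINDOW, trials=tdf, units=units_df)
    return rm, spike_data


def balanced_type_trials(n_per_type: int) -> pd.DataFrame:
    """A balanced trials table with ``n_per_type`` trials of each of the 16
    canonical trial types (no temporal structure; used for decoding fixtures)."""
    types = np.repeat(np.arange(N_TYPES), n_per_type)
    odor = types % 8 + 1
    is_match = types >= 8
    return pd.DataFrame(
        dict(
            trial_index=np.arange(len(types)), odor=odor, is_match=is_match,
            type_index=types, rewarded_nm=~is_match, rewarded_ci=odor <= 4,
        )
    )


def synth_rate_matrix(
    spec: PopulationSpec, trials: pd.DataFrame, seed=None
) -> RateMatrix:
    """Poisson rate matrix for an arbitrary labeled trials table (no spikes)."""
    rng = np.random.default_rng(seed)
    tunings = build_tuning(spec, rng)
    rates_hz = _window_rates(tunings, trials)
    counts = rng.poisson(rates_hz * RESPONSE_WINDOW)
    units_df = pd.DataFrame(
        dict(
            unit_id=[t.unit_id for t in tunings],
            rat_id=[t.rat_id for t in tunings],
            baseline_rate=[t.baseline_rate for t in tunings],
            delta_nm=[t.delta_nm for t in tunings],
            delta_ci=[t.delta_ci for t in tunings],
        )
    )
    return RateMatrix(rates=counts / RESPONSE_WINDOW, trials=trials.copy(),
                      units=units_df)


def split_by_rat(rm: RateMatrix) -> dict:
    """Per-rat (rates, type_index) views of a rate matrix, for pseudo-population
    assembly and LOSO."""
    out = {}
    types = rm.trials.type_index.to_numpy()
    for rat in pd.unique(rm.units.rat_id):
        cols = np.flatnonzero((rm.units.rat_id == rat).to_numpy())
        out[str(rat)] = (rm.rates[:, cols], types)
    return out


# ------------------------------------------------------- schedules -------

RULE_SWITCHING = "rule_switching"
CONTROL = "control"

#: sessions per phase used by the default schedules
SESSIONS_PER_PHASE = 5


def schedule_selectivity(session_index: int, phase: str, group: str) -> PopulationSpec:
    """Default per-session population spec emulating learning dynamics.

    * ``rule_switching`` / non-match phase: the fraction of non-match-coding
      units ramps from 5% to 25% across sessions; no cue-identity coding.
    * ``rule_switching`` / cue-identity phase: cue-identity coding ramps from
      5% to 25% while a residual 10% of units keep non-match coding at a
      reduced (3 Hz) effect.
    * ``control`` (cue-identity only): cue-identity coding ramps identically;
      non-match coding is absent in every session.
    """
    if group not in (RULE_SWITCHING, CONTROL):
        raise KeyError(f"unknown group {group!r}")
    if phase not in (NON_MATCH, CUE_ID):
        raise KeyError(f"unknown phase {phase!r}")
    if group == CONTROL and phase == NON_MATCH:
        raise KeyError("control group is never trained on the non-match rule")
    s = min(session_index, SESSIONS_PER_PHASE - 1)
    ramp = 0.05 + (0.25 - 0.05) * s / (SESSIONS_PER_PHASE - 1)
    if phase == NON_MATCH:
        return PopulationSpec(
            frac_nm_selective=ramp, frac_ci_selective=0.0, frac_both=0.0,
            frac_untuned=1.0 - ramp, effect_nm=5.0,
        )
    if group == CONTROL:
        return PopulationSpec(
            frac_nm_selective=0.0, frac_ci_selective=ramp, frac_both=0.0,
            frac_untuned=1.0 - ramp, effect_ci=5.0,
        )
    resid = 0.10
    return PopulationSpec(
        frac_nm_selective=resid, frac_ci_selective=ramp, frac_both=0.0,
        frac_untuned=1.0 - ramp - resid, effect_nm=3.0, effect_ci=5.0,
    )
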