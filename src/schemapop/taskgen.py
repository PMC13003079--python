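"""Go/no-go odor discrimination task: trial generation, behavioral agents, metrics.

The task presents one of ``n_odors`` odors per trial and the animal (or a
simulated agent) decides whether to respond ("go") at a fluid well.  Two
orthogonal rules govern which trials carry a potential reward:

* **non-match rule** — reward is available when the current odor differs
  from the previous trial's odor;
* **cue-identity rule** — reward is available when the odor belongs to a
  fixed rewarded set, regardless of trial history.

Odor sequences are built as a repeat-or-redraw Markov chain: with
probability ``repeat_prob`` the previous odor repeats (a "match" trial),
otherwise a new odor is drawn uniformly from the remaining odors.  With the
default ``repeat_prob = 0.49`` the long-run fraction of potentially rewarded
trials is ~0.51 under the non-match rule and ~0.5 under cue identity,
mimicking a task engineered for a near 50/50 reward balance under both rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

NON_MATCH = "non_match"
CUE_ID = "cue_id"
RULES = (NON_MATCH, CUE_ID)

GO = "go"
NOGO = "nogo"

#: number of distinct trial types: n_odors x {non-match, match}
N_TYPES = 16

# fixed event cadence (seconds) used to lay out per-trial timestamps;
# the response window [t_odor_on, t_unpoke] is 500 ms and the baseline
# window is the 1 s preceding t_start.
TRIAL_PERIOD = 6.0
_T_START_OFFSET = 1.5   # leaves room for the 1 s baseline epoch
_POKE_DELAY = 0.5
_ODOR_DELAY = 0.5       # 500 ms pre-odor delay after the nosepoke
_SAMPLING = 0.5         # odor sampling: odor-on -> un-poke
_WELL_DELAY = 0.5


class DegenerateSequenceError(ValueError):
    """Raised when a trial sequence is too short to define match/non-match."""


class UndefinedResultError(ValueError):
    """Raised when a behavioral metric is requested on an empty session."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of one session of the odor discrimination task."""

    n_odors: int = 8
    rewarded_odors: frozenset = frozenset({1, 2, 3, 4})
    active_rule: str = NON_MATCH
    n_trials: int = 300
    repeat_prob: float = 0.49
    seed: int | None = None

    def __post_init__(self):
        if self.n_odors < 2:
            raise ValueError("n_odors must be >= 2")
        if not (0.0 < self.repeat_prob < 1.0) and self.repeat_prob != 1.0:
            # repeat_prob == 1.0 is allowed only as an explicit degenerate
            # case used in tests; anything outside (0, 1] is invalid.
            raise ValueError("repeat_prob must lie in (0, 1]")
        odors = set(range(1, self.n_odors + 1))
        rw = set(self.rewarded_odors)
        if not rw or not rw < odors:
            raise ValueError("rewarded_odors must be a nonempty strict subset of odors")
        if self.active_rule not in RULES:
            raise ValueError(f"active_rule must be one of {RULES}")


@dataclass
class Trial:
    """One trial: odor, reward availability under each rule, and the response.

    ``type_index`` maps (odor, configuration) to the canonical 0–15 ordering:
    non-match trials of odors 1–8 occupy indices 0–7, match trials 8–15.
    """

    index: int
    odor: int
    is_match: bool
    rewarded_nm: bool
    rewarded_ci: bool
    active_rule: str = NON_MATCH
    response: str | None = None
    reward_delivered: bool = False
    t_start: float = np.nan
    t_poke: float = np.nan
    t_odor_on: float = np.nan
    t_unpoke: float = np.nan
    t_well: float = np.nan

    @property
    def type_index(self) -> int:
        return (self.odor - 1) + 8 * int(self.is_match)

    @property
    def rewarded_active(self) -> bool:
        return self.rewarded_nm if self.active_rule == NON_MATCH else self.rewarded_ci


@dataclass(frozen=True)
class AgentPolicy:
    """Logistic go/no-go policy mixing the two rule prescriptions.

    P(go) = lapse/2 + (1 - lapse) * logistic(go_bias + w_nm*s_nm + w_ci*s_ci)
    where s_rule = +1 if that rule prescribes "go" on the trial, else -1.
    """

    w_nm: float = 0.0
    w_ci: float = 0.0
    go_bias: float = 0.0
    lapse: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.lapse <= 1.0):
            raise ValueError("lapse must lie in [0, 1]")


@dataclass
class BehaviorSession:
    """All trials of one rat in one session under one active rule."""

    rat_id: str
    session_id: str
    phase: str
    group: str
    trials: list = field(default_factory=list)

    @property
    def active_rule(self) -> str:
        if not self.trials:
            raise UndefinedResultError("empty session has no active rule")
        return self.trials[0].active_rule


def generate_trial_sequence(config: TaskConfig) -> list:
    """Generate a session's trial sequence with reward flags set, responses unset.

    The first trial has no predecessor and is non-match by convention.
    """
    if config.n_trials < 2:
        raise DegenerateSequenceError("a session needs at least 2 trials")
    rng = np.random.default_rng(config.seed)
    odors = np.arange(1, config.n_odors + 1)
    trials = []
    prev = None
    for i in range(config.n_trials):
        if prev is None:
            odor = int(rng.choice(odors))
            is_match = False
        elif rng.random() < config.repeat_prob:
            odor, is_match = prev, True
        else:
            others = odors[odors != prev]
            odor = int(rng.choice(others))
            is_match = False
        t0 = _T_START_OFFSET + i * TRIAL_PERIOD
        t_poke = t0 + _POKE_DELAY
        t_odor = t_poke + _ODOR_DELAY
        t_unpoke = t_odor + _SAMPLING
        trials.append(
            Trial(
                index=i,
                odor=odor,
                is_match=is_match,
                rewarded_nm=not is_match,
                rewarded_ci=odor in config.rewarded_odors,
                active_rule=config.active_rule,
                t_start=t0,
                t_poke=t_poke,
                t_odor_on=t_odor,
                t_unpoke=t_unpoke,
                t_well=t_unpoke + _WELL_DELAY,
            )
        )
        prev = odor
    return trials


def simulate_agent(trials: Sequence[Trial], policy: AgentPolicy, seed=None) -> list:
    """Fill responses on a trial sequence according to a logistic policy."""
    rng = np.random.default_rng(seed)
    out = []
    for tr in trials:
        s_nm = 1.0 if tr.rewarded_nm else -1.0
        s_ci = 1.0 if tr.rewarded_ci else -1.0
        p_go = policy.lapse / 2.0 + (1.0 - policy.lapse) * expit(
            policy.go_bias + policy.w_nm * s_nm + policy.w_ci * s_ci
        )
        response = GO if rng.random() < p_go else NOGO
        tr2 = replace(tr, response=response)
        tr2.reward_delivered = response == GO and tr2.rewarded_active
        out.append(tr2)
    return out


def _rewarded_under(trial: Trial, rule: str) -> bool:
    if rule == NON_MATCH:
        return trial.rewarded_nm
    if rule == CUE_ID:
        return trial.rewarded_ci
    raise ValueError(f"unknown rule {rule!r}")


def accuracy_by_rule(session: BehaviorSession, rule: str) -> float:
    """Fraction of trials whose response is correct under ``rule``.

    Computable for either rule regardless of which one is active: a trial is
    correct when the agent responded "go" iff the named rule makes it
    potentially rewarded.
    """
    if not session.trials:
        raise UndefinedResultError("accuracy undefined on an empty session")
    correct = [
        (t.response == GO) == _rewarded_under(t, rule) for t in session.trials
    ]
    return float(np.mean(correct))


def trials_to_criterion(
    session: BehaviorSession, threshold: float = 0.80, window: int = 30
) -> int | None:
    """First trial count t at which accuracy over the trailing ``window``
    trials reaches ``threshold`` under the active rule (ties count as
    crossing). Returns None if never reached or the session is shorter than
    the window."""
    trials = session.trials
    if len(trials) < window:
        return None
    rule = session.active_rule
    correct = np.array(
        [(t.response == GO) == _rewarded_under(t, rule) for t in trials], dtype=float
    )
    csum = np.concatenate([[0.0], np.cumsum(correct)])
    for t in range(window, len(trials) + 1):
        if (csum[t] - csum[t - window]) / window >= threshold:
            return t
    return None


def go_probability_by_type(session: BehaviorSession) -> np.ndarray:
    """P(go) per trial type (length-16 vector); NaN marks types with no trials."""
    if not session.trials:
        raise UndefinedResultError("empty session")
    go = np.zeros(N_TYPES)
    n = np.zeros(N_TYPES)
    for t in session.trials:
        n[t.type_index] += 1
        go[t.type_index] += t.response == GO
    with np.errstate(invalid="ignore"):
        p = go / n
    return p


# ---------------------------------------------------------------- I/O -----

TRIAL_COLUMNS = [
    "rat_id", "session_id", "phase", "group", "trial_index", "odor",
    "is_match", "rewarded_nm", "rewarded_ci", "active_rule", "response",
    "reward_delivered", "t_start", "t_poke", "t_odor_on", "t_unpoke", "t_well",
]


def sessions_to_frame(sessions: Iterable[BehaviorSession]) -> pd.DataFrame:
    """Flatten sessions into the canonical one-row-per-trial table."""
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                dict(
                    rat_id=s.rat_id, session_id=s.session_id, phase=s.phase,
                    group=s.group, trial_index=t.index, odor=t.odor,
                    is_match=t.is_match, rewarded_nm=t.rewarded_nm,
                    rewarded_ci=t.rewarded_ci, active_rule=t.active_rule,
                    response="" if t.response is None else t.response,
                    reward_delivered=t.reward_delivered, t_start=t.t_start,
                    t_poke=t.t_poke, t_odor_on=t.t_odor_on,
                    t_unpoke=t.t_unpoke, t_well=t.t_well,
                )
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_sessions(df: pd.DataFrame) -> list:
    """Inverse of :func:`sessions_to_frame`."""
    sessions = []
    for (rat, sid), grp in df.groupby(["rat_id", "session_id"], sort=False):
        grp = grp.sort_values("trial_index")
        trials = [
            Trial(
                index=int(r.trial_index), odor=int(r.odor),
                is_match=bool(r.is_match), rewarded_nm=bool(r.rewarded_nm),
                rewarded_ci=bool(r.rewarded_ci), active_rule=str(r.active_rule),
                response=None if r.response in ("", None) or pd.isna(r.response)
                else str(r.response),
                reward_delivered=bool(r.reward_delivered),
                t_start=float(r.t_start), t_poke=float(r.t_poke),
                t_odor_on=float(r.t_odor_on), t_unpoke=float(r.t_unpoke),
                t_well=float(r.t_well),
            )
            for r in grp.itertuples()
        ]
        sessions.append(
            BehaviorSession(
                rat_id=str(rat), session_id=str(sid),
                phase=str(grp.phase.iloc[0]), group=str(grp.group.iloc[0]),
                trials=trials,
            )
        )
    return sessions
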