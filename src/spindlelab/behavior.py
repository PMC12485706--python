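"""Go/no-go trial scoring: performance, d-prime, bias, disengagement.

Each trial presents (go) or withholds (no-go) the tactile stimulus; a
lick inside the response window (2.0-3.0 s from trial start) makes the
outcome hit/false-alarm, its absence miss/correct-rejection.  Session
metrics follow standard signal detection theory:

    performance = (hits + correct rejections) / all trials
    d'   = z(H) - z(FA)
    bias = (z(H) + z(FA)) / 2

with z the standard-normal quantile.  Extreme rates (0 or 1) are
nudged by 1/(2N) of the relevant trial count before the z-transform
(flagged in the output).  A session is truncated at disengagement:
the first run of 10 consecutive unanswered go trials with no licks on
the no-go trials in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = ["Trial", "BehaviorMetrics", "score_trials", "disengagement_cut",
           "delta_metrics", "simulate_learner", "RESPONSE_WINDOW"]

RESPONSE_WINDOW = (2.0, 3.0)   # s from trial start

GO, NOGO = "go", "no-go"


@dataclass
class Trial:
    trial_index: int
    type: str                              # "go" | "no-go"
    licks: tuple[float, ...] = ()          # lick times, s from trial start
    response_window: tuple[float, float] = RESPONSE_WINDOW

    @property
    def responded(self) -> bool:
        lo, hi = self.response_window
        return any(lo <= t < hi for t in self.licks)

    @property
    def licked_at_all(self) -> bool:
        return len(self.licks) > 0

    @property
    def outcome(self) -> str:
        if self.type == GO:
            return "hit" if self.responded else "miss"
        return "false_alarm" if self.responded else "correct_reject"


@dataclass
class BehaviorMetrics:
    n_go: int
    n_nogo: int
    H: float
    FA: float
    performance: float
    dprime: float
    bias: float
    rate_corrected: bool = False


def _correct_rate(rate: float, n: int) -> tuple[float, bool]:
    if rate <= 0.0:
        return 1.0 / (2 * n), True
    if rate >= 1.0:
        return 1.0 - 1.0 / (2 * n), True
    return rate, False


def score_trials(trials: list[Trial]) -> BehaviorMetrics:
    go = [t for t in trials if t.type == GO]
    nogo = [t for t in trials if t.type == NOGO]
    if not go or not nogo:
        raise ValueError("need at least one go and one no-go trial")
    hits = sum(t.outcome == "hit" for t in go)
    crs = sum(t.outcome == "correct_reject" for t in nogo)
    fas = len(nogo) - crs

    performance = (hits + crs) / (len(go) + len(nogo))
    h, ch = _correct_rate(hits / len(go), len(go))
    fa, cf = _correct_rate(fas / len(nogo), len(nogo))
    zh, zfa = norm.ppf(h), norm.ppf(fa)
    return BehaviorMetrics(
        n_go=len(go), n_nogo=len(nogo), H=h, FA=fa,
        performance=performance,
        dprime=float(zh - zfa),
        bias=float((zh + zfa) / 2.0),
        rate_corrected=ch or cf,
    )


def disengagement_cut(trials: list[Trial]) -> list[Trial]:
    """Truncate at the first disengagement run, if any.

    The run is 10 consecutive go trials without a response-window lick,
    with no licks at all on the no-go trials strictly between the 1st
    and 10th go of the run.  Everything from the run's first go trial
    onward is dropped.  Idempotent; returns the input list unchanged
    when no run exists.
    """
    go_positions = [i for i, t in enumerate(trials) if t.type == GO]
    for w in range(len(go_positions) - 9):
        window = go_positions[w:w + 10]
        if any(trials[i].responded for i in window):
            continue
        lo, hi = window[0], window[-1]
        intervening = [t for t in trials[lo:hi + 1] if t.type == NOGO]
        if any(t.licked_at_all for t in intervening):
            continue
        return trials[:lo]
    return list(trials)


def delta_metrics(session_metrics: list[BehaviorMetrics]
                  ) -> dict[str, float]:
    """Training-half deltas: mean(second part) - mean(first part).

    The split point is the 4th session from the last, so the second
    part always holds the final four sessions.
    """
    if len(session_metrics) < 5:
        raise ValueError("need at least 5 sessions for half-split deltas")
    cut = len(session_metrics) - 4
    first, second = session_metrics[:cut], session_metrics[cut:]
    out = {}
    for name in ("performance", "dprime", "bias"):
        a = np.mean([getattr(m, name) for m in first])
        b = np.mean([getattr(m, name) for m in second])
        out[f"delta_{name}"] = float(b - a)
    return out


def simulate_learner(learning_rate: float, lapse: float = 0.1,
                     bias0: float = 0.3, n_sessions: int = 8,
                     trials_per_session: int = 100,
                     seed: int = 0) -> list[list[Trial]]:
    """Bernoulli go/no-go learner with drifting hit/false-alarm rates.

    Session s has hit probability rising from (1 - lapse - bias0)
    toward (1 - lapse) and false-alarm probability falling from
    (lapse + bias0) toward lapse, both at ``learning_rate`` per
    session.  Trial types alternate randomly in equal expected numbers.
    """
    if not 0.0 <= learning_rate <= 1.0:
        raise ValueError("learning_rate must be in [0, 1]")
    if not 0.0 <= lapse <= 0.5 or not 0.0 <= bias0 <= 0.5:
        raise ValueError("lapse and bias0 must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    sessions = []
    for s in range(n_sessions):
        gain = 1.0 - (1.0 - learning_rate) ** s
        p_hit = (1 - lapse - bias0) + bias0 * gain
        p_fa = (lapse + bias0) - bias0 * gain
        trials = []
        for i in range(trials_per_session):
            is_go = rng.random() < 0.5
            if is_go:
                licks = (2.5,) if rng.random() < p_hit else ()
                trials.append(Trial(i, GO, licks))
            else:
                licks = (2.5,) if rng.random() < p_fa else ()
                trials.append(Trial(i, NOGO, licks))
        sessions.append(trials)
    return sessions
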