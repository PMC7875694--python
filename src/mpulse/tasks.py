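"""Mobile active-task structure and parameterized agent simulators.

Three brief smartphone tasks index day-level impulse control:

* **go/no-go (GNG)** — 75 trials; a horizontal or vertical cue (after a
  250 ms fixation and 250 ms blank, shown for one of six stimulus-onset
  asynchronies) signals the upcoming target at 70% validity (horizontal →
  go, vertical → no-go); go targets are green, no-go blue, with a 500 ms
  response window and 250 ms intertrial interval.  Metrics: mean response
  latency on go trials, commission errors (responses on no-go trials) and
  omission errors (missed go trials).
* **delay discounting (DD)** — five adaptive choices between an immediate
  amount (adjusting-amount staircase: start at half the delayed reward,
  steps halving each trial) and a fixed delayed reward.  Metrics: present
  bias (fraction of immediate choices) and an indifference-point estimate.
* **balloon risk task (BART)** — 15 balloons, each with an explosion point
  uniform over pump capacity; pumping accrues gains that are lost if the
  balloon pops.  Metrics: mean pumps (risk taking) and mean per-trial gains.

Agents are governed by :class:`AgentParams`: a hyperbolic discount rate for
DD, lapse rates and a latency distribution for GNG, and a target pump count
for BART.  All simulators are bit-reproducible given a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GngTrial",
    "AgentParams",
    "generate_gng_session",
    "simulate_gng",
    "run_mdd",
    "simulate_bart",
    "hyperbolic_value",
    "bart_expected_gain",
]

#: GNG trial timing (milliseconds).
GNG_FIXATION_MS = 250
GNG_BLANK_MS = 250
GNG_SOAS_MS = (100, 200, 300, 400, 500, 750)
GNG_RESPONSE_WINDOW_MS = 500
GNG_ITI_MS = 250
#: Probability that the cue correctly signals the target type.
GNG_CUE_VALIDITY = 0.70

GNG_N_TRIALS = 75
DD_N_TRIALS = 5
BART_N_TRIALS = 15


@dataclass(frozen=True)
class GngTrial:
    """One go/no-go trial: cue orientation, cue-target asynchrony, target."""

    cue: str  # "horizontal" (signals go) or "vertical" (signals no-go)
    soa_ms: int
    target: str  # "go" (green) or "nogo" (blue)
    fixation_ms: int = GNG_FIXATION_MS
    blank_ms: int = GNG_BLANK_MS
    response_window_ms: int = GNG_RESPONSE_WINDOW_MS
    iti_ms: int = GNG_ITI_MS

    @property
    def cue_valid(self) -> bool:
        signalled = "go" if self.cue == "horizontal" else "nogo"
        return signalled == self.target


@dataclass
class AgentParams:
    """Behavioural parameters of a simulated participant.

    ``dd_k`` is the hyperbolic discount rate (1/delay-unit); ``dd_noise``
    the logistic choice-noise temperature (0 = deterministic).  GNG lapse
    rates are per-trial probabilities; the latency distribution is a normal
    truncated to the response window.  ``bart_target_pumps`` is the mean
    intended pump count, varied per balloon with SD ``bart_pump_sd``.
    """

    dd_k: float = 0.02
    dd_noise: float = 0.0
    gng_commission_rate: float = 0.02
    gng_omission_rate: float = 0.02
    gng_latency_mean: float = 424.0
    gng_latency_sd: float = 60.0
    bart_target_pumps: float = 4.5
    bart_pump_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gng_commission_rate", "gng_omission_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.gng_latency_mean <= 0 or self.gng_latency_sd <= 0:
            raise ValueError("latency parameters must be positive")


def hyperbolic_value(amount: float, delay: float, k: float) -> float:
    """Present value of a delayed reward under hyperbolic discounting:
    amount / (1 + k * delay)."""
    return amount / (1.0 + k * delay)


def generate_gng_session(
    n_trials: int = GNG_N_TRIALS,
    seed: int | np.random.Generator | None = None,
) -> list[GngTrial]:
    """Generate one go/no-go session.

    Cue orientation is drawn uniformly, the stimulus-onset asynchrony
    uniformly over the six values, and the target is consistent with its
    cue with probability 0.70.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cues = rng.choice(["horizontal", "vertical"], size=n_trials)
    soas = rng.choice(GNG_SOAS_MS, size=n_trials)
    valid = rng.random(n_trials) < GNG_CUE_VALIDITY
    trials = []
    for cue, soa, v in zip(cues, soas, valid):
        signalled = "go" if cue == "horizontal" else "nogo"
        target = signalled if v else ("nogo" if signalled == "go" else "go")
        trials.append(GngTrial(cue=str(cue), soa_ms=int(soa), target=target))
    return trials


def simulate_gng(
    trials: list[GngTrial],
    agent: AgentParams,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Simulate an agent on a go/no-go session.

    The agent responds to go targets with probability 1 − omission rate
    (latency drawn from a normal truncated to (0, response window]) and to
    no-go targets with probability equal to the commission rate.  Returns
    (mean latency over responded go trials in ms, commission error rate,
    omission error rate); latency is NaN if no go trial drew a response.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    go = np.array([t.target == "go" for t in trials])
    n_go, n_nogo = int(go.sum()), int((~go).sum())
    u = rng.random(len(trials))
    responded = np.where(go, u >= agent.gng_omission_rate, u < agent.gng_commission_rate)
    n_resp_go = int((responded & go).sum())
    if n_resp_go:
        a = (0.0 - agent.gng_latency_mean) / agent.gng_latency_sd
        b = (GNG_RESPONSE_WINDOW_MS - agent.gng_latency_mean) / agent.gng_latency_sd
        lat = stats.truncnorm.rvs(
            a, b, loc=agent.gng_latency_mean, scale=agent.gng_latency_sd,
            size=n_resp_go, random_state=rng,
        )
        latency = float(np.mean(lat))
    else:
        latency = float("nan")
    commission = float((responded & ~go).sum() / n_nogo) if n_nogo else float("nan")
    omission = float((~responded & go).sum() / n_go) if n_go else float("nan")
    if n_go == 0:
        latency = float("nan")
    return latency, commission, omission


def run_mdd(
    agent: AgentParams,
    delayed_amount: float = 100.0,
    delay: float = 30.0,
    n_trials: int = DD_N_TRIALS,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[str], float, float]:
    """Adjusting-amount delay-discounting staircase.

    The immediate offer starts at half the (fixed) delayed amount; after an
    immediate choice the next offer decreases, after a delayed choice it
    increases, with step sizes halving each trial (delayed/4, /8, …).  The
    agent prefers the immediate amount when it exceeds the hyperbolically
    discounted value delayed/(1 + k·delay), softened by logistic choice
    noise when ``dd_noise`` > 0.  Returns (choices, present bias = fraction
    of immediate choices, indifference estimate = final offer nudged by the
    final half-step).  For a noiseless agent the staircase is an exact
    bisection, so the estimate is within the final half-step of the true
    indifference point.
    """
    if delayed_amount <= 0 or delay <= 0:
        raise ValueError("delayed amount and delay must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    discounted = hyperbolic_value(delayed_amount, delay, agent.dd_k)
    offer = delayed_amount / 2.0
    step = delayed_amount / 4.0
    choices: list[str] = []
    for _ in range(n_trials):
        diff = offer - discounted
        if agent.dd_noise > 0:
            p_immediate = 1.0 / (1.0 + np.exp(-diff / agent.dd_noise))
            immediate = rng.random() < p_immediate
        else:
            immediate = diff > 0
        choices.append("immediate" if immediate else "delayed")
        offer = offer - step if immediate else offer + step
        step /= 2.0
    # after 5 choices the running offer is the final presented offer nudged
    # by the final half-step — the bisection indifference estimate
    indifference = offer
    present_bias = choices.count("immediate") / n_trials
    return choices, present_bias, float(indifference)


def bart_expected_gain(target_pumps: int, max_pumps: int, pay_per_pump: float) -> float:
    """Closed-form expected per-trial gain for a fixed pump policy under a
    uniform explosion point on {1..max_pumps}: pay·t·(M − t)/M."""
    t = min(target_pumps, max_pumps)
    return pay_per_pump * t * (max_pumps - t) / max_pumps


def simulate_bart(
    agent: AgentParams,
    n_trials: int = BART_N_TRIALS,
    max_pumps: int = 12,
    pay_per_pump: float = 3.7,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Simulate an agent on the balloon risk task.

    Each balloon's explosion point is uniform on {1..max_pumps}.  The agent
    intends a noisy number of pumps around its target; if the balloon pops
    first, the trial's gains are lost.  Returns (mean pumps, mean per-trial
    gains) over the session; pumps counted are those actually delivered
    (the balloon pops on the explosion pump).
    """
    if max_pumps < 1:
        raise ValueError("max_pumps must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    explosion = rng.integers(1, max_pumps + 1, size=n_trials)
    intended = np.clip(
        np.round(rng.normal(agent.bart_target_pumps, agent.bart_pump_sd, size=n_trials)),
        0,
        max_pumps,
    ).astype(int)
    pumps = np.minimum(intended, explosion)
    survived = intended < explosion
    gains = np.where(survived, intended * pay_per_pump, 0.0)
    return float(pumps.mean()), float(gains.mean())
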