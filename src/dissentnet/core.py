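"""Binary-choice decision rule: marginal utility plus a Fermi (logistic) response.

Each agent weighs a fixed net preference ``delta_o = o_A - o_B`` against
the local descriptive norm, the difference between the number of
neighbors currently choosing A and choosing B, scaled by the agent's
conformity weight ``w``:

    dU = delta_o + w * (n_A - n_B)

``w > 0`` is a conformist (utility from matching neighbors), ``w < 0``
an anticonformist (utility from differing), ``w = 0`` a nonconformist
(neighbors are ignored).  The agent then (re)samples its choice: A with
probability ``1 / (1 + exp(-beta * dU))``.  The inverse temperature
``beta`` controls decision noise; at the default ``beta = 100`` the rule
is effectively a deterministic threshold at ``dU = 0``.

Choices use a spin encoding fixed package-wide: sigma(A) = +1,
sigma(B) = -1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

#: Spin encoding of the two options, fixed package-wide.
CHOICE_A: int = 1
CHOICE_B: int = -1

_VALID_CHOICES = (CHOICE_A, CHOICE_B)


@dataclass
class DecisionParams:
    """Parameters of the Fermi choice rule.

    Parameters
    ----------
    beta
        Inverse temperature (> 0).  Large values make the rule a hard
        threshold at ``dU = 0``; the package default is 100.
    """

    beta: float = 100.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be a positive finite real, got {self.beta}")


@dataclass
class AgentState:
    """One agent: net preference, conformity weight, and current choice.

    The agent's behavioral type is derivable from ``sign(w)`` alone:
    conformist (w > 0), anticonformist (w < 0), nonconformist (w == 0).
    """

    delta_o: float
    w: float
    choice: int = field(default=CHOICE_A)

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_o):
            raise ValueError(f"delta_o must be finite, got {self.delta_o}")
        if not math.isfinite(self.w):
            raise ValueError(f"w must be finite, got {self.w}")
        if self.choice not in _VALID_CHOICES:
            raise ValueError(f"choice must be +1 (A) or -1 (B), got {self.choice}")

    @property
    def agent_type(self) -> str:
        if self.w > 0:
            return "conformist"
        if self.w < 0:
            return "anticonformist"
        return "nonconformist"


def marginal_utility(agent: AgentState, n_A: int, n_B: int) -> float:
    """Marginal utility of choosing A over B given the neighborhood tally.

    Returns ``delta_o + w * (n_A - n_B)`` exactly.

    Parameters
    ----------
    agent
        The deciding agent.
    n_A, n_B
        Non-negative counts of the agent's neighbors currently choosing
        A and B; their sum is the agent's degree.
    """
    if n_A < 0 or n_B < 0:
        raise ValueError(f"neighbor counts must be non-negative, got ({n_A}, {n_B})")
    return agent.delta_o + agent.w * (n_A - n_B)


def prob_choose_A(delta_U: float, params: DecisionParams | None = None) -> float:
    """Fermi probability of choosing A, ``1 / (1 + exp(-delta_U * beta))``.

    Numerically stable for arbitrarily large ``|delta_U * beta|``.
    """
    if params is None:
        params = DecisionParams()
    if not math.isfinite(delta_U):
        raise ValueError(f"delta_U must be finite, got {delta_U}")
    return float(expit(params.beta * delta_U))


def sample_choice(
    agent: AgentState,
    n_A: int,
    n_B: int,
    params: DecisionParams | None = None,
    rng: np.random.Generator | None = None,
) -> int:
    """Resample the agent's choice from the Fermi rule.

    The draw is independent of the agent's current choice: A is
    returned with probability ``prob_choose_A(marginal_utility(...))``,
    B otherwise.  The agent's stored state is not modified.
    """
    if rng is None:
        rng = np.random.default_rng()
    p = prob_choose_A(marginal_utility(agent, n_A, n_B), params)
    return CHOICE_A if rng.random() < p else CHOICE_B
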