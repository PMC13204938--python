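"""Trust estimation from observed action-outcome sequences.

The observer codes each observed trial as a binary action-outcome symbol:
``r`` when the observed action was followed by a rewarding outcome, ``n``
otherwise.  Predictability of the expert is estimated with a first-order
Markov chain over that symbol stream, and the probability that the *next*
association is rewarded -- the dynamic Bayesian probability (DBP) -- drives
an exponential-smoothing update of the scalar trust state beta in [0, 1].
Trust is then mapped affinely to the arousal gain Q that excites the
corresponding cell assembly, closing the loop from observed behaviour to
neural excitability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError

REWARDED = "r"
NOT_REWARDED = "n"
AO_ALPHABET = (REWARDED, NOT_REWARDED)


@dataclass(frozen=True)
class ObservationSequence:
    """Ordered observed trials: action identifier and rewarded flag."""

    actions: tuple
    rewarded: tuple  # of bool

    def __post_init__(self):
        if len(self.actions) != len(self.rewarded):
            raise ConfigurationError("actions and rewarded must have equal length")

    def __len__(self) -> int:
        return len(self.actions)

    @property
    def symbols(self) -> tuple[str, ...]:
        """Binary action-outcome coding: rewarded association or not."""
        return tuple(REWARDED if r else NOT_REWARDED for r in self.rewarded)

    def prefix(self, n: int) -> "ObservationSequence":
        return ObservationSequence(self.actions[:n], self.rewarded[:n])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self) + 1),
                "action": self.actions,
                "rewarded": self.rewarded,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ObservationSequence":
        return cls(
            actions=tuple(frame["action"]),
            rewarded=tuple(bool(x) for x in frame["rewarded"]),
        )


@dataclass(frozen=True)
class TransitionModel:
    """First-order conditional probabilities over the AO alphabet.

    ``matrix[i, j] = P(next = alphabet[j] | current = alphabet[i])``; rows
    sum to one.
    """

    matrix: np.ndarray
    alphabet: tuple[str, ...] = AO_ALPHABET
    smoothing: float = 1.0

    def __post_init__(self):
        k = len(self.alphabet)
        if self.matrix.shape != (k, k):
            raise ConfigurationError("transition matrix shape must match alphabet")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-12):
            raise ConfigurationError("transition matrix rows must sum to 1")

    def prob(self, current: str, nxt: str) -> float:
        try:
            i = self.alphabet.index(current)
            j = self.alphabet.index(nxt)
        except ValueError as exc:
            raise ConfigurationError(f"symbol outside alphabet {self.alphabet}") from exc
        return float(self.matrix[i, j])


def estimate_transitions(
    seq: ObservationSequence,
    smoothing: float = 1.0,
    alphabet: tuple[str, ...] = AO_ALPHABET,
) -> TransitionModel:
    """Laplace-smoothed bigram estimate of the AO transition probabilities.

    With add-``smoothing`` counts every row sums to one even for an empty
    sequence (uniform rows).  ``smoothing`` must be > 0 for the empty /
    unseen-symbol cases to be well defined; 0 is allowed when every context
    has been observed.
    """
    if smoothing < 0:
        raise ParameterError("smoothing must be >= 0")
    k = len(alphabet)
    index = {s: i for i, s in enumerate(alphabet)}
    counts = np.full((k, k), float(smoothing))
    symbols = seq.symbols
    for a, b in zip(symbols[:-1], symbols[1:]):
        if a not in index or b not in index:
            raise ConfigurationError(f"symbol outside alphabet {alphabet}")
        counts[index[a], index[b]] += 1.0
    totals = counts.sum(axis=1, keepdims=True)
    # a context never observed (possible only with zero smoothing) carries
    # no information: fall back to a uniform row
    matrix = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0), 1.0 / k)
    return TransitionModel(matrix=matrix, alphabet=alphabet, smoothing=smoothing)


def dbp_chain(seq: ObservationSequence, model: TransitionModel) -> float:
    """Chained sequence probability: the product of first-order conditionals.

    ``prod_k P(X_{k+1} = x_{k+1} | X_k = x_k)`` over the observed symbol
    stream; 1.0 for sequences shorter than two (empty product).
    """
    symbols = seq.symbols
    p = 1.0
    for a, b in zip(symbols[:-1], symbols[1:]):
        p *= model.prob(a, b)
    return p


def dbp_next_reward(seq: ObservationSequence, model: TransitionModel) -> float:
    """Probability that the next action-outcome association is rewarded.

    Under the first-order model this is ``P(r | current symbol)``.  For an
    empty sequence the smoothed marginal probability of ``r`` is returned.
    """
    symbols = seq.symbols
    if not symbols:
        # smoothing-only marginal over the alphabet
        k = len(model.alphabet)
        return 1.0 / k
    return model.prob(symbols[-1], REWARDED)


@dataclass(frozen=True)
class TrustState:
    """Scalar trust beta in [0, 1] with its update history.

    ``eta`` is the smoothing rate of the update
    ``beta' = (1 - eta) * beta + eta * dbp``; the history records
    ``(trial, dbp, beta)`` after each update.
    """

    beta: float
    eta: float = 0.1
    history: tuple = ()

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ParameterError(f"beta must lie in [0, 1], got {self.beta}")
        if not 0.0 <= self.eta <= 1.0:
            raise ParameterError(f"eta must lie in [0, 1], got {self.eta}")


def update_trust(state: TrustState, dbp: float) -> TrustState:
    """Exponentially smooth trust toward the current predictability estimate."""
    if not 0.0 <= dbp <= 1.0:
        raise ParameterError(f"dbp must lie in [0, 1], got {dbp}")
    beta = (1.0 - state.eta) * state.beta + state.eta * dbp
    trial = len(state.history) + 1
    return TrustState(
        beta=beta, eta=state.eta, history=state.history + ((trial, dbp, beta),)
    )


def trust_to_gain(beta: float, q_lo: float, q_hi: float) -> float:
    """Affine trust -> arousal-gain map ``Q = q_lo + (q_hi - q_lo) * beta``."""
    if q_hi < q_lo:
        raise ConfigurationError(f"q_hi={q_hi} must be >= q_lo={q_lo}")
    if not 0.0 <= beta <= 1.0:
        raise ParameterError(f"beta must lie in [0, 1], got {beta}")
    return q_lo + (q_hi - q_lo) * beta


def signal_value(e_s: float, q_individual: float, dbp: float) -> float:
    """Predictive signal magnitude ``E_s * Q_individual * DBP``."""
    if e_s < 0:
        raise ParameterError("signal energy must be >= 0")
    if q_individual <= 0:
        raise ParameterError("Q_individual must be > 0")
    if not 0.0 <= dbp <= 1.0:
        raise ParameterError(f"dbp must lie in [0, 1], got {dbp}")
    return e_s * q_individual * dbp
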