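"""Trial-level Hebbian and trust-modulated Hebbian weight updates.

The plain Hebbian rule drives a coactivated connection toward the hard
ceiling ``w_max``:

    dw = alpha * g_pre * g_post * (w_max - w)

Trust enters as a multiplicative modulation of the saturation term,

    dw = alpha * g_pre * g_post * (w_max - beta * w),

so for trust beta in (0, 1] the fixed point moves to ``w_max / beta`` and
the update magnitude shrinks geometrically with ratio
``1 - alpha * g_pre * g_post * beta`` under sustained constant coactivation.
At beta = 1 the two rules coincide.  Updates are applied once per trial
using the post-transient trial-mean activations, which keeps the learning
rate's scale independent of trial duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ParameterError
from .network import ConnectionMatrix, TrialTrace


@dataclass(frozen=True)
class PlasticityParams:
    """Learning rate (per trial) and weight ceiling."""

    alpha: float = 0.05
    w_max: float = 1.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ParameterError("alpha must be >= 0")
        if self.w_max <= 0:
            raise ParameterError("w_max must be > 0")


def hebbian_update(w, g_pre, g_post, alpha, w_max):
    """Saturating Hebbian increment ``alpha * g_pre * g_post * (w_max - w)``."""
    return alpha * np.asarray(g_pre) * np.asarray(g_post) * (w_max - np.asarray(w))


def _check_beta(beta: float) -> None:
    if not 0.0 <= beta <= 1.0:
        raise ParameterError(f"trust beta must lie in [0, 1], got {beta}")


def trust_hebbian_update(w, g_pre, g_post, alpha, w_max, beta):
    """Trust-modulated Hebbian increment.

    ``alpha * g_pre * g_post * (w_max - beta * w)``; reduces to
    :func:`hebbian_update` at ``beta = 1`` and vanishes at the fixed point
    ``w = w_max / beta``.
    """
    _check_beta(beta)
    return alpha * np.asarray(g_pre) * np.asarray(g_post) * (
        w_max - beta * np.asarray(w)
    )


def trial_plasticity(
    trace: TrialTrace,
    connections: ConnectionMatrix,
    params: PlasticityParams,
    beta: float,
    mask: np.ndarray | None = None,
) -> ConnectionMatrix:
    """Apply one trust-modulated Hebbian update per plastic connection.

    The pre/post activations entering the rule are the per-unit means of
    ``g`` over the post-transient window of the trial.  Only entries of
    ``connections.plastic`` (optionally further restricted by ``mask``)
    change; the result is clipped to ``[0, w_max / beta]`` and returned as a
    new :class:`ConnectionMatrix` (the input is not modified).  At
    ``beta = 0`` the trust term vanishes and no finite ceiling applies.
    """
    _check_beta(beta)
    if trace.g.shape[1] != connections.n_units:
        raise ConfigurationError(
            f"trace has {trace.g.shape[1]} units but connections have "
            f"{connections.n_units}"
        )
    update_mask = connections.plastic
    if mask is not None:
        if mask.shape != update_mask.shape:
            raise ConfigurationError("plasticity mask shape mismatch")
        update_mask = update_mask & mask

    g_mean = trace.g[trace.config.n_transient :].mean(axis=0)
    rows, cols = np.nonzero(update_mask)
    w = connections.weights.copy()
    old = w[rows, cols]
    dw = trust_hebbian_update(
        old, g_mean[cols], g_mean[rows], params.alpha, params.w_max, beta
    )
    # the rule never drives a weight past w_max/beta, but an entry that
    # started above the ceiling (e.g. encoding a strong prior) is left
    # where it is rather than truncated
    ceiling = params.w_max / beta if beta > 0 else np.inf
    w[rows, cols] = np.clip(old + dw, 0.0, np.maximum(ceiling, old))
    return ConnectionMatrix(
        weights=w,
        sign=connections.sign,
        delay_steps=connections.delay_steps,
        plastic=connections.plastic,
        w_max=connections.w_max,
        coupling=connections.coupling,
    )
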