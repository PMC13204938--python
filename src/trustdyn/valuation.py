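"""Per-option emotional and rational valuation from cell-assembly activity.

A cell assembly is a tagged subset of a structure's excitatory units whose
collective oscillation represents one decision option (or the observed
expert).  Each option's value combines the assembly's mean plastic weight
with the energy of its oscillatory signal,

    V_opt = W_opt * E_opt / norm,      E_opt = A_opt**2 * f_opt,

where ``A_opt`` is the RMS amplitude of the detrended assembly-mean
activation and ``f_opt`` its dominant frequency.  The emotional (OFC) and
rational (LPFC) channels are integrated by an elementwise sum, and the ACC
compares predicted with actual values to emit signed action (emotional) and
outcome (rational) prediction errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, FlatSignalError, ParameterError
from .network import ConnectionMatrix, TrialTrace
from .spectral import DEFAULT_BAND, dominant_frequency


@dataclass(frozen=True)
class CellAssembly:
    """A labelled subset of excitatory units within one structure."""

    label: str
    structure: str
    members: np.ndarray  # unit indices into the full network

    def __post_init__(self):
        if len(self.members) == 0:
            raise ConfigurationError(f"assembly {self.label!r} has no members")


@dataclass(frozen=True)
class AssemblyEnergy:
    """Spectral readout of one assembly: frequency, amplitude and energy.

    ``frequency`` is NaN and ``defined`` False when the assembly signal was
    flat (no oscillation), in which case amplitude and energy are zero.
    """

    frequency: float  # Hz
    amplitude: float  # RMS of the detrended assembly-mean activation
    energy: float  # amplitude**2 * frequency
    defined: bool = True


@dataclass(frozen=True)
class OptionValue:
    """Value decomposition for one option in one channel."""

    option: str
    weight: float  # W_opt: mean plastic weight within the assembly
    frequency: float  # f_opt (Hz; NaN when undefined)
    amplitude: float  # A_opt
    energy: float  # E_opt
    value: float  # V_opt


@dataclass(frozen=True)
class PredictionError:
    """Signed ACC comparison of predicted vs actual option values.

    ``action`` is the emotional-channel error, ``outcome`` the rational one.
    """

    action: float
    outcome: float


def assembly_mean_signal(trace: TrialTrace, assembly: CellAssembly, window: slice) -> np.ndarray:
    """Mean activation of the assembly members over a trace window."""
    return trace.g[window, :][:, np.asarray(assembly.members)].mean(axis=1)


def assembly_energy(
    trace: TrialTrace,
    assembly: CellAssembly,
    band: tuple[float, float] = DEFAULT_BAND,
    window: slice | None = None,
) -> AssemblyEnergy:
    """Frequency, RMS amplitude and energy of the assembly-mean signal.

    ``window`` defaults to the post-transient part of the trial.  The energy
    form ``A**2 * f`` is monotone in both amplitude and frequency, so faster
    and stronger oscillations both raise the readout.
    """
    if window is None:
        window = slice(trace.config.n_transient, trace.n_steps)
    x = assembly_mean_signal(trace, assembly, window)
    amplitude = float(np.sqrt(np.mean((x - x.mean()) ** 2)))
    fs = 1000.0 / trace.config.dt
    try:
        frequency = dominant_frequency(x, fs, band)
    except FlatSignalError:
        return AssemblyEnergy(frequency=float("nan"), amplitude=0.0, energy=0.0, defined=False)
    return AssemblyEnergy(
        frequency=frequency,
        amplitude=amplitude,
        energy=amplitude**2 * frequency,
        defined=True,
    )


def assembly_weight(connections: ConnectionMatrix, assembly: CellAssembly) -> float:
    """Mean plastic weight among the assembly's internal connections."""
    idx = np.asarray(assembly.members)
    block_plastic = connections.plastic[np.ix_(idx, idx)]
    if not block_plastic.any():
        return 0.0
    return float(connections.weights[np.ix_(idx, idx)][block_plastic].mean())


def option_value(w_opt: float, e_opt: float, norm: float = 1.0) -> float:
    """Option value ``W_opt * E_opt / norm``.

    ``norm`` is the configured normalization constant placing scenario
    values on the 0-1 reporting scale (1.0 leaves the raw product).
    """
    if w_opt < 0 or e_opt < 0:
        raise ParameterError("weight and energy must be >= 0")
    if norm <= 0:
        raise ParameterError("normalization constant must be > 0")
    return w_opt * e_opt / norm


def integrate_values(v_emo, v_rat) -> np.ndarray:
    """Integrate emotional and rational channels: elementwise sum."""
    v_emo = np.asarray(v_emo, dtype=float)
    v_rat = np.asarray(v_rat, dtype=float)
    if v_emo.shape != v_rat.shape:
        raise ConfigurationError(
            f"value vectors differ in shape: {v_emo.shape} vs {v_rat.shape}"
        )
    return v_emo + v_rat


def prediction_errors(predicted, actual) -> PredictionError:
    """ACC comparison of (emotional, rational) value pairs.

    ``predicted`` and ``actual`` are (emotional, rational) pairs for the
    same observed action; the action error is the emotional difference
    (actual - predicted), the outcome error the rational one.
    """
    pe, pr = predicted
    ae, ar = actual
    return PredictionError(action=ae - pe, outcome=ar - pr)


def select_option(v_final, options=None):
    """Argmax decision rule; ties break toward the lowest option index."""
    v_final = np.asarray(v_final, dtype=float)
    if v_final.size == 0:
        raise ConfigurationError("cannot select from an empty value vector")
    idx = int(np.argmax(v_final))  # np.argmax returns the first maximum
    return idx if options is None else options[idx]
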