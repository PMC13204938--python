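"""Three-layer oscillatory cortical sheets and their delayed rate dynamics.

Each modelled cortical structure (OFC, LPFC, ACC) is an attractor-style
rate-unit network with three layers: a slow feedforward inhibitory layer, a
middle excitatory layer, and a fast feedback inhibitory layer.  Units obey a
leaky integrator equation

    du_i/dt = -u_i / tau_i + sum_{j != i} s_j w_ij g_j(u_j(t - delta_ij))
              + I_i(t) + xi(t)

where ``g`` is Freeman's asymmetric sigmoid parameterised by an arousal gain
``Q``, ``w_ij >= 0`` is the connection strength from unit j to unit i, the
sign ``s_j`` is fixed by the presynaptic layer (Dale-like: excitatory units
excite, inhibitory units inhibit), and ``delta_ij`` is a conduction delay.
Time is measured in milliseconds throughout; the integrator is forward Euler
with a fixed step (1 ms by default) and a ring buffer of past activations
covering the longest delay.

The excitatory <-> feedback-inhibitory loop (time constants 10 ms and 7 ms)
is the gamma-band oscillation generator; the slow feedforward inhibitory
layer (70 ms) shapes the envelope.  With zero noise the dynamics are fully
deterministic given the seed used for the random initial weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from .errors import (
    ConfigurationError,
    IntegrationError,
    ParameterError,
    StabilityError,
)

# layer tags
LAYER_FF_INH = "ff_inh"  # feedforward inhibitory (slow)
LAYER_EXC = "exc"  # excitatory (middle layer)
LAYER_FB_INH = "fb_inh"  # feedback inhibitory (fast)

LAYERS = (LAYER_FF_INH, LAYER_EXC, LAYER_FB_INH)

DEFAULT_STRUCTURES = ("OFC", "LPFC", "ACC")

# Reference arousal gains (emotional structure high, rational low); the
# scenario layer normally drives Q dynamically and only uses these as the
# static preset.
NOMINAL_GAINS = {"OFC": 10.0, "LPFC": 6.0, "ACC": 6.0}


def gain(u, q, c=1.0):
    """Freeman-style input-output function ``C*Q*(1 - exp(-exp(u/Q)))``.

    Strictly increasing in ``u`` and bounded in (0, C*Q).  ``q`` may be a
    scalar or a per-unit array broadcastable against ``u``.

    Parameters
    ----------
    u : array_like
        Unit potential(s).
    q : array_like
        Arousal gain, > 0.  Controls both the saturation level ``C*Q`` and
        the potential scale over which the unit responds.
    c : float
        Normalization constant, > 0 (dimensionless, default 1).
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ParameterError(f"gain Q must be > 0, got {q}")
    if c <= 0:
        raise ParameterError(f"gain C must be > 0, got {c}")
    u = np.asarray(u, dtype=float)
    # exp(50) is already astronomically large; clipping the inner exponent
    # avoids overflow warnings without changing the result.
    inner = np.exp(np.clip(u / q, -745.0, 50.0))
    return c * q * (1.0 - np.exp(-inner))


@dataclass(frozen=True)
class LayerParams:
    """Membrane decay time constants per layer (ms)."""

    tau_ff_inh: float = 70.0
    tau_exc: float = 10.0
    tau_fb_inh: float = 7.0

    def __post_init__(self):
        for name in ("tau_ff_inh", "tau_exc", "tau_fb_inh"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")

    def tau_of(self, layer: str) -> float:
        return {
            LAYER_FF_INH: self.tau_ff_inh,
            LAYER_EXC: self.tau_exc,
            LAYER_FB_INH: self.tau_fb_inh,
        }[layer]


@dataclass(frozen=True)
class CouplingScales:
    """Per-class coupling strengths, part of the version-pinned calibration.

    For the fixed (non-plastic) inhibitory-loop classes the value is the
    *total afferent load*: each postsynaptic unit's coupling gains are
    normalized so that its summed effective weight from that class equals
    the scale, which keeps operating points homogeneous across units
    despite the random weight draw.  For the plastic excitatory classes the
    value is a plain multiplier on the learnable weight, so Hebbian changes
    feed through to the dynamics.
    """

    ee: float = 0.04  # multiplier, excitatory -> excitatory within structure
    e_fbi: float = 5.5  # row-sum load, excitatory -> feedback inhibitory
    fbi_e: float = 20.0  # row-sum load, feedback inhibitory -> excitatory
    ffi_e: float = 0.5  # row-sum load, feedforward inhibitory -> excitatory
    inter: float = 0.02  # multiplier, inter-structure excitatory bundles


@dataclass(frozen=True)
class NetworkParams:
    """Structural network parameters (counts, time constants, wiring).

    Field <-> conventional symbol: n_excitatory (Nex), n_inhibitory (Nin),
    tau_ff_inh/tau_exc/tau_fb_inh (tau_I/II/III), lambda_ee (space constant
    for excitatory-excitatory connections), lambda_ei (excitatory-inhibitory),
    spacing (nearest-neighbour distance d), t_syn (synaptic delay), v_ee
    (excitatory-excitatory conduction velocity, m/s), w_max (weight ceiling).
    """

    n_excitatory: int = 100
    n_inhibitory: int = 25
    tau_ff_inh: float = 70.0
    tau_exc: float = 10.0
    tau_fb_inh: float = 7.0
    lambda_ee: float = 5.0
    lambda_ei: float = 5.0
    spacing: float = 1.0
    t_syn: float = 0.8
    v_ee: float = 0.5
    w_max: float = 1.0

    @property
    def layer_params(self) -> LayerParams:
        return LayerParams(
            tau_ff_inh=self.tau_ff_inh,
            tau_exc=self.tau_exc,
            tau_fb_inh=self.tau_fb_inh,
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white-noise term of the unit equation.

    ``sd`` is the noise standard deviation in potential units per sqrt(ms);
    the integrator adds ``sd * sqrt(dt) * N(0,1)`` per step (Euler-Maruyama).
    Zero by default: the model is deterministic unless noise is explicitly
    introduced.
    """

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sd < 0:
            raise ParameterError("noise sd must be >= 0")


@dataclass(frozen=True)
class IntegrationConfig:
    """Euler integration settings (all times in ms)."""

    dt: float = 1.0
    duration: float = 1000.0
    transient: float = 200.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.duration < self.transient:
            raise ParameterError("duration must be >= transient window")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def n_transient(self) -> int:
        return int(round(self.transient / self.dt))


@dataclass(frozen=True)
class NetworkGeometry:
    """Unit bookkeeping: structure tag, layer tag and 2-D position per unit.

    Excitatory units sit on a regular square grid (default 10x10, spacing
    ``d`` = 1 mm); each 5x5 inhibitory layer overlays the excitatory sheet
    with each inhibitory unit centred on a 2x2 excitatory patch.  Positions
    are per-structure local coordinates in mm; distances are only meaningful
    within a structure (inter-structure bundles carry no distance decay).
    """

    structures: tuple[str, ...]
    structure_of: np.ndarray  # (N,) int index into `structures`
    layer_of: np.ndarray  # (N,) object array of layer tags
    positions: np.ndarray  # (N, 2) mm, structure-local
    spacing: float  # nearest-neighbour distance d (mm)

    @property
    def n_units(self) -> int:
        return len(self.structure_of)

    def units(self, structure: str | None = None, layer: str | None = None) -> np.ndarray:
        """Indices of units matching the given structure and/or layer tag."""
        mask = np.ones(self.n_units, dtype=bool)
        if structure is not None:
            mask &= self.structure_of == self.structures.index(structure)
        if layer is not None:
            mask &= self.layer_of == layer
        return np.nonzero(mask)[0]

    @property
    def excitatory_mask(self) -> np.ndarray:
        return np.asarray(self.layer_of == LAYER_EXC)

    def distances(self) -> np.ndarray:
        """(N, N) pairwise Euclidean distances (mm), structure-local.

        Entries for unit pairs in different structures are set to NaN.
        """
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
        same = self.structure_of[:, None] == self.structure_of[None, :]
        d[~same] = np.nan
        return d


def _square_side(count: int, what: str) -> int:
    side = int(round(np.sqrt(count)))
    if side * side != count:
        raise ConfigurationError(f"{what} count {count} does not form a square grid")
    return side


def build_geometry(
    structures: tuple[str, ...] = DEFAULT_STRUCTURES,
    n_excitatory: int = 100,
    n_inhibitory: int = 25,
    spacing: float = 1.0,
) -> NetworkGeometry:
    """Lay out the three-layer sheets for each structure.

    Unit order is, per structure: feedforward inhibitory layer, excitatory
    layer, feedback inhibitory layer.  With the defaults this yields
    ``3 * (25 + 100 + 25) = 450`` units.
    """
    if spacing <= 0:
        raise ParameterError("spacing must be > 0")
    exc_side = _square_side(n_excitatory, "excitatory")
    inh_side = _square_side(n_inhibitory, "inhibitory")
    if inh_side * 2 != exc_side:
        raise ConfigurationError(
            "inhibitory grid must tile the excitatory sheet in 2x2 patches "
            f"(got {inh_side}x{inh_side} over {exc_side}x{exc_side})"
        )

    exc_pos = np.array(
        [(i * spacing, j * spacing) for i in range(exc_side) for j in range(exc_side)]
    )
    # inhibitory unit (i, j) is centred on the 2x2 excitatory patch
    # {2i, 2i+1} x {2j, 2j+1}
    inh_pos = np.array(
        [
            ((2 * i + 0.5) * spacing, (2 * j + 0.5) * spacing)
            for i in range(inh_side)
            for j in range(inh_side)
        ]
    )

    structure_of, layer_of, positions = [], [], []
    for s_idx, _name in enumerate(structures):
        for layer, pos in (
            (LAYER_FF_INH, inh_pos),
            (LAYER_EXC, exc_pos),
            (LAYER_FB_INH, inh_pos),
        ):
            structure_of.extend([s_idx] * len(pos))
            layer_of.extend([layer] * len(pos))
            positions.append(pos)

    return NetworkGeometry(
        structures=tuple(structures),
        structure_of=np.array(structure_of, dtype=int),
        layer_of=np.array(layer_of, dtype=object),
        positions=np.concatenate(positions, axis=0),
        spacing=float(spacing),
    )


@dataclass
class ConnectionMatrix:
    """Signed, delayed connectivity.

    ``weights[i, j]`` is the non-negative strength of the connection from
    unit j to unit i; the effective synaptic sign is ``sign[j]`` (+1 for a
    presynaptic excitatory unit, -1 for inhibitory).  ``delay_steps[i, j]``
    is the conduction delay in whole integration steps.  ``plastic`` marks
    the entries subject to Hebbian learning.

    ``coupling[i, j]`` is a fixed per-entry dynamical gain (set from the
    per-class coupling scales at build time); the synaptic strength entering
    the unit equation is ``coupling * weights``, while Hebbian learning acts
    on ``weights`` alone, keeping the learnable quantity on the
    ``[0, w_max / beta]`` scale regardless of how strongly a connection
    class couples into the dynamics.
    """

    weights: np.ndarray  # (N, N) float, >= 0
    sign: np.ndarray  # (N,) float in {+1, -1}, by presynaptic layer
    delay_steps: np.ndarray  # (N, N) int, >= 1
    plastic: np.ndarray  # (N, N) bool
    w_max: float
    coupling: np.ndarray | None = None  # (N, N) float, defaults to 1

    def __post_init__(self):
        n = self.weights.shape[0]
        if self.weights.shape != (n, n) or self.delay_steps.shape != (n, n):
            raise ConfigurationError("connection matrices must be square and aligned")
        if np.any(self.weights < 0):
            raise ParameterError("connection weights must be non-negative")
        if self.coupling is None:
            self.coupling = np.ones_like(self.weights)

    @property
    def n_units(self) -> int:
        return self.weights.shape[0]

    def compiled(self) -> list[tuple[int, sparse.csr_matrix]]:
        """Signed effective weights grouped by delay, as CSR matrices.

        The delay structure is fixed after construction, so callers may
        cache the sparsity pattern; this method recompiles from the current
        weights (cheap relative to a trial integration).
        """
        effective = self.weights * self.coupling
        signed = effective * self.sign[None, :]
        groups = []
        for k in np.unique(self.delay_steps[effective > 0]):
            mask = (self.delay_steps == k) & (effective > 0)
            mat = sparse.csr_matrix(np.where(mask, signed, 0.0))
            groups.append((int(k), mat))
        return groups


def compute_delays(
    geometry: NetworkGeometry,
    t_syn: float = 0.8,
    v_ee: float = 0.5,
    dt: float = 1.0,
) -> np.ndarray:
    """Conduction delays in ms for every ordered unit pair.

    Excitatory->excitatory pairs incur a distance-dependent axonal delay
    ``d_ij / v_ee`` (``v_ee`` in m/s, i.e. mm/ms) on top of the fixed
    synaptic delay ``t_syn``; all connections involving inhibitory units are
    local and carry the synaptic delay only.  Delays are rounded to whole
    integration steps (minimum one step) by the caller via
    :func:`delays_to_steps`.
    """
    if t_syn < 0:
        raise ParameterError("t_syn must be >= 0")
    if v_ee <= 0:
        raise ParameterError("v_ee must be > 0")
    d = geometry.distances()
    exc = geometry.excitatory_mask
    ee = exc[:, None] & exc[None, :]
    delays = np.full_like(d, t_syn)
    with np.errstate(invalid="ignore"):
        delays[ee] = t_syn + d[ee] / v_ee
    delays[np.isnan(d)] = t_syn  # inter-structure bundles: synaptic delay only
    return delays


def delays_to_steps(delays_ms: np.ndarray, dt: float) -> np.ndarray:
    """Round delays to whole integration steps, at least one step."""
    return np.maximum(1, np.rint(delays_ms / dt).astype(int))


def init_weights(
    geometry: NetworkGeometry,
    lambda_ee: float = 5.0,
    lambda_ei: float = 5.0,
    w_max: float = 1.0,
    seed: int = 0,
    scales: CouplingScales = CouplingScales(),
    t_syn: float = 0.8,
    v_ee: float = 0.5,
    dt: float = 1.0,
) -> ConnectionMatrix:
    """Random distance-decayed connectivity for the three-layer sheets.

    Every realised connection gets learnable strength
    ``clip(|N(0,1)|, 0, 1) * exp(-d_ij / lambda) * w_max`` and a fixed
    dynamical coupling gain equal to its class scale.  Connection classes
    (within each structure):

    * excitatory -> excitatory: all ordered pairs (no self-connections),
      space constant ``lambda_ee``; these entries are plastic.
    * excitatory -> feedback inhibitory and back: all pairs, space constant
      ``lambda_ei``.
    * feedforward inhibitory -> excitatory: each feedforward inhibitory unit
      inhibits the four excitatory units of its 2x2 patch.

    The feedforward inhibitory layer receives external input only (it is
    feedforward with respect to the sheet).  Identical seeds yield bitwise
    identical matrices.
    """
    if lambda_ee <= 0 or lambda_ei <= 0:
        raise ParameterError("space constants must be > 0")
    if w_max <= 0:
        raise ParameterError("w_max must be > 0")

    n = geometry.n_units
    rng = np.random.default_rng(seed)
    d = geometry.distances()
    layer = geometry.layer_of
    exc = geometry.excitatory_mask
    ffi = np.asarray(layer == LAYER_FF_INH)
    fbi = np.asarray(layer == LAYER_FB_INH)
    same = ~np.isnan(d)

    def pair_mask(post_mask, pre_mask):
        return same & post_mask[:, None] & pre_mask[None, :]

    weights = np.zeros((n, n))
    coupling = np.ones((n, n))
    plastic = np.zeros((n, n), dtype=bool)

    classes = [
        (pair_mask(exc, exc), lambda_ee, scales.ee, True),
        (pair_mask(fbi, exc), lambda_ei, scales.e_fbi, False),
        (pair_mask(exc, fbi), lambda_ei, scales.fbi_e, False),
        (pair_mask(exc, ffi) & (d < geometry.spacing), lambda_ei, scales.ffi_e, False),
    ]
    for mask, lam, scale, is_plastic in classes:
        mask = mask.copy()
        np.fill_diagonal(mask, False)
        idx = np.nonzero(mask)
        draw = np.clip(np.abs(rng.standard_normal(len(idx[0]))), 0.0, 1.0)
        weights[idx] = draw * np.exp(-d[idx] / lam) * w_max
        if is_plastic:
            # plain multiplier: learned weight changes feed the dynamics
            coupling[idx] = scale
            plastic[idx] = True
        else:
            # afferent-load normalization: every postsynaptic unit receives
            # the same summed effective weight from this class
            block = np.where(mask, weights, 0.0)
            load = block.sum(axis=1)
            rows = load > 0
            gain_rows = np.zeros_like(load)
            gain_rows[rows] = scale / load[rows]
            coupling[idx] = gain_rows[idx[0]]

    sign = np.where(exc, 1.0, -1.0)
    delay_steps = delays_to_steps(compute_delays(geometry, t_syn, v_ee, dt), dt)
    return ConnectionMatrix(
        weights=weights,
        sign=sign,
        delay_steps=delay_steps,
        plastic=plastic,
        w_max=w_max,
        coupling=coupling,
    )


def add_bundle(
    connections: ConnectionMatrix,
    source_units: np.ndarray,
    target_units: np.ndarray,
    scale: float,
    seed: int = 0,
    plastic: bool = True,
) -> None:
    """Add a sparse excitatory bundle between two (assembly) unit sets.

    Used for the inter-structure pathways (LPFC -> OFC, OFC <-> ACC,
    LPFC <-> ACC): every source unit projects to every target unit with
    learnable strength ``clip(|N(0,1)|, 0, 1)``, dynamical coupling gain
    ``scale`` and the minimum (synaptic-only) delay.  Modifies
    ``connections`` in place.
    """
    rng = np.random.default_rng(seed)
    rows = np.repeat(target_units, len(source_units))
    cols = np.tile(source_units, len(target_units))
    keep = rows != cols
    rows, cols = rows[keep], cols[keep]
    connections.weights[rows, cols] = np.clip(
        np.abs(rng.standard_normal(len(rows))), 0.0, 1.0
    )
    connections.coupling[rows, cols] = scale
    if plastic:
        connections.plastic[rows, cols] = True


@dataclass(frozen=True)
class Drive:
    """A constant external input applied to a unit set over a time window."""

    units: np.ndarray
    amplitude: float
    t_on: float = 0.0  # ms, inclusive
    t_off: float = np.inf  # ms, exclusive


def materialize_input(drives: list[Drive], n_units: int, config: IntegrationConfig) -> np.ndarray:
    """Expand a drive program into a (steps, N) external-input array."""
    current = np.zeros((config.n_steps, n_units))
    t = np.arange(config.n_steps) * config.dt
    for drv in drives:
        window = (t >= drv.t_on) & (t < drv.t_off)
        current[np.ix_(window, np.asarray(drv.units))] += drv.amplitude
    return current


@dataclass
class TrialTrace:
    """Full within-trial record: potentials, activations and input at 1 ms.

    Shapes are (steps, N).  ``time_ms`` is the time axis of the samples.
    """

    time_ms: np.ndarray
    u: np.ndarray
    g: np.ndarray
    external: np.ndarray
    config: IntegrationConfig

    @property
    def n_steps(self) -> int:
        return len(self.time_ms)

    def window(self, t_start: float, t_stop: float) -> slice:
        """Index slice for the half-open time window [t_start, t_stop) ms."""
        i0 = int(round(t_start / self.config.dt))
        i1 = int(round(t_stop / self.config.dt))
        return slice(i0, i1)

    def to_frame(self):
        """Long-format table (time_ms, unit_id, u, g) for CSV export."""
        import pandas as pd

        n = self.u.shape[1]
        return pd.DataFrame(
            {
                "time_ms": np.repeat(self.time_ms, n),
                "unit_id": np.tile(np.arange(n), self.n_steps),
                "u": self.u.ravel(),
                "g": self.g.ravel(),
            }
        )


def euler_step(u, tau, syn_input, external, noise, dt):
    """One forward-Euler step of the unit equation.

    ``syn_input`` is the summed, signed, delayed synaptic input per unit
    (already weighted); ``noise`` the per-step stochastic increment (added
    outside the dt product, Euler-Maruyama style).
    """
    tau = np.asarray(tau, dtype=float)
    if dt >= np.min(tau):
        raise StabilityError(f"dt={dt} must be smaller than the fastest tau={np.min(tau)}")
    return u + dt * (-u / tau + syn_input + external) + noise


class Network:
    """A fully built network: geometry + connections + per-unit gain state.

    The per-unit arousal gain ``Q`` is mutable session state (trust raises
    it); everything else about the architecture is fixed at build time.
    """

    def __init__(
        self,
        geometry: NetworkGeometry,
        connections: ConnectionMatrix,
        layer_params: LayerParams = LayerParams(),
        gains: dict[str, float] | None = None,
        c: float = 1.0,
    ):
        self.geometry = geometry
        self.connections = connections
        self.layer_params = layer_params
        self.c = float(c)
        self.tau = np.array([layer_params.tau_of(l) for l in geometry.layer_of])
        self.q = np.empty(geometry.n_units)
        gains = gains if gains is not None else {s: 6.0 for s in geometry.structures}
        for s in geometry.structures:
            self.set_gain(gains[s], structure=s)

    def set_gain(self, value: float, structure: str | None = None, units=None) -> None:
        """Set the arousal gain for a structure or an explicit unit set."""
        if value <= 0:
            raise ParameterError("Q must be > 0")
        if units is not None:
            self.q[np.asarray(units)] = value
        elif structure is not None:
            self.q[self.geometry.units(structure=structure)] = value
        else:
            self.q[:] = value

    def run_trial(
        self,
        drives: list[Drive],
        config: IntegrationConfig = IntegrationConfig(),
        noise: NoiseSpec = NoiseSpec(),
        u0: np.ndarray | None = None,
    ) -> TrialTrace:
        """Integrate one trial and return the full trace.

        The delay ring buffer is primed with the activation of the initial
        state, so a network at rest stays at rest only if that is a fixed
        point.  With ``noise.sd == 0`` the result is bit-reproducible.
        """
        n = self.geometry.n_units
        dt = config.dt
        if dt >= np.min(self.tau):
            raise StabilityError(
                f"dt={dt} must be smaller than the fastest tau={np.min(self.tau)}"
            )
        steps = config.n_steps
        u = np.zeros(n) if u0 is None else np.array(u0, dtype=float)
        groups = self.connections.compiled()
        max_delay = max((k for k, _ in groups), default=1)

        external = materialize_input(drives, n, config)
        g0 = gain(u, self.q, self.c)
        # Ring buffer of past activations.  The explicit-Euler update itself
        # carries one step of latency (the activation computed at t first
        # acts on the step to t+dt), so a delay of k steps reads the buffer
        # k-1 positions back.
        history = np.tile(g0, (max_delay, 1))
        rng = np.random.default_rng(noise.seed)

        u_rec = np.empty((steps, n))
        g_rec = np.empty((steps, n))
        write = 0  # ring position holding g(t)
        for t in range(steps):
            syn = np.zeros(n)
            for k, mat in groups:
                syn += mat.dot(history[(write - (k - 1)) % max_delay])
            xi = (
                noise.sd * np.sqrt(dt) * rng.standard_normal(n)
                if noise.sd > 0
                else 0.0
            )
            u = u + dt * (-u / self.tau + syn + external[t]) + xi
            if not np.all(np.isfinite(u)):
                bad = int(np.nonzero(~np.isfinite(u))[0][0])
                raise IntegrationError(
                    f"non-finite potential at step {t} (unit {bad})", step=t
                )
            g = gain(u, self.q, self.c)
            write = (write + 1) % max_delay
            history[write] = g
            u_rec[t] = u
            g_rec[t] = g

        return TrialTrace(
            time_ms=(np.arange(steps) + 1) * dt,
            u=u_rec,
            g=g_rec,
            external=external,
            config=config,
        )
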