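"""Two-timescale session loop: expert observation, trial dynamics, learning.

A session is a sequence of observation trials.  Within each trial the
three-sheet network (OFC, LPFC, ACC) integrates its delayed rate dynamics
for one second of model time while the observed action's cell assemblies
(and the expert's LPFC assembly) receive a constant drive; the outcome is
presented part-way through the trial.  Across trials the loop closes:

1. the expert's action and outcome are drawn (repeat-action probability =
   consistency; reward probability = competence);
2. predicted option values are read from the OFC/LPFC assemblies before the
   outcome is shown;
3. the within-trial dynamics run with the observed action/outcome as drive;
4. actual values are read after outcome onset and compared in the ACC,
   yielding emotional (action) and rational (outcome) prediction errors;
5. the action-outcome symbol stream updates the dynamic Bayesian
   predictability estimate and, through it, trust beta;
6. the arousal gains follow trust (the rational gain directly, the
   emotional gain with a configured lag);
7. the trust-modulated Hebbian update is applied with the new beta.

With zero noise and a fixed seed the whole session is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import __version__ as _version
from .calibration import DEFAULT_CALIBRATION, Calibration
from .errors import ConfigurationError, InsufficientDataError, ParameterError
from .network import (
    ConnectionMatrix,
    Drive,
    IntegrationConfig,
    Network,
    NetworkParams,
    NoiseSpec,
    add_bundle,
    build_geometry,
    init_weights,
)
from .plasticity import PlasticityParams, trial_plasticity
from .trust import (
    ObservationSequence,
    TrustState,
    dbp_next_reward,
    estimate_transitions,
    trust_to_gain,
    update_trust,
)
from .valuation import (
    CellAssembly,
    assembly_energy,
    assembly_weight,
    integrate_values,
    option_value,
    prediction_errors,
    select_option,
)

EXPERT = "expert"
DEFAULT_OPTIONS = ("car", "public_transport", "bike")


@dataclass(frozen=True)
class OptionSpec:
    """One decision option with its initial emotional and rational value."""

    name: str
    v_emo: float
    v_rat: float

    def __post_init__(self):
        if self.v_emo < 0 or self.v_rat < 0:
            raise ParameterError("initial option values must be >= 0")


@dataclass(frozen=True)
class ExpertProfile:
    """Behavioural profile of the observed expert."""

    consistency: float = 0.95  # probability of repeating the previous action
    competence: float = 1.0  # probability of a rewarding outcome
    preferred_action: str = "public_transport"

    def __post_init__(self):
        for name in ("consistency", "competence"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class ObserverProfile:
    """Initial arousal gains and prior bias toward the expert."""

    q_emo: float = 6.0
    q_rat: float = 6.0
    prior_bias: float = 0.0  # additive increment on expert-assembly weights


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a simulated observation session.

    Defaults encode the transport scenario: an emotionally car-leaning
    observer (initial emotional values 0.2 / 0.1 / 0.08 for car, public
    transport, bike; rational values 0.1 / 0.2 / 0.05) watching a highly
    consistent, competent expert who takes public transport, with initial
    trust 0.7.
    """

    options: tuple[OptionSpec, ...] = (
        OptionSpec("car", v_emo=0.2, v_rat=0.1),
        OptionSpec("public_transport", v_emo=0.1, v_rat=0.2),
        OptionSpec("bike", v_emo=0.08, v_rat=0.05),
    )
    expert: ExpertProfile = field(default_factory=ExpertProfile)
    observer: ObserverProfile = field(default_factory=ObserverProfile)
    beta0: float = 0.7
    n_trials: int = 100
    seed: int = 0
    noise_sd: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.beta0 <= 1.0:
            raise ParameterError("beta0 must lie in [0, 1]")
        if self.n_trials < 0:
            raise ParameterError("n_trials must be >= 0")

    @property
    def option_names(self) -> tuple[str, ...]:
        return tuple(opt.name for opt in self.options)


@dataclass(frozen=True)
class TrialRecord:
    """Everything recorded after one completed observation trial."""

    trial: int
    action: str
    rewarded: bool
    dbp: float
    beta: float
    q_emo: float
    q_rat: float
    w_emo: np.ndarray  # mean OFC assembly weight per option
    w_rat: np.ndarray  # mean LPFC assembly weight per option
    w_rat_expert: float
    f_emo: np.ndarray  # dominant frequency per option (OFC), Hz
    f_rat: np.ndarray
    f_rat_expert: float
    v_emo: np.ndarray
    v_rat: np.ndarray
    v_final: np.ndarray
    pe_action: float
    pe_outcome: float
    choice: str


@dataclass
class SimulationResult:
    """Ordered trial records plus provenance (config echo, seed, version)."""

    records: list[TrialRecord]
    final_weights: dict[str, float]
    config: dict
    seed: int
    version: str = _version

    @property
    def n_trials(self) -> int:
        return len(self.records)


def generate_expert_sequence(
    consistency: float,
    competence: float,
    n_trials: int,
    seed: int,
    options: tuple[str, ...] = DEFAULT_OPTIONS,
    initial_action: str = "public_transport",
) -> ObservationSequence:
    """Draw the expert's action-outcome stream.

    The first trial takes ``initial_action``; every later trial repeats the
    previous action with probability ``consistency`` and otherwise switches
    uniformly among the remaining options.  Outcomes are rewarded
    independently with probability ``competence``.
    """
    if not 0.0 <= consistency <= 1.0 or not 0.0 <= competence <= 1.0:
        raise ParameterError("consistency and competence must lie in [0, 1]")
    if initial_action not in options:
        raise ConfigurationError(f"initial action {initial_action!r} not in options")
    rng = np.random.default_rng(seed)
    actions: list[str] = []
    current = initial_action
    for _ in range(n_trials):
        if actions and rng.random() >= consistency:
            others = [o for o in options if o != current]
            current = others[rng.integers(len(others))]
        actions.append(current)
    rewarded = tuple(bool(r) for r in rng.random(n_trials) < competence)
    return ObservationSequence(actions=tuple(actions), rewarded=rewarded)


def _assembly_blocks(side: int, assembly_size: int, n_assemblies: int):
    """Contiguous rectangular blocks of grid coordinates, row-major."""
    # block shape: (side // 2) rows x (assembly_size // (side // 2)) cols
    rows = side // 2
    cols = assembly_size // rows
    if rows * cols != assembly_size:
        raise ConfigurationError(
            f"assembly size {assembly_size} does not tile the {side}x{side} grid"
        )
    blocks = []
    per_band = side // cols  # assemblies per band of `rows` grid rows
    for k in range(n_assemblies):
        band, slot = divmod(k, per_band)
        r0, c0 = band * rows, slot * cols
        if r0 + rows > side:
            raise ConfigurationError("too many assemblies for the excitatory grid")
        members = [(r0 + r) * side + (c0 + c) for r in range(rows) for c in range(cols)]
        blocks.append(np.array(members, dtype=int))
    return blocks


def build_scenario_network(
    scenario: ScenarioConfig,
    calibration: Calibration = DEFAULT_CALIBRATION,
    seed: int | None = None,
    network: NetworkParams = NetworkParams(),
) -> tuple[Network, dict[tuple[str, str], CellAssembly]]:
    """Build the three-sheet network and tag the scenario's cell assemblies.

    Assemblies are contiguous excitatory blocks: one per option in OFC,
    LPFC and ACC, plus the expert assembly in LPFC.  Inter-structure
    excitatory bundles wire LPFC -> OFC per option and both structures
    bidirectionally to ACC.  Initial intra-assembly weights are rescaled so
    each assembly's mean plastic weight encodes the scenario's initial
    value for that option (and ``beta0`` + prior bias for the expert).
    """
    seed = scenario.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    w_seed, b_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    geometry = build_geometry(
        n_excitatory=network.n_excitatory,
        n_inhibitory=network.n_inhibitory,
        spacing=network.spacing,
    )
    connections = init_weights(
        geometry,
        lambda_ee=network.lambda_ee,
        lambda_ei=network.lambda_ei,
        w_max=network.w_max,
        seed=w_seed,
        scales=calibration.scales,
        t_syn=network.t_syn,
        v_ee=network.v_ee,
    )
    net = Network(
        geometry,
        connections,
        layer_params=network.layer_params,
        gains={
            "OFC": scenario.observer.q_emo,
            "LPFC": scenario.observer.q_rat,
            "ACC": calibration.q_acc,
        },
    )

    names = scenario.option_names
    side = int(round(np.sqrt(np.sum(geometry.units(structure="OFC", layer="exc") >= 0))))
    assemblies: dict[tuple[str, str], CellAssembly] = {}
    for structure in geometry.structures:
        exc = geometry.units(structure=structure, layer="exc")
        side = int(round(np.sqrt(len(exc))))
        labels = names + ((EXPERT,) if structure == "LPFC" else ())
        blocks = _assembly_blocks(side, calibration.assembly_size, len(labels))
        for label, block in zip(labels, blocks):
            assemblies[(structure, label)] = CellAssembly(
                label=label, structure=structure, members=exc[block]
            )

    # homeostatic balancing: each feedback interneuron samples every tagged
    # group of excitatory units with the same total afferent load
    group_map: dict[str, list[np.ndarray]] = {}
    for structure in geometry.structures:
        exc = geometry.units(structure=structure, layer="exc")
        tagged = [
            asm.members for (s, _), asm in assemblies.items() if s == structure
        ]
        rest = np.setdiff1d(exc, np.concatenate(tagged))
        group_map[structure] = tagged + ([rest] if len(rest) else [])
    _balance_interneuron_afferents(
        connections, geometry, group_map, calibration.scales.e_fbi
    )

    # inter-structure excitatory bundles (LPFC -> OFC; OFC <-> ACC; LPFC <-> ACC)
    routes = []
    for name in names:
        routes.append((("LPFC", name), ("OFC", name)))
        routes.append((("OFC", name), ("ACC", name)))
        routes.append((("ACC", name), ("OFC", name)))
        routes.append((("LPFC", name), ("ACC", name)))
        routes.append((("ACC", name), ("LPFC", name)))
    rng = np.random.default_rng(b_seed)
    for src, dst in routes:
        add_bundle(
            connections,
            assemblies[src].members,
            assemblies[dst].members,
            scale=calibration.scales.inter,
            seed=int(rng.integers(2**31)),
            plastic=False,
        )

    # encode initial preferences and trust in the assembly weights
    for opt in scenario.options:
        _set_assembly_mean_weight(connections, assemblies[("OFC", opt.name)], opt.v_emo)
        _set_assembly_mean_weight(connections, assemblies[("LPFC", opt.name)], opt.v_rat)
    _set_assembly_mean_weight(
        connections,
        assemblies[("LPFC", EXPERT)],
        scenario.beta0 + scenario.observer.prior_bias,
    )
    return net, assemblies


def _set_assembly_mean_weight(
    connections: ConnectionMatrix, assembly: CellAssembly, target: float
) -> None:
    """Scale each member's intra-assembly afferents so its row mean is ``target``.

    Per-neuron synaptic scaling: the relative strengths within a row keep
    their random draw, but every unit starts from the same mean afferent
    weight, which encodes the assembly's initial value homogeneously.
    """
    idx = np.asarray(assembly.members)
    block = np.ix_(idx, idx)
    w = connections.weights[block]
    row_mean = w.sum(axis=1) / np.maximum(w.shape[1] - 1, 1)  # no self-connections
    scale = np.where(row_mean > 0, target / np.where(row_mean > 0, row_mean, 1.0), 1.0)
    connections.weights[block] = w * scale[:, None]


def _balance_interneuron_afferents(
    connections: ConnectionMatrix,
    geometry,
    groups: dict[str, list[np.ndarray]],
    load: float,
) -> None:
    """Equalize each feedback interneuron's afferent load per assembly group.

    Every feedback inhibitory unit ends up sampling each tagged group of
    excitatory units with the same total effective weight (proportional to
    group size), so the inhibitory field tracks assembly activity uniformly
    regardless of the random draw.
    """
    for structure, blocks in groups.items():
        fbi = geometry.units(structure=structure, layer="fb_inh")
        n_exc = sum(len(b) for b in blocks)
        for members in blocks:
            target = load * len(members) / n_exc
            blk = np.ix_(fbi, members)
            eff = (connections.weights[blk] * connections.coupling[blk]).sum(axis=1)
            factor = np.where(eff > 0, target / np.where(eff > 0, eff, 1.0), 1.0)
            connections.coupling[blk] *= factor[:, None]


def _structure_mask(net: Network, structure: str) -> np.ndarray:
    units = np.zeros(net.geometry.n_units, dtype=bool)
    units[net.geometry.units(structure=structure)] = True
    return units[:, None] & units[None, :]


def run_session(
    scenario: ScenarioConfig,
    calibration: Calibration = DEFAULT_CALIBRATION,
    network: NetworkParams = NetworkParams(),
    instrumentation: Callable[[int, float], None] | None = None,
) -> SimulationResult:
    """Run a full observation session and return the per-trial records.

    ``instrumentation``, if given, is called as ``(trial, beta)`` with the
    trust value actually used by that trial's plasticity step (exposed for
    closed-loop consistency checks).
    """
    cal = calibration
    ss = np.random.SeedSequence(scenario.seed)
    net_seed, seq_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    net, assemblies = build_scenario_network(scenario, cal, seed=net_seed, network=network)
    names = scenario.option_names
    sequence = generate_expert_sequence(
        scenario.expert.consistency,
        scenario.expert.competence,
        scenario.n_trials,
        seed=seq_seed,
        options=names,
        initial_action=scenario.expert.preferred_action,
    )

    config = IntegrationConfig(
        dt=1.0, duration=cal.trial_ms, transient=cal.transient_ms
    )
    trust = TrustState(beta=scenario.beta0, eta=cal.eta)
    q_emo = float(scenario.observer.q_emo)
    q_rat = float(scenario.observer.q_rat)
    mask_emo = _structure_mask(net, "OFC")
    mask_rat = ~mask_emo

    ref = {"OFC": cal.reference_energy_emo, "LPFC": cal.reference_energy_rat}
    # last measured oscillatory energy per (structure, option); options not
    # currently attended retain the energy of their last activation, so an
    # unobserved option's value moves only through its stored weights
    e_state = {
        (s, n): ref[s] for s in ("OFC", "LPFC") for n in names
    }
    f_state = {(s, n): float("nan") for s in ("OFC", "LPFC") for n in names}

    records: list[TrialRecord] = []
    for t in range(scenario.n_trials):
        action = sequence.actions[t]
        rewarded = sequence.rewarded[t]

        _apply_gains(net, q_emo, q_rat, cal)

        drives = _trial_drives(net, assemblies, names, action, rewarded, cal)
        noise = NoiseSpec(sd=scenario.noise_sd, seed=(scenario.seed + 7919 * (t + 1)) % (2**31))
        trace = net.run_trial(drives, config, noise=noise)

        predicted_win = trace.window(cal.transient_ms, cal.outcome_ms)
        actual_win = trace.window(cal.outcome_ms + cal.settle_ms, cal.trial_ms)

        # refresh the attended option's stored oscillatory energy
        a_idx = names.index(action)
        for structure in ("OFC", "LPFC"):
            e = assembly_energy(trace, assemblies[(structure, action)], window=actual_win)
            if e.defined:
                e_state[(structure, action)] = e.energy
                f_state[(structure, action)] = e.frequency

        w_emo = np.array(
            [assembly_weight(net.connections, assemblies[("OFC", n)]) for n in names]
        )
        w_rat = np.array(
            [assembly_weight(net.connections, assemblies[("LPFC", n)]) for n in names]
        )
        v_emo = np.array(
            [
                option_value(w, e_state[("OFC", n)], ref["OFC"])
                for w, n in zip(w_emo, names)
            ]
        )
        v_rat = np.array(
            [
                option_value(w, e_state[("LPFC", n)], ref["LPFC"])
                for w, n in zip(w_rat, names)
            ]
        )
        v_final = integrate_values(v_emo, v_rat)

        # ACC prediction errors for the observed action: pre- vs post-outcome
        pred_emo = assembly_energy(trace, assemblies[("OFC", action)], window=predicted_win)
        pred_rat = assembly_energy(trace, assemblies[("LPFC", action)], window=predicted_win)
        pe = prediction_errors(
            predicted=(
                option_value(w_emo[a_idx], pred_emo.energy, ref["OFC"]),
                option_value(w_rat[a_idx], pred_rat.energy, ref["LPFC"]),
            ),
            actual=(v_emo[a_idx], v_rat[a_idx]),
        )

        # trust update from the observed action-outcome symbol stream
        prefix = sequence.prefix(t + 1)
        model = estimate_transitions(prefix, smoothing=1.0)
        dbp = dbp_next_reward(prefix, model)
        trust = update_trust(trust, dbp)

        # gains follow trust: rational directly, emotional with a lag
        q_rat = trust_to_gain(trust.beta, *cal.q_rat_map)
        q_emo_target = trust_to_gain(trust.beta, *cal.q_emo_map)
        q_emo = q_emo + cal.q_emo_rate * (q_emo_target - q_emo)

        # plasticity with the freshly updated trust
        if instrumentation is not None:
            instrumentation(t + 1, trust.beta)
        net.connections = trial_plasticity(
            trace,
            net.connections,
            PlasticityParams(alpha=cal.alpha_emo, w_max=cal.w_max_emo),
            trust.beta,
            mask=mask_emo,
        )
        net.connections = trial_plasticity(
            trace,
            net.connections,
            PlasticityParams(alpha=cal.alpha, w_max=cal.w_max_rat),
            trust.beta,
            mask=mask_rat,
        )

        exp_asm = assemblies[("LPFC", EXPERT)]
        exp_energy = assembly_energy(trace, exp_asm, window=actual_win)
        records.append(
            TrialRecord(
                trial=t + 1,
                action=action,
                rewarded=rewarded,
                dbp=dbp,
                beta=trust.beta,
                q_emo=q_emo,
                q_rat=q_rat,
                w_emo=w_emo,
                w_rat=w_rat,
                w_rat_expert=assembly_weight(net.connections, exp_asm),
                f_emo=np.array([f_state[("OFC", n)] for n in names]),
                f_rat=np.array([f_state[("LPFC", n)] for n in names]),
                f_rat_expert=exp_energy.frequency,
                v_emo=v_emo,
                v_rat=v_rat,
                v_final=v_final,
                pe_action=pe.action,
                pe_outcome=pe.outcome,
                choice=select_option(v_final, names),
            )
        )

    final_weights = {
        f"w_{'emo' if s == 'OFC' else 'rat'}_{label}": assembly_weight(net.connections, asm)
        for (s, label), asm in assemblies.items()
        if s != "ACC"
    }
    return SimulationResult(
        records=records,
        final_weights=final_weights,
        config=_echo_config(scenario, cal, network),
        seed=scenario.seed,
    )


def _apply_gains(net: Network, q_emo: float, q_rat: float, cal: Calibration) -> None:
    """Arousal acts on the principal (excitatory) units of each structure;
    inhibitory interneurons keep the fixed reference excitability."""
    geo = net.geometry
    net.set_gain(cal.q_inh)
    net.set_gain(q_emo, units=geo.units(structure="OFC", layer="exc"))
    net.set_gain(q_rat, units=geo.units(structure="LPFC", layer="exc"))
    net.set_gain(cal.q_acc, units=geo.units(structure="ACC", layer="exc"))


def _trial_drives(net, assemblies, names, action, rewarded, cal: Calibration) -> list[Drive]:
    drives = []
    for structure in ("OFC", "LPFC"):
        for name in names:
            drives.append(
                Drive(assemblies[(structure, name)].members, cal.probe_amplitude)
            )
        drives.append(Drive(assemblies[(structure, action)].members, cal.drive_amplitude))
        if cal.ffi_drive_ratio > 0:
            drives.append(
                Drive(
                    net.geometry.units(structure=structure, layer="ff_inh"),
                    cal.ffi_drive_ratio * cal.drive_amplitude,
                )
            )
    # the expert's assembly is engaged on the same footing as the observed
    # action's (probe + drive), keeping the two driven groups symmetric
    drives.append(
        Drive(
            assemblies[("LPFC", EXPERT)].members,
            cal.drive_amplitude + cal.probe_amplitude,
        )
    )
    if rewarded:
        for target in (("OFC", action), ("LPFC", action), ("LPFC", EXPERT)):
            drives.append(
                Drive(
                    assemblies[target].members,
                    cal.outcome_amplitude,
                    t_on=cal.outcome_ms,
                )
            )
    return drives


def _echo_config(
    scenario: ScenarioConfig, cal: Calibration, network: NetworkParams
) -> dict:
    from dataclasses import asdict

    def plain(node):
        # YAML/JSON-normal form: tuples become lists
        if isinstance(node, dict):
            return {k: plain(v) for k, v in node.items()}
        if isinstance(node, (list, tuple)):
            return [plain(v) for v in node]
        return node

    return plain(
        {
            "scenario": asdict(scenario),
            "calibration": asdict(cal),
            "network": asdict(network),
        }
    )


def expert_gain_frequency(
    q: float,
    calibration: Calibration = DEFAULT_CALIBRATION,
    scenario: ScenarioConfig | None = None,
    seed: int = 0,
    network: NetworkParams = NetworkParams(),
) -> float:
    """Dominant frequency (Hz) of the expert's LPFC assembly at a fixed gain.

    Builds the default network, sets the LPFC gain to ``q``, drives the
    expert assembly with the calibrated constant input for one trial and
    returns the periodogram peak of the assembly-mean activation over the
    post-transient window.  This is the gain -> frequency readout behind the
    trust <-> oscillation mapping.
    """
    from .spectral import dominant_frequency
    from .valuation import assembly_mean_signal

    scenario = scenario if scenario is not None else ScenarioConfig(seed=seed)
    net, assemblies = build_scenario_network(scenario, calibration, seed=seed, network=network)
    _apply_gains(net, scenario.observer.q_emo, q, calibration)
    config = IntegrationConfig(
        dt=1.0, duration=calibration.trial_ms, transient=calibration.transient_ms
    )
    exp_asm = assemblies[("LPFC", EXPERT)]
    drives = [Drive(exp_asm.members, calibration.drive_amplitude)]
    if calibration.ffi_drive_ratio > 0:
        drives.append(
            Drive(
                net.geometry.units(structure="LPFC", layer="ff_inh"),
                calibration.ffi_drive_ratio * calibration.drive_amplitude,
            )
        )
    trace = net.run_trial(drives, config)
    window = trace.window(calibration.transient_ms, calibration.trial_ms)
    signal = assembly_mean_signal(trace, exp_asm, window)
    return dominant_frequency(signal, fs=1000.0 / config.dt)


def steady_state_trial(series, eps: float, k: int = 5):
    """First trial at which a learning curve has settled, or ``None``.

    Returns the earliest (1-based) trial index ``t`` such that the absolute
    per-trial change stays below ``eps`` for ``k`` consecutive steps
    starting at ``t`` (i.e. ``|x_s - x_{s-1}| < eps`` for s = t .. t+k-1).
    """
    if eps <= 0:
        raise ParameterError("eps must be > 0")
    if k < 1:
        raise ParameterError("k must be >= 1")
    x = np.asarray(series, dtype=float)
    if len(x) < k + 1:
        raise InsufficientDataError(
            f"series of length {len(x)} is too short for k={k}"
        )
    small = np.abs(np.diff(x)) < eps
    for t in range(len(small) - k + 1):
        if small[t : t + k].all():
            return t + 1
    return None
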