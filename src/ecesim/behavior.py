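"""Sensorimotor network semantics and the fitness-evaluator contract.

Fitness is the straight-line Euclidean displacement an individual achieves in
a fixed 501-step locomotion trial. Joint angles are the network's response to
touch-sensor input, squashed into [-pi, pi]. The quantitative displacement a
physics engine would report is engine-dependent; the package therefore treats
the evaluator as a plug-in contract. The default backend is a deterministic
surrogate: a documented closed-form score (not a physics result) with the
qualitative structure selection needs — it rewards sensor-driven motorized
joints, peaks at moderate body sizes, and varies smoothly with part
properties. An adapter base class is provided for wiring in an external
rigid-body engine.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .assembly import AbortResult, MorphologyGraph, check_viability

__all__ = [
    "SensorimotorNetwork", "TrialResult", "compile_network", "joint_command",
    "Evaluator", "SurrogateEvaluator", "ConstantFitnessEvaluator",
    "PhysicsAdapter", "evaluate", "DEFAULT_STEPS", "get_evaluator",
]

DEFAULT_STEPS = 501


@dataclass
class SensorimotorNetwork:
    """Compiled wiring: sensor gains, neuron biases, weighted directed wires,
    and the motorized joints that act as outputs."""

    sensor_gains: np.ndarray
    neuron_biases: np.ndarray
    motor_joints: list[int]
    # wires as (source kind, source idx, target kind ('neuron'|'joint'),
    # target idx, weight)
    wires: list[tuple[str, int, str, int, float]]


@dataclass(frozen=True)
class TrialResult:
    fitness: float
    steps_run: int
    evaluator_id: str
    aborted: bool = False

    def __post_init__(self):
        if self.fitness < 0:
            raise ValueError("fitness must be non-negative")
        if self.aborted and self.fitness != 0.0:
            raise ValueError("aborted individuals score exactly 0")


def compile_network(m: MorphologyGraph) -> SensorimotorNetwork:
    return SensorimotorNetwork(
        sensor_gains=np.array([s["part"].properties.get("gain", 1.0)
                               for s in m.sensors], dtype=float),
        neuron_biases=np.array([n["part"].properties.get("bias", 0.0)
                                for n in m.neurons], dtype=float),
        motor_joints=m.motorized_joints(),
        wires=[(w["source"][0], w["source"][1], w["target"][0], w["target"][1],
                w["part"].properties.get("weight", 0.0)) for w in m.wires],
    )


def joint_command(network: SensorimotorNetwork, sensor_inputs: np.ndarray,
                  prev_neuron_out: np.ndarray | None = None
                  ) -> tuple[dict[int, float], np.ndarray]:
    """One synchronous network update.

    Each neuron outputs tanh(weighted input sum + bias), with neuron->neuron
    wires reading the previous step's activations; each motorized joint's
    commanded angle is pi * tanh(sum of its weighted inputs), guaranteed in
    [-pi, pi]. Returns ({joint index: angle}, neuron outputs).
    """
    n_neurons = network.neuron_biases.size
    sensor_out = network.sensor_gains * np.asarray(sensor_inputs, dtype=float)
    prev = (np.zeros(n_neurons) if prev_neuron_out is None
            else np.asarray(prev_neuron_out, dtype=float))
    net_in = network.neuron_biases.copy()
    for src_kind, s, tgt_kind, t, w in network.wires:
        if tgt_kind == "neuron":
            net_in[t] += w * (sensor_out[s] if src_kind == "sensor" else prev[s])
    neuron_out = np.tanh(net_in)
    angles = {j: 0.0 for j in network.motor_joints}
    sums = {j: 0.0 for j in network.motor_joints}
    for src_kind, s, tgt_kind, t, w in network.wires:
        if tgt_kind == "joint" and t in sums:
            sums[t] += w * (sensor_out[s] if src_kind == "sensor"
                            else neuron_out[s])
    for j in sums:
        angles[j] = math.pi * math.tanh(sums[j])
    return angles, neuron_out


class Evaluator:
    """Plug-in contract: name, determinism flag, evaluate(...)->TrialResult."""

    name: str = "abstract"
    deterministic: bool = True
    requires_development: bool = True

    def evaluate(self, morphology: MorphologyGraph, network: SensorimotorNetwork,
                 steps: int, seed: int | None = None) -> TrialResult:
        raise NotImplementedError


def _sensor_driven_motors(m: MorphologyGraph,
                          network: SensorimotorNetwork) -> list[int]:
    """Motorized joints reachable from some sensor through the wiring."""
    adj: dict[tuple, list[tuple]] = {}
    for src_kind, s, tgt_kind, t, _w in network.wires:
        adj.setdefault((src_kind, s), []).append((tgt_kind, t))
    frontier = [("sensor", i) for i in range(len(m.sensors))]
    seen = set(frontier)
    driven = set()
    while frontier:
        node = frontier.pop()
        if node[0] == "joint":
            driven.add(node[1])
        for nxt in adj.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return sorted(d for d in driven if d in set(network.motor_joints))


class SurrogateEvaluator(Evaluator):
    """Deterministic closed-form locomotion score (explicitly not physics).

    score = (steps/501) * 100 * drive * body * sense, where
      drive = sum over sensor-driven motorized joints j of
              strength_j * (1 + tanh(sum of |w| over wires into j)),
      body  = n * exp(1 - n/4) / 4 for n spheres (peaks at 4, penalizing
              very segmented bodies),
      sense = 1 + tanh(mean sensor gain).
    Zero when no motorized joint is sensor-driven; symmetric under part
    relabeling; smooth in all part properties.
    """

    name = "surrogate"
    deterministic = True

    def evaluate(self, morphology, network, steps=DEFAULT_STEPS, seed=None):
        driven = _sensor_driven_motors(morphology, network)
        if not driven or steps <= 0:
            return TrialResult(0.0, max(int(steps), 0), self.name)
        strengths = {j: morphology.joints[j]["part"].properties
                     .get("motor_strength", 0.0) for j in driven}
        in_weight = {j: 0.0 for j in driven}
        for _sk, _s, tk, t, w in network.wires:
            if tk == "joint" and t in in_weight:
                in_weight[t] += abs(w)
        drive = sum(strengths[j] * (1.0 + math.tanh(in_weight[j]))
                    for j in driven)
        n = len(morphology.spheres)
        body = n * math.exp(1.0 - n / 4.0) / 4.0
        gains = network.sensor_gains
        sense = 1.0 + math.tanh(float(gains.mean())) if gains.size else 1.0
        score = (steps / DEFAULT_STEPS) * 100.0 * drive * body * sense
        return TrialResult(max(score, 0.0), int(steps), self.name)


class ConstantFitnessEvaluator(Evaluator):
    """Assigns every individual the same fitness.

    Useful for neutral-evolution studies where selection must be inert; since
    fitness ignores the phenotype, the generational loop may skip development
    entirely (requires_development is False).
    """

    name = "constant"
    deterministic = True
    requires_development = False

    def __init__(self, value: float = 1.0):
        self.value = float(value)

    def evaluate(self, morphology, network, steps=DEFAULT_STEPS, seed=None):
        return TrialResult(self.value, int(steps), self.name)


class PhysicsAdapter(Evaluator):
    """Adapter interface for an external rigid-body engine.

    Subclasses implement init_world/step/read_positions; fitness is the
    Euclidean distance between the body's initial and final reference
    positions after `steps` updates on a flat, dry, empty plane.
    """

    name = "physics"
    deterministic = False

    def init_world(self, morphology, network, seed):
        raise NotImplementedError("bind an external physics engine")

    def step(self):
        raise NotImplementedError

    def read_position(self) -> np.ndarray:
        raise NotImplementedError

    def evaluate(self, morphology, network, steps=DEFAULT_STEPS, seed=None):
        self.init_world(morphology, network, seed)
        start = np.asarray(self.read_position(), dtype=float)
        for _ in range(int(steps)):
            self.step()
        end = np.asarray(self.read_position(), dtype=float)
        return TrialResult(float(np.linalg.norm(end - start)), int(steps),
                           self.name)


_EVALUATORS = {"surrogate": SurrogateEvaluator, "physics": PhysicsAdapter,
               "constant": ConstantFitnessEvaluator}


def get_evaluator(name: str) -> Evaluator:
    try:
        return _EVALUATORS[name]()
    except KeyError:
        raise ValueError(f"unknown evaluator {name!r}; "
                         f"choose from {sorted(_EVALUATORS)}") from None


def evaluate(morphology: MorphologyGraph | AbortResult,
             network: SensorimotorNetwork | None,
             evaluator: Evaluator, steps: int = DEFAULT_STEPS,
             seed: int | None = None) -> TrialResult:
    """Score one developed individual; aborted/non-viable bodies score 0
    without invoking the backend."""
    if isinstance(morphology, AbortResult) or not check_viability(morphology):
        return TrialResult(0.0, 0, evaluator.name, aborted=True)
    return evaluator.evaluate(morphology, network, steps, seed)
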