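"""Late development: grow protoparts into finished parts, queue them in
completion order, and assemble the body by fixed three-step rules.

Growth is additive: each part property starts at a documented base value and
every matching '+' / '-' property transcript in the gene's regulatory pool
shifts it by one unit increment (floored at the property minimum). Finished
parts enter per-kind FIFO pools ordered by completion cycle (gene index
breaks ties). Assembly then (1) connects spheres with joints into a tree,
(2) mounts neurons and sensors, (3) places wires between sensorimotor
connectors — all deterministic, so identical pools always give identical
bodies. Development aborts if fewer than two spheres can be connected; a body
whose wiring never links a sensor to a motorized joint is non-viable. Both
cases score fitness 0.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import yaml

from .expression import GeneExpressionState
from .genetics import PART_KINDS

__all__ = [
    "PropertySpec", "BodyPlan", "FinishedPart", "PartPools", "MorphologyGraph",
    "AbortResult", "grow_part", "build_part_pools", "assemble",
    "check_viability", "DEFAULT_BODY_PLAN",
]


@dataclass(frozen=True)
class PropertySpec:
    """Additive growth constants for one part property (design constants)."""

    base: float
    unit: float
    minimum: float | None = None


@dataclass(frozen=True)
class BodyPlan:
    """Growth constants and mount/connector capacities.

    The assembly rules reference mounts the source description never counts;
    these defaults (3 joint mounts, 4 sensor and 4 neuron mounts per sphere,
    2-way sensorimotor connectors) are versioned package constants.
    """

    properties: dict = field(default_factory=lambda: {
        ("sphere", "size"): PropertySpec(1.0, 0.1, 0.1),
        ("joint", "motor_strength"): PropertySpec(0.05, 0.1, 0.0),
        ("sensor", "gain"): PropertySpec(1.0, 0.1, 0.0),
        ("neuron", "bias"): PropertySpec(0.0, 0.1, -5.0),
        ("wire", "weight"): PropertySpec(0.5, 0.1, -3.0),
    })
    joint_mounts_per_sphere: int = 3
    sensor_mounts_per_sphere: int = 4
    neuron_mounts_per_sphere: int = 4
    sensor_out_connectors: int = 2
    neuron_in_connectors: int = 1
    neuron_out_connectors: int = 2
    motor_in_connectors: int = 2

    def properties_of(self, kind: str) -> dict[str, PropertySpec]:
        return {prop: spec for (k, prop), spec in self.properties.items()
                if k == kind}


DEFAULT_BODY_PLAN = BodyPlan()


@dataclass
class FinishedPart:
    kind: str
    properties: dict[str, float]
    completion_cycle: int
    gene_index: int

    def __post_init__(self):
        if self.kind not in PART_KINDS:
            raise ValueError(f"unknown part kind {self.kind!r}")


@dataclass
class PartPools:
    """Per-kind FIFO queues of finished parts, in completion order."""

    spheres: deque = field(default_factory=deque)
    joints: deque = field(default_factory=deque)
    sensors: deque = field(default_factory=deque)
    neurons: deque = field(default_factory=deque)
    wires: deque = field(default_factory=deque)

    def of(self, kind: str) -> deque:
        return getattr(self, kind + "s")

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(self.of(k)) for k in PART_KINDS}


@dataclass(frozen=True)
class AbortResult:
    """Development abort — a value, not an exception. Fitness is 0."""

    reason: str


@dataclass
class MorphologyGraph:
    """Assembled body: sphere tree, mounted sensors/neurons, wiring.

    Wire endpoints are (kind, index) pairs; joints are edges between sphere
    indices; sensors and neurons record their host sphere.
    """

    spheres: list[FinishedPart] = field(default_factory=list)
    joints: list[dict] = field(default_factory=list)     # part, a, b, motorized
    sensors: list[dict] = field(default_factory=list)    # part, sphere
    neurons: list[dict] = field(default_factory=list)    # part, sphere
    wires: list[dict] = field(default_factory=list)      # part, source, target

    @property
    def counts(self) -> dict[str, int]:
        return {"sphere": len(self.spheres), "joint": len(self.joints),
                "sensor": len(self.sensors), "neuron": len(self.neurons),
                "wire": len(self.wires)}

    def motorized_joints(self) -> list[int]:
        return [i for i, j in enumerate(self.joints) if j["motorized"]]

    # structured-text serialization (enough to reconstruct / feed an engine)
    def to_dict(self) -> dict:
        def part(p: FinishedPart):
            return {"kind": p.kind, "properties": dict(p.properties),
                    "completion_cycle": p.completion_cycle,
                    "gene_index": p.gene_index}
        return {
            "spheres": [part(s) for s in self.spheres],
            "joints": [{"part": part(j["part"]), "a": j["a"], "b": j["b"],
                        "motorized": bool(j["motorized"])} for j in self.joints],
            "sensors": [{"part": part(s["part"]), "sphere": s["sphere"]}
                        for s in self.sensors],
            "neurons": [{"part": part(n["part"]), "sphere": n["sphere"]}
                        for n in self.neurons],
            "wires": [{"part": part(w["part"]), "source": list(w["source"]),
                       "target": list(w["target"])} for w in self.wires],
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "MorphologyGraph":
        def part(e):
            return FinishedPart(e["kind"], dict(e["properties"]),
                                int(e["completion_cycle"]), int(e["gene_index"]))
        m = cls()
        m.spheres = [part(e) for e in d["spheres"]]
        m.joints = [{"part": part(e["part"]), "a": int(e["a"]), "b": int(e["b"]),
                     "motorized": bool(e["motorized"])} for e in d["joints"]]
        m.sensors = [{"part": part(e["part"]), "sphere": int(e["sphere"])}
                     for e in d["sensors"]]
        m.neurons = [{"part": part(e["part"]), "sphere": int(e["sphere"])}
                     for e in d["neurons"]]
        m.wires = [{"part": part(e["part"]), "source": tuple(e["source"]),
                    "target": tuple(e["target"])} for e in d["wires"]]
        return m

    @classmethod
    def from_yaml(cls, text: str) -> "MorphologyGraph":
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def grow_part(state: GeneExpressionState,
              plan: BodyPlan = DEFAULT_BODY_PLAN) -> FinishedPart | None:
    """Grow a gene's protopart using its accumulated property transcripts.

    value(p) = base(p) + unit(p) * (#'+' - #'-') over feature transcripts
    matching this part's kind and property p; floored at the property minimum.
    Transcripts targeting other kinds are inert here. Returns None when the
    gene expressed no protopart.
    """
    if state.protopart is None:
        return None
    kind = state.protopart.part_kind
    props = {}
    for prop, spec in plan.properties_of(kind).items():
        net = 0
        for t in state.regulatory_pool:
            if (t.role_category == "feature" and t.feature_target_kind == kind
                    and t.feature_property == prop):
                net += 1 if t.feature_sign == "+" else -1
        value = spec.base + spec.unit * net
        if spec.minimum is not None:
            value = max(value, spec.minimum)
        props[prop] = value
    return FinishedPart(kind, props, state.last_emission_cycle, state.gene_index)


def build_part_pools(states: list[GeneExpressionState],
                     plan: BodyPlan = DEFAULT_BODY_PLAN) -> PartPools:
    """Grow all parts and queue them FIFO by (completion_cycle, gene_index)."""
    parts = [p for p in (grow_part(s, plan) for s in states) if p is not None]
    parts.sort(key=lambda p: (p.completion_cycle, p.gene_index))
    pools = PartPools()
    for p in parts:
        pools.of(p.kind).append(p)
    return pools


def assemble(pools: PartPools,
             plan: BodyPlan = DEFAULT_BODY_PLAN) -> MorphologyGraph | AbortResult:
    """Three-step deterministic assembly; abort if <2 spheres connect.

    Step 1: the first joint connects the first two spheres; each further joint
    connects the next unused sphere to the earliest body sphere with an open
    joint mount (tree-shaped, no multi-edges). Step 2: neurons then sensors
    attach FIFO to open mounts in sphere order. Step 3: each wire consumes the
    earliest legal open connector pair in the precedence sensor->neuron,
    neuron->neuron, neuron->motor, sensor->motor.
    """
    m = MorphologyGraph()
    spheres = deque(pools.spheres)
    joints = deque(pools.joints)

    # step 1: sphere-joint tree
    if len(spheres) < 2 or not joints:
        return AbortResult("fewer than two spheres could be connected")
    joint_slots: list[int] = []
    m.spheres.append(spheres.popleft())
    m.spheres.append(spheres.popleft())
    joint_slots = [plan.joint_mounts_per_sphere] * 2
    first = joints.popleft()
    m.joints.append({"part": first, "a": 0, "b": 1,
                     "motorized": first.properties.get("motor_strength", 0.0) > 0})
    joint_slots[0] -= 1
    joint_slots[1] -= 1
    while joints and spheres:
        host = next((i for i, s in enumerate(joint_slots) if s > 0), None)
        if host is None:
            break
        part = joints.popleft()
        new_sphere = spheres.popleft()
        m.spheres.append(new_sphere)
        joint_slots.append(plan.joint_mounts_per_sphere - 1)
        joint_slots[host] -= 1
        m.joints.append({"part": part, "a": host, "b": len(m.spheres) - 1,
                         "motorized": part.properties.get("motor_strength", 0.0) > 0})

    # step 2: neurons then sensors onto open mounts, in sphere order
    def mount(parts: deque, per_sphere: int, out: list):
        open_slots = [per_sphere] * len(m.spheres)
        for si in range(len(m.spheres)):
            while open_slots[si] > 0 and parts:
                out.append({"part": parts.popleft(), "sphere": si})
                open_slots[si] -= 1

    mount(deque(pools.neurons), plan.neuron_mounts_per_sphere, m.neurons)
    mount(deque(pools.sensors), plan.sensor_mounts_per_sphere, m.sensors)

    # step 3: wires by fixed endpoint precedence
    sensor_out = [plan.sensor_out_connectors] * len(m.sensors)
    neuron_in = [plan.neuron_in_connectors] * len(m.neurons)
    neuron_out = [plan.neuron_out_connectors] * len(m.neurons)
    motors = m.motorized_joints()
    motor_in = {j: plan.motor_in_connectors for j in motors}
    existing: set[tuple] = set()

    def find_pair(src_kind, tgt_kind):
        sources = (range(len(m.sensors)) if src_kind == "sensor"
                   else range(len(m.neurons)))
        src_cap = sensor_out if src_kind == "sensor" else neuron_out
        if tgt_kind == "neuron":
            targets, tgt_cap = range(len(m.neurons)), neuron_in
        else:
            targets, tgt_cap = motors, motor_in
        for s in sources:
            if src_cap[s] <= 0:
                continue
            for t in targets:
                if tgt_cap[t] <= 0:
                    continue
                if src_kind == tgt_kind == "neuron" and s == t:
                    continue
                key = ((src_kind, s), (tgt_kind if tgt_kind != "motor"
                                       else "joint", t))
                if key in existing:
                    continue
                return s, t, src_cap, tgt_cap, key
        return None

    precedence = [("sensor", "neuron"), ("neuron", "neuron"),
                  ("neuron", "motor"), ("sensor", "motor")]
    for wire in pools.wires:
        placed = None
        for src_kind, tgt_kind in precedence:
            placed = find_pair(src_kind, tgt_kind)
            if placed:
                break
        if not placed:
            break  # open connectors depleted; remaining wires stay unused
        s, t, src_cap, tgt_cap, key = placed
        src_cap[s] -= 1
        tgt_cap[t] -= 1
        existing.add(key)
        m.wires.append({"part": wire, "source": key[0], "target": key[1]})

    return m


def check_viability(m: MorphologyGraph | AbortResult) -> bool:
    """Viable iff assembled (>=2 connected spheres) and some sensor reaches a
    motorized joint through the directed wiring."""
    if isinstance(m, AbortResult):
        return False
    if len(m.spheres) < 2:
        return False
    motors = set(m.motorized_joints())
    if not motors or not m.sensors:
        return False
    adj: dict[tuple, list[tuple]] = {}
    for w in m.wires:
        adj.setdefault(w["source"], []).append(w["target"])
    frontier = [("sensor", i) for i in range(len(m.sensors))]
    seen = set(frontier)
    while frontier:
        node = frontier.pop()
        if node[0] == "joint" and node[1] in motors:
            return True
        for nxt in adj.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return False
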