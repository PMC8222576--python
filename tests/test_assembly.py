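"""Part growth, completion-ordered pools, three-step assembly, viability."""
import numpy as np
import pytest

from ecesim import (AbortResult, MorphologyGraph, assemble, build_part_pools,
                    check_viability, grow_part)
from ecesim.assembly import DEFAULT_BODY_PLAN, FinishedPart, PartPools
from ecesim.expression import GeneExpressionState, Transcript
from ecesim.genetics import GeneRegion


def feature_t(kind, prop, sign, cycle=1):
    return Transcript(0, 0, "000", "feature", cycle, feature_target_kind=kind,
                      feature_property=prop, feature_sign=sign)


def part_state(kind, transcripts=(), gene_index=0, last_cycle=0):
    s = GeneExpressionState(gene_index, GeneRegion(0, 2))
    s.protopart = Transcript(gene_index, 1, "010", "part", 0, part_kind=kind)
    s.regulatory_pool = list(transcripts)
    s.last_emission_cycle = last_cycle
    return s


def make_part(kind, gene_index=0, cycle=0, **props):
    base = {("sphere"): {"size": 1.0}, "joint": {"motor_strength": 0.0},
            "sensor": {"gain": 1.0}, "neuron": {"bias": 0.0},
            "wire": {"weight": 0.5}}[kind]
    base.update(props)
    return FinishedPart(kind, base, cycle, gene_index)


class TestGrowth:
    def test_additive_growth_with_documented_constants(self):
        ts = [feature_t("sphere", "size", "+")] * 10 + \
             [feature_t("sphere", "size", "-")] * 4
        part = grow_part(part_state("sphere", ts))
        assert part.properties["size"] == pytest.approx(1.6)

    def test_no_transcripts_gives_base_properties(self):
        part = grow_part(part_state("sphere"))
        assert part.properties["size"] == pytest.approx(1.0)

    def test_balanced_transcripts_cancel(self):
        ts = [feature_t("sensor", "gain", "+")] * 6 + \
             [feature_t("sensor", "gain", "-")] * 6
        part = grow_part(part_state("sensor", ts))
        assert part.properties["gain"] == pytest.approx(1.0)

    def test_property_floor(self):
        ts = [feature_t("sphere", "size", "-")] * 50
        part = grow_part(part_state("sphere", ts))
        assert part.properties["size"] == pytest.approx(0.1)

    def test_foreign_kind_transcripts_are_inert(self):
        ts = [feature_t("joint", "motor_strength", "+")] * 9
        part = grow_part(part_state("sphere", ts))
        assert part.properties["size"] == pytest.approx(1.0)

    def test_no_protopart_grows_nothing(self):
        s = GeneExpressionState(0, GeneRegion(0, 2))
        assert grow_part(s) is None


class TestPartPools:
    def test_fifo_by_completion_cycle(self):
        s1 = part_state("sphere", gene_index=0, last_cycle=5)
        s2 = part_state("sphere", gene_index=1, last_cycle=3)
        pools = build_part_pools([s1, s2])
        assert [p.gene_index for p in pools.spheres] == [1, 0]

    def test_tie_broken_by_gene_index(self):
        s1 = part_state("sphere", gene_index=4, last_cycle=2)
        s2 = part_state("sphere", gene_index=1, last_cycle=2)
        pools = build_part_pools([s1, s2])
        assert [p.gene_index for p in pools.spheres] == [1, 4]

    def test_matches_stable_sort_oracle(self):
        rng = np.random.default_rng(6)
        states = [part_state("neuron", gene_index=i,
                             last_cycle=int(rng.integers(0, 5)))
                  for i in range(30)]
        pools = build_part_pools(states)
        oracle = sorted(((s.last_emission_cycle, s.gene_index)
                         for s in states))
        assert [(p.completion_cycle, p.gene_index)
                for p in pools.neurons] == oracle


def minimal_pools(motor=0.2, n_wires=2):
    pools = PartPools()
    pools.spheres.extend([make_part("sphere", 0), make_part("sphere", 1)])
    pools.joints.append(make_part("joint", 2, motor_strength=motor))
    pools.sensors.append(make_part("sensor", 3))
    pools.neurons.append(make_part("neuron", 4))
    pools.wires.extend(make_part("wire", 5 + i, weight=1.0)
                       for i in range(n_wires))
    return pools


class TestAssembly:
    def test_abort_without_connectable_spheres(self):
        pools = PartPools()
        pools.spheres.append(make_part("sphere"))
        assert isinstance(assemble(pools), AbortResult)
        pools = PartPools()
        pools.spheres.extend([make_part("sphere"), make_part("sphere")])
        assert isinstance(assemble(pools), AbortResult)  # no joints

    def test_minimal_viable_body(self):
        m = assemble(minimal_pools())
        assert not isinstance(m, AbortResult)
        assert m.counts == {"sphere": 2, "joint": 1, "sensor": 1,
                            "neuron": 1, "wire": 2}
        # wiring precedence gives sensor->neuron then neuron->motor
        assert m.wires[0]["source"][0] == "sensor"
        assert m.wires[0]["target"][0] == "neuron"
        assert m.wires[1]["source"][0] == "neuron"
        assert m.wires[1]["target"] == ("joint", 0)
        assert check_viability(m)

    def test_assembly_is_deterministic(self):
        a = assemble(minimal_pools())
        b = assemble(minimal_pools())
        assert a.to_yaml() == b.to_yaml()

    def test_tree_structure_and_mount_limits(self):
        rng = np.random.default_rng(8)
        plan = DEFAULT_BODY_PLAN
        for _ in range(30):
            pools = PartPools()
            pools.spheres.extend(make_part("sphere", i)
                                 for i in range(int(rng.integers(0, 8))))
            pools.joints.extend(make_part("joint", 10 + i,
                                          motor_strength=float(rng.random()))
                                for i in range(int(rng.integers(0, 8))))
            n_sph, n_j = len(pools.spheres), len(pools.joints)
            m = assemble(pools)
            if n_sph < 2 or n_j < 1:
                assert isinstance(m, AbortResult)
                continue
            # tree: joints used = spheres placed - 1; never exceeds supply
            assert len(m.joints) == len(m.spheres) - 1
            assert len(m.joints) <= n_j and len(m.spheres) <= n_sph
            degree = [0] * len(m.spheres)
            for j in m.joints:
                assert j["a"] != j["b"]
                degree[j["a"]] += 1
                degree[j["b"]] += 1
            assert max(degree) <= plan.joint_mounts_per_sphere

    def test_mounts_never_double_occupied(self):
        pools = minimal_pools()
        pools.neurons.extend(make_part("neuron", 10 + i) for i in range(20))
        pools.sensors.extend(make_part("sensor", 40 + i) for i in range(20))
        m = assemble(pools)
        plan = DEFAULT_BODY_PLAN
        for kind, per in (("neurons", plan.neuron_mounts_per_sphere),
                          ("sensors", plan.sensor_mounts_per_sphere)):
            per_sphere = {}
            for item in getattr(m, kind):
                per_sphere[item["sphere"]] = per_sphere.get(item["sphere"], 0) + 1
            assert max(per_sphere.values()) <= per

    def test_morphology_yaml_round_trip(self):
        m = assemble(minimal_pools())
        back = MorphologyGraph.from_yaml(m.to_yaml())
        assert back.to_yaml() == m.to_yaml()


class TestViability:
    def test_sensor_neuron_motor_chain_is_viable(self):
        assert check_viability(assemble(minimal_pools()))

    def test_no_wires_is_not_viable(self):
        assert not check_viability(assemble(minimal_pools(n_wires=0)))

    def test_unmotorized_joint_is_not_viable(self):
        assert not check_viability(assemble(minimal_pools(motor=0.0)))

    def test_abort_is_not_viable(self):
        assert not check_viability(AbortResult("x"))

    def test_matches_networkx_reachability_oracle(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(12)
        for trial in range(40):
            pools = PartPools()
            pools.spheres.extend(make_part("sphere", i) for i in range(4))
            pools.joints.extend(
                make_part("joint", 10 + i,
                          motor_strength=float(rng.random() < 0.5) * 0.3)
                for i in range(3))
            pools.sensors.extend(make_part("sensor", 20 + i)
                                 for i in range(int(rng.integers(0, 4))))
            pools.neurons.extend(make_part("neuron", 30 + i)
                                 for i in range(int(rng.integers(0, 4))))
            pools.wires.extend(make_part("wire", 40 + i, weight=1.0)
                               for i in range(int(rng.integers(0, 10))))
            m = assemble(pools)
            if isinstance(m, AbortResult):
                continue
            G = nx.DiGraph()
            for w in m.wires:
                G.add_edge(w["source"], w["target"])
            motors = set(m.motorized_joints())
            expected = any(
                nx.has_path(G, ("sensor", s), ("joint", j))
                for s in range(len(m.sensors)) if ("sensor", s) in G
                for j in motors if ("joint", j) in G)
            assert check_viability(m) == expected
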