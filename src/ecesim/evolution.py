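"""The generational loop: develop, evaluate, rank, allocate offspring,
replicate with mutation, and record every individual.

Selection is deterministic truncation: individuals are ranked by fitness
(descending; ties broken by ascending id) and the top half reproduces
asexually with a fixed offspring-allocation table — for the canonical
population of 60, ranks 1-3 make four children each, 4-9 three, 10-18 two,
and 19-30 one, restoring exactly 60 offspring. Mutation happens only during
replication; transcription error only during development. Per-individual
records (the tracked properties: id, parentage, generation, fitness, two
genetic-variance measures, and the five part counts) accumulate into a
lineage table, the unit of analysis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analysis as _analysis
from .assembly import (AbortResult, BodyPlan, DEFAULT_BODY_PLAN, assemble,
                       build_part_pools)
from .behavior import (DEFAULT_STEPS, Evaluator, SurrogateEvaluator,
                       compile_network, evaluate)
from .expression import DevelopmentTimeout, ErrorTrace, express_genome
from .genetics import CodonTable, QuaternaryGenome, init_genome, mutate_genome
from .rng import (STREAM_EVALUATOR, STREAM_GENOME, STREAM_MUTATION,
                  rate_key, stream_seed, substream)

__all__ = [
    "IndividualRecord", "Condition", "Population", "LineageTable",
    "rank_population", "allocate_offspring", "step_generation",
    "run_evolution", "develop_and_evaluate", "CANONICAL_RATE_LEVELS",
    "LINEAGE_COLUMNS",
]

# the 11-level error-rate grid used by the factorial design
CANONICAL_RATE_LEVELS = (0.0, 0.0005, 0.0010, 0.0015, 0.0020, 0.0025,
                     0.0030, 0.0035, 0.0040, 0.0045, 0.0050)

# the tracked per-individual properties, in lineage-table column order
LINEAGE_COLUMNS = ["id", "parent_id", "generation", "fitness",
                   "var_hamming_raw", "var_hamming_norm", "n_spheres",
                   "n_joints", "n_sensors", "n_neurons", "n_wires"]


@dataclass(frozen=True)
class Condition:
    """One cell of the factorial design: a (mu, tau) pair."""

    mu: float
    tau: float
    grid_index: tuple[int, int] | None = None

    def __post_init__(self):
        for r in (self.mu, self.tau):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must lie in [0, 1]")

    @property
    def key(self) -> tuple[int, int]:
        return rate_key(self.mu), rate_key(self.tau)


@dataclass
class IndividualRecord:
    id: int
    parent_id: int | None
    generation: int
    genome: QuaternaryGenome
    fitness: float = 0.0
    n_spheres: int = 0
    n_joints: int = 0
    n_sensors: int = 0
    n_neurons: int = 0
    n_wires: int = 0
    var_hamming_raw: int = 0
    var_hamming_norm: float = 0.0
    aborted: bool = False
    trace: ErrorTrace | None = None

    def row(self) -> dict:
        return {"id": self.id, "parent_id": self.parent_id,
                "generation": self.generation, "fitness": self.fitness,
                "var_hamming_raw": self.var_hamming_raw,
                "var_hamming_norm": self.var_hamming_norm,
                "n_spheres": self.n_spheres, "n_joints": self.n_joints,
                "n_sensors": self.n_sensors, "n_neurons": self.n_neurons,
                "n_wires": self.n_wires}


@dataclass
class Population:
    members: list[IndividualRecord]
    replicate_id: int = 0
    generation: int = 0

    def __len__(self):
        return len(self.members)


class LineageTable:
    """Per-generation, per-individual records for one evolutionary run."""

    def __init__(self, rows: list[dict], mu: float, tau: float,
                 replicate: int, evaluator_id: str):
        self.mu, self.tau = mu, tau
        self.replicate = replicate
        self.evaluator_id = evaluator_id
        self._rows = rows

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self._rows, columns=LINEAGE_COLUMNS)
        df.insert(0, "mu", self.mu)
        df.insert(1, "tau", self.tau)
        df.insert(2, "replicate", self.replicate)
        df["evaluator"] = self.evaluator_id
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def __len__(self):
        return len(self._rows)


# ---------------------------------------------------------------------------
# development + evaluation of one individual
# ---------------------------------------------------------------------------

def _genome_seed(genome: QuaternaryGenome) -> int:
    return int(genome.checksum()[:8], 16) & 0x7FFFFFFF

def develop_and_evaluate(record: IndividualRecord, cond: Condition,
                         dev_seed: int, table: CodonTable,
                         evaluator: Evaluator, plan: BodyPlan,
                         steps: int = DEFAULT_STEPS,
                         keep_trace: bool = False) -> None:
    """Develop, assemble and score one individual in place."""
    if not evaluator.requires_development:
        result = evaluator.evaluate(None, None, steps)
        record.fitness = result.fitness
        return
    if cond.tau == 0.0:
        # error-free development is a pure function of the genome: the
        # epistasis exchange is then seeded from the genome itself, so
        # clones develop identically wherever and whenever they occur
        dev_seed = _genome_seed(record.genome)
    try:
        states, _pool, trace = express_genome(record.genome, table, cond.tau,
                                              dev_seed)
        morphology = assemble(build_part_pools(states, plan), plan)
    except DevelopmentTimeout:
        record.aborted = True
        record.fitness = 0.0
        return
    if keep_trace:
        record.trace = trace
    if isinstance(morphology, AbortResult):
        record.aborted = True
        record.fitness = 0.0
        return
    counts = morphology.counts
    record.n_spheres = counts["sphere"]
    record.n_joints = counts["joint"]
    record.n_sensors = counts["sensor"]
    record.n_neurons = counts["neuron"]
    record.n_wires = counts["wire"]
    network = compile_network(morphology)
    eval_seed = stream_seed(dev_seed, STREAM_EVALUATOR)
    try:
        result = evaluate(morphology, network, evaluator, steps, eval_seed)
    except Exception:
        record.fitness = 0.0
        record.aborted = True
        return
    record.fitness = result.fitness
    record.aborted = result.aborted


def _annotate_variance(members: list[IndividualRecord]) -> None:
    mat = np.stack([m.genome.digits for m in members])
    contrib = _analysis.hamming_contributions(mat)
    length = mat.shape[1]
    for m, c in zip(members, contrib):
        m.var_hamming_raw = int(c)
        m.var_hamming_norm = float(c) / length


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def rank_population(members: list[IndividualRecord]) -> list[IndividualRecord]:
    """Descending fitness, ties broken by ascending id (fully deterministic)."""
    return sorted(members, key=lambda m: (-m.fitness, m.id))


def _tier_sizes(n_breeders: int) -> list[int]:
    """Breeder-tier sizes in the canonical 1:2:3:4 proportions.

    For 30 breeders this is (3, 6, 9, 12) — the published table. Other sizes
    use largest-remainder apportionment of the same proportions.
    """
    quotas = [n_breeders * w / 10 for w in (1, 2, 3, 4)]
    sizes = [int(q) for q in quotas]
    remainders = sorted(range(4), key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in remainders[: n_breeders - sum(sizes)]:
        sizes[i] += 1
    return sizes


def allocate_offspring(n: int) -> list[int]:
    """Offspring counts by rank (rank 1 first) for a population of n.

    n = 60 reproduces the canonical table exactly: 4 children for ranks 1-3,
    3 for 4-9, 2 for 10-18, 1 for 19-30, 0 for 31-60 (total 60). Other sizes
    scale the tier structure, then adjust low ranks so totals equal n.
    """
    if n < 2 or n % 2 != 0:
        raise ValueError("population size must be an even integer >= 2")
    breeders = n // 2
    sizes = _tier_sizes(breeders)
    counts = []
    for size, kids in zip(sizes, (4, 3, 2, 1)):
        counts.extend([kids] * size)
    total = sum(counts)
    i = len(counts) - 1
    while total > n:  # trim from the lowest breeder ranks
        if counts[i] > 0:
            counts[i] -= 1
            total -= 1
        i = i - 1 if i > 0 else len(counts) - 1
    i = 0
    while total < n:  # top up from the highest ranks
        counts[i] += 1
        total += 1
        i = (i + 1) % len(counts)
    counts.extend([0] * (n - breeders))
    return counts


# ---------------------------------------------------------------------------
# generational loop
# ---------------------------------------------------------------------------

def step_generation(pop: Population, cond: Condition, replicate_seed: int,
                    *, table: CodonTable, evaluator: Evaluator,
                    plan: BodyPlan = DEFAULT_BODY_PLAN,
                    steps: int = DEFAULT_STEPS,
                    next_id: int | None = None) -> Population:
    """Produce and evaluate the next generation (population size preserved)."""
    ranking = rank_population(pop.members)
    counts = allocate_offspring(len(pop))
    gen = pop.generation + 1
    base_id = (max(m.id for m in pop.members) + 1 if next_id is None
               else next_id)
    children: list[IndividualRecord] = []
    mu_k, tau_k = cond.key
    for rank, (parent, n_kids) in enumerate(zip(ranking, counts)):
        for _ in range(n_kids):
            idx = len(children)
            mut_rng = substream(replicate_seed, mu_k, tau_k, gen, idx,
                                STREAM_MUTATION)
            child_genome = mutate_genome(parent.genome, cond.mu, mut_rng)
            children.append(IndividualRecord(base_id + idx, parent.id, gen,
                                             child_genome))
    for idx, child in enumerate(children):
        dev_seed = stream_seed(replicate_seed, mu_k, tau_k, gen, idx)
        develop_and_evaluate(child, cond, dev_seed, table, evaluator, plan,
                             steps)
    _annotate_variance(children)
    return Population(children, pop.replicate_id, gen)


def run_evolution(cond: Condition, replicate_seed: int, generations: int = 100,
                  *, population_size: int = 60, n_codons: int = 6000,
                  table: CodonTable | None = None,
                  evaluator: Evaluator | None = None,
                  plan: BodyPlan = DEFAULT_BODY_PLAN,
                  steps: int = DEFAULT_STEPS,
                  replicate_id: int = 0) -> LineageTable:
    """Run one replicate population under one condition.

    Generation-0 genomes depend only on (replicate_seed, individual index) —
    never on the condition — so the same replicate seed yields identical
    starting populations in every cell of the factorial design. `generations`
    counts populations: generations=100 yields generations 0..99 (the final
    generation is 99) and 100 * population_size records.
    """
    if generations < 1:
        raise ValueError("need at least one generation")
    table = table or CodonTable.default()
    evaluator = evaluator or SurrogateEvaluator()
    mu_k, tau_k = cond.key
    members = []
    for i in range(population_size):
        g_rng = substream(replicate_seed, i, STREAM_GENOME)
        members.append(IndividualRecord(i, None, 0,
                                        init_genome(g_rng, n_codons)))
    for i, m in enumerate(members):
        dev_seed = stream_seed(replicate_seed, mu_k, tau_k, 0, i)
        develop_and_evaluate(m, cond, dev_seed, table, evaluator, plan, steps)
    _annotate_variance(members)
    pop = Population(members, replicate_id, 0)
    rows = [m.row() for m in pop.members]
    for _ in range(1, generations):
        pop = step_generation(pop, cond, replicate_seed, table=table,
                              evaluator=evaluator, plan=plan, steps=steps)
        rows.extend(m.row() for m in pop.members)
    return LineageTable(rows, cond.mu, cond.tau, replicate_id, evaluator.name)
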