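"""Factorial experiment design, seeding discipline, and the run manifest.

The canonical design crosses 11 mutation-rate levels with 11 transcription-
error levels (121 conditions), each run on the same 10 replicate populations
of 60 for 100 generations — a repeated-measures layout in which replicate
seeds derive from the master seed and replicate index only, never from the
condition, so every condition starts from identical generation-0 genomes.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from . import __version__
from .behavior import DEFAULT_STEPS, Evaluator, get_evaluator
from .evolution import Condition, CANONICAL_RATE_LEVELS, run_evolution
from .genetics import CodonTable
from .rng import stream_seed

__all__ = ["ExperimentDesign", "enumerate_conditions", "replicate_seed",
           "run_experiment"]


@dataclass
class ExperimentDesign:
    mu_levels: tuple = CANONICAL_RATE_LEVELS
    tau_levels: tuple = CANONICAL_RATE_LEVELS
    n_replicates: int = 10
    generations: int = 100
    population_size: int = 60
    n_codons: int = 6000
    steps: int = DEFAULT_STEPS
    master_seed: int = 0
    evaluator: str = "surrogate"
    out_dir: str = "runs"

    def __post_init__(self):
        self.mu_levels = tuple(float(m) for m in self.mu_levels)
        self.tau_levels = tuple(float(t) for t in self.tau_levels)
        if not self.mu_levels or not self.tau_levels:
            raise ValueError("empty error-rate level list")

    @property
    def n_conditions(self) -> int:
        return len(self.mu_levels) * len(self.tau_levels)

    @property
    def n_runs(self) -> int:
        return self.n_conditions * self.n_replicates

    @property
    def total_individuals(self) -> int:
        """Individuals produced across the whole design (by arithmetic)."""
        return self.n_runs * self.generations * self.population_size

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentDesign":
        return cls(**yaml.safe_load(text))


def enumerate_conditions(design: ExperimentDesign) -> list[Condition]:
    """Cartesian product in mu-major (row-major) order."""
    return [Condition(mu, tau, grid_index=(i, j))
            for i, mu in enumerate(design.mu_levels)
            for j, tau in enumerate(design.tau_levels)]


def replicate_seed(master_seed: int, replicate: int) -> int:
    """Replicate seeds depend on (master seed, replicate index) only."""
    return stream_seed(master_seed, replicate)


def _run_name(cond: Condition, rep: int) -> str:
    return f"mu{cond.mu:.4f}_tau{cond.tau:.4f}_rep{rep:02d}.csv"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(design: ExperimentDesign, *, resume: bool = False,
                   table: CodonTable | None = None,
                   evaluator: Evaluator | None = None,
                   log=None) -> Path:
    """Run (or resume) every (condition, replicate) cell of a design.

    Writes one lineage CSV per run plus manifest.json recording the design,
    seeds, package version, evaluator and a content hash per file. With
    resume=True, runs whose file matches its manifest hash are skipped.
    """
    out = Path(design.out_dir)
    lineage_dir = out / "lineages"
    lineage_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    design_dict = json.loads(json.dumps(asdict(design)))  # JSON-normalized
    manifest = {"design": design_dict, "version": __version__,
                "replicate_seeds": {str(r): replicate_seed(design.master_seed, r)
                                    for r in range(design.n_replicates)},
                "files": {}}
    if resume and manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("design") != design_dict:
            raise ValueError("existing manifest was produced by a different "
                             "design; refusing to resume")
        manifest["files"] = old.get("files", {})
    evaluator = evaluator or get_evaluator(design.evaluator)
    table = table or CodonTable.default()
    for cond in enumerate_conditions(design):
        for rep in range(design.n_replicates):
            name = _run_name(cond, rep)
            path = lineage_dir / name
            if (resume and name in manifest["files"] and path.exists()
                    and _sha256(path) == manifest["files"][name]):
                continue
            lineage = run_evolution(
                cond, replicate_seed(design.master_seed, rep),
                design.generations, population_size=design.population_size,
                n_codons=design.n_codons, table=table, evaluator=evaluator,
                steps=design.steps, replicate_id=rep)
            lineage.to_csv(path)
            manifest["files"][name] = _sha256(path)
            if log is not None:
                df = lineage.to_frame()
                last = df[df.generation == df.generation.max()]
                log(f"{name}: best={last.fitness.max():.3f} "
                    f"mean={last.fitness.mean():.3f}")
            manifest_path.write_text(json.dumps(manifest, indent=1,
                                                sort_keys=True))
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
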