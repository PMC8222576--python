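"""Gene expression with transcription error, magnitude-limited transcript
production over update cycles, and the shared epistasis transcript pool.

Development starts by expressing every gene once (cycle 0): each codon in the
gene's span is transcribed — with each digit independently corrupted at rate
tau — and the transcript's role is decided by the *transcribed* triplet, so an
error can turn a feature codon into a magnitude codon (and vice versa). The
first transcript with a part role becomes the gene's protopart; feature and
magnitude transcripts join the gene's regulatory pool; transcripts whose
transcribed role is start/stop or a surplus part are inert. Magnitude
transcripts additively set the gene's feature-transcript allowance.

On every subsequent update cycle each gene re-transcribes each of its
(genomic) feature codons — fresh error draws each time — until its allowance
is exhausted, then genes exchange transcripts through a shared pool: each
contributes 10% of its newly expressed transcripts, then pulls 5% of the
pool. Pulled magnitude transcripts raise the puller's allowance.

Transcription errors are epigenetic: the genome itself is never modified, and
every error event is recorded in an ErrorTrace whose replay reproduces the
whole development bit-for-bit (the determinism contract behind partitioning
realized fitness into genetic and epigenetic components).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .genetics import (FEATURE, MAGNITUDE, PART, QuaternaryGenome, CodonTable,
                       GeneRegion, parse_genes)
from .rng import substream, STREAM_TRANSCRIPTION, STREAM_EPISTASIS

__all__ = [
    "Transcript", "GeneExpressionState", "EpistasisPool", "ErrorTrace",
    "CycleStats", "DevelopmentTimeout", "transcribe_codon",
    "initialize_gene_expression", "run_update_cycle", "express_genome",
    "replay_expression",
]

DEFAULT_CYCLE_CAP = 10_000


class DevelopmentTimeout(Exception):
    """Raised when development exceeds the update-cycle cap."""


@dataclass(slots=True)
class Transcript:
    source_gene: int
    source_codon_index: int
    codon_as_transcribed: str
    role_category: str
    cycle: int
    # role payloads, denormalized for speed during growth
    part_kind: str | None = None
    feature_target_kind: str | None = None
    feature_property: str | None = None
    feature_sign: str | None = None
    magnitude_value: int = 0


class ErrorTrace:
    """Ordered record of every transcription-error event.

    Events are keyed by a global transcription-event counter (one per codon
    transcription, error or not) so a replay applies each recorded corruption
    at exactly the event where it occurred. The trace also carries the seeds
    of the transcription and epistasis substreams so the exchange randomness
    replays identically.
    """

    def __init__(self, tau: float, transcription_seed: int, epistasis_seed: int):
        self.tau = float(tau)
        self.transcription_seed = int(transcription_seed)
        self.epistasis_seed = int(epistasis_seed)
        self.events: dict[int, tuple[int, int, int, str, str]] = {}

    def record(self, counter: int, gene: int, codon_index: int, cycle: int,
               original: str, transcribed: str) -> None:
        self.events[counter] = (gene, codon_index, cycle, original, transcribed)

    def __len__(self):
        return len(self.events)

    # line-oriented text serialization for replay and audit
    def to_text(self) -> str:
        lines = [f"# tau {self.tau!r}",
                 f"# transcription_seed {self.transcription_seed}",
                 f"# epistasis_seed {self.epistasis_seed}",
                 "# event gene codon_index cycle from to"]
        for counter in sorted(self.events):
            g, ci, cy, a, b = self.events[counter]
            lines.append(f"{counter} {g} {ci} {cy} {a} {b}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ErrorTrace":
        tau = t_seed = e_seed = None
        events = {}
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["tau"]:
                    tau = float(parts[1])
                elif parts[:1] == ["transcription_seed"]:
                    t_seed = int(parts[1])
                elif parts[:1] == ["epistasis_seed"]:
                    e_seed = int(parts[1])
                continue
            counter, g, ci, cy, a, b = line.split()
            events[int(counter)] = (int(g), int(ci), int(cy), a, b)
        if tau is None or t_seed is None or e_seed is None:
            raise ValueError("trace header incomplete")
        trace = cls(tau, t_seed, e_seed)
        trace.events = events
        return trace


class _LiveTranscriber:
    """Transcribes codon blocks with fresh error draws, recording the trace."""

    def __init__(self, tau: float, rng: np.random.Generator, trace: ErrorTrace):
        if not 0.0 <= tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")
        self.tau = tau
        self.rng = rng
        self.trace = trace
        self.counter = 0

    def transcribe_block(self, codons: np.ndarray, positions, gene: int,
                         cycle: int) -> np.ndarray:
        """codons: (k, 3) genomic digits; returns (k, 3) transcribed digits."""
        k = codons.shape[0]
        out = codons.copy()
        if self.tau > 0.0:
            hit = self.rng.random((k, 3)) < self.tau
            offset = self.rng.integers(1, 4, size=(k, 3), dtype=np.uint8)
            out[hit] = (out[hit] + offset[hit]) % 4
        for j in range(k):
            c = self.counter
            self.counter += 1
            if self.tau > 0.0 and not np.array_equal(out[j], codons[j]):
                self.trace.record(c, gene, int(positions[j]), cycle,
                                  _trip(codons[j]), _trip(out[j]))
        return out


class _ReplayTranscriber:
    """Applies recorded error events; consumes no randomness."""

    def __init__(self, trace: ErrorTrace):
        self.trace = trace
        self.counter = 0

    def transcribe_block(self, codons, positions, gene, cycle):
        out = codons.copy()
        for j in range(codons.shape[0]):
            ev = self.trace.events.get(self.counter)
            self.counter += 1
            if ev is not None:
                out[j] = [int(d) for d in ev[4]]
        return out


def _trip(digits) -> str:
    return f"{digits[0]}{digits[1]}{digits[2]}"


@dataclass
class GeneExpressionState:
    """Per-gene expression bookkeeping during development."""

    gene_index: int
    region: GeneRegion
    protopart: Transcript | None = None
    regulatory_pool: list[Transcript] = field(default_factory=list)
    feature_limit: int = 0
    features_emitted: int = 0
    feature_positions: np.ndarray | None = None  # genomic feature codons in span
    last_emission_cycle: int = 0

    @property
    def can_emit(self) -> bool:
        return (self.feature_positions is not None
                and self.feature_positions.size > 0
                and self.features_emitted < self.feature_limit)


@dataclass
class EpistasisPool:
    """Shared transcript pool through which genes interact each cycle."""

    contribute_fraction: float = 0.10
    pull_fraction: float = 0.05
    contents: list[Transcript] = field(default_factory=list)

    def __post_init__(self):
        self._contrib = Fraction(str(self.contribute_fraction))
        self._pull = Fraction(str(self.pull_fraction))


def _round_half_even(x: Fraction) -> int:
    q, r2 = divmod(2 * x.numerator, 2 * x.denominator)
    if r2 > x.denominator or (r2 == x.denominator and q % 2 == 1):
        q += 1
    return int(q)


@dataclass
class CycleStats:
    """Instrumentation of one update cycle (used by calibration checks)."""

    cycle: int
    emitted_per_gene: dict[int, int]
    contributed_per_gene: dict[int, int]
    pool_before_pulls: int
    pulled_per_gene: dict[int, tuple[int, int]]  # gene -> (pool_pre_pull, pulled)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def transcribe_codon(codon, tau: float, rng: np.random.Generator,
                     table: CodonTable | None = None, *, gene: int = 0,
                     codon_index: int = 0, cycle: int = 0,
                     trace: ErrorTrace | None = None) -> Transcript:
    """Transcribe a single codon with per-digit error rate tau."""
    if table is None:
        table = CodonTable.default()
    if isinstance(codon, str):
        digits = np.array([int(d) for d in codon], dtype=np.uint8)
    else:
        digits = np.asarray(codon, dtype=np.uint8)
    if digits.shape != (3,) or digits.max() > 3:
        raise ValueError(f"malformed codon {codon!r}")
    if trace is None:
        trace = ErrorTrace(tau, 0, 0)
    live = _LiveTranscriber(tau, rng, trace)
    out = live.transcribe_block(digits[None, :], [codon_index], gene, cycle)[0]
    return _make_transcript(out, table, gene, codon_index, cycle)


def _make_transcript(digits, table: CodonTable, gene: int, codon_index: int,
                     cycle: int) -> Transcript:
    role = table.classify(digits)
    return Transcript(gene, codon_index, _trip(digits), role.category, cycle,
                      part_kind=role.part_kind,
                      feature_target_kind=role.feature_target_kind,
                      feature_property=role.feature_property,
                      feature_sign=role.feature_sign,
                      magnitude_value=role.magnitude_value or 0)


def initialize_gene_expression(gene: GeneRegion, genome: QuaternaryGenome,
                               table: CodonTable, transcriber,
                               gene_index: int = 0) -> GeneExpressionState:
    """Cycle-0 expression of one gene.

    Every codon in the span gets one transcription attempt, in order. The
    first transcript with a part role becomes the protopart; feature and
    magnitude transcripts join the regulatory pool (initial feature
    transcripts are exempt from the magnitude allowance); everything else is
    inert. The feature allowance starts as the sum of retained magnitude
    values.
    """
    state = GeneExpressionState(gene_index, gene)
    span = np.arange(gene.start_index + 1, gene.stop_index)
    genomic_cats = table.category_codes[genome.codon_indices()[span]] if span.size else None
    if span.size:
        state.feature_positions = span[genomic_cats == FEATURE]
        codons = genome.codons()[span]
        out = transcriber.transcribe_block(codons, span, gene_index, 0)
        cats = table.category_codes[16 * out[:, 0].astype(np.int64)
                                    + 4 * out[:, 1] + out[:, 2]]
        for j in range(span.size):
            cat = cats[j]
            if cat == PART and state.protopart is None:
                state.protopart = _make_transcript(out[j], table, gene_index,
                                                   int(span[j]), 0)
            elif cat in (FEATURE, MAGNITUDE):
                t = _make_transcript(out[j], table, gene_index, int(span[j]), 0)
                state.regulatory_pool.append(t)
                if cat == MAGNITUDE:
                    state.feature_limit += t.magnitude_value
    else:
        state.feature_positions = np.array([], dtype=np.int64)
    return state


def run_update_cycle(states: list[GeneExpressionState], pool: EpistasisPool,
                     genome: QuaternaryGenome, table: CodonTable,
                     transcriber, epistasis_rng: np.random.Generator,
                     cycle: int) -> CycleStats:
    """One development update cycle: emit, contribute, pull (in gene order).

    Emission: each gene re-transcribes each of its feature codons (fresh error
    draws), stopping mid-cycle once its allowance is reached; transcripts
    whose transcribed role is feature count against the allowance, magnitude
    transcripts raise nothing yet, inert roles produce nothing. Exchange: each
    gene moves a random 10% (half-even rounded) of its newly expressed
    transcripts to the shared pool, then each gene pulls a random 5% of the
    pool's current contents (without replacement, capped at pool size);
    retained/pulled magnitude transcripts raise the owner's allowance.
    """
    codons = genome.codons()
    new_per_gene: dict[int, list[Transcript]] = {}
    emitted = {}
    for state in states:
        if not state.can_emit:
            continue
        fpos = state.feature_positions
        out = transcriber.transcribe_block(codons[fpos], fpos,
                                           state.gene_index, cycle)
        new: list[Transcript] = []
        for j in range(fpos.size):
            if state.features_emitted >= state.feature_limit:
                break
            t = _make_transcript(out[j], table, state.gene_index,
                                 int(fpos[j]), cycle)
            if t.role_category == "feature":
                state.features_emitted += 1
                new.append(t)
                state.last_emission_cycle = cycle
            elif t.role_category == "magnitude":
                new.append(t)
                state.last_emission_cycle = cycle
            # part/start/stop as transcribed: inert
        if new:
            new_per_gene[state.gene_index] = new
            emitted[state.gene_index] = len(new)

    # contributions: 10% of each gene's newly expressed transcripts
    contributed = {}
    for state in states:
        new = new_per_gene.get(state.gene_index, [])
        n_c = _round_half_even(pool._contrib * len(new)) if new else 0
        if n_c > 0:
            picked = sorted(epistasis_rng.choice(len(new), size=n_c,
                                                 replace=False).tolist())
            picked_set = set(picked)
            moved = [new[j] for j in picked]
            kept = [new[j] for j in range(len(new)) if j not in picked_set]
            pool.contents.extend(moved)
        else:
            moved, kept = [], list(new)
        contributed[state.gene_index] = len(moved)
        for t in kept:
            _retain(state, t)

    pool_before_pulls = len(pool.contents)

    # pulls: 5% of the pool's current contents, per gene in order
    pulled = {}
    for state in states:
        pre = len(pool.contents)
        n_p = min(_round_half_even(pool._pull * pre), pre)
        if n_p > 0:
            idx = sorted(epistasis_rng.choice(pre, size=n_p,
                                              replace=False).tolist(),
                         reverse=True)
            for i in idx:
                t = pool.contents.pop(i)
                _retain(state, t)
        pulled[state.gene_index] = (pre, n_p)

    return CycleStats(cycle, emitted, contributed, pool_before_pulls, pulled)


def _retain(state: GeneExpressionState, t: Transcript) -> None:
    state.regulatory_pool.append(t)
    if t.role_category == "magnitude":
        state.feature_limit += t.magnitude_value


def express_genome(genome: QuaternaryGenome, table: CodonTable, tau: float,
                   seed, *, pool: EpistasisPool | None = None,
                   max_cycles: int = DEFAULT_CYCLE_CAP
                   ) -> tuple[list[GeneExpressionState], EpistasisPool, ErrorTrace]:
    """Develop a genome's expression phase to completion.

    `seed` may be an int or a Generator; two named substreams (transcription,
    epistasis) are derived from it so each can be replayed in isolation.
    Cycles run until no gene can emit (every allowance met), or the cycle cap
    triggers a DevelopmentTimeout (the individual is then scored as aborted).
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    if isinstance(seed, np.random.Generator):
        t_seed = int(seed.integers(1 << 31))
        e_seed = int(seed.integers(1 << 31))
    else:
        t_seed = substream(int(seed), STREAM_TRANSCRIPTION).integers(1 << 31)
        e_seed = substream(int(seed), STREAM_EPISTASIS).integers(1 << 31)
        t_seed, e_seed = int(t_seed), int(e_seed)
    trace = ErrorTrace(tau, t_seed, e_seed)
    transcriber = _LiveTranscriber(tau, np.random.default_rng(t_seed), trace)
    return _run_expression(genome, table, transcriber, trace,
                           np.random.default_rng(e_seed), pool, max_cycles)


def replay_expression(genome: QuaternaryGenome, table: CodonTable,
                      trace: ErrorTrace, *, pool: EpistasisPool | None = None,
                      max_cycles: int = DEFAULT_CYCLE_CAP):
    """Replay a recorded development; consumes no transcription randomness."""
    transcriber = _ReplayTranscriber(trace)
    return _run_expression(genome, table, transcriber, trace,
                           np.random.default_rng(trace.epistasis_seed),
                           pool, max_cycles)


def _run_expression(genome, table, transcriber, trace, epistasis_rng, pool,
                    max_cycles):
    genes = parse_genes(genome, table)
    pool = pool if pool is not None else EpistasisPool()
    states = [initialize_gene_expression(g, genome, table, transcriber, i)
              for i, g in enumerate(genes)]
    cycle = 0
    while any(s.can_emit for s in states):
        cycle += 1
        if cycle > max_cycles:
            raise DevelopmentTimeout(
                f"development exceeded {max_cycles} update cycles")
        run_update_cycle(states, pool, genome, table, transcriber,
                         epistasis_rng, cycle)
    return states, pool, trace
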