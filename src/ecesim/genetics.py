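"""Genome representation, codon classification, gene parsing, mutation.

The heritable material is a fixed-length string of quaternary digits read as
non-overlapping triplet codons. A codon table classifies each of the 64 codons
as a part, feature, magnitude, start, or stop codon. Start/stop codons
demarcate genes (open reading frames); only codons strictly between them are
expressed. Mutation happens only at replication: each digit is independently
replaced, with probability mu, by one of the other three digits.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PART_KINDS", "CATEGORIES", "QuaternaryGenome", "CodonRole", "CodonTable",
    "GeneRegion", "init_genome", "classify_codon", "parse_genes",
    "mutate_genome", "replicate", "genome_to_fasta", "genomes_from_fasta",
]

PART_KINDS = ("sphere", "joint", "sensor", "neuron", "wire")
CATEGORIES = ("part", "feature", "magnitude", "start", "stop")

# integer category codes used in vectorized scans
PART, FEATURE, MAGNITUDE, START, STOP = range(5)

_DIGIT_TO_BASE = str.maketrans("0123", "ACGT")
_BASE_TO_DIGIT = str.maketrans("ACGT", "0123")


class QuaternaryGenome:
    """Immutable fixed-length sequence of digits in {0,1,2,3}.

    Length must be a multiple of 3 (whole codons). The digit buffer is
    write-protected; all operators return new genomes.
    """

    __slots__ = ("_digits",)

    def __init__(self, digits: Sequence[int] | np.ndarray):
        arr = np.array(digits, dtype=np.uint8, copy=True)
        if arr.ndim != 1:
            raise ValueError("genome digits must be one-dimensional")
        if arr.size == 0 or arr.size % 3 != 0:
            raise ValueError("genome length must be a positive multiple of 3")
        if arr.max(initial=0) > 3:
            raise ValueError("genome digits must lie in {0,1,2,3}")
        arr.setflags(write=False)
        self._digits = arr

    @property
    def digits(self) -> np.ndarray:
        return self._digits

    def __len__(self) -> int:
        return int(self._digits.size)

    @property
    def n_codons(self) -> int:
        return len(self) // 3

    def codons(self) -> np.ndarray:
        """(n_codons, 3) read-only view."""
        return self._digits.reshape(-1, 3)

    def codon_indices(self) -> np.ndarray:
        """Each codon as an integer 0..63 (16a + 4b + c)."""
        c = self.codons().astype(np.int64)
        return 16 * c[:, 0] + 4 * c[:, 1] + c[:, 2]

    def checksum(self) -> str:
        return hashlib.sha256(self._digits.tobytes()).hexdigest()

    def to_string(self) -> str:
        return "".join(chr(48 + d) for d in self._digits)

    @classmethod
    def from_string(cls, s: str) -> "QuaternaryGenome":
        return cls(np.frombuffer(s.encode("ascii"), dtype=np.uint8) - 48)

    def __eq__(self, other) -> bool:
        return (isinstance(other, QuaternaryGenome)
                and np.array_equal(self._digits, other._digits))

    def __hash__(self):
        return hash(self._digits.tobytes())

    def __repr__(self):
        return f"QuaternaryGenome(n_codons={self.n_codons})"


@dataclass(frozen=True)
class CodonRole:
    """Classification of one codon.

    category is one of part/feature/magnitude/start/stop. part_kind is set for
    part codons; (feature_target_kind, feature_property, feature_sign) for
    feature codons; magnitude_value (a strictly positive transcript allowance)
    for magnitude codons.
    """

    category: str
    part_kind: str | None = None
    feature_target_kind: str | None = None
    feature_property: str | None = None
    feature_sign: str | None = None
    magnitude_value: int | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "part" and self.part_kind not in PART_KINDS:
            raise ValueError(f"part codon needs a valid kind, got {self.part_kind!r}")
        if self.category == "feature":
            if self.feature_target_kind not in PART_KINDS:
                raise ValueError("feature codon needs a target part kind")
            if self.feature_sign not in ("+", "-"):
                raise ValueError("feature sign must be '+' or '-'")
            if not self.feature_property:
                raise ValueError("feature codon needs a property name")
        if self.category == "magnitude":
            if not isinstance(self.magnitude_value, int) or self.magnitude_value <= 0:
                raise ValueError("magnitude values must be strictly positive integers")


def _codon_str_to_index(codon: str) -> int:
    if len(codon) != 3 or any(ch not in "0123" for ch in codon):
        raise ValueError(f"malformed codon {codon!r}")
    return 16 * int(codon[0]) + 4 * int(codon[1]) + int(codon[2])


def _index_to_codon_str(i: int) -> str:
    return f"{i // 16}{(i // 4) % 4}{i % 4}"


class CodonTable:
    """Total mapping from the 64 codons to roles.

    The default table honors the fixed anchors (002 = sphere size+, 003 =
    sphere size-, 230 = magnitude 100), contains at least one start and one
    stop codon, makes all five part kinds reachable, and pairs every feature
    effect with its counter-acting sign. Round-trips bit-exactly through YAML.
    """

    def __init__(self, roles: dict[str, CodonRole], provenance: str = "user-supplied",
                 version: int = 1):
        if set(map(_codon_str_to_index, roles)) != set(range(64)):
            raise ValueError("codon table must classify all 64 codons exactly once")
        self.roles = dict(sorted(roles.items()))
        self.provenance = provenance
        self.version = version
        self._by_index = [self.roles[_index_to_codon_str(i)] for i in range(64)]
        cat_code = {c: i for i, c in enumerate(CATEGORIES)}
        self.category_codes = np.array(
            [cat_code[r.category] for r in self._by_index], dtype=np.int8)
        self.magnitude_values = np.array(
            [r.magnitude_value or 0 for r in self._by_index], dtype=np.int64)
        self._validate()

    def _validate(self):
        cats = self.category_codes
        if not (cats == START).any() or not (cats == STOP).any():
            raise ValueError("table needs at least one start and one stop codon")
        kinds = {r.part_kind for r in self._by_index if r.category == "part"}
        if kinds != set(PART_KINDS):
            raise ValueError(f"all 5 part kinds must be reachable; got {kinds}")
        # counter-acting +/- pairs per (kind, property)
        signs: dict[tuple[str, str], set[str]] = {}
        for r in self._by_index:
            if r.category == "feature":
                signs.setdefault((r.feature_target_kind, r.feature_property),
                                 set()).add(r.feature_sign)
        bad = [k for k, s in signs.items() if s != {"+", "-"}]
        if bad:
            raise ValueError(f"feature effects must come in +/- pairs; missing sign for {bad}")

    # -- lookup ------------------------------------------------------------
    def classify(self, codon) -> CodonRole:
        """Role of a codon given as '012', (0,1,2), or an int index 0..63."""
        if isinstance(codon, str):
            return self._by_index[_codon_str_to_index(codon)]
        if isinstance(codon, (int, np.integer)):
            if not 0 <= int(codon) < 64:
                raise ValueError("codon index out of range")
            return self._by_index[int(codon)]
        trip = tuple(int(d) for d in codon)
        if len(trip) != 3 or any(d not in (0, 1, 2, 3) for d in trip):
            raise ValueError(f"malformed codon {codon!r}")
        return self._by_index[16 * trip[0] + 4 * trip[1] + trip[2]]

    def codons_of(self, category: str, **match) -> list[str]:
        """Codon strings with the given category (and matching role fields)."""
        out = []
        for c, r in self.roles.items():
            if r.category != category:
                continue
            if all(getattr(r, k) == v for k, v in match.items()):
                out.append(c)
        return out

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        codons = {}
        for c, r in self.roles.items():
            e: dict = {"category": r.category}
            if r.category == "part":
                e["part"] = r.part_kind
            elif r.category == "feature":
                e.update(part=r.feature_target_kind, property=r.feature_property,
                         sign=r.feature_sign)
            elif r.category == "magnitude":
                e["value"] = r.magnitude_value
            codons[c] = e
        return {"version": self.version, "provenance": self.provenance,
                "codons": codons}

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=None)

    @classmethod
    def from_dict(cls, d: dict) -> "CodonTable":
        roles = {}
        for c, e in d["codons"].items():
            cat = e["category"]
            if cat == "part":
                roles[c] = CodonRole("part", part_kind=e["part"])
            elif cat == "feature":
                roles[c] = CodonRole("feature", feature_target_kind=e["part"],
                                     feature_property=e["property"],
                                     feature_sign=e["sign"])
            elif cat == "magnitude":
                roles[c] = CodonRole("magnitude", magnitude_value=int(e["value"]))
            else:
                roles[c] = CodonRole(cat)
        return cls(roles, provenance=d.get("provenance", "user-supplied"),
                   version=int(d.get("version", 1)))

    @classmethod
    def from_yaml(cls, text: str) -> "CodonTable":
        return cls.from_dict(yaml.safe_load(text))

    _default = None

    @classmethod
    def default(cls) -> "CodonTable":
        """The shipped versioned default table (cached)."""
        if cls._default is None:
            text = (resources.files("ecesim") / "data" / "default_codon_table.yaml"
                    ).read_text()
            table = cls.from_yaml(text)
            # anchored entries are fixed for the default table
            assert table.roles["002"] == CodonRole(
                "feature", feature_target_kind="sphere", feature_property="size",
                feature_sign="+")
            assert table.roles["003"].feature_sign == "-"
            assert table.roles["230"].magnitude_value == 100
            table.provenance = "default"
            cls._default = table
        return cls._default


@dataclass(frozen=True)
class GeneRegion:
    """Open reading frame: codon indices of its start and terminating stop.

    The expressed span is the codons strictly between them.
    """

    start_index: int
    stop_index: int

    def __post_init__(self):
        if not self.start_index < self.stop_index:
            raise ValueError("start must precede stop")

    @property
    def span(self) -> range:
        return range(self.start_index + 1, self.stop_index)

    @property
    def span_length(self) -> int:
        return self.stop_index - self.start_index - 1


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def init_genome(rng: np.random.Generator, n_codons: int) -> QuaternaryGenome:
    """Random genome of n_codons codons, digits iid uniform on {0,1,2,3}."""
    if int(n_codons) < 1:
        raise ValueError("n_codons must be positive")
    return QuaternaryGenome(rng.integers(0, 4, size=3 * int(n_codons), dtype=np.uint8))


def classify_codon(codon, table: CodonTable) -> CodonRole:
    return table.classify(codon)


def parse_genes(genome: QuaternaryGenome, table: CodonTable) -> list[GeneRegion]:
    """Scan the fixed reading frame for start..stop regions.

    A gene opens at a start codon seen while no gene is open and closes at the
    next stop codon; starts inside an open gene are ordinary expressed codons;
    a trailing unclosed start yields no gene. Regions are disjoint and in
    genomic order.
    """
    cats = table.category_codes[genome.codon_indices()]
    events = np.flatnonzero((cats == START) | (cats == STOP))
    regions: list[GeneRegion] = []
    open_start: int | None = None
    for i in events:
        if cats[i] == START:
            if open_start is None:
                open_start = int(i)
        elif open_start is not None:
            regions.append(GeneRegion(open_start, int(i)))
            open_start = None
    return regions


def mutate_genome(genome: QuaternaryGenome, mu: float,
                  rng: np.random.Generator) -> QuaternaryGenome:
    """Point-mutate each digit independently with probability mu.

    An alteration replaces the digit uniformly with one of the *other* three
    digits, so mu is exactly the per-digit change probability. The input
    genome is untouched.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    n = len(genome)
    hit = rng.random(n) < mu
    offset = rng.integers(1, 4, size=n, dtype=np.uint8)
    out = genome.digits.copy()
    out[hit] = (out[hit] + offset[hit]) % 4
    return QuaternaryGenome(out)


def replicate(parent, mu: float, rng: np.random.Generator):
    """Asexual reproduction: mutated copy of the parent genome + parentage.

    `parent` is anything with .genome and .id (an IndividualRecord works).
    Returns (child_genome, parent_id).
    """
    child = mutate_genome(parent.genome, mu, rng)
    return child, parent.id


# ---------------------------------------------------------------------------
# serialization: plain quaternary strings and FASTA (0->A 1->C 2->G 3->T)
# ---------------------------------------------------------------------------

def genome_to_fasta(records: Iterable[tuple[QuaternaryGenome, str]], handle) -> None:
    """Write (genome, header) pairs as FASTA using the fixed 0123->ACGT map.

    The header conventionally carries `id|generation|parent_id`.
    """
    seqs = [SeqRecord(Seq(g.to_string().translate(_DIGIT_TO_BASE)),
                      id=header, description="") for g, header in records]
    SeqIO.write(seqs, handle, "fasta")


def genomes_from_fasta(handle) -> list[tuple[QuaternaryGenome, str]]:
    out = []
    for rec in SeqIO.parse(handle, "fasta"):
        digits = str(rec.seq).upper().translate(_BASE_TO_DIGIT)
        out.append((QuaternaryGenome.from_string(digits), rec.id))
    return out
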