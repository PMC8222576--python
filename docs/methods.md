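# Methods

## Model overview

`ecesim` implements an embodied computational evolution system with three
coupled layers:

1. **Genetic system.** Each individual carries a fixed-length haploid genome
   of 18,000 quaternary digits (6,000 codons; digits 0–3 map to A/C/G/T for
   FASTA interchange). Codons are read in a fixed, non-overlapping frame
   from digit 0. A 64-entry codon table classifies every codon as part,
   feature, magnitude, start, or stop. Genes are the codon spans strictly
   between a start codon and the next stop codon; a start codon inside an
   open gene is an ordinary expressed codon, and a trailing unclosed start
   yields no gene. Mutation occurs only at replication: each digit is
   independently replaced, with probability μ, by one of the *other* three
   digits drawn uniformly, so μ is exactly the per-digit change probability
   and is dimensionally identical to the transcription-error rate τ.

2. **Developmental system.** Expression proceeds in update cycles. At cycle
   0 every codon in a gene's span is transcribed once; each digit of each
   transcription is independently corrupted with probability τ (same
   substitution model as mutation). The transcript's role is decided by the
   *transcribed* triplet — an error can make a feature codon masquerade as a
   magnitude codon and vice versa; transcripts whose transcribed role is
   start/stop, or a part beyond the gene's first, are inert. The first
   part-role transcript becomes the protopart; feature and magnitude
   transcripts accumulate in the gene's regulatory pool. Magnitude
   transcripts additively set the gene's feature-transcript allowance
   (codon 230's transcript allows one hundred; the other magnitude codons
   of the default table carry values 5–80). Cycle-0 transcripts are exempt
   from the allowance. On each later cycle a gene re-transcribes each of
   its genomic feature codons — fresh error draws every time — until the
   allowance is exhausted mid-cycle. Then genes interact: each contributes a
   uniformly random 10% of the transcripts it newly expressed this cycle to
   a shared epistasis pool, then each gene pulls a uniformly random 5% of
   the pool's current contents (without replacement, capped at pool size);
   counts are rounded half-to-even using exact rational arithmetic since no
   rounding rule is inherent to the percentages. Pulled magnitude
   transcripts raise the puller's allowance, so development can re-ignite.
   A hard cap of 10,000 cycles guards non-termination; hitting it aborts
   the individual.

3. **Body and behavior.** A finished part's properties grow additively:
   value = base + unit × (#'+' − #'−' matching feature transcripts), floored
   at a documented minimum. Defaults: sphere size (base 1.0, unit 0.1, min
   0.1), joint motor strength (0.05, 0.1, 0.0), sensor gain (1.0, 0.1,
   0.0), neuron bias (0.0, 0.1, −5.0), wire weight (0.5, 0.1, −3.0). Parts
   queue FIFO by (completion cycle, gene index). Assembly is deterministic:
   joints connect spheres into a tree (3 joint mounts per sphere; the first
   joint joins spheres 1–2, each later joint attaches the next unused
   sphere to the earliest open mount); neurons then sensors mount in sphere
   order (4 mounts each per sphere); wires consume the earliest legal open
   connector pair in the precedence sensor→neuron, neuron→neuron,
   neuron→motor, sensor→motor (sensors: 2 outputs; neurons: 1 input, 2
   outputs; motorized joints: 2 inputs; no duplicate edges or self-loops).
   A joint is motorized iff its grown motor strength exceeds 0. Development
   aborts if fewer than two spheres connect; a body is non-viable if no
   directed wire path links a sensor to a motorized joint. Both cases score
   fitness exactly 0.

## Fitness evaluation

Fitness is defined as straight-line displacement over a 501-step trial on a
flat, dry, empty plane, but its numeric value is a property of whichever
rigid-body engine hosts the trial. The package therefore specifies an
evaluator contract (name, determinism flag, `evaluate(morphology, network,
steps, seed) → TrialResult`) with three backends:

- **surrogate** (default): the deterministic closed form
  `(steps/501) · 100 · drive · body · sense`, with
  `drive = Σ_j strength_j · (1 + tanh Σ|w_in,j|)` over sensor-driven
  motorized joints, `body = n·e^(1−n/4)/4` for n spheres (peaks at four
  spheres and penalizes highly segmented bodies), and
  `sense = 1 + tanh(mean sensor gain)`. It is *not* a physics simulation;
  it exists to give selection a smooth, relabeling-symmetric objective that
  rewards sensor-driven actuation. Published displacement magnitudes from
  physics-backed experiments are not comparable to surrogate scores.
- **constant**: assigns every individual the same fitness and sets
  `requires_development = False`, letting the generational loop skip
  development entirely. This is the neutral-evolution control: with
  selection inert the phenotype cannot matter, and skipping development
  changes nothing but runtime.
- **physics**: an adapter base class (init world / step / read positions)
  for plugging in an external engine; nothing in the package or its tests
  requires one.

Joint commands are `π·tanh(Σ weighted inputs)`, always in [−π, π]; neurons
apply tanh to bias plus weighted input, with neuron→neuron wires reading the
previous synchronous step. The tanh update rule is a package default, chosen
for boundedness and smoothness, not a fidelity claim.

## Selection and the factorial experiment

Populations hold 60 individuals (configurable, even). Ranking is by
descending fitness with ties broken by ascending id, making selection fully
deterministic. For n = 60 the offspring table is exact: ranks 1–3 → 4
children, 4–9 → 3, 10–18 → 2, 19–30 → 1, 31–60 → 0 (total 60). Other even
sizes scale the same 1:2:3:4 tier proportions over the top half via
largest-remainder apportionment, then adjust from the lowest breeding ranks
until offspring equal n — a package generalization used only for scaled-down
runs (n = 20 gives tiers 1/2/3/4 making 4+6+6+4 = 20).

The canonical design crosses 11 μ levels with 11 τ levels
(0 to 0.0050 in steps of 0.0005), 121 conditions × 10 replicates × 100
generations × 60 individuals = 7.26 × 10⁶ records. `generations` counts
populations: generation 0 is the randomly initialized population and
generation 99 is the final one. Replicate seeds derive from (master seed,
replicate index) only — never the condition — so all 121 conditions start
from identical generation-0 genomes (the repeated-measures contract, checked
by test).

## Randomness and replay

Every random choice comes from a named substream keyed by small integers
(master seed, replicate, rate keys, generation, individual, stream tag) via
`numpy` SeedSequence, so any component replays in isolation. Development
records an `ErrorTrace`: the seeds of its transcription and epistasis
substreams plus every transcription-error event keyed by a global
transcription-event counter. Replaying a trace applies the recorded
corruptions at the same event positions without consuming transcription
randomness and re-seeds the epistasis stream, reproducing transcripts,
parts, morphology and (with a deterministic evaluator) fitness bit-for-bit.
This is the operational form of partitioning realized fitness into its
genetic and epigenetic components.

One deliberate asymmetry: at τ = 0 the epistasis exchange is seeded from a
digest of the genome itself rather than the individual's slot, which makes
error-free development a pure function of the genome. Without this, clones
of the best genome could develop differently in different slots and clonal
truncation selection could lose fitness at μ = τ = 0, violating the
monotonicity the error-free system is supposed to exhibit. At τ > 0 the
exchange seed varies with (replicate, condition, generation, individual) as
usual. During a cycle the transcriber always draws corruption variates for a
gene's full feature-codon block even if the allowance gate truncates the
walk, keeping RNG consumption independent of transcribed-role outcomes.

## Analysis

- **H** is computed from per-position digit counts in O(nL) (an individual
  differs at a position from exactly n − count(its digit) others); per-
  individual contributions are recorded raw and divided by genome length —
  the two genetic-variance measures in the lineage table — and H is half
  their sum. A brute-force pairwise loop serves as the test oracle.
- **Fitness summaries** report per-generation mean and SD; the SD uses the
  population denominator n, since the whole population is observed.
- **Cubic trends** ω̄ = A + Bx + Cx² + Dx³ are ordinary least squares on the
  Vandermonde design, fitted per population; by default every individual's
  fitness is regressed on its generation (pooled), with a generation-means
  entry point as the alternative. Repeated-measures ANOVA on the
  coefficients is out of scope; the tidy coefficient export is shaped for
  external statistical software.
- **Cost of τ** is loss(μ, τ) = ω̄_final(μ, 0) − ω̄_final(μ, τ) after
  averaging replicates; it requires the τ = 0 baseline column.

## Problem sizes in the shipped tests

The test suite and acceptance script run the full mechanism at reduced
scale: binomial calibrations use 10⁵–10⁶ digits; the trace-replay check
develops 50 full-length (6,000-codon) individuals at τ = 0.005; the
neutral-drift property uses 20-member populations, 300-codon genomes and 30
generations across the 11-level μ grid with 20 seeds per level; determinism
is checked on a 2 × 2 grid × 2 replicates. These sizes are the package's
choice of desk-scale study conditions; the full 1,210-run design is
expressed by the shipped default configuration and scales linearly.

## Known limitations

- The surrogate evaluator's scores have no physical units; cross-study
  comparisons of fitness magnitudes require a physics adapter.
- Bodies are trees (the assembly rules cannot form cycles); joint geometry,
  collision and 3D placement are delegated to the evaluator backend.
- The default codon table beyond its anchored entries (002/003 sphere-size
  pair, 230 = 100, start 111, stop 333), the growth constants, and the
  mount/connector capacities are versioned package defaults; alternative
  tables and body plans can be supplied as YAML.
- Diploidy, recombination, indels, variable-length genomes, and alternative
  selection schemes are out of scope.
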