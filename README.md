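# ecesim — embodied computational evolution

`ecesim` simulates populations of embodied agents whose genomes are strings
of quaternary digits read as triplet codons, and asks a population-genetics
question: how does random *epigenetic* error during development interact with
random *genetic* mutation to shape the genetic variance of an evolving
population?

Each agent develops through an explicit genotype-to-phenotype map. Start and
stop codons demarcate genes; a gene expresses one **part** transcript
(sphere, joint, sensor, neuron, or wire), plus **feature** transcripts that
additively grow the part's properties and **magnitude** transcripts that set
how many feature transcripts may be expressed. Every transcription event can
corrupt digits at the per-digit transcription-error rate τ — the genome
itself is never altered — while replication corrupts the genome at the
per-digit mutation rate μ. Genes interact through a shared epistasis pool:
each update cycle every gene contributes 10% of its newly expressed
transcripts to the pool and pulls 5% of the pool's contents. Finished parts
are assembled by fixed rules into a sphere-and-joint body with a wired
sensorimotor network; locomotor fitness ω is the Euclidean displacement over
a 501-step trial, and deterministic truncation selection (top half breeds;
the top 3 of 60 make 4 children each, ranks 4–9 make 3, 10–18 make 2,
19–30 make 1) closes the generational loop.

The population-level observables are mean fitness ω̄ and the genetic variance

> H = Σ over all unordered pairs (i, j) of Hamming(genome_i, genome_j),

tracked per generation across an 11 × 11 factorial grid of (μ, τ) ∈
{0, 0.0005, …, 0.0050}², 10 shared replicate populations of 60, 100
generations (a repeated-measures design: generation-0 populations depend
only on the replicate seed, never on the condition).

Because quantitative displacement values depend on a rigid-body physics
engine, fitness evaluation is a plug-in contract. The default backend is a
deterministic *surrogate* score (documented in `docs/methods.md`, and
explicitly not a physics result) with the qualitative structure selection
needs; `ecesim.behavior.PhysicsAdapter` is the hook for wiring in an
external engine.

## Worked example

```python
import ecesim as e

cond = e.Condition(mu=0.0025, tau=0.0025)
lineage = e.run_evolution(cond, replicate_seed=123, generations=5,
                          population_size=20, n_codons=3000)
df = lineage.to_frame()
print(df.groupby("generation")["fitness"].agg(["mean", "max"]).round(2))
final = df[df.generation == 4]
print("final-generation H:", int(final["var_hamming_raw"].sum() // 2))
```

prints

```
               mean      max
generation
0            161.52  1622.45
1            406.47  1128.36
2            746.41  1850.22
3            852.18  3156.25
4           1281.99  3998.78
final-generation H: 582878
```

Mean and best surrogate fitness climb under truncation selection within a
few generations, while H measures the genetic variance retained in the final
population (each individual's `var_hamming_raw` is its summed Hamming
distance to the rest of the population, so the pairwise sum is half the
column total).

The same machinery scales to the full factorial design from the shell:

```sh
ece run --config design.yaml --evaluator surrogate --out runs/ --resume
ece analyze --in runs/ --report grid     # final ω̄ as a mu x tau matrix
ece analyze --in runs/ --report trends   # per-population cubic coefficients
ece analyze --in runs/ --report cost     # fitness loss relative to tau = 0
ece replay --genome g.txt --trace t.txt  # re-develop a recorded individual
ece validate-table --codon-table src/ecesim/data/default_codon_table.yaml
```

`src/ecesim/data/default_design.yaml` holds the canonical design (121
conditions × 10 replicates × 100 generations × 60 individuals = 7.26 × 10⁶
records); scale `generations`, `population_size` and the level lists down
for desk-scale runs. Every run writes a lineage CSV (one row per individual:
id, parentage, generation, fitness, raw and length-normalized Hamming
variance contributions, and the five part counts) plus a manifest with
content hashes, so interrupted experiments resume cleanly and identical
master seeds reproduce byte-identical outputs.

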