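# kmerwalk

Coined quantum-walk search on the 4-dimensional DNA k-mer hypercube, with a
built-in exact statevector simulator — no quantum SDK required.

## The problem

DNA 2-mers over {T, C, A, G} encode to 4 bits (T=00, C=01, A=10, G=11), so
the 16 possible 2-mers are the vertices of a 4-dimensional hypercube
(tesseract) whose edges connect labels differing in one bit. A discrete-time
coined quantum walk can search this graph for a *marked* vertex: a 2-qubit
Grover coin chooses among the four edge directions, a shift operator moves
the walker, a phase oracle flags the target 2-mer, and quantum phase
estimation over the walk operator `W = S·(C ⊗ I)` turns the oracle's sign
flip into amplitude amplification of the marked vertex.

The full circuit uses 11 qubits — 4 theta (phase estimation), 4 node
(hypercube vertex), 2 coin, 1 auxiliary — and is loaded through an
11-character binary *initialization string* `aux|coin|node|theta` (rightmost
character → qubit 0). This package asks the question the study design poses:
**which of the 2048 possible register initializations still yield a usable
search?** It answers by sweeping all 2048 × 16 (initialization, mark)
combinations at 1024 measurement shots each and classifying every
initialization by the sample standard deviation σ of its 16-bin hit
distribution (σ ≈ 0 means featureless/random; large σ means a sharp,
interpretable pattern):

| category | band |
|----------|------|
| Random   | σ < 14.7 |
| Emerging | 14.7 ≤ σ < 21.0 |
| Weak     | 21.0 ≤ σ < 40.0 |
| Complex  | 40.0 ≤ σ < 50.0 |
| Clear    | 50.0 ≤ σ < 80.0 |
| Strong   | 80.0 ≤ σ |

## Worked example

```python
from kmerwalk import run_search, SearchConfig, encode_kmer, string_sigma_runs

# Search for the 2-mer GC (node 1101) from the all-zeros register
rec = run_search("00000000000", encode_kmer("GC"), SearchConfig(seed=1))
print(rec.marked_hits(), "/", rec.shots)      # -> 896 / 1024

# Setting theta = 0001 inverts the behaviour: the marked vertex is avoided
rec = run_search("00000000001", "0000", SearchConfig(seed=1))
print(rec.marked_hits(), rec.counts.min())    # -> 6 6

# sigma over an initialization's 16 mark runs drives its category
print(round(string_sigma_runs("00000000001", SearchConfig(seed=1)), 2))  # -> 29.26
```

With the calibrated default of 2 oracle + phase-estimation repetitions, the
all-zeros initialization hits the marked vertex with exact probability
0.886 for every mark (~904/1024 shots). The theta=0001 initialization
instead *avoids* the marked vertex (≈6/1024 hits, the minimum bin), and its
aggregate σ ≈ 29 places it in the Weak band — a pattern an interpreter can
still exploit by reading the minimum instead of the maximum.

The same circuits are available from the shell:

```bash
kmerwalk run --kmer CA --mark GC --seed 1
kmerwalk sweep --seed 1 --init-prefix 0000000 --out part.csv
kmerwalk analyze --in part.csv
kmerwalk kmers --fasta genome.fasta --k 2
```

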