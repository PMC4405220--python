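# holoperm

Circular convolution and random permutation are the two standard binding
operators in vector symbolic architectures for distributed semantic memory:
both compress a pair (or sequence) of high-dimensional random vectors into a
single vector of the same dimensionality from which the constituents can be
approximately recovered. `holoperm` implements both operators and the
experiments that compare them — as **paired-associate memories** with
clean-up retrieval, and as **order-sensitive semantic space models** trained
on text corpora — together with a relaxed "random connection" variant of
permutation that drops the one-to-one wiring constraint. It is written for
computational cognitive scientists who want to study the storage capacity
and semantic performance of these binding schemes under controlled,
fully reproducible conditions.

## The operators

**Circular convolution** (holographic reduced representation, HRR) binds
x⃗ and y⃗ into z⃗ = x⃗ ⊛ y⃗ with

    z_i = Σ_j  x_j · y_{(i−j) mod D}

computed here via FFT in O(D log D). Decoding uses the correlation operator
`#` (convolution with the index involution of the probe): y⃗ ≈ x⃗ # (x⃗ ⊛ y⃗).
An exact frequency-domain inverse is also provided
(`deconvolve_exact`), with the usual caveat that it amplifies superposition
noise.

**Random permutation** (RP) binds by position instead: Π is a random
coordinate shuffle, Πⁿ indexes the n-th slot of a sequence, and a
paired-associate trace takes the form

    M⃗ = Π y⃗₁ + Π² x⃗₁ + Π³ y⃗₂ + Π⁴ x⃗₂ + …

Decoding searches inverse powers Π⁻ⁿ M⃗ for the probe (argmax cosine over
n = 1…28), then applies one further inverse permutation to read out the
associate. Permutations are exactly invertible and O(D).

**Random connections** (RC) relax the bijection: every coordinate feeds one
random (not necessarily unique) coordinate; colliding inputs sum, unfed
coordinates go to zero. This is the `T` transform (y_k = Σ_i x_i w_ik with a
single 1 per row of w), a more neurally plausible cousin of Π.

The corpus encoders accumulate, for every word, a dynamic *memory vector*
m⃗_w from the static random *signal vectors* e⃗_w of its neighbours: either
all λ ≤ 5 n-gram convolutions containing the word (with a placeholder Φ in
the word's slot), signed permutation powers Π^j by relative position, or
direction-only variants over a ±2 window (Π⁻¹/Π, T/nothing, or T/T²).
Word similarity is the cosine between memory vectors.

## Worked example

Everything below runs with no external data; the corpus is generated with
planted synonym groups (words that interchangeably fill the same sentence
templates).

```bash
holoperm synth --documents 400 --seed 3 --out-dir fx
holoperm train --corpus fx/corpus.txt --operator rp --dim 1024 --seed 11 --out-dir model
holoperm evaluate --model model/model.txt --synonymy fx/synonymy.tsv \
    --similarity fx/similarity.tsv --out results.json
```

which prints

```json
{
 "synonymy": {
  "score": 1.0,
  "coverage": 1.0
 },
 "similarity": {
  "score": 0.7614334190168569,
  "n": 32
 }
}
```

Synonymy accuracy is the fraction of 4-way multiple-choice items answered
correctly (chance = 0.25): the permutation-trained order space recovers
every planted synonym pair. The similarity score is the Spearman rank
correlation between model cosines and the synthetic human ratings over the
32 rated pairs (the two-band rating design caps the achievable ρ well below
1 even for a perfect model).

The same pipeline is available as a library, sklearn-style:

```python
from holoperm import SemanticSpace

model = SemanticSpace(D=1024, operator="convolution", master_seed=11)
model.fit("fx/corpus.txt")
print(model.similarity("syn0_0", "syn0_1"))   # 0.990 — planted synonyms
print(model.similarity("syn0_0", "syn5_1"))   # 0.034 — unrelated words
```

The capacity experiment compares how many paired associates a single trace
can hold:

```bash
holoperm capacity --scheme rp --trials 100 --seed 1 --out-dir cap
```

writes per-cell retrieval counts (`capacity_cells.csv`) over the
dimensionality grid {256, 512, 1024, 2048} × pair counts {2, …, 14} against
a clean-up pool of 1,000 candidates, plus a JSON summary with the
cross-cell mean and SD of successful retrievals.

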