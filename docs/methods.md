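# Methods

This note documents the models implemented in `holoperm`, the choices made
where the underlying procedures admit more than one reading, and what the
synthetic fixtures do and do not establish.

## Binding operators

All representations are dense real vectors of dimensionality D. Circular
convolution z⃗ = x⃗ ⊛ y⃗, z_i = Σ_j x_j y_{(i−j) mod D}, is computed with the
real FFT (`irfft(rfft(x)·rfft(y))`); the test suite verifies agreement with
the literal double sum to 1e−8 relative tolerance at D ∈ {8, 64, 1024}.
The decoding operator `#` is defined, following Plate's standard
construction, as convolution with the index involution of the probe
(x*_i = x_{(−i) mod D}); in the frequency domain this is multiplication by
the complex conjugate. The sources that use `#` typically cite this
construction rather than restating it, so it is fixed here explicitly.
An exact inverse (frequency-domain division) is exposed as
`deconvolve_exact` / `retrieve_conv_associate(..., decode="exact_inverse")`.
It is exact for a single binding but amplifies superposition noise wherever
the probe's Fourier spectrum is small, which makes its retrieval accuracy
from crowded traces both worse and far more variable than correlation's —
a property worth having on hand when comparing decoding regimes
(see "Capacity experiment" below).

Permutation maps store `target_index` (source i → destination
`target_index[i]`); applying a power Πⁿ iterates the index map, which is
exactly invertible and norm-preserving. Negative powers use the inverse
map; n = 0 is the identity. Random-connection maps drop the bijection
constraint: destinations are drawn uniformly with replacement, application
sums colliding inputs (`bincount` with weights), and coordinates with no
incoming connection become zero. In expectation a fraction (1 − 1/D)^D →
1/e of coordinates receive no input after one application.

Cosine similarity of a zero vector is defined as 0 with a `RuntimeWarning`
rather than an error: random-connection transforms can zero out sparse
vectors entirely, and a batch experiment should record a failed retrieval,
not abort. Clean-up retrieval breaks cosine ties toward the lowest pool
index, making it deterministic.

## Signal vectors

Gaussian signal vectors have i.i.d. N(0, 1/D) entries, so E‖x⃗‖² = 1 at any
D. Sparse ternary vectors ("spatter codes") place n₊ = n₋ = 2 entries of ±1
by default at uniformly random distinct positions. Scale never matters for
retrieval (cosine is scale-invariant); the 1/√D convention keeps
superpositions O(1).

## Paired-associate traces and retrieval

A convolution trace stores k pairs as M⃗ = Σᵢ x⃗ᵢ ⊛ y⃗ᵢ; probing with y⃗ᵢ
computes y⃗ᵢ # M⃗ and retrieves the most cosine-similar member of the
clean-up pool E. A permutation trace stores the same pairs positionally,
M⃗ = Π y⃗₁ + Π² x⃗₁ + Π³ y⃗₂ + …, built here by a Horner recursion (2k
permutation applications). Retrieval is a sequential search: compute
cosine(Π⁻ⁿ M⃗, y⃗ᵢ) for n = 1 … 2·max_pairs (max_pairs = 14, so bound 28),
take the argmax n* (ties toward the smallest n), and clean up Π⁻⁽ⁿ*⁺¹⁾ M⃗.
A fixed-iteration search is used rather than a similarity threshold so the
decoder always returns an answer; a wrong n* counts as a retrieval error
like any other wrong label.

## Capacity experiment

Each (D, k) cell draws a fresh pool of m = 1,000 labeled signal vectors
(the clean-up memory), runs 500 independent trials (grid defaults;
scaled-down runs are a config parameter), and in each trial samples 2k
distinct pool members as the x's and y's (re-drawn across trials — i.e.
sampled with replacement at the experiment level), builds the trace, probes
one stored pair chosen uniformly, and counts a success only when the true
associate's label is returned. Chance is 1/m = 0.1%. The grid is
D ∈ {256, 512, 1024, 2048} × k ∈ {2, 4, 6, 8, 10, 12, 14}; seven k-levels
reproduce the degrees of freedom of the original factorial analysis, whose
exact k-values were not printed. Summary statistics are the mean and
sample SD of per-cell success counts across the 28 cells. Every cell's RNG
stream is derived from (master_seed, scheme, vector kind, D, k), so results
are bit-reproducible and independent of iteration order.

Under these conditions the random-permutation arms land on the published
statistics almost exactly (Gaussian: mean ≈ 459/500, SD ≈ 85 versus
published 457/86; sparse ternary with 20 nonzeros: ≈ 458/88 versus 455/88).
The sparse condition uses 20 nonzero elements because that is the
configuration behind the published grid figures; with only 4 nonzeros the
low-D cells degrade (grid mean ≈ 422), consistent with the published
observation that accuracy levels off once vectors carry more than a
handful of nonzeros. The convolution arm is reported by this package as it
measures it: correlation decoding under the same protocol yields a grid
mean ≈ 493/500 with SD ≈ 22, substantially better and far less variable
than the published 381/145 for the matching condition. We verified the
convolution/correlation algebra against independent direct-sum oracles and
checked the exact-inverse decoding variant (grid mean ≈ 322, SD ≈ 146) as
the nearest alternative reading; neither matches the printed mean, so the
discrepancy is documented rather than tuned away.

## Corpus encoders

Per word w the lexicon keeps a static signal vector e⃗_w and a dynamic
memory vector m⃗_w (zero-initialized). The convolution order update adds,
for every contiguous n-gram of length 2…λ containing w within a sentence
(λ = `max_ngram`, default 5), the left-to-right convolution of the
constituent signal vectors with a fixed placeholder Φ (drawn once at
lexicon initialization) substituted in w's slot. It is computed with
cumulative prefix/suffix products in the frequency domain — one inverse
FFT per (sentence, target). Because ⊛ is commutative, this literal form
cannot distinguish mirror-image n-grams; the non-commutative directional
variant used by some holographic models is deliberately not the default
here, matching the form the encoders are usually written in.

The permutation order update adds Π^j e⃗_u for every neighbour u at signed
offset j, 1 ≤ |j| ≤ λ−1: positive powers for following words, negative for
preceding. The canonical example only shows following words, so
preceding-word handling was an open choice; signed powers keep
decode-by-inverse well defined on both sides and match the
relative-position logic of the direction-only model.

Direction-only encoding (the window-±2 regime) applies one transform per
side: Π⁻¹ to the summed signal vectors of up to two words before the
target and Π to up to two after (powers of a single base permutation —
the alternative of two independent permutations is statistically
equivalent for decorrelation purposes); the first random-connection
variant applies T before and nothing after; the second applies T before
and T² after. Context updates add the plain sum of cue signal vectors
(sentence-wide with the bundled 280-entry function-word stop list for the
convolution model; the ±2 window with the 87 most-frequent-words threshold
for the permutation model). Frequency-thresholded and stop-listed words
are omitted as *cues* only: their own memory vectors are still trained.
Frequency rank ties break lexicographically. The full-scale permutation
model runs at D ≈ 25,000 and the holographic model at 1,024; the package
default is a desk-scale 2,048, configurable to either.

The published stop list contents are not available, so the package ships
its own 280-entry English function-word list as a replaceable data file
(`holoperm/data/stoplist_280.txt`).

## Synthetic corpus

The generator plants paradigmatic structure: each synonym group owns a few
sentence *templates* (a fixed sequence of filler words with one slot), and
every sentence realizes one template with one group member in the slot.
With probability `template_overlap` (default 0.9) a sentence uses one of
the group's own templates, otherwise a group-neutral one. A deterministic
seeding pass guarantees every member appears at least once in each home
template. Defaults: 16 groups of 2, 120 fillers, 400 ten-sentence
documents, sentence lengths 5–9. Evaluation files probe each member once
(3 distractors from other groups; chance 25%) and rate synonym pairs
3.2–4.0 versus cross-group pairs 0.0–0.8 on a 0–4 scale.

What the fixtures show: that each encoder recovers interchangeability-in-
context, the specific statistical signal it is built to capture, and that
the permutation and random-connection variants behave near-identically.
What they do not show: natural-language effects — Zipfian frequencies,
polysemy, topic drift, syntax beyond fixed templates — so synthetic scores
say nothing about absolute performance on real synonymy tests or human
similarity norms. The harness reads user-supplied corpora and TOEFL-style
TSV files for that purpose. Note one rank-statistics artifact: with
two-band ratings and within-band jitter, even a model that orders the two
bands perfectly has E[ρ] ≈ 0.75 (between-band rank variance over total),
so Spearman scores on the synthetic similarity file saturate around there.

## Numerical and design notes

- All randomness flows through integer master seeds via
  `numpy.random.default_rng`; derived streams are seeded with
  (master seed, component coordinates) tuples.
- Permutation powers are iterated index applications; any precomposition
  optimization must (and in tests does) agree exactly.
- Degenerate inputs: empty pair lists, empty vocabularies, empty corpora,
  and out-of-range target positions raise `ValueError`/`IndexError`;
  all-zero vectors participate with cosine 0 and a warning.
- The sklearn facade (`SemanticSpace`) treats the corpus as `X` in
  `fit(X)` and words as the transformable items; `get_params`/`set_params`
  and `clone` work as usual, so the encoder drops into sklearn model
  selection. The capacity experiment is not estimator-shaped and stays a
  plain function (`run_capacity_grid`).
- Known limitations: no complex-valued holographic networks, no GPU path,
  no threshold-based early-stop decoding as a default, lexicon size
  uncapped (no frequency-based truncation), and absolute scores on real
  benchmark datasets are out of scope without user-supplied data.
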