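# Methods

## The problem being modelled

A DEL selection against a protein–protein-interaction target is an extreme
needle-in-a-haystack experiment: of ~10⁶–10⁷ barcoded compounds, often one
enriches genuinely, and everything downstream — scoring, dataset
construction, model fitting — must work with essentially a single positive
example. `delscreen` implements that full analysis path and, because such
screen data are proprietary, a synthetic replica of the experiment on which
every stage can be exercised and tested.

## Enrichment scoring

Per condition (target, beads-only, tag-only) each compound has a
pre-selection and post-selection read count. The enrichment fold is

    EF = (post count / post depth) / (pre count / pre depth),

computed exactly whenever the pre-count is positive; a compound never seen
before selection gets a pseudo-count of 1 in the denominator (the ratio is
otherwise undefined, and this choice never changes a compound with observed
pre-reads). Counts and EFs are then normalized per condition across the
whole library and the two background channels subtracted, giving the score
`a·count + b·EF` with defaults a = 0.8, b = 0.2 — the count channel is the
more reliable readout at realistic depths.

Normalization is min–max by default (z-score behind a switch): it is the
simplest scheme that pins the top of each channel at 1, so a clean single
binder scores near 1. A constant channel normalizes to all zeros rather than
NaN — a channel with no variation carries no information. Scores are *not*
clipped: matrix binders (enriched on beads regardless of target) legitimately
score below zero, and the subtraction is exactly what removes them from the
hit region.

IC50 bucketing uses half-open intervals [10,20), [20,30), … with the two open
ends <10 → 1 and >50 → 0; exactly 50 µM falls into the last measured bucket
(0.6). The prose rule is boundary-ambiguous; the boundaries live in one
constant (`IC50_BUCKETS`).

## Synthetic data generator

The generator emulates the *layout and regime* of a real screen, not its
chemistry or amplification physics:

* **Counts** are multinomial per condition with the read depth as a fixed
  budget (reads are a conserved resource; independent Poissons would not
  conserve depth). Pre-selection weights are uniform; post-selection weights
  multiply a binder's weight by the enrichment multiplier in the target
  condition only. A configurable "sticky" subpopulation (default 2% of the
  library at weight ×20) is enriched in **all three** conditions — the
  matrix-binder background that the tag/beads subtraction exists to remove.
  The planted binder's expected EF has the closed form m·M/(M−1+m) for
  multiplier m and library size M, which the tests check.
* **The derivative panel** plants a structure–activity relationship around
  the hit: actives are single-site small R-group additions that keep the
  hit's naphthalene pharmacophore; inactives (censored at >50 µM, stored as
  the sentinel 51.0) mostly have the pharmacophore ring system replaced by
  cyclohexane plus one or two substituents, while ~15% keep it but carry
  heavy multi-site edits — so pharmacophore retention predicts activity
  noisily, not perfectly. Active IC50s are log-uniform on 3–48 µM with one
  forced below 10 µM, spanning the potency range such panels show.

What the generator does **not** emulate: PCR amplification bias, sequencing
error, barcode misassignment, synthesis yields, or any real binding
thermodynamics. Passing the planted-signal benchmark therefore shows that
the pipeline recovers a recoverable signal under the stated count model — it
is not evidence about any particular real target.

## Dataset construction

Undersampling sorts by score ascending (ties broken by compound id, so the
order is total and reproducible) and keeps every N-th record starting at
index 0 — size ⌈n/N⌉. Oversampling repeats each of the top-k (default 100)
highest-scored compounds `multiple` times; the two sets are built
independently and concatenated. Positive-sample generation, when enabled,
replaces all but one repeat of each oversampled compound with bit-perturbed
copies (type 1 sets randomly chosen zero bits; type 2 flips randomly chosen
bits) and jitters the score by Uniform(−0.1, 0.1). Generated fingerprints
correspond to no molecule: they carry no atom-environment map and are
excluded from attribution.

valid1/test1 are drawn without replacement from the library excluding every
training compound id (disjointness is enforced by id even though repeats
enter training). The derivative panel is ranked most-active first (censored
last, ties by id); odd ranks form valid2, even ranks test2.

At full screen scale, interval sampling of 1,104,808 records with N = 8
yields 138,101 training records (⌈n/N⌉); published bookkeeping for this
regime sometimes quotes slightly larger totals, which pure interval sampling
cannot produce — this implementation documents and tests the closed form.

## Models

* **LightGBM**: bagging fraction 0.8 (freq 1), feature fraction 0.76,
  λ₁ = λ₂ = 10, learning rate 0.5, 31 leaves, 200 boosting rounds, single
  thread and `deterministic=true` so model files are byte-stable. Early
  stopping on valid1 is implemented but **off by default**: valid1 contains
  essentially no positives, so its MSE is blind to whether the oversampled
  binder has been fit at all and stops training after one round — a fixed
  round count is the defensible default in this imbalance regime.
* **MLP**: one hidden layer of 256 relu units, dropout with *drop*
  probability 0.8 (some frameworks quote keep-probability; this one does
  not), softplus output (predictions ≥ 0), Adam at 0.005. Epochs (30),
  batch size (256) and early-stopping patience (5, on valid1 MSE with best
  weights restored) are implementation choices exposed in the config. The
  network is implemented directly on numpy, which makes training exactly
  reproducible from the seed across runs.

Model selection: among grid points with valid1_mse + valid2_mse < 0.15,
take the highest valid2 hit ratio, ties to the smaller MSE sum. An empty
feasible set raises an error carrying the best-ratio report as advisory. A
hit ratio with an empty high-score set is `None`/null, never 0 — a model
that scores nothing highly has found nothing, not found nothing *active*.

Default high-score thresholds are 0.5 for the GBM and 0.4 for the MLP,
reflecting where the two models' prediction scales sit.

## Attribution

For each set bit i, weight(i) = predict(fp) − predict(fp with bit i
cleared); unset bits are not probed (they encode no present substructure).
Weights are normalized by the largest *absolute* weight (so
negative-dominated molecules normalize sensibly), added to the center atom
of every environment that hashed to the bit, and — if summed magnitudes
exceed 1 — rescaled so the peak atom stays at ±1. Rendering uses
atom-centered Gaussians (default σ 0.3 in depiction units) with green for
favourable contributions.

## The scaled benchmark

The shipped end-to-end study uses a 37³ = 50,653-member library (the full
catalogue of 37 acids × 37 amino acids × 37 amines), depth 10⁶ per
condition, one planted binder at multiplier 1000, and a 34-member panel with
7 actives. Undersampling N = 8 and oversampling 100×800 are the method's
standard operating point and are kept as-is: the oversample multiple
interacts with LightGBM's leaf regularization (leaf values shrink by
m/(m+λ)), so scaling it down with library size would push the model into a
shrinkage regime the method is not meant to run in. valid1/test1 are 5,000
each (~9% of the library, matching the full-scale proportion). Ten fixed
seeds (1–10) define the benchmark; the whole suite runs in a few minutes on
one CPU.

## Numerical and degenerate-input choices

* All randomness flows from explicit `numpy.random.default_rng` seeds; the
  pipeline derives stage seeds as master+0…+3 and reruns are byte-identical.
* Enumeration reports template failures per block combination instead of
  dropping them; ambiguous template matches keep the first canonically
  sorted product (or raise, by config).
* Fingerprints are binary (presence, not counts), matching the
  substructure-existence semantics of the representation.
* Constant normalization channels → zeros; all-zero attribution weights →
  all-zero map (no division); empty high-score sets → undefined ratios.

## Known limitations

* The count model is multinomial with uniform base weights; real screens
  have strongly non-uniform synthesis yields and amplification bias, so
  real EF distributions are wider than the simulator's.
* The derivative generator edits molecules by single-bond substituent
  attachment and ring replacement; it does not attempt synthesizable
  chemistry.
* The MLP is a minimal dense implementation (no GPU, no sparse input); at
  full screen scale the GBM is the practical model.
* Bit-masking attribution inherits hash-collision ambiguity: a bit shared by
  several environments distributes one weight to all of them.
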