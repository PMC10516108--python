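# Methods

## The alignment loop

`genalign` treats molecular generation as a language-modelling problem over
SMILES tokens and alignment as iterated fine-tuning on a strategically
constructed training set. The quantity being optimized is the score of a
protein–ligand interaction scorer; the mechanism that makes the loop cheap
is a *chemical space proxy* — a PCA of molecular descriptors — in which
position correlates with score, so scores measured on a small subset can be
extrapolated to cluster-mates that were never scored.

Assumptions the loop rests on:

1. position in the proxy correlates with the scoring function, and
2. nearby molecules in the proxy have similar scores.

Both hold by construction for the bundled surrogate scorer (a smooth
Gaussian bump in proxy space) and empirically for interaction-count scorers
over descriptor PCAs; nothing in the machinery checks them at run time.

## Corpus preprocessing

Raw SMILES are parsed with RDKit; invalid strings are dropped and the rest
canonicalized and deduplicated (results are input-order independent).
Tokenization uses the standard SMILES regex grammar: bracket atoms,
two-letter elements (`Cl`, `Br`, `Si`, `Se`), aromatic atoms, bonds,
branches, ring-closure digits and `%nn` closures are single tokens. Strings
containing any token occurring fewer than `min_count` times (default 1000;
counts taken once, over the pre-pruning corpus) are removed. A token-length
cutoff is set at the smallest length covering a `coverage` quantile
(default 99.99%). Sequences are encoded as `!` + tokens + `~` padded with
`<` to a uniform length; the specials occupy indices 1, 2, 0. The
train/validation split is seeded, with train size = ⌊fraction·n⌋.

The canonical-SMILES dialect is RDKit's default; the RDKit version is
recorded in preprocessing reports and run manifests because canonical forms
differ across versions.

## Generator

A GPT-style transformer decoder: learned token + position embeddings, then
`n_blocks` pre-norm blocks (causal multi-head attention, 4×-width GELU MLP),
a final layer norm and an untied linear head. The 4×-width/GELU block
internals are a conventional choice. Full-scale defaults: 256-d, 8 blocks,
8 heads, dropout 0.10 after each feed-forward output (not on the head).
Weights initialize N(0, 0.02²), layer-norm gains 1, biases 0.

Training minimizes token-level cross-entropy with pad targets masked.
The optimizer is AdamW with β = (0.965, 0.99), decoupled weight decay 0.1
applied to linear-layer weights only (not embeddings, layer norms or
biases), and global gradient-norm clipping at 1.0. (A Sophia-style
second-order optimizer would match the published recipe exactly; the
methodology is agnostic to this choice and the manifest records the
fallback.) The learning rate warms up linearly from 0 to the peak over the
first 10% of training tokens (pretraining) and then follows a cosine decay
to the final value; fine-tuning uses no warmup. Full-scale schedules:
pretrain 30 epochs, batch 512, 3e-4 → 3e-5; fine-tune 10 epochs, batch 512,
3e-5 → 3e-6.

The implementation is NumPy with hand-written backpropagation, verified
against finite differences in the test suite. Batches are length-bucketed
and trimmed to their longest member, and sampling uses a KV cache with
periodic compaction of finished sequences; both are pure efficiency
measures with no effect on the math (the loss already masks pads).

Generation samples autoregressively from the start token (multinomial at
temperature 1.0 by default, configurable) until the end token or the
context limit; outputs are canonicalized, invalid strings discarded, and
uniqueness enforced by canonical form. Sampling stops with a reported
shortfall when a configurable attempt budget is exhausted.

## Chemical space proxy

Descriptors come from a pluggable provider: the full RDKit
`CalcMolDescriptors` set (~210 descriptors) by default, or a curated
22-descriptor fast subset used by the tiny profile (~30× faster; spans
size, lipophilicity, polarity, topology and ring content). Any descriptor
column that is NaN/inf for at least one molecule is dropped and reported.
Descriptors are standardized to zero mean and unit variance before PCA
(configurable; raw descriptors span wildly different magnitudes, and
unstandardized PCA would be dominated by the largest ones). The PCA (first
120 components at full scale) is fitted once per run on the pretraining
corpus and reused for every later projection, so ensembles from different
iterations share a coordinate system.

k-means (scikit-learn, k-means++ init) is run `n_restarts` times (default
100), restart *r* seeded `seed + r`. Among the five lowest-inertia restarts
the one with the lowest population variance of cluster sizes is selected;
ties break toward lower inertia, then lower restart index.

Scored-subset selection takes up to `cap` (default 10) random molecules
per cluster — all of them when a cluster is smaller — then tops up
uniformly from not-yet-selected molecules in above-cap clusters until
`total` (default 1000) is reached or the population is exhausted (reported
as a shortfall, not an error). With the defaults this scores 1% of a
100 000-molecule ensemble.

## Scoring

`score(profile) = Σ_t weight_t · count_t` over nine attractive interaction
types with fixed default weights (hydrophobic 2.5, hydrogen bond 3.5,
ionic 7.5, cation–π 2.5, van der Waals 1.0, halogen bond 3.0, π-stack
face 3.0, π-stack edge 1.0, metallic 3.0). The score threshold for AL-set
membership is the minimum score over a reference-ligand set.

Pose generation is strictly behind the `PoseProvider` contract
(SMILES → `InteractionProfile` or failure); shipped providers read
precomputed profile CSVs or use the synthetic surrogate. The reference
geometric detector is intended for toy complexes and validation, not as a
docking replacement. Its criteria live in one config: hydrophobic — apolar
C/S pairs ≤ 4.5 Å; hydrogen bond — N/O donor–acceptor pairs ≤ 3.5 Å, with
a ≥ 130° D–H…A angle requirement when explicit hydrogens are present
(distance-only otherwise); ionic — opposite formal charges ≤ 4.5 Å;
cation–π — cation to aromatic-ring centroid ≤ 4.5 Å; halogen bond —
C-bonded halogen to N/O acceptor ≤ 3.5 Å; π-stacking — ring centroids
≤ 5.5 Å, face-to-face at interplanar angle ≤ 30°, edge-to-face at ≥ 60°;
metal complexation — metal to N/O/S ≤ 2.8 Å; van der Waals — heavy-atom
pairs within the vdW-radii sum + 0.5 Å *not already counted* under any
other type.

Counting conventions: a qualifying protein/ligand pair is counted once per
type and may satisfy several types (an ionic N⁺/O⁻ pair at 3.4 Å is also a
hydrogen bond), with two exclusions beyond the van-der-Waals rule above:
atom pairs between two rings counted as a π-stack, and cation–ring-atom
pairs of a counted cation–π contact, are not re-counted as hydrophobic.
Without this convention any edge-to-face stack inside the 5.5 Å centroid
cutoff would unavoidably add spurious hydrophobic contacts from the rings'
own carbons (the geometry leaves no gap between the two cutoffs), which
would make planted-interaction round-trips impossible; interaction
fingerprints conventionally avoid such double counting as well.

## AL training-set construction

With `n` scored molecules at or above the threshold, each is replicated
N = ⌈floor / n⌉ times (floor 5000), so N·n ≥ floor and (N−1)·n < floor.
Mean cluster scores (over clusters with at least one scored member;
clusters with none are excluded — no mean exists) are converted to sampling
fractions by an overflow-guarded softmax. Fraction × budget (budget 5000)
is integerized by largest-remainder rounding; clusters capped at their
population return their surplus, which is redistributed proportionally
among uncapped clusters until the budget is met or the population is
exhausted. The sampled part is drawn without replacement per cluster from
the generated ensemble; sampled molecules may coincide with scored ones
(the set feeds training, not evaluation). Replicas and samples are
shuffled together under the training seed. If nothing passes the
threshold, the loop continues with the sampled part alone (and the naive
control, which has no sampled part, skips fine-tuning for that iteration).

## Modes and orchestration

`complete` is the methodology; `uniform` replaces the softmax fractions by
1/k (isolating the score-independent *diffusion effect* of cluster
sampling); `naive` scores a random subset and fine-tunes on replicas only.
All three share code paths — forcing equal mean scores makes `complete`
and `uniform` produce identical allocations (tested).

All randomness derives from a master seed through a hash-based ledger
keyed by (stage, iteration), so any stage is independently reproducible.
The projection model is frozen after fitting. Metrics row 0 evaluates the
pretrained model; a run with `n` iterations emits `n + 1` rows. With a
workdir, checkpoints and metrics are written per iteration and a run
resumes from the last completed one. Score statistics are computed on the
scored subset (the molecules actually evaluated), not the full ensemble —
subset and ensemble statistics should not be conflated.

## Synthetic world (tiny profile)

The tiny profile preserves the full recipe's ratios at desk scale:
300-molecule corpus, 2000 generated per iteration, scored subset 100 (5%),
k = 20 with cap 5, replica floor 250, sampling budget 250, 64-d/2-block/
2-head model, batch 16, fast descriptors, 10 PCA components, 20 k-means
restarts. Pretraining runs 50 epochs at peak 6e-4 (chosen for desk-scale
convergence; a model this small needs a larger step than the full-scale
3e-4), and fine-tuning keeps the full recipe's 10× lr reduction
(peak 6e-5) and 10 epochs.

The toy corpus enumerates a scaffold × substituent space (benzene,
pyridine, cyclohexane, naphthalene, amide/ester/amine templates; halogen,
hydroxyl, nitrile, carboxyl, trifluoromethyl substituents; plus alkane and
ether chains for token-length spread), validated and deduplicated through
RDKit — about 850 molecules.

The surrogate scorer stands in for docking + contact scoring:
`score(x) = A·exp(−‖x − target‖² / 2s²) (+ noise)` at projected coordinate
x, with per-molecule deterministic noise. Its calibration *is* the stated
starting world: the target sits at the corpus's extreme along the first
principal component, the length scale is half the corpus's RMS distance
from the target, and A is set so 25% of the pretraining corpus scores at
or above the threshold — matching the starting range of the full-scale
experiments (21–39% at iteration 0). Scores are back-filled into pseudo
profiles as van-der-Waals counts (weight 1.0), so the profile reproduces
the score at integer granularity. What the surrogate does **not** emulate:
rugged score landscapes, pose failures, and any chemistry the descriptors
miss — a green end-to-end test establishes that the loop aligns a
generator to a smooth objective through the proxy, not that it reproduces
docking results.

Toy complexes for detector validation plant each requested interaction
exactly: one geometric unit per contact (e.g. an N⁺/O⁻ pair at 4.2 Å for
ionic — inside the ionic cutoff, outside hydrogen-bond range), on a 40 Å
grid so no cross-unit pair approaches any cutoff. The round-trip
detect(make_complex(p)) = p is verified exhaustively for all profiles with
total count ≤ 5.

## Numerical choices and degenerate inputs

- Softmax is overflow-guarded by max subtraction; fractions sum to 1 within
  1e-12.
- Largest-remainder rounding breaks ties by first occurrence (stable sort).
- k-means selection ties break toward lower inertia, then lower restart
  index.
- Threshold comparisons are inclusive (≥) throughout.
- Empty score lists, empty corpora, and k > n are errors; selection and
  generation shortfalls are warnings with partial results.
- Seeds derived from the master seed are SHA-256-based and < 2³¹.

## Known limitations

- The published experiments' absolute numbers (e.g. threshold-fraction
  trajectories for c-Abl kinase or the Cas9 HNH domain) require pretraining
  on millions of molecules and GPU docking; this package reproduces the
  methodology and its desk-scale dynamics, not those values.
- At desk scale the naive control is anomalously strong: with a smooth
  surrogate and a tiny corpus, fine-tuning on replicas of ~25 winners
  generalizes locally almost as well as cluster extrapolation, so the
  full-scale ordering complete > uniform > naive collapses to
  complete > naive > uniform in the bundled benchmark. The complete
  methodology still wins on every seed tested.
- The reference detector is O(n²) in atom count with distance-inferred
  connectivity — adequate for toy complexes, not for real structures.
- Default drug-likeness filters are a configurable Lipinski-style stand-in,
  not a validated ADMET panel.
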