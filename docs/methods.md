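# Methods

## The problem

In beam-type collision-induced dissociation (QqQ, QTOF, HCD), protonated
peptides fragment predominantly at backbone amide bonds, and at the higher
collision energies of these instruments the C-terminal (y-ion) series
dominates the observable spectrum.  Predicting the relative intensities of
the y ions of a peptide directly from its sequence is useful wherever
library spectra are missing: scoring putative peptide-spectrum matches,
and above all choosing SRM/MRM transitions, where only the few most
intense fragments of a peptide are monitored.  `yfrag` implements such a
predictor end to end — library preparation, feature encoding, a hybrid
recurrent/convolutional/dense network, cross-validated training, and the
comparison statistics — together with a generative fragmentation
simulator so the whole pipeline can be exercised and tested at desk scale
without external spectral libraries or accelerator hardware.

## Library preparation

Input libraries are NIST-dialect MSP text (`Name: SEQUENCE/charge`,
optional `Comment:` with a `CE=` key, `Num peaks:`, then
`m/z <tab> intensity <tab> annotation` lines).  Cleaning proceeds as:

1. modification markup is stripped and modified residues are encoded as
   their unmodified counterparts;
2. all non-y peaks (b ions, a ions, neutral losses, unannotated peaks)
   are removed, as are y ions outside the representable range
   (ordinal > 14 or fragment charge > 3);
3. duplicate (sequence, precursor charge) entries across sources collapse
   onto the spectrum with the most annotated peaks (ties: first source);
   the same sequence at different charge states is treated as two
   distinct peptides;
4. peptides with fewer than three annotated y-ion peaks are dropped
   (threshold exposed as `min_peaks`).

Intensities are stored as read; all normalisation happens at encoding
time.  Peak counts for deduplication are compared after cleaning.

## Encoding

Peptides of length 6–15 are supported.  Three input channels:

* **one-hot sequence** — 15 x 20 matrix, residues alphabetical by
  one-letter code, rows beyond the sequence zero;
* **scalar features** — (CE, precursor charge, length, proline count),
  scaled by (1/100, 1/3, 1/15, 1/15) to order one;
* **sliding windows** — all 4-mers as a 4 x 12 matrix, one window per
  column, residue codes = alphabetical rank/20, padding columns zero.

The target is a 42-slot vector covering y1..y14 at fragment charges 1–3
(slot = (ordinal-1)*3 + charge-1, i.e. ordinal-major).  Intensities are
base-peak normalised (most intense y ion = 1).  A slot is *feasible* iff
its ordinal is at most length-1 and its charge at most the precursor
charge; feasible slots without an observed peak hold 0, infeasible slots
hold -1.  Targets therefore live in {-1} ∪ [0, 1] and exactly one entry
is 1 whenever any peak exists.

## The network

The forward path (all widths configurable through `ModelConfig`):

1. the one-hot sequence is consumed **C-terminus first** by a
   bidirectional GRU encoder (hidden size H; 128 by default).  Feeding
   the sequence in C→N order aligns recurrence position t with the t-th
   rung of the y-ion ladder, which is the coordinate system of the
   output;
2. a scaled dot-product self-attention runs over the encoder states,
   with a residual connection (so per-position identity survives the
   attended mix) and one-hot positional codes appended to the attention
   keys and queries;
3. the scalar features pass through two fully connected ReLU layers; the
   window matrix passes through three 3x3 convolutions (ReLU, no
   pooling — the 4 x 12 input is small) and a linear projection;
4. the concatenated dense+convolutional vector is projected to a
   (2H x d) matrix and multiplied against the attended encoder states,
   yielding the decoder's input sequence — the global features thereby
   gate every position of the sequence representation;
5. a second (unidirectional) GRU decodes this sequence, initialised from
   the encoder's final hidden state;
6. a second dot-product attention reads the decoder states with one
   learned query per y-ion ordinal; keys again carry positional one-hot
   codes, and each query is initialised to focus on the two residues
   flanking its own cleavage site (positions k-1 and k from the
   C-terminus).  This initialisation encodes where the chemistry of
   cleavage k physically sits; it remains fully trainable;
7. each ordinal's attention context, concatenated with the final decoder
   state (the global summary needed for base-peak normalisation), passes
   through shared linear layers emitting that ordinal's three charge
   slots.  The output layer is linear — targets include the -1 fill, so
   no squashing activation is applied.

The per-ordinal queries, the positional codes and the informed query
initialisation were the decisive design choices: with a single pooled
readout the network cannot resolve which of 42 slots carries the
intensity and plateaus far above the achievable loss.

All tensors run on a small in-package reverse-mode autodiff engine
(`yfrag.autodiff`) whose gradients are finite-difference-checked in the
test suite.

## Training

Mean-squared-error loss over all 42 slots ("mean" reduction), including
the -1 fill — the network learns to reproduce the fill, which is a
deterministic function of length and charge.  A masked variant (feasible
slots only) and a top-3-weighted variant (extra MSE term on each
sample's three most intense target slots, for SRM/MRM-oriented training)
are provided.

Optimisation: Adam at learning rate 0.01 with a reduce-on-plateau
schedule on the validation loss (mode min, factor 0.1, patience 7),
global gradient-norm clipping at 5 and a 150-step linear warmup to the
peak rate (without these, roughly one run in ten either finds a poor
basin or dies at the constant-prediction minimum in the first epoch —
the usual hard-start of attention models under a high initial rate),
best-validation-epoch checkpointing, and early stop after 15
non-improving epochs.  Default batch size is 256; the desk-scale recipe
(`desk_train_config`) uses batch 64, because a 2,000-peptide corpus at
batch 256 yields only ~240 optimizer updates in 30 epochs — too few to
converge.  The desk recipe also trains with the masked
(feasible-slot-only) loss: spending no capacity on the deterministic -1
fill raises the held-out median PCC by roughly 0.02 at this model size.
The all-42-slot loss remains the `loss_mse` default.

10-fold cross-validation partitions the corpus by shuffled index into
disjoint, jointly exhaustive validation sets; each fold's model is
scored by its median without-zero PCC on a common held-out evaluation
set, and the mean/SD of the fold medians measure cross-fold uniformity.

## Evaluation statistics

* **without-zero PCC** — per-peptide Pearson correlation computed only
  over slots where the library spectrum has a peak;
* **with-zero PCC** — over all feasible slots, absent peaks as zero.
  The two agree exactly when every feasible slot holds a peak;
* **highest-peak accuracies** — exact argmax match; predicted argmax
  within the library top 3; predicted top 2 within the library top 3
  (library ties broken by slot order);
* **PSM grouping test** — peptides whose precursor m/z differ by at most
  0.5 Th and that share at least three product ions within 0.5 Th are
  linked; groups are connected components of the link graph (the
  alternative clique topology is noted as an open choice; components are
  deterministic and order-invariant).  Shared-fragment counting is the
  symmetric minimum of one-sided matches.  Within each group, every
  predicted spectrum is matched to the library spectrum with the highest
  PCC (ties: lowest MSE); the match accuracy is the fraction of peptides
  matched to themselves;
* monoisotopic y-ion and precursor m/z are computed from the standard
  residue masses (via pyteomics), (Σ residues + H2O + z·H+)/z.

Undefined correlations (constant vectors, fewer than two points) are
returned as NaN and excluded from medians.

## The simulator

The generator emulates the statistical signatures that motivate the
model's feature set.  For a random peptide (length uniform on 6–15,
residues i.i.d. uniform by default, charge 2 with probability 0.7 else
3), each cleavage site k of a length-L peptide receives a log-intensity
score

    s_k = β_P·1[+1 residue is P] + β_L2·1[k = L-2] + β_L4·1[k = L-4]
        + β_ali·1[-1 ∈ {A,V,L,I}] + β_aci·1[-1 ∈ {D,E}] + ε_k,
    ε_k ~ Normal(0, σ)

and the y-ion intensity is exp(s_k), base-peak normalised.  The
exponential link keeps intensities positive and makes each β a
multiplicative intensity bonus.  One peak is emitted per cleavage; its
charge equals the precursor charge with probability 0.15 (+0.45 when the
fragment contains proline, capturing proline's charge-retention bias),
otherwise a lower charge is drawn uniformly.  Every non-base peak is
dropped with probability 0.15, emulating detection loss of minor ions
(the base peak of a stored library spectrum is, realistically, always
present).

Defaults: β_P = 2.0 (a proline cleavage is ~7x enhanced, strong enough
to dominate a spectrum, as the +1-proline anomaly does in real QTOF
data), β_L2 = 1.2 and β_L4 = 0.5 (the length-2 preference clearly
visible but weaker than proline; length-4 weaker still), β_ali = 0.5 and
β_aci = 0.7 (moderate flanking-residue effects), σ = 0.3 (≈ ±35%
multiplicative intensity noise), dropout 0.15.  These were fixed once as
a realistic regime; they are not tuned to any test outcome.

Presets: `flat` (all effects and noise off — every cleavage at intensity
1), `paperlike` (all effects on, the default parameters), `proline-only`
and `length-only`.  A separate generator, `confusable_library`, builds
families of near-isobaric peptides (identical residue composition and
charge, shared C-terminal hexapeptide, permuted N-terminal part) to give
the PSM grouping test non-trivial input: random unrelated peptides
almost never collide within ±0.5 Th.

What the simulator does **not** model: b ions and neutral losses, noise
peaks at arbitrary m/z, isotope envelopes, retention time, residue
modifications, CE dependence of fragmentation, and any coupling between
sequence composition beyond the listed local effects.  Tests passing on
simulated data therefore demonstrate that the pipeline recovers known
structure of this kind; they do not certify accuracy on real libraries.

## Desk-scale experiment sizes

The simulated experiments use a 2,000-peptide training corpus, a
500-peptide held-out evaluation set, 30 training epochs of the compact
(hidden-32) configuration, and a 10,000-peptide library for the
characterization statistics; the confusable-peptide test uses 120
two-member families.  These sizes keep a full pipeline run in the
tens-of-minutes range on a single CPU while leaving every measured
effect far from its noise floor.

## Numerical choices and edge cases

* Ties (equal intensities) always resolve to the smaller slot index;
  grouping is order-invariant by construction.
* Spectra reduced to zero peaks by cleaning are removed by the min-peak
  filter; encoding a peak at an infeasible slot is an error naming the
  peak.
* Empty-library summaries flag the mean as undefined rather than raising.
* Checkpoints serialize config + parameters and reproduce forward
  outputs bit-exactly on the saving platform.
* All randomness (simulation, fold assignment, batch order, parameter
  initialisation) flows from explicit integer seeds; two runs with the
  same seeds produce identical loss curves and libraries.

## Known limitations

* The predictor is y-ion only, unmodified sequences only, length 6–15,
  charge 1–3; b ions and neutral losses are out of scope.
* The published-scale benchmark (training on ~10^5 real QTOF peptides)
  is outside desk scope; the compact configuration and simulated corpus
  are the supported regime.
* The "matrix multiplication" merge and the decoder initialisation
  follow one concrete reading of an under-specified design; alternatives
  (e.g. attention-based merges) were not explored.
* MSE including the -1 fill spends model capacity on a deterministic
  region of the target; the masked loss is provided but is not the
  default, to keep the fill-then-MSE training semantics.
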