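# Methods

`aptazyme` implements an end-to-end pipeline for predicting and designing the
basal gene-regulatory activity of sTRSV hammerhead ribozyme variants and
aptazyme (ribozyme switch) candidates. This note records the models, the
conventions chosen where the design was genuinely open, the synthetic data the
tests rely on, and the limitations of both.

## The system

The sTRSV hammerhead ribozyme self-cleaves when tertiary contacts form between
its two stem-loops. Placed in the 3' UTR of a GFP reporter (with constitutive
mCherry for normalization), cleavage destabilizes the transcript, so a
ribozyme's *basal gene-regulatory activity* is its mean log10(GFP/mCherry) —
low values mean efficient cleavage. A tertiary-interaction ribozyme switch
replaces one loop with a ligand-binding aptamer; design aims for the lowest
possible basal activity, on the assumption that ligand binding will disrupt
the loop-loop contacts and raise expression.

## Scaffold and structure parsing (`scaffold`)

The scaffold is data, not code: a JSON fixture with ordered fixed-sequence
blocks (closing-stem arms, stem I/II arms, catalytic core) and two insertion
slots. The bundled fixture is the literature-derived 52-nt sTRSV ribozyme;
assembling its native loops (UGUGCUU, GUGA) reproduces that sequence exactly.
Its 5'/3' spacer segments are empty; users studying cassette context can edit
them.

Folding is pluggable:

* `vienna` (default): ViennaRNA's MFE fold via its python bindings. All
  design-pipeline results use this backend; the backend name is recorded in
  every output.
* `nussinov`: a deterministic maximum-weight pairing DP (GC=3, AU=2, GU=1,
  minimum hairpin 3, no lonely pairs) compiled with numba. It exists for
  dependency-free, bit-stable testing of the fold/parse plumbing. It is *not*
  a thermodynamic model: on full constructs it typically shifts the designed
  stem register, which the parser then (correctly) flags as misfolded, so it
  cannot drive the design pipeline.

Parsing walks the predicted dot-bracket with known scaffold coordinates. A
construct is parseable only if every designed stem pair is present in the MFE
structure. Loop-flanking bases that stack contiguously on a scaffold stem are
credited to that stem (`stem_len` grows, the loop shrinks) — which nucleotides
form the loop is only known after folding. Pairs wholly inside a loop are
recorded as branch stems with per-nucleotide paired flags. A construct whose
stems are broken, or whose loop bases pair outside their own loop, is flagged
misfolded and excluded from encoding, training and ranking (it is counted and
reported, never silently dropped). Pairing of catalytic-core bases is not
itself a misfold criterion; with intact stems the MFE structures we observe
leave the core essentially unpaired.

The *structure key* (stem I/II lengths, loop I/II lengths, branch flags) is
the unit of structural stratification used for segment hold-out.

## Encoding (`encoder`)

Each stem-loop becomes a 2-D grid: rows run from the stem's core-proximal base
pair toward the loop apex; two columns hold the 5' and 3' strand sides. Stem
pairs occupy both sides of one row with "paired" channels; the loop walks up
the 5' side — ceil(n/2) positions, apex on the 5' side for odd n — and back
down the 3' side; branch-stem nucleotides keep their walk position but carry
paired channels. Cells are one-hot over 8 channels ({A,C,G,U} x
{unpaired,paired}); unoccupied cells are all zero. The two grids stack on a
third axis, aligned at row 0 (no reversal), giving a `(L_max, 2, 2, 8)` binary
tensor whose 2x2x2 neighborhoods contain spatially adjacent nucleotides of
*both* loops — the geometry the loop-loop interaction model assumes.

`L_max` defaults to 20 rows: training loops reach 13 nt on stems extended to
11 bp, and grafted aptamer loops reach 26 nt on the 6-bp stem I
(6 + ceil(26/2) = 19 rows). A 16-row default was tried first and rejected
because every aptamer-grafted candidate overflowed. Overflow policy is skip
and report.

## Models (`models`)

The regressor is a small 3-D CNN: 2x2x2 convolution, stride 1, valid padding
(32 filters, ReLU) → 25% dropout → flatten → dense 128 (ReLU) → 50% dropout →
dense 1. Loss is MSE, optimizer Adam (lr 1e-3), batch size 128, 100 epochs.
The convolution/dense widths, batch size and learning rate are free
parameters of this package (configurable in `RegressorConfig`); the kernel,
stride, dropout rates, epoch count, loss and optimizer are fixed features of
the architecture. The ReLU after the convolution is our choice; a linear
convolution feeding the dense ReLU layer is the other defensible reading.

The network is implemented directly in numpy — im2col convolution (the 2x2x2
window collapses the side and stem-loop axes, so only the row axis is
scanned), manual backpropagation, inverted dropout, and a hand-rolled Adam.
One integer seed drives weight init, shuffling and dropout masks, making
training bit-reproducible on one machine; inference disables dropout and is
deterministic and batch-size invariant. Artifacts round-trip through
`.npz` weights + JSON metadata (encoder settings, config, seed, per-epoch
training-loss trace); prediction refuses tensors whose encoder settings
differ from the model's metadata.

Baselines — lasso with internally cross-validated penalty (`LassoCV`), an RBF
SVM, and a 100-tree random forest — operate on the flattened tensor via
scikit-learn.

## Sort-seq quantification (`facs_seq`)

The 8-bin scheme has open first/last bins (top and bottom expression
percentiles) and six equal-width interior bins; the default spans
log10(GFP/mCherry) in [-1.5, 1.0], the range between a strongly cleaving
ribozyme and the inactive control. Read counting is exact multiset counting
keyed on (sequence, bin barcode), with unrecognized barcodes tallied.

Activity estimation fits a normal distribution to a sequence's per-bin
profile. The default fit is maximum likelihood for an interval-censored
normal — open extreme bins contribute `Phi` tail masses exactly — with a
least-squares-on-profile alternative exposed for comparison. Both act on the
normalized profile `counts/bin_totals * cell_fractions` when per-bin totals
and sorted-cell fractions are supplied; by default raw counts are used, which
is the correct weighting when each bin's reads are already proportional to
its sorted cells (true of the bundled simulator; supplying totals without the
matching cell fractions badly distorts equal-depth profiles). Degenerate
cases: all reads in one open bin → unconverged, mean pinned just outside the
boundary; all reads in one interior bin → the symmetric-limit bin center. A
sigma floor of 0.01 log10 units prevents collapse. `fit_activities` is a
vectorized Adam implementation of the same ML objective for whole tables;
tests pin its agreement with the per-sequence scipy fit to <1e-3.

Sequences with fewer than 20 reads are dropped (inclusive: exactly 20 is
kept), with the removal count reported.

## Forward design (`designer`)

Aptamers are data (JSON fixtures): full sequence, dot-bracket, annotated
ligand-binding bulge, allowed loop positions, provenance. Grafting removes
the terminal helix enclosing the bulge (configurable `retained_pairs`,
default 0) and attaches the remainder to stem I or II, completing that loop.
If no bulge is annotated, the unpaired internal loop nearest the terminal
stem is used; a structure with no internal loop raises.

The design space is the aptamer on loop I or II crossed with every variable
loop of length 5-8 on the opposite loop: 2 x (4^5+4^6+4^7+4^8) = 174,080
candidates per aptamer, streamed lazily and scored in batches (default
4,096): fold → parse (misfolds excluded but counted) → encode → predict. A
bounded max-heap keeps the k lowest-predicted candidates (k=200 by default);
ties break lexicographically on the full sequence. `top_n` takes the 15
'predicted best' for individual characterization.

Two of the five bundled aptamers (theophylline, neomycin) carry
literature-derived cores; tetracycline, chloramphenicol and folinic acid are
synthetic placeholders (flagged in their provenance fields and file name)
that exercise the pipeline but must be replaced with verified sequences
before any wet-lab use.

## Evaluation (`evaluation`)

`r_squared` always reports both conventions — squared Pearson correlation
(affine-invariant; the headline number) and the coefficient of determination
1 − SS_res/SS_tot (penalizes bias) — because "R²" alone is ambiguous.
Splits are seeded shuffles with round-half-up training size. Segment
hold-out retrains the model with every record of one structure key excluded
and evaluates on that segment only, for each qualifying segment
(`min_segment_size` default 50); this probes robustness to structures absent
from training, the regime a designed aptamer loop lives in.
Flow-cytometry-style normalization divides a switch's GFP/mCherry by the
condition-matched inactive-control value (percent scale); the activation
ratio is normalized-induced over normalized-basal.

## Motif analysis (`motifs`)

Shared-membership counts are exact set intersections keyed on (loop position,
variable-loop sequence) — identical sequences on different loops are distinct
designs. Consensus matrices are 5'-anchored per-position frequencies over
{A,C,G,U,gap}, shorter sequences contributing gap mass at tail positions
(the alignment convention is ours). Motif queries accept IUPAC degenerate
codes, so UGGAG and UGGAR are both expressible; activity contrasts report the
matched-set mean, the full-background mean, and a two-sided Wilcoxon
rank-sum p-value of matched vs unmatched.

## Synthetic data (`synthetic`)

The surrogate activity function is a deliberate caricature, not a biophysical
model:

    activity = base
             + w_pair * maxrun(loop1, reverse(loop2))
             + sum(motif effects)
             + w_len * (len1 + len2 - 8)
             + Normal(0, noise_sd)

with defaults base 0, `w_pair` = −0.05 per nucleotide of the longest
antiparallel WC/GU-complementary run, motif effects {UGGAG on loop II: −0.30;
GGA on loop II: −0.12; UU on loop I: +0.10}, `w_len` = +0.06 per nucleotide,
and `noise_sd` = 0 (deterministic; the optional noise is a stable function of
seed and loops). These weights were calibrated once, during development, so
that (a) activities span roughly the observed dynamic range with a typical
value near 0, (b) the deterministic signal is learnable by the small CNN, and
(c) the complementarity term — non-additive in any flattened one-hot basis —
plus the local motifs give the spatially paired convolutional encoding a
reproducible advantage over the lasso. They were then frozen.

Library generation mirrors the training-set designs: both loops N5–N10
uniform by default, with "long" (N9–N13) and "short" (N5–N7) presets for the
asymmetric libraries. The read simulator draws, per sequence, `depth` reads
multinomially over the 8 bins with probabilities from Normal(activity, sigma)
integrated over the bin intervals — the idealized sort of a clonal population
with cell-to-cell log-expression spread sigma (default 0.4).

What the surrogate does **not** emulate: real cleavage kinetics and
sequence-activity structure, transformation bottlenecks, sorting impurity,
PCR/qPCR amplification noise, replicate disagreement. Passing tests therefore
demonstrate that the pipeline machinery (folding, parsing, encoding,
fitting, training, ranking) is correct and that the architecture can exploit
structural signal — not that the trained CNN reproduces the accuracy
reported on real sort-seq data.

## Problem sizes and numerical choices

* Pipeline-closure runs (tests and the acceptance script) use n = 20,000
  surrogate constructs, read depth 500, sigma 0.4, a 75/25 split, and the
  default 100-epoch CNN. About 25% of random constructs misfold under the MFE
  backend and are excluded.
* Design runs in the test suite and acceptance script use an N5 variable-loop
  pool (2,048 candidates per aptamer) with top-200 selection per aptamer;
  the full N5–N8 enumeration is verified by streaming count against the
  closed form.
* The binned-normal recovery check uses 200 seeded replicates at depth 1,000.
* Interval-censored ML: parameters (mu, log(sigma − floor)); Nelder-Mead for
  single fits, 400 Adam iterations (lr 0.05, gradient clip 1e4, probability
  floor 1e-12) for the batched fitter.
* All float32 in the network; reproducibility is per-machine bit-level, and
  across BLAS builds agreement is to numerical tolerance only.

## Known limitations

* MFE-structure dependence: a single MFE structure decides parseability and
  encoding; suboptimal ensembles and pseudoknots are out of scope, and
  backend choice changes MFE details (hence the recorded backend name).
* The misfold-exclusion policy and the apex-split, loop-alignment and
  consensus-gap conventions are package choices; alternatives are plausible.
* The surrogate's limitations above; segment hold-out R² values on surrogate
  data are not comparable in magnitude to real-data accuracies.
* Ligand responsiveness (activation ratio) is measured, not predicted: the
  model targets basal activity only.
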