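# Methods

`psmembed` matches tandem mass spectra to peptides by learned cross-modal
similarity instead of a hand-crafted scoring function. Two encoders project
the two modalities onto one unit hypersphere in R^256; a spectrum is
assigned the database peptides whose embeddings are nearest in squared
Euclidean distance (SED), subject to a precursor-mass window.

## Representations

**Spectra.** Each MS/MS peak list is binned onto a fixed grid of 80,000
bins of 0.1 Da (masses up to 8,000 Da); peaks falling into one bin are
summed. The occupied bins are rescaled to zero mean and unit variance
(population convention); empty bins stay exactly 0, so the vector remains
sparse. Two degenerate cases are handled explicitly: a spectrum with one
occupied bin, or with identical intensities in all occupied bins, has no
scale and its occupied bins are set to 0 (logged). The precursor's neutral
mass is recovered as `m/z * z - z * 1.007276`.

Note one representational consequence of this normalization: an occupied
bin whose intensity equals the mean normalizes to exactly 0 and becomes
indistinguishable from an empty bin. `BinnedSpectrum.occupied_bins`
records occupancy separately for bookkeeping, but the encoder sees only
the normalized vector.

**Peptides.** Peptide strings are tokenized one symbol per character over
a 30-symbol vocabulary: the 20 amino acids, nine inline modification
characters (p phospho, o oxidation, h deamidation, c carbamidomethyl,
a acetyl, r ammonia-loss, y carbamyl, d dehydrated, t delta-H2C2), and a
pad symbol with id 0. A modification character is written immediately
after the residue it modifies; N-terminal modifications lead the string
(e.g. `aPEPTIDEK`). Sequences are right-padded to 64 tokens. Placement of
the modification character is a convention of this package — only the
character set itself is fixed by the training-data encoding.

## Encoders

The spectrum encoder (SSN) is `80,000 -> 1024 -> 256` with ReLU after both
layers, dropout 0.3 after the first, and L2 normalization at the output.
The peptide encoder (PSN) embeds each token into a 256-vector, runs one
bidirectional LSTM with hidden size 1024 per direction, concatenates the
final forward and final backward hidden states into a 2048-vector, and
applies `2048 -> 1024 -> 256` ReLU layers, dropout 0.3 after the Bi-LSTM
and the first fully connected layer, then L2 normalization. Because both
outputs are unit vectors, all SEDs lie in [0, 4].

Design choices where the architecture description is genuinely open:

- *Recurrent readout.* "Concatenating the outputs of both directions" is
  read as concatenating the final hidden state of each direction
  (1024 + 1024 = 2048), not pooling per-step outputs.
- *Pad handling.* Pad positions are masked out of the recurrence (state
  carries through), so an embedding does not depend on how much padding
  follows the sequence; this is asserted as a property test.
- *Initialization.* Uniform fan-in initialization, seeded; forget-gate
  biases start at 1 (standard recurrent practice). The output layers sit
  under a ReLU feeding the normalization, so their biases start at 0.1 to
  avoid dead units at the first step.
- *Numerical guard.* Row normalization divides by `max(||x||, 1e-12)`.

The encoders, loss, and optimizer run on a small reverse-mode automatic
differentiation engine written for this package (`psmembed._autograd`,
numpy-based, with a sparse-input affine op so the 80,000-wide first layer
costs only the occupied bins). Backpropagation through both encoders is
verified against central finite differences in the test suite.

## Loss and mining

For a batch of b pairs, three SED matrices D_QxQ, D_QxP, D_PxP are formed
with the Gramian identity `D = g 1^T - 2 A B^T + 1 g^T` (negative
round-off clamped to 0). Per anchor pair (q_i, p_i) four hardest negatives
are mined: j = nearest other spectrum to q_i (row scan of D_QxQ),
k = nearest other peptide to q_i (row scan of D_QxP), l = nearest other
spectrum to p_i (column scan of D_QxP), m = nearest other peptide to p_i
(row scan of D_PxP). Ties break to the lowest index. The loss is

    L = 1/(4 b') * sum_i sum_{r=1..4} max(d_i - d_nr + margin, 0)

with d_i the positive-pair SED, d_n1..d_n4 the four negative SEDs,
margin 0.2, and b' the number of contributing anchors.

Eligibility: by default a row sharing the anchor's peptide *string* is
ineligible as a negative — with duplicate peptides in a batch, an
index-only exclusion would mine the anchor's own peptide as its "hardest
negative" and push true pairs apart. A strict index-only mode
(`label_aware_mining=False`) is available for mining that excludes only
the anchor itself. Anchors with no eligible negative drop out of the loss
(hence b').

Batch accuracy is the fraction of spectra whose nearest in-batch peptide
carries their own label; it is the training/evaluation metric throughout.

## Training

Adam (lr 1e-4, weight decay 1e-4 coupled into the gradient), batch 1024,
margin 0.2, and a 0.8/0.2 train/test split performed at the peptide level
(all spectra of a peptide land on one side) are the reference defaults.
No learning-rate schedule or early stopping. Evaluation batches are
assembled round-robin over peptides so each batch holds at most one
spectrum per peptide where replicate counts allow, matching the
one-correct-peptide-per-anchor premise of the accuracy metric.

A desk-scale toggle (`ModelConfig.desk_scale()`, `TrainConfig.desk_scale()`)
keeps the architecture but shrinks it for single-CPU work: SSN hidden 128,
embedding width 64, symbol embedding 32, LSTM hidden 64 per direction,
dropout 0 (no overfitting concern when the goal is to fit a small fixture),
batch 64, Adam lr 1e-3, 40 epochs. On the default synthetic fixture
(64 peptides x 2 spectra) training lifts in-batch accuracy from chance
(1/64 ~ 0.016) to 1.0 within a few epochs, in well under a minute of CPU
time; the acceptance checks run 15 epochs. This is a fit/optimization
check — it demonstrates that mining, loss, gradients and both encoders
cooperate, not that 64 training peptides generalize to unseen ones.

## Database, decoys, search

Proteins are digested trypsin-style: cleavage after K/R (proline
suppression off by default, available by flag), up to 2 missed cleavages,
7–50 residues. Variable modifications are enumerated per peptide, at most
one per site, respecting per-modification caps and a global cap; deltas
are Unimod monoisotopic values. Masses are residue sums (pyteomics
monoisotopic table) + water (18.010565) + deltas. Decoys reverse the
internal residues, keeping the first and last fixed; modification
characters travel with their residue, N-terminal modifications stay at
the N-terminus. A decoy colliding with any target string is dropped. In
the database, a decoy record reuses its target's mass bit-for-bit (the
reversal permutes residues, so recomputing the sum could differ in the
last ulp). Records are sorted ascending by mass.

Search embeds the database once into a mass-sorted index. Per spectrum
batch (default 1024), candidates are the peptides whose mass falls in the
precursor window — ±5 ppm by default, Da windows supported, bounds
inclusive, located by binary search on the sorted masses. Distances are
computed with the Gramian identity over sub-batches of at most 16,384
peptides; candidates outside the window are treated as infinitely
distant. (A literal elementwise product of the distance matrix with the
0/1 mask would set excluded pairs to distance 0, the best possible score;
exclusion is the only semantics consistent with ranking only relevant
pairs.) Each sub-batch contributes its local top-5 and the union is
re-ranked under (distance, peptide index) order, which provably equals
the unpartitioned top-5; this invariance is tested. The reported score is
1/L2 = 1/sqrt(SED), with the SED floored at 1e-12; ranks are ascending in
distance; results can be written as plain TSV or as a Percolator input
(pin) table with label, score, inverse-distance and mass-difference
features. FDR estimation itself is delegated to Percolator downstream.

## Synthetic data

The generator stands in for spectral-library training data. Peptides are
uniform random residues with a C-terminal K or R, lengths 7–50, unique,
seeded. Spectra contain the full b/y series (`b_k = prefix sum + proton`,
`y_k = suffix sum + water + proton`), singly charged fragments by
default, with three realism knobs: Gaussian m/z jitter (sd 0.005 Da),
per-peak dropout (keep probability 0.9), and 20 uniform noise peaks in
50–2000 m/z at low intensity. Precursor charge is drawn from
{1: 0.10, 2: 0.50, 3: 0.30, 4: 0.10}, roughly the composition of large
tryptic libraries; the precursor m/z is exact for the sampled charge.
Modified peptides shift every fragment containing the modified residue.

Fragment intensities default to a rank profile (1/r over a random
fragment order). A constant-intensity ("fixed") spectrum interacts
degenerately with occupied-bin mean/variance normalization — every bin
normalizes to 0 and the spectrum vanishes — so constant intensities,
while available via `intensity_model="fixed"`, cannot be the default for
data meant to be learned from. `"uniform"` (iid U(0.2, 1)) is also
available. Dataset generation is a pure function of the config; the
manifest records every field and regeneration is exact.

What the generator does **not** emulate: realistic fragment intensity
patterns, isotope envelopes, neutral losses, co-isolation chimeras, or
charge-dependent fragmentation. Passing the desk-scale learnability check
therefore says nothing about accuracy on real instrument data; it
validates the machinery, not the chemistry.

## Known limitations

- The full-scale configuration (80,000 x 1024 layers, 1024-unit Bi-LSTM,
  millions of training pairs) is expressed but not trained here; training
  at that scale needs GPU hardware and real spectral libraries.
- Peptide embeddings are charge-independent; spectra of high charge map
  farther from their peptide than 2+ spectra in practice.
- Open (wide-window) search is out of scope; the mask assumes a narrow
  precursor tolerance.
- The MGF dialect is the reference spectrum input; vendor formats and
  deisotoping are out of scope.
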