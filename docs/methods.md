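# Methods

## Spectrum discretization and broadening

Carbon K-edge absorption is modeled on a uniform energy grid of
`n_grid = 100` bin centers between `e_min = 270` and `e_max = 300` eV, with
spacing `delta_e = (e_max − e_min)/n_grid = 0.3` eV. Bin centers (rather
than inclusive endpoints) were chosen deliberately so that the grid spacing
equals the `delta_e` appearing in the RSE denominator exactly; an
endpoint-inclusive grid would give a spacing of 30/99 eV and a small
systematic inconsistency between the grid and the error metric.

Stick spectra are broadened with Gaussians. The broadening width parameter
(default 0.8 eV) is interpreted as the **FWHM**, σ = FWHM/(2√(2 ln 2));
XAS broadening conventions vary between σ and FWHM, so the width is a
plain argument, not a constant. Amplitudes are peak-height normalized
(a stick of oscillator strength f contributes f at its center) rather than
area normalized. Only relative intensities matter downstream: the RSE is
invariant under joint rescaling, and AUC uses rank order only.

**RSE** = RMSE over grid points divided by the target's total spectral
energy Σ_i y_i^tar ΔE. It is zero iff the spectra are identical, invariant
under joint positive rescaling, and undefined (error) for an all-zero
target.

**Peak windows.** Peaks are local maxima with prominence ≥ 5% of the
spectrum's global maximum (scipy's prominence machinery); the FWHM comes
from linear interpolation of the half-height crossings. A peak's window is
the set of grid indices within ±FWHM/2 of the center; sticks are assigned
to a peak by the matching **half-open** energy interval
[center − FWHM/2, center + FWHM/2), so a transition lying exactly between
two adjacent windows is counted once.

## Molecular graphs

Heavy-atom graphs: C/N/O/F nodes with hydrogens folded into a per-atom
count. Node features (length 11): one-hot element (4), one-hot
hybridization sp/sp2/sp3/other (4), one-hot aromaticity (2), integer H
count. Edge features (length 6): one-hot bond order
single/double/triple/aromatic, bond length in Å when 3-D coordinates are
supplied, and a length-present flag (0-filled length otherwise). Vocabulary
orders are frozen module constants so encodings are bit-stable. Atom order
is RDKit's canonical order of the canonicalized SMILES, which makes graph
construction deterministic and reproducible across sessions.

## Models

All three architectures share one head contract: message-passing layers
produce per-atom activations F_k(i) (K = last hidden size), a
permutation-invariant readout pools them, and a **single affine layer**
maps the pooled vector to the 100 outputs. Nothing sits between readout
and output, so CAM (below) needs no gradients or approximations.

* **GCN** — per layer, each node state is replaced by the mean over itself
  and its neighbors, then linearly transformed and passed through a leaky
  ReLU. Edge features are ignored.
* **GraphNet** — per block: edge update from (edge state, the **sum** of
  its two endpoint states, global state); node update from (node state,
  sum of incident updated edges, global state); global update from
  (global, mean node state, mean edge state). The endpoint sum keeps the
  edge update invariant to the arbitrary storage orientation of an
  undirected bond — an asymmetric concatenation of the two endpoints
  breaks permutation invariance. The initial global state is the mean of
  the raw node features.
* **GATv2** — per layer and head, edge logits a^T lrelu(W_l h_i + W_r h_j)
  (nonlinearity before the scoring vector, so attention is dynamic in both
  endpoints), softmax-normalized over each target's neighborhood including
  a self-loop. Heads are concatenated on intermediate layers and averaged
  on the last message-passing layer, whose width is the activation
  dimension K.

Unstated architecture details were fixed as: 4 attention heads, sum
readout (keeps CAM completeness exact; mean available), leaky-ReLU (slope
0.01) activations, Glorot-uniform initialization, no dropout, no output
activation (raw affine — small negative intensities are tolerated by RSE
and irrelevant to rank-based AUC; a clamp flag exists for reporting).

The tensor plumbing is a ~250-line numpy reverse-mode autodiff engine
(broadcast arithmetic, matmul, gather/segment-scatter, segment softmax)
written for this package; its gradients are verified against central
finite differences in the test suite.

## Training

AdamW (weight decay 0.01), RMSE loss, batch size 100, learning rate 1e-3
multiplied by 0.8 every 100 epochs, 80:20 train/validation split from the
training seed, validation RMSE and RSE every 50 epochs, and restoration of
the checkpoint with the best validation RMSE (ties broken by RSE). The
full-scale profile (hidden sizes 128/256/512, 1000 epochs) is preserved in
the configuration; the desk-scale profile used by tests and examples is
hidden sizes 32/64 and 200 epochs on 300 synthetic molecules, which trains
in well under a minute on one CPU core and is large enough to separate a
learning model from the constant-mean baseline.

## CAM attribution

Score of atom i for grid point ("class") c: Σ_k ω_k^c F_k(i), with ω the
output layer's weight matrix. With sum readout and a bias-free output
layer, Σ_i scores[i, c] equals the prediction at c exactly
(completeness); with mean readout the scores are divided by the atom count
so the identity still holds. Negative scores are **kept** — ROC-AUC is
rank-based, and clamping would destroy ranking information. Per-peak
scores are the sums over the peak's FWHM grid window.

## Ground-truth labels

For the transitions inside a peak's window, the weight of atom a in
channel ch ∈ {core, virtual} is

w(a) = Σ_s f_s · Σ_pairs pair_weight · pop_a(MO_ch),

max-normalized to 1. Pair weights are renormalized per transition;
orbital populations must sum to 1 over atoms (tolerance 1e-6, renormalized
with a warning beyond it). Binary labels: atom a gets 1 iff
w(a) ≥ θ·max(w), inclusive boundary, default θ = 0.1. The threshold is
relative, hence scale-free and insensitive to molecule size; the choice of
θ is a genuinely open parameter and is exposed everywhere it is consumed.
Peaks whose labels end up single-class have undefined AUC and are excluded
from averages (and counted in reports) rather than imputed.

## Synthetic data generator

The generator emulates the structure of a QM9-derived carbon-edge dataset:
H/C/N/O/F molecules with ≤ 9 heavy atoms built from curated scaffolds and
substituents, per-carbon transitions, sparse orbital populations.

* **Energies/strengths are deterministic in the molecular graph.** Each
  carbon's environment signature (aromaticity category, hybridization,
  H count, sorted neighbor elements) hashes to 1–3 transitions with
  energies in spectroscopically ordered windows (aromatic 283.5–287 eV,
  sp 285–288.5, non-aromatic sp2 284.5–289, sp3 287.5–293) and oscillator
  strengths log-uniform in [0.02, 0.2]. Identical environments therefore
  produce identical contributions in every molecule, which is what makes
  the regression learnable by a message-passing network — and it is why a
  trained model's CAM can meaningfully localize peaks.
* **Populations.** Core: 0.95 on the excited carbon, remainder spread
  over its heavy neighbors — well above the θ = 0.1 labeling cut, so
  label recovery on clean peaks is exact by construction. Virtual: equal
  shares over a seeded connected neighborhood of ≤ 4 atoms around the
  carbon (the user seed controls only molecule sampling and these
  neighborhoods; it cannot change spectra).
* **Collisions.** Transitions of different carbons may share a peak
  (realistic); such peaks carry union labels and are flagged `clean=False`
  so exactness tests can filter to single-carbon peaks without discarding
  the colliding ones from training or scoring.

What the generator does **not** emulate: real oscillator-strength physics,
vibronic structure, delocalized virtual orbitals spanning non-contiguous
atoms, basis-set or functional effects. Passing tests on synthetic data
therefore demonstrate the pipeline's correctness and the architectures'
capacity to learn environment-determined spectra — not quantitative
accuracy on real TDDFT data, which requires the full-scale dataset and
training profile.

## Perturbations

Methyl addition replaces one hydrogen on a uniformly random
hydrogen-bearing heavy atom (seeded) with CH3: heavy atoms +1, net
hydrogens +2. Coordinate distortion adds i.i.d. zero-mean Gaussian noise
with standard deviation σ per axis (σ ∈ {0.02, 0.05, 0.1} Å are the
conventional probe values), giving an expected per-atom RMS displacement
of σ√3. Reference spectra for perturbed molecules are *not* recomputed
here — the pipeline accepts new transition records (or synthetic ones).

## Numerical notes and degenerate inputs

* Segment softmax subtracts the per-segment max as a constant for
  stability.
* Edgeless graphs (methane) flow through all three architectures: GCN/GAT
  degenerate to self-loop updates, GraphNet's edge aggregations are empty
  sums.
* All-zero spectra: peak finding returns an empty list; RSE raises on an
  all-zero target.
* Ties between equal-height neighboring peak candidates resolve toward
  lower energy (scipy's left-to-right scan order).
* Training raises on a non-finite loss, reporting the epoch.

## Known limitations

* CAM is the only attribution method; gradient-based variants and edge or
  attention-weight explanations are out of scope.
* No Lorentzian/Voigt or energy-dependent broadening.
* Geometry enters only through bond lengths; distortion experiments probe
  robustness, not geometric learning (richer 3-D features would be needed
  for that).
* Orbital populations are consumed, never computed: there is no
  Löwdin/Mulliken analysis here, and no converter from any specific
  quantum-chemistry program's output format.
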