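# Methods

## Scope and model

`contactdiff` treats a molecular-dynamics trajectory as an exchangeable
sample of conformations and reduces it to residue-level contact
statistics. A residue pair (i, j) is *in contact* in a frame when its
distance is less than or equal to a cutoff; two distance definitions are
supported:

* **Cα mode** — the Cα–Cα Euclidean distance, cutoff 8.0 Å. A coarse,
  backbone-level definition suited to interdomain topology.
* **heavy mode** — the minimum over all heavy-atom pairs of the two
  residues, cutoff 4.5 Å. A side-chain-aware definition suited to
  specific interfaces (client peptides, the Hsp70 EEVD tail).

Both boundaries are inclusive (distance exactly equal to the cutoff
counts). The contact probability `P_ij` is the fraction of frames in
contact — identically the time-average of the per-frame contact
indicator, and the two computations are implemented as independent code
paths that must agree exactly. Pairs excluded by the minimum sequence
separation (default 1, i.e. all i<j pairs retained, because intradomain
secondary-structure contacts near the diagonal are themselves
informative) or by chain scope, and the diagonal, are NaN in every
export and excluded from all sums.

The mean-distance matrix averages the residue distance over **all**
frames, not contact frames only, so that it works as a continuous
persistence proxy (the all-frames average is what makes rarely-touching
pairs light and persistent pairs dark on a fixed scale); a
contact-frames-only variant is available via a flag and its use is
recorded in the export metadata.

## Condition comparison

Differences are always oriented A − B with A the perturbed condition
(mutant) and B the reference (wild type); the orientation string is
embedded in every export. Thresholds follow the analysis protocol's
printed values and inequality senses exactly:

| parameter | default | semantics |
|---|---|---|
| Cα cutoff | 8.0 Å | inclusive (≤) |
| heavy-atom cutoff | 4.5 Å | inclusive (≤) |
| significance τ_sig | 0.2 | `|ΔP| ≥ 0.2` (inclusive) |
| gain τ_gain | +0.3 | `ΔP > +0.3` (strict) |
| loss τ_loss | −0.3 | `ΔP < −0.3` (strict) |
| persistence | 0.5 | occupancy `> 50%` of frames (strict) |
| KLD peak | 0.1 bits | `KLD > 0.1` (strict) |
| KLD pseudocount ε | 1e-4 | see below |
| Rg rolling window | 50 frames | valid-window mean |

The persistence rule is interpreted in the condition where the contact
exists: a *gained* pair must be occupied in more than the threshold
fraction of condition-A frames, a *lost* pair in condition-B frames.
Both occupancies are exported so stricter user-side rules remain
possible. No multiple-testing correction is applied — the thresholds
are effect-size filters, not p-values.

## Per-residue KL divergence

Each residue i has a contact-probability vector over its partner
residues in each condition. The default per-residue divergence sums,
over partners j, the KL divergence between the *binary*
contact/no-contact distributions:

    KLD_i = Σ_j [ p̃ log2(p̃/q̃) + (1−p̃) log2((1−p̃)/(1−q̃)) ]

with pseudocount smoothing `p̃ = (P_A[i,j] + ε)/(1 + 2ε)` (ε = 1e-4) to
keep every term finite. This rule is non-negative term by term, exactly
zero for identical inputs, and sensitive to the *magnitude* of contact
change — a contact going from 90% to 30% occupancy contributes ≈1.15
bits regardless of how many other partners the residue has. Residues
with all-zero vectors in both conditions come out at exactly 0 bits.

A second rule (`method="partners"`) adds ε to the partner vector,
normalizes it to sum 1 within each condition and compares the resulting
categorical distributions. It sees only *redistribution* among partners
and is blind to uniform gain or loss of contact mass (a single-partner
residue whose occupancy collapses from 0.9 to 0.3 scores ≈0.004 bits).
Both rules are well-defined divergences; the binary-sum rule is the
default because peak calling at a fixed bit threshold is only meaningful
when outright contact loss registers. The divergence is directional,
KLD(A‖B) with A the mutant; a symmetrized Jensen–Shannon variant of
either rule is available but off by default.

## Geometry

Rg is the mass-weighted root-mean-square distance from the per-frame
centre of mass (square root reported, units Å). Smoothing uses a
valid-window rolling mean (output length F − w + 1, no edge padding —
no edge convention is invented). Histograms use half-open bins
[lo, lo+w) with the origin snapped down to a bin-width multiple; counts
always total F. Bin width defaults to 0.5 Å (a 10 Å compactness range
resolves into ~20 bins). Structural superposition solves the weighted
Kabsch problem restricted to proper rotations (molecules are chiral;
reflections are never admitted) and reports the weighted RMSD of the
superposed pairs.

## Domain and interface aggregation

Domain tables sum contact probabilities over domain blocks and are, by
linearity of the average, identical to counting block contacts frame by
frame and dividing by F (asserted in tests). Diagonal blocks count each
unordered intra-domain pair once; the total over unordered blocks equals
the total pairwise contact probability of the mapped residues
(conservation identity). Residues outside the map are excluded and
logged, never silently misattributed. The shipped Sis1 map
(J = 1–75, GF = 76–121, GM = 122–178, CTD = 179–352) is configuration,
not ground truth: the J boundary is well anchored, the linker/CTD splits
are approximations consistent with the known sub-elements (GF helix
~107–119, GM stretch ~130–138, CTD binding segments 180–257), and every
analysis takes the map as an input.

Interface profiles use the heavy-atom 4.5 Å rule between two chains; a
residue pair contributes at most 1 per frame (an atom-pair-count variant
sits behind `granularity="atom"`; whether published class-pair counts
use atom or residue granularity is ambiguous, and residue granularity
matches the interface contact definition, so it is the default).
Residue-class categorization uses aliphatic {G,A,V,L,I,P,M}, aromatic
{F,W,Y}, polar {S,T,C,N,Q,H}, charged {D,E,K,R}; histidine's placement
in the polar class is flagged as genuinely ambiguous and the whole
scheme is overridable. The class-pair table partitions the total mean
interface contacts exactly.

## Synthetic ensembles and what they do (not) show

The generator encodes a Bernoulli contact process geometrically instead
of simulating dynamics. Residues sit on a straight lattice at 12 Å
spacing (beyond every cutoff); each *planted* pair gets an independent
per-frame coin flip with its condition's probability, moving the mobile
residue either to `d_bound` (default 5.0 Å, for heavy-mode fixtures
3.5 Å) from its partner or to `d_unbound` (20 Å) off its own lattice
site, each pair on its own perpendicular lane. Gaussian jitter
(σ = 0.2 Å) is added everywhere. Spec validation enforces
`d_bound + 3σ < cutoff < d_unbound − 3σ` for every cutoff in use, and a
jitter-free geometry audit rejects any layout in which an unplanted pair
could approach the largest cutoff. Consequently:

* planted pairs are Binomial(F, p)/F in the contact matrix,
* unplanted pairs are **exactly** zero,
* ΔP, per-residue frequencies, domain tables, interface profiles and
  KLD profiles all have closed-form expectations (`planted_truth`),
  computed with the same pseudocount rule as the pipeline.

Randomness is one `numpy` Generator per (seed, condition), seeded as
`default_rng([seed, crc32(condition)])`, with a documented draw order
(planted pairs then anchors, pair-major, F Bernoulli draws each, then a
single Gaussian jitter block) — identical inputs reproduce identical
coordinates bit for bit.

What passing these tests does **not** show: the generator has no
polymer connectivity, no excluded volume, no correlated frames
(autocorrelation in real MD reduces the effective sample size, so real
4σ bounds are wider), no PBC artifacts and no physical energetics. It
validates the *statistics*, not force-field behaviour.

## Problem sizes and numerical choices

The test suite and the acceptance script use 40-residue ensembles with
10,000 frames for parameter recovery (4σ binomial tolerance ≈0.02 at
p = 0.5) and a 50-residue + 4-residue-peptide complex at 200 frames for
exact oracle equivalence against naive double-loop recomputation; both
sizes keep a full run in well under a minute on one CPU while leaving
hundreds of null pairs for false-positive checks. Distance stacks are
processed in 512-frame chunks to bound memory. Contact-probability
comparisons between code paths are exact (they are ratios of integer
counts over identical indicator sets); distance comparisons use 1e-10
absolute tolerance.

File I/O is text-only by design (multi-MODEL PDB and multi-frame XYZ,
parsed via MDAnalysis): fixtures stay diffable and dependency-light.
Binary trajectory formats can be adapted behind the same `Trajectory`
contract. Coordinates written at `%.3f` round-trip to within 5×10⁻⁴ Å
plus the float32 representation error of the reader (≈6×10⁻⁸·|x|).
PDB `resSeq` numbering is preserved through every filter; matrices are
indexed by residue-table position with an explicit position↔resSeq table
exported alongside.

## Known limitations

* No PBC unwrapping, imaging or alignment of raw simulation output —
  inputs are assumed preprocessed (solvent stripping is provided).
* Frame subsampling is a plain stride; no statement is made about how
  published trajectories were discretized, and no assumption is needed.
* The KLD rule choice (binary-sum default) is a documented design
  decision, not an inference about any published implementation; the
  alternative rule is one keyword away.
* Rg uses all atoms of the (stripped) selection literally; whether
  hydrogens should be excluded is left to the caller via selections.
* The persistence rule and the ±0.3 / 0.2 thresholds are effect-size
  heuristics; with 10⁴ correlated MD frames they carry no error-rate
  guarantee.
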