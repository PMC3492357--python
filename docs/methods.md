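# Methods

This note records the models and procedures `turnkit` implements, the
parameters that matter, the design choices made where more than one
defensible option existed, and what the synthetic benchmarks do and do
not demonstrate.

## 1. Unified turn definition and ground-truth annotation

A tight turn is a chain-reversal site closed either by a backbone
hydrogen bond between its first and last residue or by an endpoint
Cα–Cα distance under 7 Å; γ/β/α/π turns span 3/4/5/6 residues.
`turnkit.annotate` labels a residue *turn* when it is covered by any
detected span of any type or by a run of at least three consecutive
'T' states in the 8-state secondary-structure string. Maximal runs of
turn residues are reported as segments carrying the set of contributing
types; overlapping spans merge (segments may therefore exceed any single
span length). Per-residue labels, not segments, are the primary ground
truth: the sequence model predicts residues.

Detector criteria:

* **β (4 residues):** |Cα(i) − Cα(i+3)| strictly below `ca_dist_max`
  (7.0 Å) and neither central residue (i+1, i+2) in state 'H'. The
  strict inequality matters at the boundary: a distance of exactly
  7.0 Å is not a turn.
* **γ (3 residues):** hydrogen bond CO(i) → NH(i+2) with energy below
  `hbond_energy_cut`. We follow the 1→3-residue CO/NH convention for
  the γ bond; classic literature definitions vary in indexing, and the
  1→3 form is the one adopted here.
* **α/π (5/6 residues):** endpoint bond CO(i) → NH(i+n−1) or endpoint
  Cα distance under the cutoff, *excluding* spans inside regular
  helices (see §1.2). Most α/π spans overlap β or γ spans, so the
  union is dominated by the shorter types — the expected behaviour for
  this family of definitions.
* **δ (2 residues):** listed in turn taxonomies but given no usable
  geometric criterion by coordinate-analysis tools; not detected.

### 1.1 Hydrogen bonds

The Kabsch–Sander electrostatic model:

    E = 0.084 · 332 · (1/d(ON) + 1/d(CH) − 1/d(OH) − 1/d(CN))  kcal/mol

with a bond asserted below −0.5 kcal/mol (both the cutoff and the
Cα threshold are exposed in `TurnConfig`). Backbone amide hydrogens are
absent from PDB backbone records and are synthesized 1.0 Å from N along
the bisector of the C(i−1)–N and Cα–N directions; the first residue has
no donor. Atom pairs closer than 0.5 Å raise a degenerate-geometry
error rather than returning a huge energy.

### 1.2 Reduced 8-state assignment and helix exclusion

`assign_ss8` is a *reduced* DSSP-style assignment from hydrogen-bond
patterns: runs of two consecutive n-turns give H (n=4), G (n=3), I
(n=5) with H taking precedence; bridge patterns give E; isolated n-turn
interiors give T; everything else is '-'. Bends (S) and the B/E bridge
distinction are not reproduced — callers wanting exact DSSP parity
should supply a DSSP file, which the readers accept.

A *regular helix region* is a maximal run of ≥ 4 consecutive 'H'
states **extended by one residue on each side**. The extension exists
because hydrogen-bond-based assignment marks the bonded helix termini
as 'T' rather than 'H' although they belong to the regular helix: an
ideal α-helix of length 6 assigns H only to residues 2–5, yet its
terminal 5-residue windows close an i→i+4 bond and would otherwise be
reported as α-turns. With the extension, ideal helices of any length
from 6 to 30 produce zero α/π spans (a property the test suite checks
across the whole range). β spans use the separate central-residue rule
and need no extension.

## 2. Profiles and features

Alignment hits carry one structural element per query position (gap
allowed). Filtering keeps hits with E-value strictly below 1e−6, sorts
ascending (stable for ties), and truncates to the top 50; both
parameters sit in `ProfileConfig`. Profile cells are normalized
frequencies over the **non-gap** elements at each position; positions
covered by no hit yield all-zero rows. Zero rows, not uniform rows,
signal absence — a flat prior would be indistinguishable from a
genuinely uncertain position.

PSI-BLAST ASCII PSSMs are parsed from their 20 log-odds columns and
squashed through the logistic 1/(1+e^(−x)) so that all feature families
share the [0, 1] scale. The 43 columns per residue are:

| block | columns | content |
|---|---|---|
| PSSM | 20 | squashed log-odds, PSI-BLAST column order |
| SPSSM | 3 | secondary-structure profile (H, E, C) |
| PSS | 3 | one-hot predicted secondary structure |
| SSProfile | 8 | shape-string profile (S, R, U, V, K, A, T, G) |
| SSPred | 8 | one-hot predicted shape string |
| bias | 1 | constant 1 |

The five named feature families contribute 42 columns; the 43rd is a
constant bias. This keeps every named family intact and is the most
conservative filler; the composition is a single documented constant
(`FEATURE_COLUMNS`) and swappable. The 8-letter shape-string alphabet
encodes φ/ψ Ramachandran regions; it is configurable where it appears.

Context expansion concatenates the rows at offsets (−2, −1, 0, +1, +2)
— two upward and two downward neighbours — into 215 columns.
Out-of-range offsets contribute all-zero rows, so the bias column of
each block doubles as a "real residue" indicator; no wrap-around, no
special boundary tokens.

External predictors (PSI-BLAST, secondary-structure and shape-string
predictors) are *inputs*: the package parses their outputs and never
reimplements them.

## 3. The conditional random field

Binary states (nonturn, turn). Observations enter through label-unigram
weights only; the 2×2 transition matrix carries no observation — the
standard unigram-template factorization for real-valued features. All
inference runs in log space with log-sum-exp; chains of 10⁵ residues
are safe from underflow, and the forward and backward recursions'
log-partitions are cross-checked against each other at run time.

Training maximizes Σ log P(y|X) − ‖w‖²/(2σ²) with exact gradients
(empirical minus expected feature counts minus w/σ²) under L-BFGS,
zero-initialized, hence deterministic for a fixed dataset order.
Defaults: σ = 1.0, 200 iterations maximum, gradient tolerance 1e−5.
Sequences are grouped by length and batched through vectorized
forward–backward during fitting.

Decoding applies the decision threshold to the **posterior marginals**,
not to the Viterbi path: thresholding a probability is only meaningful
on marginals, and the threshold is the instrument for trading
sensitivity against specificity (0.5 default, 0.2 as the
high-sensitivity operating point). The threshold rule is inclusive
(p ≥ t → turn), and Viterbi (ties toward nonturn at each backtrack
step) is available separately. Model files are versioned JSON with
hex-encoded floats, so save/load round-trips are bit-exact.

## 4. Evaluation

From residue-level TP/TN/FP/FN: Ac = (TP+TN)/N, Q_pred = TP/(TP+FP),
Sn = TP/(TP+FN), Sp = TN/(TN+FP), and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). Any 0/0 ratio
is reported as 0 with the metric's name recorded in an `undefined`
flag set — degenerate predictors are visible, not silently perfect.
AUC is the rank statistic (probability a random turn residue outranks a
random non-turn residue, ties ½), which equals the trapezoidal ROC
area; the unit tests cross-check it against scikit-learn.

Cross-validation always splits by chain, never by residue; folds are a
seeded balanced partition (sizes differ by at most one). Pooled metrics
are micro-averaged: counts are summed over folds before the formulas
are applied, matching residue-level reporting; per-fold reports are
retained alongside.

## 5. Synthetic data: what it emulates, what it does not

`turnkit.simulate` generates every input the pipeline consumes.

**Backbones** are built from internal coordinates (ideal bond lengths
and angles, NeRF placement, carbonyl O in the peptide plane);
reconstruction reproduces the input dihedrals to below 1e−6 degrees.
Planted-turn peptides use canonical Venkatachalam dihedrals for the
turn interiors (β-I: (−60,−30),(−90,0); β-II: (−60,120),(80,0); γ:
(75,−65)), polyproline-II-like flanks (−75, 145), and span-anchor
dihedrals chosen so the *unified* annotation equals exactly the planted
span — the anchors keep the enclosing 5/6-residue windows beyond the
7 Å endpoint criterion. Every fixture re-runs its own detector at
generation time and fails loudly on any mismatch; nothing is silently
shifted. The 91-residue stand-in chain concatenates ten planted β-turns
between extended flanks and verifies at generation that annotation
yields exactly ten segments. These peptides are geometric fixtures:
ideal covalent geometry, no side chains, no sterics, no solvent.

**Alignment hits** are drawn per position from a known categorical
distribution with optional gaps, so rebuilt profiles can be compared
against the generating truth with binomial error bounds. A note on the
envelope check: a per-cell 3σ band is sound as a simultaneous criterion
only for small cell counts — across hundreds of cells a correct
multinomial sampler is *expected* to breach some individual band. The
acceptance check therefore uses a 3-cell profile over 10 seeds; the
larger-profile variant lives in the unit tests with a fixed seed.

**Labelled corpora** stand in for a real training set. Labels follow a
sticky two-state chain with stationary turn fraction 0.245 — the
residue-level turn percentage observed in large non-redundant PDB
subsets — and stay-probability 0.8 (mean turn segment ≈ 5 residues).
Emissions are class-conditional: Dirichlet rows for the profile blocks,
categorical draws for the one-hots, logistic-squashed Gaussians for the
PSSM block. The default separation emulates informative-but-imperfect
upstream predictors (3-state secondary-structure prediction plateaus
near Q3 ≈ 80% in practice), so posteriors are graded and the decision
threshold genuinely trades Sn against Sp. Desk-scale results on this
corpus (five-fold CV, 200 chains of 50–70 residues: Ac ≈ 0.96–0.97,
MCC ≈ 0.90–0.92) demonstrate that the pipeline *recovers a known
generating process*; they say nothing about accuracy on real proteins,
which depends on the quality of the real upstream predictors and on
training data at the thousands-of-chains scale. The emission model
draws feature columns independently given the labels, which the CRF's
unigram factorization matches by construction — real profile features
are correlated within and across positions in ways this fixture does
not reproduce.

Problem sizes throughout (200-chain corpora, ≤ 8-residue enumeration
oracles, 400-hit profiles) are chosen so the whole suite and the
acceptance script each run in well under a minute of CPU; they are
desk-scale stand-ins, not reduced claims about production scale.

## 6. Numerical and formatting conventions

* Spans are 0-based half-open internally; all human-readable reports
  use 1-based residue numbering, and PDB author numbering (with
  insertion codes) is preserved verbatim in annotation output.
* PDB reading takes the first model, altloc blank/'A' (first), ignores
  HETATM except MSE → M, and drops residues lacking Cα with a warning.
* The prediction report prints nine lines per query (sequence, position
  ruler every 10 residues, predicted turn + probability digits,
  predicted secondary structure + confidence, predicted shape string +
  confidence, structure diagram) wrapped at 60 columns. The diagram
  alphabet is '+' turn, '=' sheet, '*' helix, '-' otherwise; a residue
  that is both turn and helix/sheet renders as turn, since turn is the
  predicted quantity. One-character-per-residue lines cannot carry
  two-decimal numbers, so the block shows floor(10·p) digits; the
  machine-readable TSV twin carries probabilities to two decimals and
  is the normative output format.
* All writers are deterministic byte-for-byte for identical inputs.

## 7. Known limitations

* `assign_ss8` is deliberately reduced; against full DSSP it differs at
  bends, bridges and helix termini. Supplying real DSSP files is the
  supported route for exact parity.
* No β-turn subtype classification (I, II, VIII, …), no multi-model
  NMR handling, no clash checking in generated peptides.
* The 43rd feature column (bias) is this package's documented choice of
  filler; alternative compositions plug in through `FEATURE_COLUMNS`.
* Promotif, the coordinate-analysis program whose turn calls inspired
  this family of definitions, has internal dihedral windows that are
  not public in detail; `turnkit` does not attempt bit-parity with it.
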