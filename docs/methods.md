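# Methods

This note documents the models implemented in `cdrdesign`, the choices made
where the method leaves room, and what the synthetic test fixtures do and do
not establish.

## Overview of the pipeline

The package connects three ingredients at an antibody–antigen interface:

1. **Experimental preferences** from phage-display selections
   (`phageprof`): per-position amino-acid counts from selected binders,
   normalized against the NNK degenerate-codon background.
2. **Structure-derived scores** (`structio`, `confrot`, `pdm`, `scoring`):
   an atomistic contact term X, a hydration/desolvation term Y and a
   structural-propensity term Z for each (position, amino-acid type) pair,
   computed on an alanine-reduced scaffold so that no side-chain knowledge
   of the real sequence leaks into the score.
3. **Preference models** (`prefmodel`): one logistic regression per
   amino-acid type, trained leave-one-out over the contact positions, with
   per-type MCC-optimal thresholds and the closed-form random baseline as
   the reference point.

## Structures, atom types and accessibility (`structio`)

PDB text is parsed with gemmi; hydrogens are dropped, alternate locations
resolve to the highest-occupancy conformer, and waters are kept only on
request. Van der Waals radii default to the Bondi set (C 1.70, N 1.55,
O 1.52, S 1.80 Å; configurable).

The atom-typing scheme groups protein heavy atoms into 10 physicochemical
classes (aliphatic/aromatic/carbonyl carbon; amide/aromatic/positive
nitrogen; carbonyl/carboxylate/hydroxyl oxygen; sulfur) plus water oxygen
and a reserved `OTHER` fallback for unknown (residue, atom) pairs. The
class boundaries follow standard practice (e.g. the arginine guanidinium
carbon is grouped with carbonyl-like sp² carbons); the scheme is an
explicit, swappable table.

SASA uses the Shrake–Rupley construction with a deterministic golden-spiral
quadrature (default 960 points, probe 1.4 Å). A point exactly on a
neighbour sphere is owned by the lower-index atom, so duplicated atoms count
shared surface exactly once instead of zero or twice. Relative
accessibility normalizes by the Tien et al. theoretical maxima.

Interface classes follow the Levy convention: a residue is *interface* if it
loses more than 0.5 Å² SASA on complexation; *core* if its relative SASA is
≥ 25 % in the free protomer and < 25 % in the complex; *rim* otherwise.
Thresholds are keyword arguments. A CDR position is flagged *contact* when
any heavy atom of any clash-free rotamer of any amino-acid type comes within
6.0 Å of the antigen (`confrot.contact_flags_by_rotamers`); when those flags
are not supplied, `classify_interface` falls back to a conservative
backbone-reach rule (backbone/CB within 6.0 + 7.0 Å), which errs toward
flagging contact.

## Rotamer placement and clash filtering (`confrot`)

Side chains are built by superimposing ideal residue geometry (Chemical
Component Dictionary coordinates via biotite) onto the scaffold N/CA/C frame
and driving χ torsions to rotamer-library values; the CB of a reduced
position is rebuilt at the ideal tetrahedral direction with a fixed 1.526 Å
bond. No post-placement minimization is applied — the intent of the original
"local geometry clean-up" step is preserved by sampling rotamers and
removing clashes instead, which keeps the placement fully deterministic.

The shipped rotamer table (`data/rotamers.tsv`) lists the common staggered
rotamers per type (1–4 each, with approximate frequencies); Ala/Gly are
single conformers and proline keeps its ideal ring as one conformer, since
driving its χ1 would break ring closure. The table format (TSV: restype,
χ1–χ4, frequency) accepts any replacement library.

Two non-bonded heavy atoms clash when their distance is below
`r₁ + r₂ − 0.6 Å`. Atoms of the placed residue itself and backbone atoms of
the two chain neighbours are exempt (1-3/1-4 covalent proximity). The 0.6 Å
tolerance is configurable; it accepts mild overlap consistent with fixed
ideal geometry on a real backbone.

Backbone conformation classes are six half-open φ/ψ rectangles (helix,
sheet, PPII, left-handed, bridge, other) crossed with three χ1 wells
(g−, t, g+), plus an `unclassified` sentinel for chain termini. The binning
is a declared, configurable stand-in: any classification that partitions
residue conformations plugs in.

## Probability density maps (`pdm`)

Contact statistics are harvested from a structure library: for every buried
source residue (relative SASA < 5 %; the cutoff and the buried/surface/all
selector are parameters), the positions of neighbouring atoms within a
0–6 Å shell of the residue are recorded in the residue's local N–CA–C frame
and binned into a 3-D histogram (±8 Å extent, 1 Å cells) keyed by
(residue type, conformation class, neighbour atom type). Water statistics
use *surface* source residues, since crystallographic waters sit on
surfaces. Atom-type pair contacts within 4.5 Å feed a pairwise
interaction-preference filter: log10 odds of the observed unordered pair
frequency against the marginal expectation (with the factor 2 for
heterotypic pairs); pairs below a threshold (default −1.0) or never
observed are treated as non-interacting and contribute no density.

A PDM for atom type *m* around a query structure is built by projecting the
class-conditioned histograms out of every surface residue of the query.
Each covered residue deposits its histogram normalized to unit weight, so
the final map is exactly invariant to the size of the statistics library.
Deposits use trilinear (cloud-in-cell) splatting and are blurred with an
isotropic Gaussian (σ = 0.75 Å by default), which makes the binned
statistics behave as a density: averages over an atom-sized sphere then
change by only a few percent of the map scale when the query is rigidly
rotated and the grid re-derived. The map is normalized to sum 1 over the
grid; cells below the reference probability p_ref = 10⁻¹⁰ are stored as 0.
A query with no residue covered by the statistics yields the uniform map.
Maps are written and read in OpenDX scalar format.

`AVE`, the average of a map over the grid-cell centers inside an atom's van
der Waals sphere, is the quantity entering the scores; it is 0 when no cell
center is enclosed.

## Scores (`scoring`)

- **X** (per rotamer): Σ over the residue's heavy atoms of
  `log10(max(AVE, p_ref)/p_ref)`; per (position, type) the maximum over
  clash-free rotamers. The flooring at p_ref makes empty map regions
  contribute exactly zero for any p_ref, and within one amino-acid type
  (fixed atom count) the per-rotamer ranking is independent of p_ref once
  p_ref sits below the smallest positive map value. The sum runs over all
  heavy atoms including the backbone by default (configurable by passing a
  reduced placement), and log base 10 is fixed for reproducibility — both
  choices only rescale a regression feature.
- **Y** (per rotamer): with water maps `ab` (built for the placed residue
  alone) and `ag` (antigen) on one shared grid, and molecular-volume masks
  of both sides,
  `Y = −Σ_{ag volume} L(ab) − Σ_{ab volume} L(ag) + Σ_{overlap} [L(ab)+L(ag)]`
  where `L = log10(max(·, p_ref)/p_ref)` and the overlap is the set of cells
  where both water maps exceed p_ref outside both molecular volumes. Per
  (position, type) the minimum over rotamers is kept (the most
  hydration-favourable conformation before binding). Fully separated
  partners give Y = 0 exactly.
- **Z**: for a profile column with counts C_i, depth M (gaps included) and
  pseudo-count base B (default √M): with M′ = ΣC and B′ = B + M − M′,
  `Z_i = 2·log2(((C_i + B′·p_i)/(M′ + B′))/p_i)`. With no gaps and B = √M
  this is identical to the experimental preference form, which is tested.
- Types with no clash-free rotamer are scored X = 0, Y = 0 and flagged
  `sterically_excluded` rather than dropped, so the downstream model always
  sees a complete 20-type table.
- The per-antigen-atom contact map attributes each placed atom's
  `L(AVE)` contribution to the nearest antigen atom within 6 Å and averages
  over binder models.
- Correlations between W and X/Y/Z are Pearson coefficients over the 20
  types per position; zero-variance vectors report NaN.

## Experimental preferences (`phageprof`)

The NNK codon set (N = A/C/G/T, K = G/T) contains 32 codons covering all 20
types plus the amber stop. The default background reads TAG as Gln
(`amber_to_Gln`, matching supE suppressor hosts; Gln = 2/32); the
alternative drops the stop and renormalizes over the 31 sense codons. Counts
are exact multiset counts (duplicate clones count separately).
`W = 2·log2(((C + √M·p)/(M + √M))/p)` in half-bit units; `δW = 1 ⟺ W ≥ 0`,
which is algebraically equivalent to `C ≥ M·p` and therefore independent of
the log base. Information content is the relative entropy of the
pseudo-counted frequencies against the background, which is non-negative
and approaches `log2(1/p_i)` for a fully conserved column.

## Preference models (`prefmodel`)

One logistic regression per amino-acid type: features (X, Y, Z) are z-scored
with training-fold statistics (constant features are zeroed), the fit is
deterministic (lbfgs, tolerance 10⁻⁸, L2 strength 10⁻⁶), and folds whose
labels are all identical fall back to an intercept-only model. Training is
leave-one-out over positions: the model predicting position *j* never sees
row *j*. A single-row training fold is degenerate but defined (intercept
fallback), so the protocol works from 2 positions upward.

The regression target is the binary label δW (cross-entropy); a least
squares mode against min-max-rescaled W is available
(`objective="w_regression"`) because the verbal description of the original
objective is ambiguous between the two — the evaluation, thresholds and MCC
are all binary, so binary is the default.

Thresholds t_i are shared per type and optimized on the pooled leave-one-out
activations over the candidate grid {0, midpoints of consecutive sorted
unique pW, 1}; ties break toward the larger threshold; single-class types
default to t = 0.5. Optimizing thresholds on the pooled predictions being
evaluated carries a small selection optimism: on label-independent data at
the benchmark size (24 positions × 20 types) it contributes an MCC of
roughly +0.16 even though the leave-one-out signal itself is zero (the
fixed-threshold MCC is ~0). This is a property of the published protocol,
reproduced deliberately, and is why the null-signal test asserts near-zero
MCC at the neutral threshold and only bounds the optimized-threshold value.

`evaluate` computes TP/FP/TN/FN and accuracy, specificity, recall,
precision and MCC, with the 0/0 → 0 convention for MCC. The closed-form
random baseline for k predicted positives against m true positives among n
types uses the hypergeometric mean E[TP] = km/n per position; with
(n, m, k) = (20, 5.7, 5.7) it gives 0.5925 / 0.285 / 0.285 / 0.715 for
accuracy / precision / recall / specificity. Rankings order the 20 types by
the activation margin pW − t (ties alphabetical); rank distributions are
normalized per interface class against the uniform 5 %-per-rank reference.

## Synthetic fixtures (`synthfix`)

All tests run offline on generated data:

- **Toy complexes**: two ideal-geometry peptide strands facing across an
  exactly-controlled minimum gap (bisection-set), with optional seeded
  coordinate jitter. They exercise parsing, SASA, interface classes,
  scaffolding and clash logic, not realistic protein packing.
- **Statistics libraries**: three-residue peptides with one neighbour atom
  planted at a known offset in the central residue's local frame plus
  far-away decoys; the manifest records the planted geometry so the
  histogram mode and map maxima are predictable.
- **Simulated selections**: sequences drawn position-independently with
  probability ∝ p_i·enrichment_ji over the NNK background (default
  M = 200 binders, matching the scale of a few hundred selected variants
  per library). Position independence means the simulation cannot probe
  higher-order couplings between CDR positions — neither can the
  first-order model being tested.
- **Planted model tables**: X, Y, Z standard normal per cell with default
  generating weights (1.5, −1.0, 0.8, 0) at 24 positions; the label is the
  sign of the (optionally noisy) linear predictor, and W is the predictor
  itself. Draws whose noiseless predictor falls within 0.5·‖w‖ of the
  decision boundary are redrawn: boundary points carry no recoverable label
  information, and without the margin leave-one-out consistency at
  realistic sample sizes is not achievable by any learner — with it, the
  noiseless pipeline recovers MCC = 1 at the benchmark size.

Passing on these fixtures establishes the arithmetic, the protocols and the
invariants; it does not establish predictive performance on real
antibody–antigen complexes, which depends on the depth of the structure
statistics library and the realism of the rotamer and typing tables.

## Problem sizes and runtimes

The test suite and the reproduction script use deliberately small instances:
toy complexes of 3–6 residues per chain, statistics libraries of 1–4
structures, grids of ~20–40 cells per axis at 1 Å spacing, selections of
150–10 000 sequences, and model tables at the benchmark size of 24 positions
× 20 types. The Monte-Carlo baseline check uses 10⁵ random predictors. The
full suite and the script each complete in about a minute on one CPU.

## Known limitations

- The conformation classes, atom-typing boundaries, interaction-filter
  threshold and PDM smoothing kernel are declared substitutes where the
  original pipeline's exact tables are not reproducible; all are
  configuration, not code.
- Y is computed with the placed residue alone as the antibody-side water
  source; cooperative hydration between CDR residues is out of scope, as is
  backbone flexibility and any energy minimization.
- The per-type thresholds inherit the pooled-optimization optimism described
  above; a stricter nested protocol would trade fidelity to the published
  procedure for less biased absolute numbers.
- mmCIF input, hydrogen placement and structure refinement are out of scope.
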