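# Methods

## Binding analysis

**Saturation.** Direct titration of the fluorescent tracer is modelled as
a rectangular hyperbola F = F₀ + F_max·[L]/(K_d + [L]), optionally with a
Hill exponent n. The free ligand concentration is approximated by the
total added concentration; this ignores ligand depletion even though the
protein concentration (~5 µM) and the K_d are of the same order, because
it is the standard analysis for this assay and keeps the fitted constant
comparable with published values. A depletion-corrected quadratic model
(exact single-site binding for total concentrations) is provided behind
`depletion_correction=True` but is off by default.

**Displacement.** The default displacement model is a four-parameter
logistic with free slope (top, bottom, IC₅₀, Hill slope), the common
"sigmoidal dose-response, variable slope" parameterisation; the exact
functional form used in the original Prism analyses is not documented, so
free slope is the safer default. Monotone-rising displacement data are
rejected for this model. For proteins whose cavity transiently co-binds
tracer and competitor the signal first rises (better solvent exclusion of
the tracer) and then falls as displacement wins; this is fitted with a
two-phase rise-then-fall model (independent rising and falling logistic
limbs), and the reported IC₅₀ is the midpoint of the *descending* limb,
since that is the displacement event.

**Conversions.** K_i = IC₅₀/(1 + [tracer]/K_d,tracer) (Cheng–Prusoff,
valid for competitive binding with free-ligand ≈ total); ΔG = −RT ln K_i
with K_i in molar, T fixed at 298.15 K (measurements at 25 °C) and
R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹, reported as a positive magnitude in
kcal/mol. Fits are unweighted least squares (lmfit/Levenberg–Marquardt);
standard errors come from the estimated covariance.

## Limited-proteolysis model

**Cleavage rules.** Trypsin cleaves after K/R, chymotrypsin after
F/Y/W/L, both blocked by a following proline. These canonical rules are
kept pure; documented nonstandard cuts (for wheat LTP1, the Asp7–Ser8
site) enter through `ProteaseRule.extra_sites`. A pepsin rule (after
F/L/W/Y at gastric pH) is available but contributes no boundaries by
default: structurally intact LTPs resist pepsinolysis, so the gastric
stage is modelled as cut-free.

**Fragment enumeration.** Because limited proteolysis of the folded
protein cuts only a few exposed sites, fragments are enumerated over all
pairs of {N-terminus, cut boundaries, C-terminus} — C(b+2, 2) intervals
for b boundaries — rather than only adjacent pairs. Intervals are 1-based
and inclusive throughout; boundary k means a cut between residues k and
k+1.

**Masses.** Fragment mass = Σ residue masses + water, from an embedded
residue-mass table (average and monoisotopic, standard IUPAC-derived
values identical to the Expasy/Unimod references; see
`src/ltpdigest/config/masses.yaml`). Cysteine state matters at this
protein's scale (8 Cys in 90 residues): `reduced` adds nothing,
`disulfide` subtracts 2 H per bridge fully contained in the interval, and
`carbamidomethyl` adds 57.051 Da (average) per cysteine. The bundled
wheat LTP1 digest table is reproduced by the carbamidomethylated state:
every published calculated mass matches the alkylated average mass to
±0.01 Da, except the single 1–34 row, which instead matches the
*unmodified* average mass exactly — an internal inconsistency of the
published table that the package records rather than resolves. The
bundled wheat record therefore defaults to `cys_state="carbamidomethyl"`,
while the package-wide default for new records is `reduced`.

**Peak assignment.** The default matching tolerance is 250 ppm, suited to
linear-mode MALDI of large peptides (the worst assigned pair in the
bundled table is ~227 ppm; the 1–39 pair is ~193 ppm); a 100 ppm setting
is available to mirror stricter reflectron-grade matching, and tolerance
is always an explicit parameter, never hard-coded. Both average and
monoisotopic fragment masses are tried and the matching scale recorded,
since published tables rarely state which convention a given row uses.
Every within-tolerance candidate is kept: with a 90-residue protein and a
limited-digest fragment space the candidate density is high, so peaks
with ≥2 candidates are flagged `ambiguous` (best candidate first) rather
than silently resolved. Published "normalised relative intensity" columns
are consumed as given (`external_scale` passthrough); the pipeline never
re-normalises published values, and fold changes are only computed
between conditions normalised the same way. Fragments undetected in one
condition are flagged, not given a ratio.

**Cleavage-site calling.** Boundary k is supported by each assigned
fragment starting at k+1 or ending at k. Sites are ranked by support
count, then summed intensity, then position. On synthetic digests with
mass error ≤ tolerance/5 and ≤30% decoys this recovers all true
boundaries with zero false positives (seeded tests).

## Structural metrics

**Superposition.** Kabsch closed-form least squares on atom pairs matched
by residue number and atom name (default: all Cα pairs); unmatched
residues are dropped pairwise; the rotation determinant is forced to +1.
Degenerate (collinear or <3-point) selections are rejected.

**SASA.** Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points — converged to <0.5% against 4000 points), probe
radius 1.4 Å, Bondi (1964) element radii (recorded as `bondi-1964` in
every output). Hydrogens are excluded by default since crystal structures
lack them; NMR ensembles are handled per model and reported as ensemble
means. Because no radii set or algorithm is canonical for the published
surface areas, comparisons against published values use tolerances, not
bit-exact matches. Whole-residue area is the default for the Tyr79
report; side-chain-only is a flag.

**RMSF.** Every frame is superposed onto the first frame (the stated
convention; a mean-structure reference is available) on the alignment
selection, then RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩ over frames and residues
average their reported atoms. Note a finite-size effect: superposition
absorbs 6 rigid-body degrees of freedom out of 3N, deflating RMSF by
roughly a factor √(1 − 2/N); for a 90-residue Cα trace this is ≈1% and
tests use protein-sized ensembles so the √3·σ closed form holds within
2%.

**Reference structures.** The deposited LTP coordinate sets (1GH1, 1CZ2,
1BWO, 2ALG) are not redistributed with the package; the acceptance check
that orders Tyr79 SASA across them (buried ≈5 Å² unliganded, ≈38 Å² with
one ligand, ≈83 Å² with two) and bounds their pairwise Cα RMSD at ≤1.8 Å
runs only when local copies are placed under `data/pdb/`.

## Synthetic data

Generators are pure functions of (parameters, seed) and return the
fixture together with its ground truth. Fluorescence noise is
multiplicative (CV, default 0.05 — triplicate-scale scatter — since
fluorescence error grows with signal). Default binding parameters mirror
the modelled assay: tracer K_d 4.5 µM, tracer concentration 2 µM,
twelve-point titrations spanning ~0.05–8×K_d. Peak-list mass error is
Gaussian in ppm (default 50 ppm, a fifth of the matching tolerance);
decoy peaks are placed ≥5 matching tolerances from every true mass so
"unassignable" is well defined, and the decoy count is sized so decoys
make up the requested fraction of the final list. Coordinate ensembles
add per-atom, per-axis Gaussian jitter (closed-form RMSF = √3·σ) with an
optional random rigid motion per frame that alignment must cancel.

What the generators do *not* emulate: isotope envelopes, adducts,
detector saturation or baseline chemistry in spectra; correlated
(collective) motions in ensembles; cooperative or multi-site binding
beyond the phenomenological bell shape. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise models,
not robustness to every artefact of real instruments.

## Numerical choices and limitations

* Initial guesses for curve fits come from the data (half-saturation
  interpolation, first half-signal crossing); bounds keep constants
  positive and slopes in [0.05, 10].
* Assignment ties are broken by absolute Da error; cleavage-site ties by
  position ascending.
* MD-scale claims (nanosecond trajectories) are out of reach at desk
  scale; ensemble analytics are validated against closed forms and
  invariances on synthetic ensembles instead.
* The bell-model IC₅₀ is a phenomenological descending-limb midpoint, not
  a thermodynamic constant of a two-site model; multi-site global fitting
  is out of scope.
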