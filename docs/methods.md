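# Methods

## The model

`miaqsar` implements multivariate image analysis QSAR (MIA-QSAR) for a
congeneric series: compounds sharing one scaffold and differing only at
defined substituent slots. Each compound is drawn as an aligned 2D
ball-and-stick depiction on a fixed 300 × 348 pixel canvas; every atom is a
filled disk whose radius is proportional to the element's van der Waals
radius and whose pixel value is an atomic property — either the Bondi van
der Waals radius r_vdW (Å) or the Pauling electronegativity ε. Row-major
unfolding of each image gives a 1 × 104,400 descriptor vector, and the
series stacks into the matrix **X** (n × 104,400). Because the scaffold is
pixel-aligned across compounds, every column that varies across rows is
attributable to a substituent choice; constant columns (background and
shared scaffold) carry no information and are masked out before modeling.

Activity is regressed on the retained pixels by single-response partial
least squares (PLS1, NIPALS): **X** is column-mean centered, y mean
centered, no further scaling (all pixels of one model share a unit). The
weight vector of each latent variable is **X**′y of the deflated block, so
the fit is fully deterministic. The regression vector
b = W(P′W)⁻¹q maps a centered descriptor row to a predicted pIC₅₀.

Activities are pIC₅₀ = −log₁₀(IC₅₀ / (1000·MW)) with IC₅₀ in mg/L and the
molar mass MW in g/mol computed from the assembled structure.

## Scaffold template

The series is the phenyltriazolinone herbicide family: an N-phenyl
1,2,4-triazol-5(4H)-one (N-methyl, ring carbonyl) linked through a
methylene bridge to a five-membered heteroaryl ring. Four positions vary:
X (heteroaryl ring atom 1: S, O or CH), Y (ring atom 5: CH/C or S), R¹
(phenyl para substituent: H, Cl, CH₃, CF₃, Br, F) and R² (heteroaryl 3-
and/or 5-substituents: H, 3-CH₃, 3-Br, 5-CH₃, 3,5-CH₃). The template
library (`data/template_library.json`, versioned) stores the scaffold atom
coordinates (Å, explicit hydrogens), bonds, and per-slot attachment points
and directions; substituent swaps never move a scaffold atom, which
guarantees pixel-level alignment by construction.

The published series does not come with structure files, so the template's
composition was validated against the activity table itself: the implied
molar mass MW = IC₅₀·10^pIC₅₀/1000 of every row pins the parent compound
(X=S, Y=CH, R¹=R²=H) to 271.1–271.5 g/mol, and the adopted connectivity
gives C₁₄H₁₃N₃OS = 271.34. With it, all 33 IC₅₀/pIC₅₀ pairs round-trip
within the printed precision (±0.01 log units) and the reference compound
sulfentrazone (C₁₁H₁₀Cl₂F₂N₄O₃S, 387.18 g/mol) reproduces its tabulated
pIC₅₀ of 6.70. Table rows with a 5-substituent print the position-5 ring
atom as "C" rather than "CH"; the assembler treats both codes as "carbon at
position 5" and adds the implicit hydrogen only when the position is
unsubstituted, which also resolves the proposal rows that combine Y=CH with
R² = 3,5-CH₃.

## Rasterization choices

* Disk radius = 0.25 × r_vdW × scale, rounded half-up to whole pixels
  (ball-and-stick convention; configurable).
* Default scale is the largest half-integer px/Å that keeps every compound
  the library can produce within 90 % of both canvas dimensions
  (17 px/Å for the packaged template), with the series' union bounding box
  centered. This makes the canvas a pure function of the template library.
* Draw order is decreasing disk radius with ties broken by atom index, so
  small atoms (H, F) stay visible on top of their bonded neighbours.
* Bonds are not painted by default: property-recoded 1-px carbon-valued
  sticks would add mostly constant columns that the mask removes anyway. A
  `paint_bonds` flag exists for fidelity experiments.
* Pixel convention: (row, col) with row 0 at top; atom centers map by
  rounding half-up. Background is exactly 0, which is unambiguous because
  every coded property value is ≥ 0.7.

The rendering is *a* faithful depiction, not a reproduction of any
particular drawing program's raster; pixel-level statistics therefore
differ from any other rendering of the same series, and the published
point statistics are treated as acceptability bounds rather than equality
targets wherever they depend on the rendering.

## Validation protocol

* **Applicability domain first.** A preliminary PLS model on all 33
  compounds supplies leverages h_i = 1/n + t_i′(T′T)⁻¹t_i and standardized
  residuals (residual / calibration RMSE); compounds with h > h* = 3(A+1)/n
  or |standardized residual| > 3 are flagged. On the packaged series no
  compound is flagged for either pixel property.
* **Kennard-Stone split**, 75 % training / 25 % test (33 → 25/8, round-half-
  up test size). The classic maximin algorithm on Euclidean distances
  selects the *training* set; ties break toward the lowest row index. The
  split runs per descriptor matrix, so the two property models can have
  different test sets.
* **Component selection** minimizes leave-one-out RMSECV, ties toward fewer
  components, capped at min(n_train − 2, 15). The categorical substituent
  design gives **X** a low effective rank (≈ 10 for the packaged series);
  NIPALS stops at rank exhaustion and component counts beyond the rank are
  treated as the max-rank model (their predictions are identical).
* **Statistics.** RMSEC and r² (squared Pearson) on the training fit;
  RMSECV and q² = 1 − PRESS/SS by leave-one-out; on the test set RMSEP,
  MAE, r²_pred, Roy's r²_m forward/reverse pair (with |r² − r₀²| under the
  square root) summarized by mean and absolute difference, Lin's CCC (1/n
  variances), and Q²F1/Q²F2 (denominators referenced to the training and
  test response means respectively).
* **y-randomization**: 10 cycles of refitting on permuted responses at the
  selected component count; reported as the cycle means of RMSE and r² and
  the corrected statistic ᶜr²_p = r·√(r² − r̄²_y-rand). The cycle count is
  configurable; 10 is the default. Mean-across-cycles is used for
  RMSE_y-rand.
* **Bootstrap stability**: 10 cycles of random test-set re-selection
  without replacement (8 of 33), re-running the entire calibration and
  validation block (including component selection and y-randomization) per
  cycle; each statistic is summarized as mean ± sd across cycles.
* **Acceptability bounds** enforced by the tests: r² ≥ 0.6, q² ≥ 0.5,
  CCC ≥ 0.85, ᶜr²_p ≥ 0.5.

## Interpretation and proposals

VIP (variable importance in projection, Σ VIP² = p) and the regression
vector b are folded back to canvas shape for heat-map export; dropped
columns render as exact zeros, and the raw CSV sidecar is the artifact of
record (the rendered PNG color scale is presentation only). Maps come from
the model refit on all 33 compounds.

Proposed analogs are encoded on the same canvas and predicted by each
property model refit on all data (prediction should use all available
information; the training-split model exists for honest error estimation,
not deployment). The reported value is the unweighted arithmetic mean of
the per-property predictions, and proposals whose leverage exceeds any
model's h* are flagged as extrapolations.

## Synthetic data generator

`synthetic_data` emulates the measured design: compounds are sampled
without replacement from the valid substituent combinations (78 for the
full alphabets — position 5 cannot be substituted when Y = S) and
activities are base + additive per-slot effects + Gaussian noise. Defaults:
n = 33 compounds, noise sd = 0.05 pIC₅₀ (a tight enzyme assay), R¹ effects
spanning 2.0 log units with the measured ordering CF₃ ≫ F > Cl > Br > H >
CH₃, secondary R² and ring-atom effects. Effects are additive (no
interactions) by default.

What the generator does *not* emulate: correlated assay error,
heteroscedastic noise at extreme potencies, activity cliffs, or any 3D
property — passing recovery tests demonstrates that the pipeline recovers a
linear additive substituent signal from pixel descriptors, not that real
SAR is additive.

Recovery checks: (i) leave-one-out q² and calibration r²; (ii) exact
least-squares recovery of the effect table from noiseless data (one-hot
design anchored at the generator's reference levels); (iii) coefficient-map
sign agreement, defined as whether b·(x_substituent − x_reference) over two
probe renderings has the sign of the planted effect — the net predicted
shift of that substitution (per-pixel sign is not well-defined for weak
effects on near-collinear fringe pixels); (iv) the fraction of top-decile
VIP pixels inside regions controlled by slots with nonzero planted effects.
Median q² over 20 seeds is non-increasing in the noise level.

## Numerical conventions and degenerate inputs

Rounding of pixel geometry and test-set sizes is half-up. Zero-variance
responses, constant predictions, all-identical rows (Kennard-Stone), atoms
leaving the canvas, duplicate compound ids, and unknown slot codes raise
explicit errors — nothing is silently clipped or imputed. A model whose
randomized refits beat its calibration r² reports ᶜr²_p = 0 with a warning.
Score-covariance condition numbers above 10¹² raise rather than invert.
All stochastic steps (y-randomization, bootstrap, the generator) derive
from one explicit seed via independent spawned streams; Kennard-Stone and
every fitting step are seed-independent.

## Problem sizes

The packaged study is exactly the published design: 33 compounds,
104,400 descriptors before masking (≈ 2,200 retained), two property
models, 10 y-randomization and 10 bootstrap cycles; it completes in a few
seconds on one CPU. The synthetic degradation study uses 20 seeds per
noise level at the same series size.

## Known limitations

* The template geometry is a transcription, validated compositionally (molar
  masses) but not crystallographically; only 2D depiction is supported.
* Published point statistics that depend on the original rendering are
  reproduced as bounds, not equalities (see above).
* The component-selection rule of the original software is unknown;
  leave-one-out minimum is this package's documented choice, and selected
  counts can differ from published ones.
* PLS1 only; no multi-response, kernel or sparse variants.
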