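# Methods

## Scope and model form

`cwqsar` implements a Monte Carlo correlation-weight (optimal-descriptor)
QSAR for continuous toxicity endpoints on a log10 mg/kg bw/day scale. The
model is intentionally one-variable: a descriptor DCW(T, N) is the sum of
learned per-feature correlation weights over a molecule's non-rare
attributes, and the endpoint is an affine function `C0 + C1·DCW` calibrated
by ordinary least squares on the active training set. There is no
multivariate regression, no fingerprint similarity and no 3D information;
everything the model knows is carried by the attribute alphabet and its
weights.

## Molecular representation

SMILES are parsed by a purpose-built tokenizer and graph builder rather than
a chemistry toolkit, because the attribute alphabet is defined on tokens and
adjacency, not on perceived chemistry:

* Two-character halogens (Cl, Br) and complete bracket atoms are single
  tokens; ring-closure digits, `%nn` pairs, bond symbols and parentheses are
  their own tokens. Token concatenation reproduces the input exactly.
* The hydrogen-suppressed graph (HSG) drops explicit hydrogens; bracket
  atoms contribute one vertex whose element symbol is stripped of isotope,
  charge and H-count. Stereo markers (`/`, `\`, `@`) are retained as tokens
  but carry no graph semantics.
* Aromatic atoms keep lowercase symbols in both string and graph attribute
  keys; aromatic bonds count as single bonds for degree/Morgan purposes.

## Attribute families

* **S/SS/SSS** — token n-grams. Two- and three-token windows are compared
  with their reversal and the lexicographically smaller orientation kept, so
  a SMILES and its mirror produce identical keys ("combination", not
  "sequence").
* **EC1–EC3** — Morgan extended connectivity: EC0 = degree,
  ECk(v) = Σ_{u∈N(v)} ECk−1(u), emitted as element-tagged codes
  (`C/EC2=6`). Order-0 codes are computed but not emitted.
* **NNC** — nearest-neighbor code: element plus sorted neighbor-element
  multiset (`C/N[C,C,O]`). The historical code definition is not publicly
  specified; this element+sorted-neighborhood form is this package's own
  definition and tests treat it as such.
* **APP** — atom-pair proportions over {F, Cl, Br, N, O, S, P, =, #}
  ('=' and '#' counted as bond tokens outside brackets; aromatic n/o/s/p
  count toward N/O/S/P). One key `(A.B)..nA.nB` per present pair, with
  multiplicity 1. The γ block exposes the four chlorine pairs individually
  (y1–y4); the δ block covers the upper triangle of the full 9×9 pair
  matrix. A pair selected by both γ and δ enters the descriptor with
  multiplier 2, matching the additive block structure.

## Dataset curation

Curation mirrors conservative regulatory practice: multi-fragment SMILES
(mixtures/salts) and structures outside an organic element whitelist
(default C, H, O, N, S, P, F, Cl, Br, I) are rejected; duplicates — keyed by
CAS, or by the exact SMILES string when CAS is absent — collapse to the
*lowest* endpoint value; rows violating NOAEL ≤ LOAEL are dropped when
paired values are supplied. Values arriving on a linear mg/kg scale are
log10-transformed at read time and checked against a plausibility window
(default −3 to 5 log units, bracketing curated sub-chronic datasets with
margin). An optional histogram-tail trim (`tail_min_count`) can drop
endpoint values in sparsely populated extreme bins; it is off by default
because no published threshold exists for this step — it is a policy knob,
not a claim.

## Optimization

The data are split uniformly at random (seeded) into active training,
passive training, calibration and validation subsets; the first three sizes
are ⌊n·f⌋ and the remainder goes to validation, so equal quarters of 561
records give 140/140/140/141. The target function is

    TF = r_AT + r_PT − tf_balance·|r_AT − r_PT| + IIC_w·IIC_C + CII_w·CII_C

with Pearson correlations r between DCW and endpoint on the two training
subsets, and IIC/CII on the calibration set (IIC uses predictions from the
per-evaluation OLS fit on active training). The balance form with
`tf_balance = 0.1` is the standard penalty keeping active and passive
correlations close; it is exposed as configuration.

Monte Carlo details, all deterministic under the seed:

* every active feature starts at weight 1.0 — an all-equal start makes the
  initial descriptor proportional to attribute count, a scale-free baseline;
* one epoch visits each active feature once in seeded random order;
  proposals are uniform on ±0.1 and accepted only when TF strictly
  increases, so the accepted-move TF trace is non-decreasing by
  construction;
* epochs are pass-level (one full sweep), which keeps the published small
  epoch counts (N* = 4–33) comparable across dataset sizes;
* after each epoch the calibration R² (squared DCW–endpoint correlation) is
  recorded and the best snapshot kept — calibration, not TF, guards against
  overtraining; the passive training set never drives weight updates or
  snapshot selection;
* rare features (present in fewer than T active-training *compounds* —
  presence, not occurrence, counts) are blocked before training and
  contribute exactly 0 forever; features never seen in training are treated
  as blocked for the descriptor at prediction time but still raise the
  domain defect (see below).

Hyperparameter selection is a grid search over (T, N) maximizing calibration
R², ties broken toward smaller T then smaller N.

## Validation statistics

R² is the squared Pearson correlation between observed and predicted values
(consistent with reconstructing the one-predictor F-ratio
F = R²(n−2)/(1−R²) from published tables). Q² is leave-one-out on the
one-variable OLS, 1 − PRESS/Σ(y−ȳ)². Q²F3 anchors external error on the
*active training* variance (the anchor subset is not standardized in the
literature; this choice is documented rather than discovered). CCC uses
population moments. IIC multiplies the correlation coefficient by
min(MAE⁻, MAE⁺)/max(MAE⁻, MAE⁺) over negative/non-negative residuals and is
defined as 0 when all residuals share one sign (including a perfect fit).
CII recomputes the fit per excluded compound (the stricter reading) and
subtracts the summed R² gains; for a one-variable OLS the refit R² equals
the squared Pearson correlation of the remaining pairs, which the
implementation computes by moment downdating and the tests verify against a
literal refit loop.

## Applicability domain

For each non-blocked feature, d_k = |P(S_k) − P′(S_k)| / (N(S_k) + N′(S_k)),
with P/N (P′/N′) the compound-level probability and frequency in the active
training (calibration) set; a feature absent from both sets has maximal
defect 1. A molecule's defect sums d_k over its *distinct* non-blocked
features, and a prediction is reliable when defect < 2·D̄ (D̄ = mean
active-training defect). Two deliberate resolutions: the defect formula is
read as a ratio (the flat typesetting of the source formula omits the
fraction bar — division is the only reading under which frequent shared
features are low-defect); and a molecule with defect exactly 0 is in-domain
unconditionally, which makes the degenerate case of identical
active/calibration feature distributions (D̄ = 0, threshold 0) behave
sensibly under the otherwise strict inequality.

## Synthetic data

The generator emulates the *shape* of curated sub-chronic datasets, not
their chemistry: random valence-respecting trees over
{C, N, O, S, P, F, Cl, Br} with occasional double/triple bonds and phenyl
substituents, serialized depth-first (guaranteeing parseability and valence
sanity), with every alphabet symbol forced into at least five molecules.
Default library size is 200 molecules, matching the scale of per-organ
endpoint datasets (90–283 compounds). Labels are planted: true weights
uniform in [0.5, 2.5] per feature, affine scale mapping the true-descriptor
range onto −1 … 4.3 log units (the span of curated endpoint tables), plus
Gaussian noise. Paired mode emits LOAEL = NOAEL + U(0.05, 0.5), satisfying
the ordering constraint by construction.

What passing on this data does and does not show: the planted endpoint is
*realizable* within the model class, so recovery tests measure the
optimizer and pipeline, not the adequacy of one-variable DCW models for
real toxicity data; real endpoints carry inter-study variability,
activity cliffs and mechanism diversity the generator does not emulate.
The domain-shift experiment (halogen-free training family vs perhalogenated
challenge set) tests the defect machinery, not realistic chemical-space
coverage.

## Problem sizes and numerical choices

Tests and the acceptance script use 200-molecule libraries, quarter splits,
N = 30 epochs and three seeds per condition — the package's chosen
desk-scale study conditions, at which one training run takes a couple of
seconds. Degenerate situations raise typed errors rather than producing
NaNs: constant descriptors (calibration impossible), empty active-feature
sets after blocking (threshold too high), constant metric inputs.
Zero-variance DCW encountered *during* a proposal evaluates the target
function to −∞ and the move is rejected. The one statistical invariant
asserted as a seed-average rather than per-seed is the ≈90% in-domain rate
of active-training compounds: with 50 compounds per run it is a binomial
draw with ~4% standard error, so the test averages over three fixed seeds.

## Known limitations

* The NNC code and the target-function base form follow this package's
  documented definitions where the literature is silent; retrained weights
  are not numerically comparable to models trained by other software, and
  published per-endpoint coefficients are stochastic-run artifacts that this
  package reproduces in form, not in value.
* No structure standardization (neutralization, tautomers, InChI); duplicate
  detection is string/CAS-based by design.
* SMILES support is a Daylight-style subset: stereo descriptors are inert
  tokens, and exotic bracket-atom contents beyond isotope/charge/H-count are
  not interpreted.
* The applicability domain is a feature-coverage criterion, not a
  reliability probability; it knows nothing about endpoint uncertainty.
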