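# Methods

## Scope and model

`foldscreen` analyses *predicted* multi-chain structures: coordinates (PDB
or mmCIF) plus the predictor's confidence output — a per-residue pLDDT
vector on the 0–100 scale and a square pairwise predicted-aligned-error
(PAE) matrix in Å. PAE(i, j) is the expected positional error of residue j
when the prediction is aligned on residue i; the matrix is generally
asymmetric. Residues are indexed globally, 0-based, concatenated in file
chain order; per-chain index ranges are half-open and partition [0, N),
which makes the structure↔confidence correspondence testable as an exact
bijection.

Parsing drops hydrogens ("heavy atom" = element ≠ H/D) and collapses
alternate locations to the highest-occupancy conformer (ties prefer
altloc A). Nucleic chains are parsed with the same residue/atom types as
protein chains so that composite-stage distance measurements can address
DNA atoms. Confidence files are accepted in two JSON dialects: a combined
scores file (`plddt` + `pae` keys) and a PAE-only file
(`predicted_aligned_error`, optionally wrapped in a one-element list as
deposited-database files are) with pLDDT read from the coordinate file's
B-factor column. Both dialects yield identical bundles for the same data;
files record values to 2 decimals and the generator emits values at that
precision, so round trips are exact.

## Confident contacts and interface statistics

A confident inter-chain contact is a residue pair from different chains
with

- minimum heavy-atom distance strictly `< 5 Å` (configurable; a
  Cβ-only rule is selectable),
- both residues' pLDDT strictly `> 50`,
- combined PAE strictly `< 15 Å`.

All boundary comparisons in the package are strict, so values exactly at a
threshold fail. Because PAE is directional, the two values of a pair are
reduced by a configurable rule: `min` (default — either direction
confident suffices; permissive and recorded in outputs), `mean`, or
`both_must_pass` (implemented as the maximum, so the strict `<` test is
equivalent to requiring both directions to pass).

Interface statistics are computed over exactly the confident contacts:
`n_contacts`, average interface pLDDT (per-contact residue-pair means by
default; a unique-residue mean is available as an option since either
convention is defensible), and average combined PAE. An empty contact set
reports count 0 with the averages undefined (NaN); NaN never passes a
confidence flag and ranks below every number.

The KD-tree-accelerated extraction is contractually equal to the all-pairs
brute-force filter; the test suite and the acceptance script verify exact
set equality on seeded fixtures, including confidence distributions that
straddle every threshold.

## Ensemble agreement (avg_models)

For M models of the same pair scored with identical parameters, let U be
the union of canonical contacts across models. Then

    avg_models = (1/|U|) * Σ_{c in U} count(c) / M,

where count(c) is the number of models containing c. An empty union scores
0; identical non-empty sets score 1. Canonical ordering of contact pairs
(lexicographic by (chain, residue number)) makes the union well defined
and the statistic symmetric under chain relabelling.

## pDockQ

pDockQ is computed independently of the confident-contact rule, per its
published definition: interface contacts are Cβ–Cβ pairs (Cα for glycine)
within 8 Å (non-strict, matching the reference code), `x` is the mean
pLDDT over unique interface residues times the natural log of the contact
count, and

    pDockQ = 0.724 / (1 + exp(-0.052 (x - 152.611))) + 0.018
    (Bryant, Pozzati & Elofsson, Nat. Commun. 13:1265, 2022).

A contact-free interface returns exactly 0.0. For models with more than
two chains the census runs over all inter-chain pairs jointly.

## Confidence calls and screening

Flags use strict `>` at the conventional thresholds: interface pLDDT 70,
avg_models 0.5, pDockQ 0.23, external classifier 0.5. The classifier slot
is a hook — any callable `(metrics, models) -> [0, 1]` can be registered;
the package ships none, because trained classifiers are separately
published artifacts with their own data dependencies.

A screen scores each entry's M-model ensemble once. The single-model
statistics reported per pair are those of the *representative* model,
chosen deterministically as the model with the highest own average
interface pLDDT (ties toward the lowest model id); avg_models uses all M
models. Ranking is descending by the chosen key with ties broken by
pair_id ascending; entries that fail to parse or score are logged,
reported with their error, and ranked after every scored entry. Ranks are
therefore total, gap-free, and invariant under permutation of the input.

## Composite assembly

Superposition is the SVD least-squares fit: with centred coordinate
matrices, H = MᵀR, SVD H = U S Vᵀ, and rotation V diag(1, 1, d) Uᵀ where
d = sign(det(V Uᵀ)). Flipping the smallest singular component when the
unconstrained optimum is a reflection keeps rotations proper
(det = +1 within 1e-9) — rigid bodies cannot be mirrored. Fits require at
least 3 matched atoms and reject collinear sets (second singular value
below 1e-8 of scale), where the rotation about the line is
underdetermined.

Anchored alignment fits on one shared chain's matched atoms (residue-
number intersection by default; explicit pair lists override) and applies
the transform to all mobile atoms. The anchor atom rule is α-carbons by
default, with full-backbone and all-shared-atom-names variants (the last
also serves coarse traces and nucleic anchors). Assembly applies steps
sequentially — each step's reference must be the base or an already placed
component — records per-component provenance (anchor, transform, RMSD),
and resolves chain-id collisions by suffixing (`A` → `A_1`), with the
mapping reported. Because each placement is fit directly against already-
placed coordinates, a two-step assembly equals the single composed
transform to floating-point precision.

The clash census enumerates inter-component heavy-atom pairs violating a
steric rule. The default "major clash" rule is distance
< r_vdW(a) + r_vdW(b) − 1.5 Å with Bondi (1964) van der Waals radii
(extended with common metals; unknown elements fall back to carbon's
1.70 Å); a fixed-cutoff rule (< 2.0 Å) is selectable. The 1.5 Å slack
tolerates ordinary packing contacts and flags only substantial
interpenetration. Anchor-chain pairs are excluded automatically (the
placed copy of the anchor trivially coincides with its reference), as are
user-listed (component, chain) pairs. A KD tree restricts candidates to
the rule's maximum threshold before the exact per-element rule is applied,
so the accelerated census equals the naive O(n²) scan — an equality the
tests assert on every fixture.

## Synthetic data generator

The generator defines the conditions under which the pipeline is tested.

*Geometry.* Chains are idealized coarse traces: one residue per 8 Å along
x with two pseudo-atoms (CA, plus a CB offset 1.5 Å in z); the partner
chain mirrors the bait at a 20 Å offset except at planted positions, where
the partner residue is placed so the pair's minimum heavy-atom distance
falls in the requested range (default 3.5–4.5 Å). This guarantees, by
construction and verified post hoc by the brute-force oracle, that exactly
the planted pairs are in contact and every other inter-chain pair clears
the 5 Å cutoff by ≥ 2 Å. A "helical" style adds a cosmetic z-wobble
(useful because a straight Cα line is collinear and cannot anchor a
superposition). The traces are not stereochemically valid protein — only
inter-residue distances and confidence values matter to the analysis under
test — so passing tests demonstrate correctness of the *analysis*, not
robustness to real-structure pathologies (missing atoms, alternate
conformers at interfaces, genuinely ambiguous interfaces).

*Confidence.* pLDDT is drawn per residue from interface
(default 90 ± 4) or background (60 ± 10) normals, clipped to [0, 100]; PAE
is background (25 ± 4 Å) everywhere except planted pairs (5 ± 2 Å), drawn
independently in each direction because real PAE is asymmetric, clipped to
[0, 35] and rounded to the 2-decimal file precision. Defaults emulate a
confident predicted interface over an uncertain background; screens with
these defaults are deliberately easy, and the noisy variants used in the
oracle-equivalence tests straddle every threshold instead.

*Ensembles.* Reproducibility p is the per-model inclusion probability of
each true contact. The default sampling is stratified: each contact is
reproduced in floor(pM) or ceil(pM) models (stochastic rounding, model
subset uniform), so the marginal per-model probability is exactly p *and*
the realized avg_models is unbiased for p. This is a deliberate design
choice: under independent Bernoulli sampling the score averages only over
the union of *observed* contacts, giving E[score] = p / (1 − (1 − p)^M)
— for p = 0.2, M = 5 that is 0.30, and no calibration statement against p
would hold. The independent mode remains available (`sampling="bernoulli"`)
for studying exactly that conditioning bias. A decoy pool can inject
spurious confident contacts at a chosen per-model rate. Suppression of a
non-reproduced contact is imposed through its PAE (pushed to background
level in both directions), since pLDDT is a per-residue quantity shared
across contacts.

*Screens.* Default conditions: 100 decoy pairs (40+40 residues, no planted
interface — their chains never approach the cutoff) and 5 true pairs
(40+40 residues, 20 planted contacts, 5-model ensembles at p = 0.9). Decoys
therefore score avg_models = 0 with undefined interface pLDDT, and true
pairs are recovered at ranks 1–5. Per-entry seeds derive from the master
seed via `SeedSequence.spawn`, making manifests and files byte-identical
per seed (file formats carry no timestamps).

## Numerical and testing choices

- Tolerances: rotations proper/orthogonal to 1e-9; superposition recovery
  and transform composition to 1e-6 Å; PDB coordinate round trip to
  1e-3 Å (format precision); confidence round trips exact at file
  precision; pDockQ against the directly evaluated sigmoid to 1e-9.
- Problem sizes: oracle-equivalence runs use chains of 30–150 residues
  (50 fixtures); avg_models calibration uses 200 true contacts on
  200+200-residue chains over 100 seeds per p ∈ {0.2, 0.6, 0.9};
  screen-recovery uses the default 100+5 screen over 100 seeds. These
  sizes give the statistical assertions comfortable power while keeping
  the whole suite to a few minutes on one CPU.
- Ties are always broken deterministically (representative model by
  lowest model id; ranking by pair_id; altloc toward 'A').
- Degenerate inputs have defined behaviour: empty contact sets (NaN
  statistics, avg_models 0), single-chain models (distinct error), < 3 or
  collinear anchor atoms (distinct error), empty clash reports.

## Known limitations

- The exact atom-level distance rule and PAE direction handling of any
  particular upstream analysis script are conventions, not standards; both
  are parameters here (`atom_rule`, `pae_combine`) and are recorded in
  every output rather than guessed silently. Likewise whether interface
  pLDDT averages contact pairs or unique residues is an option.
- pDockQ was calibrated on two-chain complexes; for k-chain models the
  joint census is a pragmatic extension, not a recalibration.
- The synthetic generator does not emulate prediction failure modes beyond
  confidence noise (no compositional errors, no partially disordered
  interfaces), and its backbones are not physical.
- Composite assembly is rigid: no flexible fitting, no refinement, no
  density-map docking. Clash assessment is geometric only.
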