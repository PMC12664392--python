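# Methods

## X-scan profiling

An X-scan measures T-cell activation (% IFNγ⁺ CD8⁺ cells) for every
single-residue variant of a reference 9-mer epitope: 9 positions × 20
residues, in replicate. The pipeline order is fixed: **average replicates
first, then normalize** the averaged matrix so the wild-type cell of every
position reads exactly 100%. Averaging before normalization follows the
order in which the operations are naturally described for duplicate assays;
per-replicate normalization is possible by calling `normalize_to_wildtype`
on each replicate before averaging, but is not the default, and the test
suite asserts the documented order rather than equivalence of the two.

Normalization divides each position's row by its wild-type cell, so the
wild-type value is exactly 100 in floating point (x/x ≡ 1). A matrix is
normalized at most once; renormalizing is rejected rather than treated as a
no-op, because a second pass would silently hide a pipeline wiring error.
The normalization anchor is the per-position wild-type variant cell (the
same peptide measured within each position's series), not a single global
wild-type measurement — with per-position anchoring the wild type is
trivially a member of every tolerance set.

**Tolerance calls** use a strict inequality: residue r is tolerated at
position i iff normalized activation > 30%. The wild type is included by
construction (100 > 30), never by special-casing. Raising the threshold can
only shrink the sets (tested as a property). Values above 100% (variants
outperforming wild type) are legal and kept on the raw 0–100+ scale.
Missing cells are errors, not imputed zeros: silently imputing would shrink
motifs and hide candidate cross-reactive peptides, the worst failure mode
for a safety screen.

**Alanine scan.** Each position is substituted with alanine individually,
except the two MHC anchor positions (p2/p9 for HLA-A\*02:01 9-mers), which
are substituted simultaneously — mutating an anchor alone mostly probes MHC
binding, not binder recognition. The joint variant is modelled as one
pseudo-position labelled `"2+9"`. A position is *sensitive* when its
alanine-variant activation is at or below the threshold (complementing the
strict ">" of the tolerance call).

## Motifs and proteome scanning

A tolerance profile serializes to a PROSITE-style pattern: bracketed,
alphabetically sorted residue classes joined by `-`, singletons written
bare. Emission is deterministic and byte-stable; `parse(emit(m)) == m` is a
tested round-trip. Scanning semantics follow the ScanProSite reporting
convention: windows at 1-based inclusive offsets, all overlapping matches
reported. The implementation compiles the motif to a lookahead regular
expression; the test oracle is a naive per-window set-membership loop, so
the two routes stay independent.

Non-canonical letters (X, B, Z, U, \*) fail every class and are never
expanded to ambiguity sets — a candidate epitope must be a real peptide.
Deduplication keys on the peptide string: a peptide occurring in several
proteins is one candidate with multiple provenance rows. The wild-type
target epitope is normally excluded from the candidate summary (it is the
intended target, not a cross-reactivity risk) but retained in the raw hit
list; the CLI exposes `--keep-self` to disable the exclusion. No
MHC-binding-affinity filter is applied to candidates; that is a documented
extension point, not a default, since motif matching alone defines the
candidate set here.

## Assay arithmetic

**HTRF specificity.** The ratio divides the target-complex signal by the
*maximum* negative-control signal — the conservative reading when several
controls are present. The hit call is inclusive (`ratio ≥ fold`), default
fold 25 (`HTRF_FOLD_SCREEN`); a 50-fold preset (`HTRF_FOLD_STRINGENT`)
matches the stricter criterion used for final binder selection. Both are
exposed; neither is silently preferred. Zero negative signals are floored
at `min(positive signals) × 1e-3` (configurable) before division.

**Dose-response.** The three-parameter log(agonist) vs. response model
fixes the Hill slope at 1 — that is precisely what distinguishes it from
the four-parameter variant: `y = Bottom + (Top − Bottom)/(1 + EC50/x)`.
Fitting is deterministic least squares (`scipy.optimize.curve_fit`,
trust-region reflective) with a fixed initialization rule: bottom =
min(response), top = max(response), EC50 = the dose nearest the
half-maximal response; the optimizer works in log10(EC50) space, bounded
three decades beyond the measured dose range, with plateau bounds ten spans
beyond the data. Degenerate inputs (non-positive doses, < 4 distinct dose
levels, constant responses) are rejected. `DoseResponseModel.fit()` returns
a results object with parameters, covariance-based standard errors,
residual diagnostics and a `summary()` — the statsmodels idiom. The
effective concentration for fraction F has the closed form
`EC_F = EC50·F/(100−F)` under unit slope, hence EC90 = 9·EC50; the
plug-back identity (model response at EC_F equals Bottom + F% of the span)
is tested.

**Specific lysis** is the exact release formula; results below 0% or above
100% (counter noise) are reported as-is, not clipped, and the % is invariant
to counter gain (all three releases scaled together).

## Structural footprints

**SASA** is Shrake–Rupley: each atom's sphere is inflated by the 1.4 Å
water probe, quadrature points are placed on it, and the accessible
fraction is the share of points outside every other inflated sphere.
Points are placed on a Fibonacci (golden-spiral) lattice — deterministic
for any point count — with 960 points per atom by default; doubling the
count changes fixture totals by < 0.5% (tested). The radius table is
NACCESS-like (C 1.70, N 1.55, O 1.52, S 1.80 Å); hydrogens are dropped on
reading (deposited models at ~3 Å have none), waters and hetero residues
are excluded by default, and alternate locations keep the
highest-occupancy atom. Because PISA's exact radii are unpublished,
agreement with published interface areas is asserted at ±10% rather than
exactly.

**Interface area** is `½(SASA_A + SASA_B − SASA_AB)` over a two-group
partition (binder vs MHC heavy chain + β2m + peptide). Per-atom buried
areas (SASA alone − SASA in complex) are clipped at 0 to absorb tiny
negative quadrature noise; their sum equals twice the interface area, each
side contributing its ΔSASA. The backbone fraction of a side is the share
of its buried area on atoms named N, CA, C, O (OXT included) — for
glycine, CA counts as backbone, so an all-glycine interface has fraction 1.

**Contacts** are distance-only heavy-atom calls, appropriate for ~3 Å
models without hydrogens: hydrogen bonds are donor/acceptor-typed N/O
pairs across the partition at ≤ 3.5 Å (typing from a fixed per-residue
atom table: backbone N donates, backbone O accepts, plus the standard
side-chain donors/acceptors); hydrophobic contacts are apolar-carbon pairs
at ≤ 4.5 Å, where carbonyl/carboxylate/amide/guanidinium carbons and the
TYR CZ count as polar. Angle terms are out of scope. A pair qualifying as
a hydrogen bond is not double-counted as hydrophobic.

**Superposition** is Kabsch with the proper-rotation (determinant)
correction. Atom pairing uses author residue numbers per mapped chain,
dropping residues missing on either side; Cα-only is the default and
all-atom is a flag (published RMSDs of this kind rarely state which was
used; Cα is the common convention).

## Synthetic data

The generators define the conditions under which the pipeline is tested.
X-scan simulation draws tolerated cells from Normal(80, 5) and
non-tolerated cells from Normal(5, 5) — in % activation, two replicates —
truncated at 0, with the wild-type cell drawn from the active
distribution. These levels put the 30% threshold 5 σ above the inactive
mean and 10 σ below the active mean (the spec-level invariant
`active − inactive > 4σ` is enforced), which is what makes exact profile
recovery the expected outcome: per-cell error probability is below 1e-6
after averaging two replicates. No above-wild-type tail is simulated by
default. Proteome simulation uses uniform residue frequencies by default
(a SwissProt-like frequency preset, `UNIPROT_FREQS`, is provided); planted
peptides are spliced at recorded offsets, and colliding plant sites are
rejected with advice to reseed rather than silently overwritten. All
randomness flows through NumPy's PCG64 (`default_rng`), so outputs are
byte-identical per seed across platforms.

What the synthetic data does *not* emulate: plate effects and replicate
correlation in activation assays, compositional structure of real
proteomes (domains, repeats, homologs — which raise chance motif-hit
counts), heteroscedastic reader noise in dose-response data, and real
protein packing in the toy coordinate sets. Passing tests therefore
demonstrate the correctness of the arithmetic and the recovery behaviour
under the stated noise model, not performance on real screening data.

## Problem sizes

The test suite and the acceptance script run the scanner-vs-enumeration
comparison on 100 proteomes of ~30 proteins × ~330 residues (~10⁴
residues each), profile recovery over 500 seeds, and dose-response checks
on 13-point curves — sizes chosen so every claim is exercised end-to-end
while the whole suite completes in well under a minute on one core.

## Known limitations

* Structure-anchored regression values (buried area ≈ 1170 Å², Cα RMSD
  0.4 Å, the published binder contact-residue set) require the deposited
  coordinate files (PDB 9FE1/9EPA); the corresponding test downloads them
  when a local copy is absent and fails cleanly offline.
* Interface areas depend mildly on the radius set and quadrature; ±10% is
  the honest comparison window against webserver values.
* Candidate ranking beyond occurrence-count deduplication (e.g. by
  predicted MHC binding) is deliberately out of scope.
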