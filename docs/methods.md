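# Methods

`biogps` compares enzyme active sites without superimposing the proteins
first. Each site is turned into an alignment-free descriptor — a set of
probe interaction fields condensed into four-point geometric codes — and
sites are scored against each other by the volume overlap of those fields
at the best code-derived superposition. The resulting similarity profiles
are clustered and mapped with PCA. This note documents the model, every
tunable that matters, the synthetic test bed, and the numerical choices.

## 1. Catalytic-machinery superposition (visual baseline)

Structures can be superposed on three (optionally four) anchor atoms: the
general-base nitrogen (e.g. His Nε2), the two oxyanion-hole backbone amide
nitrogens, and the catalytic serine Oγ when available. The fit is Horn's
closed-form quaternion solution: the optimal proper rotation is the
eigenvector of the 4×4 matrix built from the cross-covariance of the
centred anchor sets. Iterative refinement (default 15 rounds) first fits
everything onto the first structure, then repeatedly onto the arithmetic
mean of the current anchor positions; the aggregate anchor RMSD about the
mean is non-increasing by construction.

Serine hydrolases occur with mirror-image catalytic machineries. Because a
proper rotation cannot undo a reflection, a structure whose anchor
tetrahedron (base, oxyanion 1, oxyanion 2, Oγ) has the opposite signed
volume to the reference is first reflected through the x = 0 plane
(x → −x). The signed-volume test is this package's formalization of "when
necessary"; the user can force either behavior.

A backbone-RMSD matrix (N, CA, C, O paired by residue rank, truncated to
the shorter chain, Horn-fit before the RMSD) plus classical MDS serves as
the deliberately crude geometric baseline against which the field-based
map is judged.

## 2. Pocket detection

The active site is a set of lattice nodes (default spacing 1.0 Å, 4 Å
bounding-box margin) that are *accessible* — farther from every heavy atom
than its van der Waals radius plus a 1.4 Å solvent probe — and *buried*:
of 26 lattice rays per node, at least `b_min = 16` hit protein within an
8 Å scan range. Occupancy is heavy-atom-only; including hydrogens would
carve the H-bond approach corridor of every donor out of the pocket, which
is exactly where the polar probes must sit. The pocket is the largest
26-connected buried component (ties broken toward the structure centroid).
These buriedness parameters are this package's own, documented choices;
they reproduce "enclosed but accessible" with nothing hidden.

A deterministic fallback, `pocket_from_serine`, takes all accessible nodes
within a radius (default 10 Å) of the catalytic serine Oγ. It exists so
that workflows projecting designed mutants never depend on cavity-detection
quirks.

## 3. Probe fields

Four probes sense complementary properties at every pocket node
(kcal/mol, negative favorable, clamped to [−15, +5]):

| probe | senses | energy terms |
|-------|--------|--------------|
| H | shape | steric only |
| O | site H-bond donors (carbonyl-like acceptor probe) | steric + directional H-bond vs donors |
| N1 | site H-bond acceptors (amide-NH-like donor probe) | steric + directional H-bond vs acceptors |
| DRY | hydrophobicity | steric + Gaussian shell over aliphatic carbons |

with

    E_LJ(r)   = ε[(r_min/r)^12 − 2 (r_min/r)^6],   ε = 0.10, r_min = 3.4 Å
    E_HB(r,θ) = E_hb · cos²θ · exp(−(r − 2.9)² / 2·0.4²),  E_hb = −4.0,
                zero beyond 4.0 Å
    E_DRY(r)  = −w_phobic · exp(−(r − 4.0)²/2),    w_phobic = 1.0

θ is measured from the donor's X–H axis when the hydrogen is present,
otherwise from the lone-pair proxy (away from the mean of bonded heavy
neighbors); an atom with no resolvable neighbors is treated as an
unconstrained group (cos²θ = 1). Donor/acceptor typing is a name-based
table (backbone N–H donor except Pro, backbone O acceptor, the usual
S/T/Y/N/Q/K/R/H/W/C donors and D/E/N/Q/S/T/Y/H/M acceptors); hydrophobic
carbons are those bonded only to C or H, with bonds inferred from
distances (1.8 Å heavy–heavy, 1.3 Å X–H). All parameters live in
`ProbeParameters` and are config-overridable. The probes' partial charges
are carried implicitly by the sign and depth of the H-bond well; this
energy model is intentionally simple and fully open — it reproduces the
qualitative contrasts of the four probe chemistries, not any proprietary
force field's numbers.

## 4. Condensation: pseudo-fields and representative points

The node field is condensed twice:

*Pseudo-fields.* Every favorable node's |energy| is attributed to the
nearest chemically eligible atom (O → donors, N1 → acceptors, DRY →
aliphatic carbons, H → heavy atoms within 5 Å of the pocket), giving an
atom-centred cloud of Gaussian kernels with per-probe widths σ = 1.0 (H),
0.8 (O/N1), 1.2 (DRY) Å. Two weighting rules keep the chemistry visible:

* the chemical probes (O, N1, DRY) attribute only their probe-specific
  energy component — the steric baseline, which is identical for every
  probe and carries only shape information, stays with the H probe.
  Without this split the polar clouds are ~80% shape signal and
  donor-rich vs acceptor-rich sites become nearly indistinguishable;
* kernels are unit-integral, so a center's volume contribution equals its
  attributed |energy| regardless of σ. Probes then pool by energy rather
  than by kernel width (a σ = 1.2 kernel would otherwise carry 3.4× the
  volume per kcal/mol of a σ = 0.8 one) — the weighting that puts polar
  and hydrophobic interactions on one scale.

All similarity scoring happens on these clouds.

*Representative points.* A greedy energy/space-coverage rule picks at most
`k_max = 30` nodes per probe: repeatedly take the most favorable remaining
node (ties by node index), discard nodes within `min_sep = 1.5` Å, stop at
the energy cutoff (−0.5 kcal/mol). Deterministic by construction.

## 5. Quadruplet fingerprints

Representative points are pooled across probes — capped at 30 points,
strongest first with round-robin probe balance, keeping the quadruplet
count at C(30,4) ≈ 27k — and every 4-point combination is encoded as:

* the sorted 4-multiset of probe labels (2 bits each),
* the six pairwise distances in a canonical order, binned at 1.0 Å up to
  16 Å (6 bits each),
* a chirality sign: the sign of the signed volume in canonical order,
  zeroed when |V| < 0.5 Å³ (near-planar).

Canonical order sorts the four points by (probe rank, sorted incident
distances, energy); distances are rounded to 1e-6 Å before binning and key
comparison so that rigid motions at floating-point precision cannot flip a
bin. When sort keys tie exactly, chirality is the maximum over
key-consistent orderings — permutation invariance is kept at the cost of
chirality for perfectly symmetric sets. The code multiset is invariant
under rigid motion and flips only its chirality field under reflection,
which is what makes mirror-image sites distinguishable and the fingerprint
usable with no prior alignment.

## 6. Comparison and the five matrices

Two sites are joined on identical codes (per code, the 20 strongest rows
per side pair combinatorially); the joined list is ranked by combined
point |energy| and truncated to the top M = 200 matches. Each match
proposes a pose (Horn fit of the four canonical points; collinear
quadruplets are skipped), poses closer than 2° / 0.25 Å to an earlier one
are deduplicated, and each surviving pose is scored.

Overlap of two kernel clouds under a pose is the normalized Gaussian
cross-correlation scaled to volume units:

    V_ov = ⟨f_a, f_b∘T⁻¹⟩ / √(⟨f_a,f_a⟩⟨f_b,f_b⟩) · min(V_a, V_b)

where ⟨·,·⟩ is the analytic Gaussian-pair integral and V the analytic
kernel volume Σ w (2πσ²)^{3/2}. This definition makes self-overlap exactly
the full volume and bounds V_ov by min(V_a, V_b) (Cauchy–Schwarz). The
Tanimoto score is V_ov / (V_a + V_b − V_ov) ∈ [0, 1].

The *global* score pools all probes' kernels into one cloud and applies
the same formula, with one essential restriction: overlap is counted
probe-with-probe (block-diagonal in probe identity). The probes are
different chemical "colors" of density — letting an O kernel on one
site's donors overlap an N1 kernel on the other site's acceptors would
make chemically opposite linings look alike. The pose maximizing the
global score is kept and all per-probe scores are reported at that single
pose — one consistent superposition per pair. A probe absent from both sides is
undefined (NaN in the matrices), not zero. The all-against-all run
computes the upper triangle plus diagonal, mirrors for symmetry, asserts
the computed self-similarities ≈ 1 and turns pairwise failures into
flagged zero entries rather than aborting.

## 7. PCA map and projection

Each structure's feature vector is its row of the chosen similarity matrix
(its Tanimoto profile against all n references), mean-centred and not
variance-scaled. One refinement matters for projection: the diagonal
self-similarity is identically 1 and carries no comparative information,
yet it would give every training row a one-coordinate spike that a
projected object's profile can never reproduce — measured on the synthetic
set, that spike shrinks every out-of-sample projection toward the map
centre by roughly the inter-class centroid gap. The fit therefore imputes
each diagonal entry with its column's off-diagonal mean (raw-row behaviour
remains available via ``impute_self=False``), and projection applies the
same replacement to any row entry ≥ 1 − 1e-3 (a similarity of ~1 simply
identifies the object *as* that reference). Projecting a training
structure consequently reproduces its fit-time scores exactly, and fresh
structures land inside their class's cluster instead of between clusters. SVD of the centred rows gives orthonormal loadings,
scores and explained-variance ratios; the sign convention (largest-|·|
loading entry positive) makes maps reproducible. Projection of a new
structure computes only its similarity row against the original
references, centres it with the stored means and multiplies by the stored
loadings — the model is never refitted, so mutants never distort the map
they are judged against.

Classical (Torgerson) MDS of the backbone-RMSD matrix — double-centred
squared distances, top eigenpairs, √λ scaling — provides the geometric
baseline embedding; a warning is attached when over 30% of the spectral
mass is negative.

## 8. Synthetic test bed

No public structure set can exercise this pipeline offline, so the
`fixtures` module generates parametric pockets: a spherical cup (radius
6 Å, opening half-angle 35°) of 16 lining groups — backbone-like N–H
donors, carbonyl C=O acceptors, methyl-like carbons in controllable
fractions — pointing at a focal point, jittered by seeded noise (σ 0.3 Å,
truncated at 2σ), behind an inert double backing shell (proline nitrogens
at +2.5/+3.9 Å) that seals the cavity for the buriedness scan, plus two
inward lip rings at the rim that constrict the mouth so the buriedness
boundary is a sharp plane (this keeps the detected mask stable under
rigid motion of the input). The bottom pole carries a catalytic serine Oγ and
a triad-like anchor set sits below the cup, so superposition, reflection
handling and the serine-anchored pocket are all exercisable. The three
canonical classes are donor-rich, acceptor-rich and hydrophobic
(0.70/0.15/0.15 permutations). Stepwise morphs convert a seeded subset of
lining groups toward a target chemistry with everything else frozen — a
ground-truth "mutant series" for projection.

What the fixtures do *not* emulate: real hydrolase folds, sequence
context, side-chain flexibility, bound water, or crystallographic noise.
Passing the class-recovery and morph-projection checks therefore shows the
machinery is sound and sensitive to lining chemistry at realistic length
scales — not that any particular real enzyme family will separate.

## 9. Numerical choices and degenerate inputs

* Horn fit: n < 3, mismatched lengths, or collinear sets raise; the
  rotation is re-orthonormalized by SVD to meet the 1e-9 properness
  contract; RMSD is invariant under common rigid motion to 1e-9.
* Clash nodes (≤ 0.3 Å treated as 0.3 Å in the steric term) clamp to
  +5 kcal/mol for every probe.
* Empty pseudo-fields (no eligible atoms) are legal and score 0 against
  anything non-empty, undefined against another empty field.
* Fingerprints with fewer than four pooled points are empty; comparison
  then reports flagged zeros ("no-pose"), never an exception.
* All randomness flows through explicit integer seeds; reruns are
  bit-identical (the PNG plot is the only artifact whose bytes may embed
  library metadata, and it carries no data used anywhere).

## 10. Problem sizes used by the test suite and acceptance script

Class recovery runs 3 classes × 8 seeds (24 sites, 276 unique pairs) at
full default budgets; the similarity-axiom batch uses 13–21
random-chemistry sites at reduced budgets (10 points/probe, 20 pooled) —
the axioms under test are size-independent; the Horn/rotation-grid
comparison uses a 10° Euler grid (23k rotations). These sizes were chosen
to make a complete desk run take minutes while every check still exercises
the full code path.

## 11. Known limitations

* The energy model is a documented simplification: no electrostatics
  beyond the implicit H-bond charges, no protonation assignment, no
  solvation. Absolute energies are not comparable to any calibrated force
  field; only contrasts between probes and between sites are meaningful.
* Buriedness thresholds (16/26, 8 Å) suit desk-scale cups and typical
  enzyme pockets at 1 Å spacing; very wide, shallow grooves will need a
  lower `b_min`.
* The pose search is exact-code matching plus a finite pose budget; two
  sites similar only under a pose that no shared quadruplet proposes will
  be under-scored. Increasing `top_m` trades time for recall.
* Per-probe scores are reported at the global-best pose, not each probe's
  own best pose; a probe can therefore score lower than a probe-specific
  alignment would give.
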