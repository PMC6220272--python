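# Methods

## The descriptor

`whales3d` computes a 33-value, alignment-free 3D molecular descriptor from
the heavy-atom geometry and partial charges of a single conformer. For each
heavy atom *j* of a molecule with heavy-atom coordinates *x₁…xₙ* (Å) and
partial charges *δ₁…δₙ* (elementary charge), a charge-weighted covariance of
the atom distribution about *j* is formed:

    S_w(j) = Σᵢ |δᵢ| (xᵢ − xⱼ)(xᵢ − xⱼ)ᵀ / Σᵢ |δᵢ|

The atom-centred Mahalanobis matrix (ACM) holds the quadratic forms

    ACM(i, j) = (xᵢ − xⱼ)ᵀ S_w(j)⁻¹ (xᵢ − xⱼ)

so atoms lying along a centre's directions of high variance are "close" in
that centre's local metric and peripheral atoms are "far". The matrix is not
symmetric: each column j carries its own metric. Per-atom summaries follow,
with the diagonal excluded throughout: **remoteness** Remᵢ is the row
average, **isolation degree** Isⱼ is the column minimum, and their ratio
IRᵢ = |Isᵢ|/|Remᵢ|. Atoms carrying strictly negative partial charge have all
three values negated, so the sign structure of the charge distribution
survives the reduction. Finally each of the three per-atom distributions is
summarized by its minimum, nine deciles and maximum, concatenated as
[Rem | Is | IR] × [min, d1…d9, max] into 33 values that do not depend on
molecular size, atom order, or rigid motions of the conformer.

The quadratic form is used exactly as written (no square root); an
`acm_sqrt` option provides the rooted variant. Deciles use
linear-interpolation quantiles (`numpy.percentile`, method="linear") on the
signed per-atom values, and the IR sign is the atom's own sign (a negative
atom has negative IR even though the ratio of two negatives would be
positive).

## Numerical choices

* **Rank-deficient covariances.** Two-atom, collinear and coplanar
  geometries make S_w(j) singular. The inverse is the Moore–Penrose
  pseudo-inverse with relative singular-value cutoff 1e-8·σ_max, which
  restricts the metric to the occupied subspace without ridge inflation.
* **Degenerate weights.** If Σ|δᵢ| vanishes the descriptor is undefined and
  the molecule is rejected with a `degenerate weights` error. This happens
  for real inputs: a perfectly apolar symmetric molecule (e.g. benzene)
  under Gasteiger–Marsili charges with hydrogen folding has exactly zero
  net charge on every heavy atom. The shape (unit-charge) variant covers
  such molecules.
* **Validity domain of the numerical cross-checks.** The test suite and the
  acceptance script compare the pseudo-inverse ACM against a naive per-pair
  least-squares oracle. That agreement is only well-posed away from the
  rank cutoff: when σ_min/σ_max of some covariance approaches 1e-8 the two
  formulations legitimately disagree (different rank decisions), and near
  that regime roundoff grows like κ·ε times the quadratic form. The
  oracle-check generator (`make_conditioned_cloud`) therefore resamples
  random clouds until every atom-centred covariance has condition number
  ≤ 100 — two orders of magnitude inside the well-posed regime — where the
  observed agreement is ~1e-12. Rank-deficient geometries are exercised
  separately through exact line/plane fixtures at a 1e-8 tolerance.
* **Tie-breaks.** Conformers with equal minimized energy: lowest conformer
  index. Equal screening distances and equal fusion scores: lexicographic
  molecule id. Ranks are post-tie-break integers (no fractional ranks).

## Molecule preparation

Input SMILES/SDF records are sanitized with RDKit: the largest organic
fragment is kept (salts and counter-ions removed), representable charged
groups are neutralized, and the canonical SMILES is stored. Conformers are
generated with ETKDGv3 distance-geometry embedding (experimental-torsion and
basic-knowledge terms, random starting coordinates, caller-supplied seed,
default 0), 10 starting conformers each minimized with MMFF94 for up to
1000 iterations; the lowest-energy minimized conformer is kept. No RMS
pruning is applied so that exactly `n_confs` starting conformers are always
minimized. Records that already carry 3D coordinates can bypass embedding.

Charge schemes: `gasteiger_marsili` (iterative partial equalization on the
full molecule with explicit hydrogens), `unit` (δᵢ = 1, the pure-shape
variant), and `external` (per-atom charges from a TSV keyed by molecule id
and heavy-atom index, e.g. quantum-derived charges produced elsewhere).
Because only heavy atoms enter the descriptor, hydrogen charges are by
default folded into their bonded heavy atom before stripping
(`fold_h_charges`), which conserves the total molecular charge to machine
precision; the flag makes the unfolded alternative testable since either
convention is defensible.

## Screening

Libraries are ranked by Euclidean distance on Gaussian-normalized
descriptors: each column standardized to zero mean and unit *population*
standard deviation. Zero-variance columns contribute zero but are kept so
dimensionality and column order are stable. The normalization population is
configurable (`norm_scope`): library ∪ queries for prospective screening
(external queries must live in the same standardized space), library alone
for the retrospective benchmark where queries are library members.
Multi-query campaigns are fused by the sum of reciprocal ranks and sorted
descending.

## Scaffold-hopping evaluation

Murcko frameworks (ring systems plus linkers, side chains removed) are
computed with RDKit; acyclic molecules share a single empty-string
pseudo-scaffold rather than each counting as unique, a conservative choice
that avoids inflating diversity. The relative scaffold diversity of actives,
SD_A% = 100·ns/na, counts unique active scaffolds (ns) against retrieved
actives (na) in the top fraction (default 5%) of a ranking; it is undefined
(excluded from aggregation) when na = 0. The top segment holds
max(1, ⌊fraction·m⌋) entries. The enrichment factor EF_f compares the active
rate in the top fraction (default 1%) with the library-wide rate; with
self-excluded queries the query is counted in neither.

The retrospective benchmark keeps each target with at least 20 annotated
actives (inclusive threshold), uses every active in turn as a self-excluded
query, and aggregates SD_A% and EF per target as medians over runs (the
median is applied to EF as well, mirroring the SD_A% rule). Descriptor-set
comparison uses PCA on the descriptors × targets SD_A% table augmented with
per-target Best/Worst rows, column-mean-centred and decomposed by SVD, with
components oriented so Best ≥ Worst on PC1; PC1 then orders descriptor sets
by average scaffold-hopping ability.

## Synthetic fixtures: what they emulate and what they do not

`make_point_cloud` produces exact geometries (regular tetrahedron, line,
plane, seeded Gaussian) so the descriptor core can be validated against
hand-derivable or brute-force values, including the rank-deficient paths.

`make_screening_fixture` builds chemically valid SMILES libraries from six
ring frameworks (benzene, pyridine, piperidine, naphthalene, biphenyl,
indole) with enumerated acyclic substituents, so every molecule's Murcko
family is known by construction. Each target's actives are drawn from
designated families (default min(4, families)) in equal blocks, emulating
the congeneric analog series that real activity data contain. Defaults —
200 molecules, 5 families, 2 targets, 20 actives per target — keep the
leave-one-active-out benchmark exact and fast on one CPU.

`make_planted_descriptors` emits descriptor matrices with controlled
neighbourhood structure: `scaffold` mode clusters molecules by framework
with same-(family, target) actives in tight analog subclusters — the
scaffold-copying behaviour of fragment fingerprints, which retrieve the
query's own series first — while `activity` mode clusters actives by target
irrespective of framework, an idealized scaffold-blind descriptor. Centres
are dense ±1 sign patterns over all 33 columns (magnitude 10, analog offset
2, jitter sd 0.3) so the planted separation survives per-column
standardization. On these fixtures the scaffold-blind set scores higher
SD_A% than the scaffold-copying set on every target, reproducing the
3D-descriptor-versus-fingerprint contrast as a direction, not a number.

These fixtures do not emulate real activity-data properties: no activity
cliffs, no assay noise, no inactive analogs inside an active series, no
realistic scaffold frequency distribution, and library sizes far below
screening scale. Passing tests demonstrate the correctness of the
arithmetic and the direction of the scaffold-hopping contrast under planted
structure — not retrieval performance on real targets.

## Known limitations

* Quantum-derived charges are supported only by ingesting an external
  charge file; no electronic-structure code is run.
* Single lowest-energy conformer per molecule; no conformer ensembles.
* Charge is the only atomic weighting exposed (other atomic properties can
  be injected through the external-charge mechanism).
* Molecules whose heavy atoms all carry exactly zero weight are rejected
  rather than silently falling back to the shape variant.
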