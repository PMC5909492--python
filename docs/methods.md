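# Methods

This note records the models implemented in `cylmap`, the conventions chosen
where the method definition leaves genuine freedom, and what the synthetic
test bed does and does not establish.

## Canonical orientation of the complex

All surface and cylinder mathematics assume the inter-subunit axis is Z.
The frame is built from the data: e₃ is the unit vector from subunit A's
centroid to subunit B's, the origin is the centroid midpoint, and the
in-plane X direction is the leading principal axis of the pooled atom cloud
projected orthogonally to e₃. Principal axes carry a sign ambiguity, which
we resolve with the third central moment of the coordinates along the
candidate axis (skewness): this functional is rotation-invariant, so the
whole frame is equivariant — any rigid pre-transform of the inputs yields
identical oriented coordinates, which is verified to 1e-9 on the maps. The
convention degrades only for inputs that are exactly mirror-symmetric about
the candidate axis (zero skewness), where the sign may flip; real atom
clouds and jittered fixtures are never symmetric to machine precision.

## Contact surface

Per grid node (step 1 Å by default), the lower bound is the maximum z of
below-subunit atoms whose lateral distance to the node is ≤ step·√2/2, the
upper bound the minimum z of above-subunit atoms, and z is their midpoint.
The capture radius makes "the vertical through the node" operational — a
zero-width ray almost never intersects atom centers. A node is undefined if
either side has no atoms in the capture cylinder or if the vertical gap
exceeds `gap_threshold`.

`gap_threshold` defaults to 8 Å: wide enough to span a cavity holding a
small ligand between the subunits, narrow enough to exclude open solvent.
The method only fixes that *some* threshold exists; 8 Å is this package's
choice and is exposed as a parameter.

## Sliding cylinder

The cylinder is infinite in z — membership is purely lateral (XY distance
≤ r, default r = 4 Å). Bounding the height is a possible variant, but
nothing in the method requires it and an unbounded cylinder keeps
membership monotone in r. The per-residue weight is
w = f·exp(−(d−d_min)²/h): f is the atom fraction inside the cylinder, d the
mean **3D** distance of all the residue's atoms to the node (the node is a
3D point on the curved surface, so the vertical offset matters), and the
bandwidth h defaults to s²/2 with s the subunit's mean atom-to-centroid
distance, making the decay scale with protein size. The closest residue
always attains w = f, and w is non-increasing in d at fixed f.

Diversity per node delegates to the population statistics with columns =
the mapped alignment positions of the cylinder residues and weights = w.
Residues that cannot be mapped to an alignment column are dropped with a
warning rather than failing the whole map.

## Population statistics

* **π** is the count-weighted average pairwise mismatch fraction. Clone
  copy counts enter combinatorially — the per-column mismatch mass is
  (N² − Σ_a n_a²)/2 over state copy totals n_a — never by materializing
  rows, so 100 clones with 30 haplotypes cost 30 rows. Columns containing
  gaps are kept and the gap is a distinct character state: pooled cloned
  fragments can carry indels, and silently dropping such columns would
  bias π downward.
* **Shannon entropy** is per-column, count-weighted, base 2 (bits), gap as
  a 21st state; 0 iff the column is monomorphic, upper bound log₂ 21.
* **Nei–Gojobori sites**: per codon, each position contributes the fraction
  of its three single-nucleotide alternatives that are synonymous /
  non-synonymous; the two counts sum to exactly 3. Mutations to stop codons
  count as non-synonymous (conservative and deterministic). Site counts for
  a column are averaged over gap-free rows, copy-count weighted.
* **Substitutions** are counted against the **major-allele codon** (count-
  weighted most frequent; ties broken lexicographically): every distinct
  observed codon is decomposed position-wise and each differing nucleotide
  is classified by mutating the major codon at that position. The
  alternative — all unique pairs — is a legitimate reading; major-allele
  counting is deterministic and matches the pooled-population setting where
  variants are naturally read against the dominant haplotype.
* **dN/dS** over a column set is (Σk_n_sub·w / Σk_n_site·w)/(Σk_s_sub·w /
  Σk_s_site·w), with two explicit sentinels: `no-variation` (no
  substitutions at all) and `undefined-high` (non-synonymous variation
  only). For RG rendering these map to intensity 0 and 1 respectively.
  No Jukes–Cantor correction is applied: within-population divergence is
  far below saturation.

## RG classification

Channels are normalized **per channel** by the maximum over defined finite
nodes ("maximum intensity" in image terms is per color), making the filter
invariant to rescaling either raw map. The filter is precedence-ordered:
black first (both < 0.2), then green (G > 2R), red (R > 2G), yellow as the
remainder — the precedence guarantees a partition. Under a uniform (R, G)
measure on the unit square the four classes integrate to 0.04 / 0.24 /
0.24 / 0.48 (black/red/green/yellow), so the mutual classes (0.52) and the
one-sided classes (0.48) are close to, but not exactly, equiprobable; we
report this measured split rather than forcing equality.

## Ternary poses

Merging superposes the shared subunit with Kabsch (proper rotation);
atoms are matched on (chain, residue index, atom name) and a superposition
RMSD above 1 Å warns about differing conformers of the shared subunit.
The two filter constraints are **inclusive** (N_o ≤ 10 at t_o = 1 Å,
mean distance ≤ 5 Å), matching their "not higher than" definition; boundary
poses are kept. Pose clustering is single linkage on second-subunit RMSD in
the anchored frame with a 5 Å default cut — orientation groups in practice
are separated by tens of Å, so the exact cut is not delicate; it is a CLI
flag. A membrane-orientation screen of heterodimers is deliberately not
implemented: the original criterion is visual/manual and has no numeric
definition; consumers can pre-filter their pose manifests.

## Gene-tree congruence

Pseudo-haplotype collapsing is average-linkage hierarchical clustering of
Hamming distances cut at exactly k = 15 clusters (`cut_tree`, robust to
tied merge heights); the representative is the highest-count member and
frequencies pool. The 3D embedding is classical metric MDS with a
deterministic sign convention (first nonzero loading of each axis
positive). Each population becomes an isotropic GMM: component means from
the embedding, weights = frequencies, shared σ² = (0.1 × mean
inter-component distance)² — σ is a smoothing choice, exposed as a
parameter; results are insensitive to moderate changes because ΔG
comparisons hold σ fixed.

ΔG is defined here as the squared L2 distance between the two mixture
densities, ∫(f₁−f₂)², which has a closed form via pairwise Gaussian product
integrals, is symmetric, nonnegative, zero iff the densities coincide, and
monotone with component separation; it is verified against 3D grid
integration to 1e-4. Superposition minimizes ΔG over rotations,
translations and mirror reflections — no scaling — via frequency-weighted
Kabsch on component means (pair weight = mean of the two components'
frequencies), evaluating both the proper and the reflected optimum.
Components correspond by index.

The permutation null shuffles the component frequencies of **both**
mixtures independently (the stronger null; one-sided shuffling is a flag),
holding positions fixed, and recomputes the superposition optimum each
time; p = (1 + #{ΔG_null ≤ ΔG_obs})/(n_perm + 1) with n_perm = 1000, so
p ∈ [1/(n+1), 1] and equal frequencies give p = 1 exactly.

NJ trees come from scikit-bio's neighbor joining; tanglegram edges connect
leaves that are mutual 5-nearest neighbours in the common post-Procrustes
frame, ties broken by index.

## Structure ↔ alignment mapping

How structure residue numbering relates to alignment columns is not fixed
by the method; this package's convention is ungapped sliding of the chain's
one-letter sequence along the count-weighted alignment consensus, keeping
the offset with maximal identity and rejecting matches below 0.9 identity.
A property test confirms exact offset recovery for structures generated
from alignment rows.

## Synthetic test bed

The generators emulate the study conditions: pooled populations of 100
clones collapsing to tens of haplotypes with Zipf-skewed frequencies
(exponent 1.0 — dominant-haplotype populations), codon-consistent nt/aa
rows, and substitutions confined to planted patches with a controlled
synonymous fraction; both the aa-level and nt-level haplotype counts are
plantable (e.g. 50/77 and 30/36 per 100 clones for the two genes). Dimers
are jittered residue lattices with a known planar interface at z = 0 and
residue names taken from the major haplotype so structures map onto their
alignments exactly.

What passing tests show: the geometry, weighting, counting and inference
machinery is correct on inputs with known truth, at realistic population
scale. What they do not show: behaviour on real folds (curved interfaces,
buried residues, heterogeneous residue sizes), on alignments with
misalignment artifacts, or on docking poses with physically meaningful
energies — flat-slab fixtures make the planted truth exact but are not
proteins. Problem sizes used by the default suite and acceptance script —
14×14-residue subunits (~800 atoms), 8×8 for the 20-transform invariance
sweep, 50 random alignments for the π oracle, 50 seeded runs (199
permutations each) for the decoupled congruence control and 1000
permutations for the matched pair — were chosen as the smallest sizes at
which every planted effect is unambiguous.

## Numerical conventions

Tie-breaks are deterministic throughout: lexicographic for major codons and
consensus characters, first occurrence for haplotype tables, lowest index
for nearest-neighbour ties and cluster representatives. Degenerate inputs
raise typed errors (`InputError`, `EmptyResultError`; the CLI maps them to
exit codes 2 and 3). PDB coordinates round-trip at the format's 3-decimal
precision; alternate locations keep the highest-occupancy conformer;
insertion codes survive inside string residue indices. All randomness flows
through seeded `numpy` generators; identical seeds give byte-identical
outputs.
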