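# Methods

`sarclust` groups bioassay-tested small molecules into structure–activity
relationship (SAR) clusters: sets of compounds that are similar both in
structure and in bioactivity. This note records the models, parameter
choices, numerical conventions and known limitations of the implementation.

## Bioactivity contexts

A compound is *non-inactive* in an assay when any of its outcome records is
`active`, `inconclusive` or `unspecified` — only an explicit `inactive` call
excludes it. The existential rule is deliberate: depositors frequently leave
genuinely active compounds unspecified, and the same compound may carry
several rows per assay (e.g. extra potency rows). Clustering runs separately
for every UID of three contexts:

* **assay** — UID is the assay id (AID); compounds non-inactive in that assay;
* **protein** — UID is a protein identity group (PIG). Every assay maps to
  the sequence ids (GIs) of its targets; GIs whose case-normalized sequences
  are identical share one PIG, so the same protein tested under different
  identifiers (or from different organisms) pools its assays. PIG ids are
  the 1-based rank of the sequence in sorted order — deterministic and
  insensitive to input order. Outputs list the member GIs of each PIG;
* **pathway** — UID is a pathway id (BSID), reached assay → GI → BSID.

Assays without a protein mapping contribute only to the assay context, and
proteins without a pathway only to assay + protein, so compound coverage is
nested: pathway ⊆ protein ⊆ assay. Multi-target assays propagate their
assay-level outcome to every linked GI (per-target outcomes are not part of
the data model).

## Similarity measures

Five measures are used; each UID × measure combination is clustered
independently, giving 3 × 5 = 15 cluster subtypes.

**2-D.** Tanimoto over substructure-key fingerprints, T = AB/(A+B−AB) with
A, B the popcounts and AB the intersection popcount; 0 when both
fingerprints are empty (no similarity evidence rather than 0/0). The exact
881-key dictionary used by the reference pipeline is not public, so the
package ships a documented 64-key default (element counts, ring and
functional-group SMARTS with per-key match-count thresholds) and accepts any
other key set or precomputed fingerprints verbatim (hex text table,
MSB-first within each byte).

**3-D.** Atom-centered Gaussian volume overlap. Each heavy atom contributes
a density p·exp(−α‖r−R‖²) with fixed prefactor p = 2.7 and width α chosen so
the Gaussian volume matches the hard-sphere volume of the atom,
p(π/α)^{3/2} = (4/3)πr³. Overlap volumes are first-order (pairwise) only:

    V_XY = Σ_i Σ_j p² (π/(α_i+α_j))^{3/2} exp(−α_i α_j d_ij² / (α_i+α_j)),

which is the exact integral of the product of the two summed densities; no
higher-order inclusion–exclusion terms are applied. Shape-Tanimoto is
ST = V_AB/(V_AA+V_BB−V_AB); under the first-order convention ST(A, A) = 1
exactly. Color-Tanimoto applies the same formula to fictitious feature
("color") atoms, summed over six pharmacophoric types (donor, acceptor,
cation, anion, hydrophobe, ring), with only same-type pairs contributing to
V_AB; CT = 0 when both molecules are feature-free. ComboT = ST + CT ranges
0–2; wherever a unit scale is required it is divided by 2 first.

Parameter defaults: uniform heavy-atom radius 1.7 Å (per-element radii can be
supplied), hydrogens discarded on read; feature-atom radius 1.0 Å and the
same p = 2.7. Feature typing follows a fixed rule table — cation: formal
charge > 0; anion: charge < 0; donor: N/O with ≥ 1 attached H; acceptor: N/O
with charge ≤ 0; hydrophobe: carbon with only C/H neighbors; ring: centroid
of each smallest-set ring. The six types are standard but their operational
definitions vary between published implementations; these are this package's
documented defaults, not a reconstruction of any proprietary table.

**Superposition.** Scores are evaluated at a rigid pose of B onto A optimized
either for ST alone (*ST-opt*) or for ST + CT (*CT-opt*; feature-free pairs
fall back to the shape objective, logged). Both molecules are centered on
their heavy-atom centroids and rotated into principal-axes frames whose axis
signs are fixed by the third moment of the coordinate projections (largest
component as fallback); this makes optimized scores invariant under rigid
motion of either input to well below the 1e−3 documented tolerance. Four
proper axis-flip starts (twelve extra 90° starts under `--starts thorough`)
seed a derivative-free Nelder–Mead search over a rotation vector plus
translation (convergence: simplex score spread < 1e−5, parameter spread
< 1e−4, ≤ 800 iterations per start); the best start wins. Pairs are always
optimized in canonical order (smaller compound id, then conformer index) so
cached scores are reproducible regardless of argument order. Only four of
the six score × pose combinations are clustered (ST^ST-opt, ComboT^ST-opt,
CT^CT-opt, ComboT^CT-opt): each optimization's ComboT together with its ST
or CT determines the remaining one.

**Conformers.** Up to N_max = 10 diverse conformers represent each compound,
selected by max–min heavy-atom RMSD after centroid alignment, seeded at the
lowest conformer index with ties to the lowest index. The selection
procedure of the reference conformer pipeline is not published; max–min over
RMSD is this package's stand-in. Scores between compounds are pre-computed
only for pairs co-tested non-inactive in at least one common assay and kept
in a TSV score warehouse (scores plus the 12-number rigid transform at 17
significant digits, so reloads are bit-identical); pre-computation is
idempotent.

## Thresholds

The clustering distance threshold per measure is d_thresh = 1 − (x̄ + 2s)/norm,
where x̄ and s are the mean and sample standard deviation ((n−1) denominator;
the reference work does not state its convention) of the measure's score
distribution over randomly sampled pairs of biologically tested compounds,
and norm = 2 for ComboT. Two compounds more similar than x̄ + 2s are treated
as structurally similar. Thresholds are reported at 4 decimals (half-up);
values outside [0, 1] are clamped with a warning. The packaged defaults are
the published reference thresholds at N_max = 10: 0.3119 (2-D), 0.1502
(ST^ST-opt), 0.4822 (ComboT^ST-opt), 0.6102 (CT^CT-opt), 0.4748
(ComboT^CT-opt). The reference table's CT row re-adds to 0.3897 from its
printed mean and sd while its printed combined statistic is 0.3898 (a
hidden-digit carry); since the derivation subtracts the combined statistic
from unity, the packaged constants come from that column
(`threshold_from_upper`). Thresholds may also be supplied directly via
config, or re-derived from any compound set with
`score_distribution_stats` (seeded, uniform distinct pairs without
replacement; 3-D compound-level scores take the maximum over the ≤
N_max × N_max diverse-conformer pairs).

## Clustering

Taylor–Butina exclusion (leader) clustering over 1 − similarity distances:
repeatedly pick the unassigned item with the most unassigned neighbors
within d_thresh as representative, assign it with those neighbors, stop when
the best neighbor count is zero; the remainder are singletons. Membership is
boundary-inclusive (distance ≤ d_thresh); the reference description ("closer
than") is ambiguous at equality, so `--strict-boundary` switches to strict.
Ties in neighbor count go to the smallest item id (the reference
implementation's tie order is unrecoverable). No singleton-reassignment pass
is applied. A sampled symmetry/range check on the distance provider guards
against inconsistent inputs.

2-D clustering runs directly on compounds (each compound in ≤ 1 cluster per
UID). 3-D clustering runs on conformers and the conformer clusters are then
collapsed to compound clusters by replacing conformer ids with compound ids
and deduplicating; distinct conformer clusters stay distinct even when their
compound sets coincide or nest, so one compound can occur in several 3-D
clusters of the same UID. Clusters with fewer than two distinct compounds —
including multi-conformer single-compound clusters — are singletons and are
removed from all outputs and statistics.

## Annotation and reporting

A high-value compound (HVC) has an IC50 or EC50 strictly below 10 µM in any
assay, a MeSH annotation, or a MeSH Pharmacological Action annotation
(forced to imply MeSH, with a warning, when the input flags disagree).
Potency qualifiers (">", "<") are outside the data model; only numeric µM
values are accepted. Cluster overlap between measures i and j for one UID is
O(i,j) = 100·N_cmpd(i,j)/N_cmpd(i) over compounds covered by non-singleton
clusters; the aggregate table is the unweighted mean over UIDs where measure
i covers at least one compound (the reference work does not state a
weighting). Summary statistics (compounds/cluster, conformers/cluster,
clusters/compound, clusters/UID) use the (n−1) standard deviation and
exclude singletons. Networks export to GraphML (or SIF): nodes are cluster
members (compound vs conformer recorded as a `role` attribute, matching the
square/round drawing convention), and edges exist only within clusters —
conformer nodes when their distance is ≤ d_thresh, compound nodes when at
least one conformer pair from the two compounds is; close pairs in different
clusters get no edge, which is an inherent property of exclusion clustering.

## Synthetic data

The fixture generator plants a known partition so the full pipeline can be
tested against ground truth. Scaffolds are parametric heavy-atom templates
with distinctive shapes (extended zigzag chain, compact two-ring drum,
planar ring, L-shape; later scaffolds rescale by 12% per cycle) carrying a
scaffold-specific feature element (N/O/P/S → donor/acceptor/cation/anion) on
three anchor atoms, so shape and color similarity both separate scaffolds.
Defaults: 2 scaffolds × 4 compounds × 3 conformers, coordinate jitter
0.05 Å, one atom substitution per compound, rigid random rotation +
translation plus a ≤ 7° torsion-like bend per conformer, 15% inactive
admixture, 25% HVC fraction — small enough that the five-measure 3-D
pipeline runs in minutes on one core while keeping intra-scaffold
similarities far above and inter-scaffold similarities far below every
default threshold. Synthetic fingerprints give each scaffold a disjoint
64-bit block (40 bits set, 2 flipped per compound): intra-scaffold Tanimoto
≥ ~0.8, inter-scaffold exactly 0. The first assay is a screening panel
testing every compound (so one UID co-tests all scaffolds — needed for
recovery checks); the remaining assays are per-scaffold, with each
compound forced non-inactive in its scaffold's first assay unless
`fraction_inactive` is 1.0, which makes every outcome inactive and all
context sets empty. Annotations wire assays to GIs round-robin, duplicate
one protein sequence (to exercise PIG merging) and group GIs into BSIDs.

Fixture molecules are valence-relaxed point molecules — geometry without
chemistry — because the 3-D mathematics needs coordinates, not valences;
their feature atoms are planted from the element map rather than derived
from a connection table. Consequently, passing fixture tests demonstrates
the correctness of the scoring, thresholding, clustering, collapse and
reporting machinery, but not robustness to real conformer ensembles,
tautomers/protonation states, or realistic fingerprint bit correlations. A
small set of real SMILES (benzene, acetate, ethane, sulfamide, …) backs the
fingerprint and feature-typing tests.

## Numerical conventions and degenerate inputs

* Coordinates are Å throughout; no unit auto-detection. SDF round-trips are
  exact to the format's 4-decimal precision; fingerprints and the score
  cache round-trip bit-exactly.
* Compound and conformer ids are opaque positive integers; conformer indices
  are 1-based and unique within a compound.
* Single-atom or fully degenerate molecules optimize by pure translation
  (their principal frames are arbitrary but consistent).
* 0/0 score cases (empty fingerprints, feature-free pairs) score 0 —
  conservative, never similar.
* Threshold reporting rounds half-up at 4 decimals; Python's default
  banker's rounding would make the reported value depend on the binary
  representation at exact .5 ulps.

## Limitations

* Alignment is rigid; no torsional flexibility, electrostatics, or
  higher-order volume corrections.
* The default key set is a compact stand-in, not the 881-key reference
  dictionary; published fingerprints should be supplied when bit-exact 2-D
  behavior is required.
* The optimizer is a multi-start local search; it can in principle miss the
  global pose for pathological shapes, though it matches exhaustive
  rotation-grid search within 1e−3 on the tested geometries.
* Desk-scale only: the reference corpus (~10⁶ compounds, ~10⁷ clusters) is
  out of scope; statistics produced here describe the synthetic datasets the
  package generates.
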