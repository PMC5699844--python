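# Methods

`allocomp` asks whether two labeled sets of bioactive small molecules —
allosteric modulators versus competitive (active-site) ligands — differ in
their physicochemical properties, once the pathologies of curated bioactivity
data are corrected for.  Curated databases are heavily redundant: a handful of
famous targets carry thousands of near-duplicate analogs, the same
protein-ligand pair is deposited many times, and single panel screens annotate
one compound against hundreds of targets.  Any naive set-level statistic
mostly measures this sampling history, not chemistry.  The package implements
a redundancy-aware comparison pipeline and a synthetic-study generator that
makes every stage testable against known ground truth.

## Curation

Each ligand row carries a SMILES, a set label, and its protein targets.
Curation applies, in order:

1. **Assay gate** (optional): assays are kept only if their free-text
   description contains the set's keyword stem (`alloster` / `compet`) as a
   case-insensitive substring, the assay is not a high-throughput screen, and
   it is not manually blacklisted.  Ligands survive only if reported active
   (positive standard value) in at least one kept assay.  Records from a
   curated allosteric-specific source (`ASD`) bypass the gate, since that
   source is allosteric by construction.
2. **Wash**: the largest fragment by heavy-atom count is kept (salt
   stripping); strong acids are deprotonated and strong bases protonated per
   a fixed SMARTS rule table approximating speciation at pH 7 — carboxylic,
   sulfonic and phosphorus O–H acids and tetrazoles lose a proton; aliphatic
   amines, amidines and guanidines gain one; weak acids (phenols) and weak
   bases (anilines, aromatic N) stay neutral.  The rule table is deterministic
   and idempotent, so washing is auditable and reapplication is a no-op.
3. **Deduplication**: one record per (washed SMILES, set); target links are
   merged, so each protein-ligand pair occurs once while polypharmacology is
   preserved.  Uniqueness is keyed on canonical SMILES *including*
   stereochemistry, because stereocenter counts are among the compared
   descriptors.  Counting happens after the wash.
4. **Panel-artifact removal**: any ligand annotated against more than
   `max_targets` (default 100) targets is flagged and removed.  The default
   separates single-study panel screens (hundreds of targets) from ordinary
   polypharmacology (typically < 20).

## Descriptors

29 properties per washed ligand: 18 base descriptors — heavy atoms, aromatic
atoms, H-bond acceptors/donors, acidic/basic atoms, bond count, aromatic
bonds, rotatable single bonds, net formal charge, SlogP, logS, stereocenters,
rings, and Lipinski / lead-likeness violation counts with their boolean
summaries — plus 11 size-corrected versions (raw count ÷ heavy atoms), which
remove the strong correlation between molecule size and every extensive
count.

Atom typing is deliberately open and documented rather than a clone of any
proprietary typer:

- donors: N/O bearing ≥ 1 H (ammonium included); acceptors: O with charge
  ≤ 0, pyridine-type aromatic N, sp/imine N, and amine-type N that is not an
  amide/sulfonamide nitrogen and not positively charged (pyrrole-type N
  excluded);
- acidic/basic atoms: the ionizable sites of the wash rule table, counted in
  either protonation state, keeping ionization and acid/base counting
  internally consistent;
- rotatable bonds: single, acyclic, both endpoints bonded to ≥ 2 heavy
  atoms, excluding amide C–N;
- SlogP: Wildman–Crippen atomic contributions; logS: the ESOL linear model
  (0.16 − 0.63·SlogP − 0.0062·MW + 0.066·rotatable − 0.74·aromatic
  proportion), an established open aqueous-solubility estimate;
- stereocenters: tetrahedral centers *including unassigned ones*, since
  database SMILES frequently omit stereo flags;
- Lipinski violations over {MW > 500, SlogP > 5, donors > 5, acceptors > 10};
  lead-likeness violations over {MW ≤ 450, SlogP ∈ [−3.5, 4.5], rings ≤ 4,
  rotatable ≤ 10, donors ≤ 5, acceptors ≤ 8}; "drug-like"/"lead-like" means
  fewer than two violations.

Because the typers are substitutions for closed implementations, medians of
small integer counts are robust to the substitution, but exact counts on any
particular molecule may differ from other software; the hand-verified fixture
in the test suite pins *this* package's definitions.

## Two-level redundancy clustering

Redundancy is removed at four paired levels of protein sequence identity and
ligand Tanimoto similarity: 60 %/0.6, 75 %/0.75, 90 %/0.9, 100 %/1.0.

**Protein families.**  Pairwise identity comes from one exact local alignment
(BLOSUM62, gap open 11, extend 1); the identical-position count is divided by
each sequence's own full length, giving a bidirectional pair of identities
(a short perfect substring scores 100 % in one direction only).  Families are
built greedily: proteins are visited in canonical order (descending length,
ties by id) and join the first family whose *representative* matches with
`min(identity_ab, identity_ba)` at or above the threshold, else found a new
family.  Exact alignment replaces heuristic database search deliberately: it
is deterministic, dependency-light, and testable; family partitions at
ordinary thresholds are insensitive to the difference.

**Ligand clusters.**  Within each family, the ligands of all member proteins
are pooled (a ligand targeting k families enters k pools — each family is its
own evidence context), deduplicated by washed SMILES, ordered canonically
(descending heavy atoms, ties by id), and clustered by maximum-dissimilarity
sphere exclusion on ECFP6-class fingerprints (hashed circular, radius 3,
2048 bits, no counts or chirality — the closest open analogue of the
commercial fingerprint dialects): the first seed is the ligand with minimal
total similarity to the pool; seeds are added greedily (always the
worst-covered ligand) until every non-seed is within the level's Tc of some
seed; each ligand is then assigned to its most similar seed.  The cluster
center is the member minimizing the summed Tanimoto distance (1 − Tc) to the
other members.  All ties resolve by canonical order, making every run
reproducible.  Because the seed sequence does not depend on the threshold,
cluster counts are monotone in the threshold on a fixed pool.

## Cluster-normalized statistics

Each protein-ligand cluster contributes total probability mass 1: every
member gets weight 1/cluster-size.  Histograms are accumulated at bin width
1 for integer-valued descriptors and 0.001 for continuous ones (SlogP, logS,
and all per-HA ratios), with the floor rule and a round-at-1e-9 guard against
binary representation jitter.  The weighted median is the lower edge of the
first bin whose cumulative mass reaches half the total — a deterministic
convention that lands on integer values for integer descriptors; whether to
interpolate within bins is an open choice and this package declares the
lower-edge convention rather than inferring one.

**Weighted Wilcoxon rank-sum.**  Pooled observations receive mid-ranks on
the weighted empirical CDF, `R_i = (mass below x_i + mass at x_i/2) / W`.
The statistic is the difference in weighted mean ranks between the sets; its
null variance is permutation-style with a design-effect sample size taken
from *cluster total* weights (Kish effective count — every cluster totals
weight 1, so it equals the number of clusters m):

    Var = sigma²_R · M/(M−1) · (1/m_A + 1/m_B),

with sigma²_R the weighted pooled mid-rank variance and M the pooled
effective cluster count; two-sided p from the normal approximation.  Two
properties were design requirements and are verified in the tests to
1e-9/1e-12: with all-singleton clusters and equal weights the formula reduces
*algebraically* to the classical tie-corrected large-sample rank-sum test,
and replicating any cluster's members k-fold (weights rescaling to match)
changes the p-value not at all — the effective counts see clusters, not rows.
An observation-level effective size or an iid sandwich variance would violate
one or the other, which is why this construction was pinned.

**Bootstrap 95 % CIs.**  Each replicate draws `sample size = number of
clusters` values from the histogram bins with probability proportional to
mass and takes the statistic; the interval is the 2.5th–97.5th percentile
over 100,000 replicates (default).  The replicate size matches the weighting
unit — one cluster is one observation's worth of evidence — and is
configurable since "about the number of clusters" admits latitude.  The
replicate median (lower-middle order statistic, rank (n+1)//2) is sampled
exactly through the order-statistic identity — the k-th order statistic of n
i.i.d. draws is the inverse CDF at a Beta(k, n−k+1) variate — making the
default replicate count cheap and the CI a deterministic function of the
seed; means use chunked multinomial resampling.  The center-of-cluster
scheme uses straight random sampling (unit masses).

**Significance and robustness.**  A descriptor differs at one level iff the
weighted rank test gives p < 1e-4 *and* the two 95 % CIs of the median are
disjoint.  No further multiple-testing correction is applied; the strict
threshold itself guards the many comparisons.  A difference is *robust* only
if significant with a consistent direction at all four clustering levels.
Two alternative normalizations are provided as sensitivity analyses: the
center-of-cluster scheme (one center per cluster, unit weights, classical
rank test) and single-level clustering (chemistry only, ignoring protein
families, at Tc 0.6/0.75/0.9/1.0).

The four-level conjunction at p < 1e-4 makes the family-wise false-positive
rate of the robust verdict very small; the test suite measures it on 500
null studies and requires ≤ 1 false verdict per 1000 descriptor decisions.

## Synthetic studies

The generator emulates the statistical structure of curated data without any
external chemistry source.  Molecules are assembled from a closed fragment
grammar — benzene/pyridine/cyclohexane ring units, alkyl/ether/amide/ester
linkers, small caps (H, methyl, hydroxyl, amine, halogen, carboxyl) — into
linear SMILES that always parse and wash.  Two constraints keep compositions
drug-like: every molecule has at least one ring unit and one non-ring unit
(whenever the weights make both reachable), and an ether unit cannot sit at
a bare chain end (it would silently become a hydroxyl).  Baseline fragment
weights were solved once so the expected densities sit at the scale reported
for curated competitive ligand sets — aromatic fraction ≈ 0.46, donors per
heavy atom ≈ 0.08, rotatable bonds per heavy atom ≈ 0.26, median ≈ 25 heavy
atoms — and 4–9 chain units reproduce realistic molecule sizes.

Expected per-heavy-atom densities of the grammar are computed *exactly* by a
dynamic program over chain assembly: the joint distribution of (heavy atoms,
descriptor total) is convolved unit by unit, carrying the tail-fragment
class so junction bonds are scored with the same rules as the descriptor
module (junctions rotatable except amide-N→carbonyl-C, bonds to single-atom
caps terminal, edge alkyl/ester units losing their outer internal bond when
the chain ends bare), and conditioning on the composition constraints.
Set-level shifts (`shift_spec`, e.g. aromatic fraction +0.07, donor density
−0.03, rotatable density −0.02 by default — the directions such a comparison
is expected to find) are imposed by recalibrating one weight knob per
shifted code against this expectation by bisection; realized sample means
track the analytic targets to a few thousandths.

Study structure: family sizes follow a Zipf-like allocation (exponent 0.9 —
a few families hold much of the data); each family holds 1–3 protein
isoforms generated at ~92 % within-family identity by substituting a fixed
position set of a random seed sequence (between-family identity is that of
unrelated random sequences, < 30 %); within a family a configurable fraction
of ligands are analogs of earlier members (one fragment swapped); exact
duplicate rows and an optional panel artifact (n ligands × hundreds of
panel targets) are injected; per-family assays carry the keyword stems, plus
HTS and keyword-free decoys that the filters must drop.  The manifest
records every ground truth: true shift directions, expected densities,
family memberships, duplicate row indices, panel ligand ids.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real medicinal-chemistry scaffold diversity
(fragment grammar, not real molecules), activity values and assay noise
(activity magnitudes are never analyzed), correlated descriptor structure
beyond what the shared grammar induces, and real sequence phylogenies
(families are star-shaped around a seed sequence).  Conclusions about any
real pair of ligand sets must come from running the pipeline on that data.

## Problem sizes in the validation experiments

Chosen once as desk-scale study conditions: type-I control uses 500 null
studies of 6 families/60 ligands per set with bootstrap n = 5,000; power
uses 100 studies with a +0.1 aromatic-fraction shift and ~300 protein-ligand
clusters per set (10 families × ~310 ligands, low analog/duplicate rates),
requiring detection with the correct direction in ≥ 95 % of seeds; the
acceptance script re-runs the same experiments at 200 and 60 studies and a
full default study (300/200 ligands) with 100,000-replicate CIs.

## Numerical and degenerate-input conventions

Zero-variance rank tests (all pooled values equal) return p = 1.  A group
with zero total weight, an empty cluster, or an empty distribution is an
error, not a silent default.  Non-finite descriptor values are excluded from
histograms with a log entry.  Ties in seeding, assignment and center choice
all break toward the canonical order.  Every stochastic quantity (bootstrap,
generator) is driven by explicit seeds; pipeline reruns with the same config
and seed are byte-identical, and each comparison derives an independent
substream from (seed, descriptor, level, scheme, set).

## Known limitations

- Descriptor typing and the fingerprint dialect are open substitutions;
  counts comparable across this package's runs, not across vendors.
- Greedy family assignment is order-dependent by nature; the canonical order
  makes it reproducible, not order-free.
- The weighted rank test treats clusters as independent evidence units; a
  ligand appearing in several families contributes to several clusters, a
  mild dependence the design-effect variance does not model.
- The lower-edge median convention can sit a full bin below an interpolated
  median for coarse discrete distributions.
- Local-alignment identity for families of thousands of proteins is
  quadratic in the number of family representatives; the identity cache
  amortizes it across the four levels.

## Repository shape

The package is a library: the importable API plus `examples/` scripts are
the interface, and the pipeline module is the single orchestration entry
point (`allocomp.run`).  No console script is shipped — the intended users
drive the analysis from Python, and every command-line-style capability
(ingest, descriptors, clustering, analysis, synthesis, full runs) is a
one-call function shown in a worked example.
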