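# Methods

## Units of analysis

Three nested units structure everything: an **ARISA peak** is one
electrophoretic peak in a sample's profile; a **clone** is one sequenced
IGS+23S amplicon; an **OTU** is the set of unique clones that share an
identical 23S fragment and differ only in the IGS. The OTU definition is
deliberately conservative: bacteria carry multiple rRNA operons whose
spacers differ in length, so one organism legitimately owns several clone
lengths and several peaks. The 23S fragment is taken from the 3′ terminus
of the amplicon (the reverse primer anchors inside the 23S gene at
position 132, giving a 131-bp conserved fragment); a 5′ mode exists for
other primer systems. Sequences "share" a 23S fragment only under exact
string identity by default — the ambiguity code N never matches, so two
cores that differ only at an ambiguous base are not merged. A mismatch
tolerance is exposed but off by default, because how sequencing errors
within the conserved fragment should be absorbed is a judgement call the
analyst must opt into.

## Peak binning and clone–peak matching

Capillary electrophoresis reports fractional fragment sizes; profiles are
binned to 1-bp integers (round half up), merging same-bin peaks at their
maximum height and discarding anything outside the sizing standard's
range of 105–1007 bp. Cloned fragments run a few bp long or short of
their sized peak, systematically per fragment, so matching uses a window
on (clone length − peak size) of [−6, +15] bp — the empirically observed
range; a symmetric ±6 "strict" window is available.

Within each age class, each unique clone is assigned to at most one peak
bin. Candidate (clone, bin) pairs inside the window are scored by
co-occurrence support: the number of same-class samples in which the
clone was recovered *and* the bin observed. Assignment is greedy by
descending support, ties broken by smaller |offset| then smaller bin.
Greedy (rather than a global matching objective) is a deliberate choice:
it is transparent, deterministic, and no objective function is implied by
the underlying procedure, which is informal. Clones are exclusive (one
bin each); bins are not — distinct OTUs genuinely share fragment lengths,
and the assignment must be able to express that. Peaks that no clone
claims are artefacts and are removed per sample. Matching is per age
class, so the same bin may be owned by different OTUs in adults and
chicks.

An OTU is flagged as a contaminant when any member clone was cloned from
a saline-control sample or any of its assigned bins occurs in a control
profile; flagged OTUs are dropped from the presence matrix but kept in
reports. The presence matrix is binary (no abundance weights): cell
(s, o) = 1 iff at least one bin assigned to OTU o for s's class survives
in s's filtered profile. OTUs that never received a peak assignment are
excluded from the matrix (they are invisible to the fingerprint) but
remain in clone-based summaries.

## Taxonomy

Per OTU, two lineages on the scale phylum / class / order / suborder /
family / genus / species (suborder included because actinobacterial
classifications resolve there) are combined: the best similarity hit of
its member clones (highest score) and a placement lineage — walking from
the OTU's leaf toward the root of a reference tree to the first ancestor
with support ≥ 0.7 containing reference taxa, then taking the longest
common rank prefix of their lineages. Unlabelled internal nodes count as
fully supported. When hit and placement agree at a rank (and at all
shallower ranks both fill), the OTU is assigned at the deepest agreeing
rank. On conflict the default mode follows the tree unless it contradicts
the hit's phylum ("tree_emphasis"); a "strict" mode truncates to the last
rank before the conflict instead. Raising the support threshold can only
shallow the assignment (clades nest), which the tests assert.

## Rarefaction

Analytical (hypergeometric) rarefaction of clone counts: with S OTUs of
counts N_i (total N), the probability OTU i is missed by a uniform
subsample of n clones is q_i = C(N−N_i, n)/C(N, n), so

    E[S_n]   = Σ_i (1 − q_i)
    Var[S_n] = Σ_i q_i(1−q_i) + 2 Σ_{i<j} [C(N−N_i−N_j, n)/C(N, n) − q_i q_j]

Binomial coefficients are computed in log space (gammaln), so N in the
thousands is safe. 95% limits are E ± 1.96√Var clamped to [0, S]; the
normal approximation is the documented choice (the construction used by
the classic desktop rarefaction tools is not specified anywhere
authoritative). A curve is flagged "plateaued" when the last 10% of
sampling effort adds under half an OTU. Both E and Var are validated
against exhaustive subsample enumeration for all libraries with N ≤ 12.

## Community comparison

All community statistics run on a rooted, branch-lengthed 23S tree whose
leaves are OTUs, with environments defined either as individuals (leaf
sets from the presence matrix) or age classes (one label per leaf;
OTUs found in both classes carry no single label and are excluded from
the two-class permutation tests).

**Unweighted UniFrac.** For environments A and B the tree is restricted
to A ∪ B (pruned; unary chains collapsed; branches at or above the
restricted MRCA dropped — counting the root branch is the documented
alternative, off by default), and U = (branch length unique to A or B) /
(total restricted branch length). Internally the restriction is computed
arithmetically from per-branch descendant counts, which makes the
permutation tests and jackknife cheap; the test suite checks this against
a literal prune-and-classify oracle on all small trees and against
scikit-bio's implementation where the two definitions coincide.

**Permutation tests.** UniFrac significance shuffles leaf labels among
mapped leaves preserving class sizes; the P test uses the minimum number
of label changes on the tree (Hartigan's generalisation of Fitch
parsimony, exact on multifurcations, verified against a Sankoff DP
oracle) under the same null. Both report p = (1 + k)/(1 + n_perm), never
exactly zero, with 100 permutations by default. Because the parsimony
count is integer-valued its null distribution is coarse, making the
P test conservative (empirical size ≈ 0.03 at nominal 0.05); this is a
property of the statistic, not the implementation.

**Lineage-specific analysis.** Every internal clade with at least 4
mapped descendants (root excluded) is tested with a two-sided Fisher
exact test on (environment × inside/outside), sorted by p with
Benjamini–Hochberg q-values. The 2×2 exact test is this package's
explicit choice of statistic.

**Ordination and clustering.** PCoA Gower-centres the squared distance
matrix, eigendecomposes, and reports coordinates for positive eigenvalues
only; percent variation is computed over positive eigenvalues, negative
ones are reported but excluded, and each axis is oriented so its
largest-magnitude coordinate is positive. UPGMA is average-linkage with
lexicographic tie-breaking (bit-identical reruns), validated against
scipy's average linkage via cophenetic distances. Jackknife support
resamples min(keep, |environment|) leaves per environment (keep = 5 by
default) n_perm times and scores each dendrogram node by the fraction of
replicates reproducing its environment grouping; environments smaller
than `keep` are used whole by default, with a "drop" policy reproducing
the original tool's removal behaviour. Identical single-leaf assemblages
are a degenerate pair with no restricted branch length; the pairwise API
treats that as an error, while the matrix path scores it as distance 0 so
one species-poor individual cannot abort a study-level analysis.

## Assemblage statistics

Richness is the row sum of the presence matrix (fingerprint data, not
clone counts, which are distorted by unequal cloning success between
classes). Group comparisons default to seeded permutation tests (10,000
label shuffles, two-sided on the mean difference or on Pearson's r) —
appropriate at n ≈ 20 per group — with the classical statistics
(Mann-Whitney U, F from r) reported alongside for comparability.

## Synthetic studies

The generator emulates the sampling design the analysis assumes: 22
adults and 21 chicks (ages uniform on 5–30 days) plus 4 saline controls;
OTU pools of 24 adult-only, 33 chick-only, 7 shared and 12 contaminants;
per-OTU operon counts 1 + min(Geometric(2/3), 8) (mean ≈ 1.5, max 9) with
amplicon lengths in 304–1090 bp; adult richness Normal(9.2, 2.3) and
chick richness 2.65 + 0.18·age + Normal(0, 2.68) — calibrated so the
population age–richness correlation is 0.45 and the chick mean 5.8 —
rounded and clipped to [1, pool]; cloning depths Normal(47, 28) for
adults, Normal(20.2, 6.7) for chicks (min 8); per-(OTU, operon) size
offsets from a discretised Normal(1.0, 3.6) truncated to [−6, +15]
(systematic per fragment — mobility bias belongs to the fragment, which
is exactly what makes co-occurrence matching work); Poisson artefact
peaks (12.7/sample in adults, 7.6 in chicks); lognormal abundance weights
that produce the singleton-heavy chick tail. `zero_noise()` switches
offsets, artefacts and hit disagreement off; this is the configuration
under which the pipeline must reconstruct the truth exactly, and the one
used for the richness-recovery numbers.

Choices that create a clean identifiability regime, and their rationale:

* **Pool coverage.** Per-sample richness targets are drawn first, then
  every pool OTU is seated in one individual of its class before the
  remaining slots are filled by weighted draws; after cloning, any
  (class, OTU, operon) whose peak is sizeable but uncloned receives one
  guaranteed clone. The study's pools *are* its observed OTUs and its
  stated aim was a cloning effort comprehensive enough to classify every
  common peak; coverage makes the simulated pools observed in the same
  sense without perturbing the richness distributions.
* **Unique operon lengths.** By default all operon lengths are distinct
  across the pool, and lengths in 1002–1022 bp are excluded (fragments
  there exceed the sizing standard, yet their clones would sit inside the
  matching window of in-range peaks and be mis-anchored). Longer clones
  (≥ 1023 bp) are generated and remain unassignable, like the real
  study's longest clones. Set `unique_operon_lengths=False` to allow the
  one-peak/two-OTUs collisions real data show.
* **Artefact bins** are drawn outside the class's true bins so the
  artefact filter's report can be checked exactly in the noiseless case;
  control artefacts additionally avoid all true bins so they cannot
  falsely flag cloacal OTUs.

What the simulator does **not** emulate: sequence evolution (23S cores
are random strings, so placement tests rely on the generated reference
tree, not on alignment realism), chimeras, PCR/extraction bias, baseline
noise in electrophoresis traces, and peak-height quantitativeness.
Passing the synthetic suite therefore demonstrates the *logic* of the
pipeline — assignment, filtering, statistics — under the study's design
parameters, not robustness to every artefact of real ARISA data. Under
the default noisy configuration, fragment-size collisions after offsets
make presence recovery imperfect by construction (F1 ≈ 0.86–0.95, mean ≥
0.9 over seeds), mirroring the one-peak/multiple-OTUs ambiguity reported
for the real data.

## Problem sizes and numerical choices

Default analysis problem sizes were chosen to keep a full synthetic study
under a second and the replicate suites in tens of seconds: 20 replicates
for recovery means (standard errors ≈ 0.12 OTUs), 200 null replicates at
100 permutations for test calibration, rarefaction curves on a 10-clone
grid in the pipeline (exact values at every grid point; step 1 available).
Recovered chick richness carries a small upward bias (~+0.1 OTUs) from
rounding and truncating richness draws at 1; it is inherent to the
calibration, not a pipeline error. PCoA treats eigenvalues above
10⁻¹² · max|λ| as positive; permutation p-values use the +1 correction;
all randomness flows through seeded `numpy` generators, and reruns with
the same seed are bit-identical down to the output files.
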