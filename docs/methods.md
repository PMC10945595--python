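# Methods

This note documents the models, conventions, numerical choices, and known
limitations of the package, in the order data flows through it.

## Sequence and tree handling

FASTA parsing is strict: duplicate ids and header-only records are
errors, residues are uppercased, and each record declares a nucleotide or
amino-acid alphabet admitting only its ambiguity symbol (N / X) and the
gap `-`; the `.` gap dialect is rejected so one canonical dialect exists.
Coordinates are 0-based half-open internally and 1-based inclusive in
reports; codon *i* spans columns [3i, 3i+3). Newick trees are handled by
dendropy behind thin wrappers that force rooting, preserve underscores in
labels, and read internal-node labels as support values on the 0–100
scale. Codon alignments must have equal row lengths divisible by three;
rows with internal stop codons are flagged, not deleted. A
neighbor-joining helper (scikit-bio) is provided as plumbing so
reconciliation workflows can build a working topology without external
tools.

## Codon simulation

The simulator is an acceptance–rejection scheme, deliberately *not* a
named maximum-likelihood codon model: it is simple, exactly seedable, and
sufficient for recovery testing. Per branch, the number of accepted
substitutions is Poisson with mean t·L (t = branch length in expected
accepted substitutions per codon site, L = codons). Each event proposes a
single-nucleotide change at a uniform site/position, choosing the
transition with weight κ against weight 1 for each transversion;
proposals creating stop codons are rejected. Nonsynonymous proposals are
accepted with probability min(1, ω) and synonymous proposals with
probability min(1, 1/ω), so the accepted nonsynonymous:synonymous rate
ratio equals ω over the whole range ω ≥ 0 (with only the nonsynonymous
thinning rule, every ω > 1 would collapse to ω = 1 and regimes of
positive selection could not be simulated). The root sequence is uniform
over the 61 sense codons. At κ = 1, ω = 1 each site has one transition
and two transversion neighbors, so the transition fraction converges to
1/3 — a property test. Alignments are generated gap-free; indel
realism is out of scope.

All simulators are pure functions of their parameters plus one integer
seed (sub-streams derived deterministically), and each returns a
`PlantedTruth` record sufficient to score the downstream estimator.

## dN/dS estimation

Counting follows the classic proportion-based recipe. Site counts per
codon enumerate the nine single-nucleotide neighbors; neighbors that are
stops are excluded from the per-position denominator (mutational-
opportunity convention; a flag restores the include-stops convention),
and s + n = 3 per codon by construction. S and N average the two
sequences. Observed counts average over all substitution pathways
between differing codons, equally weighted, excluding pathways through
stop codons; in the degenerate case where every pathway passes a stop,
all pathways are averaged with a warning. Codons containing gaps,
ambiguity, or stops in either sequence are skipped.

The Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p) is applied to
p_s and p_n; p ≥ 0.75 raises a saturation error and the estimate carries
a `saturated` flag with a NaN distance — never a silently capped value.
ω = dN/dS is NaN with an `omega_undefined` flag when dS = 0. Filters
discard ω > 10, dS < 0.01, dS > 3, dN > 3 (first matching reason
recorded, in that order; saturated distances count against the ceiling
they exceeded); all four boundaries are strict, so boundary values
survive. The member-level gap filter removes rows with *more than* 30%
gaps+ambiguity.

A documented tension: the pairwise recipe here is the counting +
Jukes–Cantor procedure, although parts of the originating literature
describe dS/dN estimation generically as "maximum likelihood"; the
counting recipe is the only fully specified one and is what the oracle
tests pin down. Equivalent ML estimates would differ slightly at high
divergence.

### Per-branch estimates

Ancestral sequences are reconstructed column-wise by Fitch parsimony
(gaps/ambiguity act as wildcards). Ambiguity is resolved deterministically:
a top-down pass assigns each internal node its parent's state whenever
the up-pass set allows it (the most-parsimonious choice), else the
alphabetical minimum; when scoring a terminal branch, a parent state not
forced by its own ancestor prefers the tip's state before falling back to
the alphabetical rule. Each terminal branch is then scored as an ordinary
pairwise comparison of tip vs reconstructed parent. Parsimony slightly
underestimates change on long branches; the planted-ω recovery test
bounds the practical effect. At least three leaves are required
(ancestral states are unidentifiable below that).

### Rates and spectra

μ = dS/(2T) with T in years, dS the group mean. Ti/Tv spectra compare
each sequence against the master with maximum mean pairwise identity
(ties: smallest id): A↔G and C↔T are transitions, other pairs
transversions, one-sided gap columns indels; each substitution is
classified silent/nonsilent by mutating the master codon in place, and
columns inside gapped/ambiguous master codons are excluded from that
split (hence silent + nonsilent ≤ Ti + Tv).

## Expansion Z-scores

Per family, Z = (focal − mean)/SD across proteomes. The focal proteome
is included in mean and SD (the natural reading of "all proteomes";
`exclude_focal` reverses it) and SD uses the sample (n−1) denominator
(`population_sd` reverses it). SD = 0 yields Z = NaN, never called
expanded. The call rule is Z strictly above 2 with ≥ 3 focal members.
The leave-clade-out variant drops a named clade's proteomes (keeping the
focal one) and needs ≥ 3 surviving proteomes.

Operating characteristics under the default synthetic conditions (74
proteomes, mean-1 Poisson background, planted focal counts 10–15):
sensitivity is essentially 1, but the false-positive rate is a few
percent, because a background Poisson(1) draw of ≥ 4 in the focal column
already clears Z ≈ 2.8 with ≥ 3 members — P(X ≥ 4) ≈ 0.019 alone. A
stricter Z or member threshold, or replicate support, is needed when a
~1% false-positive rate matters; the Z > 2 rule by itself cannot deliver
it against a Poisson background of mean 1.

## Reconciliation

`reconcile_dl` is classic LCA reconciliation: each gene node maps to the
LCA of its children's images; a node is a duplication iff it shares its
image with a child; losses follow the path-depth rule (dist − 1 per
child edge of a codivergence, dist per child edge of a duplication).

`reconcile_dtl` is an exact dynamic program over gene nodes × species
nodes with two tables — cost with the gene node mapped *at* a species
node, and mapped at-or-below it (the latter absorbing loss costs per
edge descended). Codivergence places the two gene children into distinct
child subtrees of an internal species node; duplication keeps both
at-or-below the same node; transfer sends exactly one child to a species
lineage incomparable to the current one (undated convention —
time-consistency checking of transfer chains is out of scope, being
NP-hard in general). The optimum over root placements is the reported
cost. Tie-breaking is total (codivergence > duplication > transfer, then
smallest postorder species index; ties in the descend chains prefer
fewer losses), so event counts are reproducible. Brute-force enumeration
over all internal-node mappings confirms optimality on random instances
in the test suite. Default costs: duplication 1.5, transfer 1,
codivergence 0, loss 1 — the loss cost is this package's choice (a zero
loss cost degenerates the model, since losses become free) and is
configurable.

Rank collapsing contracts internal species-tree nodes whose rank is not
in the retained set (species through kingdom by default), preserving the
leaf set and suppressing a single-child root. Support-driven
rearrangement collapses gene-tree edges with support < 98 into
polytomies and re-resolves each polytomy to minimize full-tree DTL cost:
exhaustively over all rooted binary shapes up to degree 6 ((2k−3)!!
candidates), stepwise best-join above, with not-yet-resolved polytomies
caterpillar-resolved during scoring. The result is compared against the
input tree and the cheaper one returned, so cost never increases; the
returned tree carries topology only, since supports are meaningless
after rearrangement.

The gene-tree simulator runs a birth–death-with-transfer process down
the species tree; transfer recipients are uniform over incomparable
branches. Truth counts events on the *surviving* history: duplications
with both copies surviving, transfers whose transferred copy survives,
and losses visible against a surviving sibling context. Events erased by
extinction are uncountable in principle from the surviving tree, which
is why recovery tests use low rates (0.03/0.02/0.01 per unit branch
length — mostly 0–2 events per family) where parsimony and truth agree
in ≥ 90% of replicates.

## Motif enrichment

Windows are 13-mers (±6) centered on S/T/Y, padded with `_` past protein
termini; padding never counts toward any frequency. The greedy recursion
scores every unfixed (position, residue) candidate with an exact
binomial upper tail — k foreground windows matching fixed + candidate,
n matching fixed, p the candidate residue's frequency at that position
among background windows matching the fixed residues (conditional
background, recomputed each step; a marginal mode is available). The
smallest tail wins (ties: smaller |position|, then position, then
residue) and is fixed if p < 10⁻⁶ and k ≥ 4; when nothing qualifies the
motif is emitted with its final step's statistics, matching foreground
and background windows are removed, and the search restarts. Candidates
whose background frequency is zero are skipped as unscorable — without
this guard a conditional pool that runs dry would hand every remaining
candidate a p-value of exactly 0. The conditional background needs
depth: backgrounds should be proteome-scale (thousands of windows;
recovery tests use 8,000) because each fixing step divides the pool by
roughly 20. No multiple-testing correction is applied beyond the hard
10⁻⁶ threshold, matching the original tool's convention.

## Curation

Functional classes are assigned by keyword lookup against a packaged,
user-editable TSV; when keywords match several classes the priority is
acting-on-polysaccharides > protease > oxidoreductase > lipid-metabolism
> interacting-domains > signaling > structural > miscellaneous (enzyme
evidence is more specific than domain presence — a package rule, since
the underlying curations resolved such conflicts manually). Unmatched
records are `unknown`, subclassified DUF (a DUF domain id present),
CW-known-unknown (other annotation present), or POF (no annotation).
Binding categories pass through extraction metadata when present;
otherwise a flagged pI heuristic applies (pI < 6 labile, ≥ 7 weakly
bound, else strongly bound), mirroring the acidic/basic phrasing of the
extraction series while keeping protocol metadata authoritative. The
20–156 kDa band is inclusive on both ends and only flags, never deletes.
Deduplication collapses exact sequence duplicates within an organism to
the lexicographically smallest id and is idempotent; near-duplicates are
left to orthogrouping.

## Orthogroups

All-vs-all similarity is the Jaccard index of k-mer sets (k = 5,
threshold 0.3 by default, both exposed) — a deliberate, documented
stand-in for alignment-based all-vs-all search that keeps the clustering
and sharing logic dependency-free; precomputed similarity tables from an
external aligner can be loaded instead. Clusters are single-linkage
connected components at the threshold, with canonical ordering so output
is independent of input order, and raising the threshold only refines
clusters. Sharing tables attribute each cluster to the exact set of
taxonomic families present in it; single-family rows are the in-paralog
clusters. Counts published for specific proteome collections depend on
full downloads and other tools' internals and are not reproduction
targets here.

## Pipeline

One `RunConfig` carries all stage parameters with the analysis defaults
(ω > 10, dS < 0.01, dS/dN > 3, 30% gaps, Z > 2 with ≥ 3 members, costs
1.5/1/0 + loss 1, support 98, motif 4 / 10⁻⁶, MW 20–156 kDa) and a
single seed; outputs are TSVs whose header comment records tool version,
config hash, and seed, and identical configs reproduce byte-identical
runs. Demo problem sizes (300-codon pairs, 200 × 20 count matrices,
4-species reconciliations, 60 + 2,000-window motif runs) are chosen so
the full suite and the acceptance script each complete in seconds to a
few minutes on one CPU while keeping every recovery test well-powered.

## What passing tests do and do not show

The synthetic generators reproduce the statistical structure the
estimators assume — independent sites, gap-free codon alignments,
Poisson count matrices, i.i.d. peptide flanks, low-rate event histories.
They do not emulate alignment error, indels, rate heterogeneity across
sites, codon-usage bias, phylogenetic correlation between families, or
compositional bias around phosphosites. Green tests therefore establish
correctness of the computations and recoverability under the stated
models, not robustness to the messiness of real matrisome data.
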