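# Methods

## The problem and the procedure

Metagenomic gene prediction yields large numbers of coding sequences (CDSs)
with no detectable homolog in reference databases — ORFans. The package
implements a five-stage analysis that (i) separates plausible ORFan protein
families from spurious predictions using explicit filtering rules, (ii)
annotates them by profile–profile remote homology to structures with an
empirically calibrated error rate, (iii) validates the annotations through
gene-neighborhood functional consistency, (iv) profiles ORFan functions
against a homology-annotatable reference, and (v) screens for candidate
metalloproteases. All thresholds live in `PipelineConfig`; the defaults
below are the analysis' operating point.

| parameter | default | meaning |
|---|---|---|
| `evalue_cutoff` | 1e-3 | domain/nr screening significance (strict `<`; a best hit at exactly the cutoff *exceeds* it and the cluster stays an ORFan) |
| `cluster_identity` | 60% | greedy clustering threshold, identity over the shorter sequence |
| `min_rep_length` | 100 aa | spurious rule: representative shorter than this |
| `spurious_identity` | 99% | spurious rule: all members at or above this identity to the representative |
| `repetitive_fraction` | 0.40 | CDSs with a larger masked fraction are discarded (strict `>`) |
| `probability_threshold` / `evalue_threshold` | 80 / 1 | remote-hit acceptance, both inclusive |
| `neighbor_window` | 1000 nt | boundary-to-boundary gap for a qualifying neighbor, inclusive |
| `n_permutations` | 1000 | neighborhood permutation null size |
| `reference_subset_size` | 10000 | Pfam-annotated CDSs sampled per metagenome |
| `go_level` | 6 | GO level (longest is_a path, roots = 1) used for profiling |
| `decoys_per_metagenome` | 1000 | column-shuffled decoy clusters per metagenome |

## ORFan calling

**Low-complexity masking.** The repetitive-sequence filter is a sliding
Shannon-entropy masker: windows of 12 residues (stride 1) are masked when
their entropy falls below 2.2 bits, overlapping masked windows merge, and
the masked fraction is the share of residues covered; sequences shorter than
one window are scored as a single window. The 2.2-bit/12-residue operating
point cleanly separates 1–3-letter repeats (≤ 1.6 bits) from typical
protein windows (≈ 3.3 bits). Only the >40% discard rule is contractual;
the masker is this package's own, chosen for determinism and testability
rather than as a reimplementation of any particular masking tool.

**Identity and clustering.** Percent identity follows the CD-HIT
convention: identical aligned positions in an optimal global alignment
(match +1, mismatch 0, linear gap −1), divided by the length of the shorter
sequence. Because several alignments can share the optimal score, the DP
maximizes the pair (score, #identities) lexicographically, making the
identity a well-defined function of the two sequences; traceback ties break
diagonal > up > left. Clustering is deterministic greedy first-fit: longest
sequence first (ties by id), each sequence joins the first cluster whose
representative it matches at ≥ 60%, else founds a new cluster. No k-mer
prefilter is used — the quadratic scan is fine at the scales this package
targets, and determinism is worth more than speed here.

**Spurious clusters** are marked in a fixed rule order — singleton, then
short representative (< 100 aa), then low variation (every other member
≥ 99% identical to the representative) — so `spurious_reason` is
deterministic; the removal outcome is order-independent. Repetitive-filter
removals are reported as a sub-count (`removed_repetitive`) inside the
spurious row of the funnel table, and the funnel counts satisfy exact
conservation: predicted = domain-removed + spurious-removed + nr-removed +
candidate ORFans, per metagenome.

## Remote homology and the decoy FDR

Cluster alignments are center-star: every member is globally aligned to the
representative and the gap patterns are merged. This is deterministic and
accurate for the shallow, ≥60%-identity clusters the funnel produces; it is
not a general-purpose MSA engine. Profiles are per-column frequencies with a
background pseudocount, p_i(a) = (c_i(a) + w·f(a)) / (n_i + w) with w = 1
and uniform f = 1/20 by default (overridable); ambiguous residues (B, Z, X,
U, O) are kept in rows but contribute the background distribution, and
all-gap columns are dropped.

The scorer is a local (Smith–Waterman) alignment over profile columns with
the log-average-odds column score σ(i,j) = log₂ Σₐ pᵢ(a)qⱼ(a)/f(a) in bits
and affine gaps: a gap of length k costs 2.5 + (k−1)·0.5 bits. It is a
column-wise profile aligner, not an HMM–HMM comparison — there are no
transition probabilities or secondary-structure terms; when higher fidelity
is needed, externally computed HHsearch `.hhr` files can be imported and
flow through identical thresholds.

Significance is calibrated on decoys made by permuting alignment *columns*
(column order, not within-column residues — this preserves per-column
conservation and composition, which is what makes the decoys a fair null
for profile search). Each query's best decoy score enters two estimators:

* **E-value**: a Gumbel tail fitted to the decoy best scores by method of
  moments (λ = π/(σ√6), μ = mean − γ/λ), with E(S) = N·exp(−λ(S−μ)) for a
  library of N templates.
* **Probability**: 100·(1 − localFDR(S)), where localFDR is the decoy/real
  density ratio on a shared score grid, clipped to [0,1] and monotonized
  non-increasing in S by pool-adjacent-violators weighted by bin counts.
  The grid uses combined-score *quantiles* (24 bins) rather than equal
  widths: real and decoy best scores typically separate by a wide score
  gulf, and equal-width grids leave empty bins whose smoothed ratio is an
  artifact; quantile bins are populated wherever data exist. The smoothing
  pseudocount is 0.1 per bin — heavy smoothing visibly caps the ratio when
  the real sample is small.

A hit is significant iff probability ≥ 80 **and** E ≤ 1 (both read as
inclusive; the thresholds' openness is not otherwise determined). The
empirical FDR is the ratio of per-query pass rates, decoy over real.
Calibration refuses to run with fewer than 50 decoy scores; when a small
study has fewer ORFan clusters than `decoys_per_metagenome`, additional
independent shuffles of the same clusters are drawn until at least
`min_total_decoys` (60) exist.

## Gene-neighborhood consistency

For each annotated ORFan CDS, the qualifying neighbors are the nearest CDS
upstream and downstream on the same contig, kept only if on the same strand
and within 1000 nt measured between nearest boundaries (inclusive) — the
boundary gap is the only monotone reading of "directly neighboring within
1 kb". S is the size of the intersection between the ORFan's assigned terms
(top-3-union of significant remote hits, propagated to member CDSs) and the
union of its neighbors' terms; S_m sums S over the metagenome. The null
permutes the ORFan term sets uniformly at random over the fixed original
ORFan positions (fixed points allowed — a derangement would bias the null),
recomputing S_m identically; neighbors that are themselves ORFans follow the
permutation. The p-value is add-one: (1 + #{null ≥ S_m})/(1 + n). ORFans may
neighbor other ORFans and those neighbors' terms count; the alternative
total that excludes ORFan neighbors is also reported
(`S_m_excluding_orfan_neighbors`).

GO levels use is_a edges only, roots at level 1, and the *longest* path from
any root. Assigned terms are never propagated to ancestors or descendants:
the statistics count shared assigned terms, and propagation would inflate
them.

## Functional profiling

Term frequencies are proportions of entities carrying a term, with zero
counts replaced by a unit pseudocount before proportioning. ORFan-side
counting uses clusters annotated by the most-confident mode (the
highest-ranked significant hit that has mapped terms), restricted to level-6
BP/MF terms; the reference side counts CDSs. Enrichment p-values are exact
one-sided binomial tails P(X ≥ c | n, p₀) against the reference proportion
and, separately, against the template-library term frequencies, each
Benjamini–Hochberg adjusted within its comparison. The enrichment
denominator is annotated clusters by default (`enrichment_denominator =
"all"` switches to all ORFan clusters). In the top-3-union assignment mode,
unmapped significant hits still consume one of the three slots — "top three"
is read as a rank cutoff, not a mapped-hit cutoff.

The reference subset is a seeded uniform sample (without replacement) of
Pfam-annotated CDSs; at desk scale the pipeline annotates it from the
Pfam→GO map directly rather than routing tens of thousands of reference
CDSs through profile search — the comparison's structure (same level
restriction, same counting and testing) is unchanged, and the remote-path
route remains available by composing the library functions.

Environment specificity tests each key (top-hit template; separately each
GO term) per metagenome against a background probability pooled from the
other metagenomes (unit pseudocount when the pooled count is zero), with
Bonferroni correction spanning every p-value computed (keys × metagenomes).
Profile clustering uses 1 − Pearson correlation on the union term space and
average linkage; the dendrogram is emitted as newick.

## The metalloprotease screen

A cluster is a candidate iff its rank-1 *significant* remote hit has
"protease" or "peptidase" as a case-insensitive substring anywhere in the
template description (description categories are collapsed into one
searchable text) and its representative contains at least one HExxH match
(overlaps allowed, case-insensitive).

## The synthetic-data generator

`make_metagenomes` emulates the statistical structure the analysis assumes,
not real sequence biology. Families are ancestors mutated per site with
uniform substitution to one of the 19 other residues (no indels by default,
so within-family identity is analytically predictable: two members at
divergence d agree at ≈ (1−d)² + d²/19 of sites; an `indel_rate` option
exists because alignment code must tolerate gaps). Default study conditions:
three metagenome labels, 25 families each of 3–6 members at divergence 0.15,
40% ORFan families, 60% of those planted with a remote structural homolog
(a template family derived from the same ancestor at divergence 0.35), junk
ORFs as 1–3-letter repeats at 10% of family CDSs, contigs of 6 same-strand
CDSs with 100 nt gaps, and a two-namespace layered ontology of depth 8 with
cross-level shortcuts so shortest- and longest-path depths disagree for a
sizeable share of terms. Templates cycle deterministically through
protease-description × HExxH-motif combinations so the metalloprotease
screen always has true positives and both kinds of negative; the template
plan includes per-metagenome-specific templates (several clusters each) and
cross-metagenome shared templates so the specificity test has planted
positives and negatives. Neighborhood correlation is planted by giving each
planted ORFan family one dedicated buddy domain family carrying exactly one
shared truth term and placing buddy members adjacent to ORFan members with
probability `neighbor_go_correlation` (the buddy grows members on demand,
so a correlation of 1 guarantees every planted ORFan a sharing neighbor).

What the generator does *not* emulate: realistic amino-acid or codon usage
(nucleotides are uniform-synonymous back-translations), indel-rich
evolution, fragmented gene calls, assembly artifacts, database noise, or
biased GO annotation depth. Passing tests therefore demonstrate that the
statistics and recovery logic behave as designed under their own
assumptions — not that the pipeline's sensitivity matches what real
metagenomes would give.

## Problem sizes used by the tests and acceptance script

The suite runs the full pipeline on the default synthetic study (~370 CDSs,
75 families, 3 metagenomes), which completes in seconds; the permutation
calibration checks use 200 single-metagenome studies (null uniformity, 500
permutations each) and 20 studies with ≥100 annotated ORFans (power at
α = 0.001, 1000 permutations); FDR recovery uses 500 real + 500 decoy
clusters against 10 templates over 10 seeds. These sizes were chosen so the
whole suite runs on a laptop-class single core in about a minute while
keeping every statistical check adequately powered.

## Known limitations

* The built-in scorer underestimates what HMM–HMM comparison with secondary
  structure can detect; treat its probabilities as calibrated against its
  own decoys, not as HHsearch probabilities.
* The Gumbel fit is anchored to decoy *best* scores, so E-values are
  per-search (best-hit) estimates rather than per-comparison ones.
* Greedy first-fit clustering is order-deterministic but, like CD-HIT, not
  an optimal partition; families straddling the 60% threshold can split.
* The permutation null conditions on the observed ORFan positions and
  annotation sets; it does not model annotation error.
* With very few ORFan clusters the probability calibration is coarse
  (quantile bins need data); the pipeline tops up decoys by re-shuffling,
  but a study with only a handful of clusters will have step-like
  probabilities.
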