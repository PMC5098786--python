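# Methods

## Model

`koinfer` treats functional inference from 16S amplicon data as a
nearest-neighbor assignment problem. The community's gene content is
approximated by assuming each OTU's genome content equals that of the
sequenced genome whose 16S rRNA gene its representative sequence matches
best. No phylogenetic tree, ancestral-state reconstruction, or
taxonomy assignment is involved; the accuracy of the estimate therefore
depends directly on how densely the reference covers the community
(clinically associated taxa are well covered by sequenced genomes;
environmental communities typically are not).

For a sample with OTU abundances `A_t`, each passing OTU assigned to `m`
tied nearest-neighbor genomes, the inferred abundance of ortholog `K` is

    A_K = Σ_t A_t · [ Σ_{g=1..m} Kcopy_g / Rcopy_g ] / m

Assumptions built into this formula:

* **16S copy-number correction.** Amplicon counts measure 16S gene
  copies, not cells; dividing by `Rcopy_g` (the genome's count of
  qualifying 16S genes) converts to genome abundance. Genomes whose 16S
  genes all fail the length filter are excluded from the reference
  entirely rather than kept with `Rcopy = 0`, which would make the
  normalization undefined.
* **Equal tie splitting.** When several genomes tie at the best
  identity, the OTU's count is split equally (`1/m` each) rather than
  discarded; discarding multi-matching sequences would bias the estimate
  in the broad search space of a genome database.
* **Dropped OTUs contribute nothing.** OTUs whose best identity falls
  below the cutoff are excluded from all downstream tables; their count
  and abundance share are reported in the run log and via
  `passed_fraction`, because the dropped share is itself an informative
  statistic (it grows sharply with cutoff in poorly covered biomes).

The genome-abundance intermediate (`assign_otus`) is exposed for
inspection, but `infer_ko_abundance` computes `A_K` per sample directly
from the OTU table — mathematically identical, with a single rounding
path.

## Alignment and identity

Queries (~250 nt amplicons) must align inside full-length (~1.5 kb) 16S
genes, so the aligner is semi-global: the query aligns end-to-end while
terminal gaps on the reference are free. Alignment uses scikit-bio's
`pair_align` dynamic program with match +1, mismatch −1 and affine gap
penalties (open 2, extend 1; a gap of length k costs 2 + k). Percent
identity is **matching columns / all alignment columns spanning the
aligned query**: internal gaps count in the denominator, free terminal
reference gaps do not. Ambiguous IUPAC codes are compared literally
(they count as mismatches unless identical). When several alignments
share the optimal score the first reported optimal path defines the
identity; for the substitution-only constructions used in testing the
optimum is unique.

Numerical choices: genomes are tied when their best identity is within
1e-9 (absolute) of the maximum; the cutoff comparison uses the same
tolerance, so an identity mathematically equal to the cutoff always
passes. A genome contributing several tied 16S copies counts once
(identical copies are deduplicated before alignment, which changes no
result). Queries are searched as given; `search_rc` additionally scores
the reverse complement and keeps the better orientation, off by default
since amplicon pipelines normally orient reads.

The exhaustive all-pairs search is the implementation; the cutoff sweep
reuses one pass of alignments across all cutoffs, which is exactly
equivalent because the per-OTU best identity does not depend on the
cutoff (asserted against re-searching in the tests).

## Parameters

| parameter | default | meaning |
|---|---|---|
| identity cutoff | 0.97 | minimum identity for an OTU to be used; 0.96–1.0 behave similarly on clinical data, lower cutoffs trade sensitivity for specificity |
| 16S length window | 1400–1600 bp, inclusive | qualifying full-length 16S genes; the window is read inclusively, the conventional reading of a min/max filter |
| tie tolerance | 1e-9 | absolute tolerance on the identity fraction for ties and the cutoff test |
| sweep cutoffs | 0.75, 0.80, 0.85, 0.90, 0.95, 0.96, 0.97, 0.98, 0.99, 1.0 | preset grid for `sweep` |

Flooring (`floor_counts`) is an explicit, separate step that maps each
fractional `A_K` down to an integer for count-based statistics
(negative-binomial models); the fractional table is never silently
rounded. Output orthologs are restricted to those detected
(`A_K > 0` somewhere) by default; `full_universe` emits all reference
orthologs with zeros.

## Evaluation statistics

`spearman_per_sample` ranks ortholog abundances per shared sample. The
feature space is the union of the two tables' orthologs with missing
entries as 0 (default), because orthologs detected by only one side are
disagreement signal; an intersection mode is provided since the choice
is genuinely open. Ties get average ranks; fewer than 3 joint features
yields NaN with a warning.

`confusion_metrics` consumes two external significance-call sets (any
test, any threshold — the package deliberately does not re-implement
differential-abundance testing) over the full reference ortholog
universe: TP = called by both, FP = inferred only, FN = observed only,
TN = the remainder, so the four counts always partition the universe.
TPR = TP/(TP+FN), FPR = FP/(FP+TN), balanced accuracy =
TPR/2 + (1−FPR)/2; empty denominators yield rate 0.

## Synthetic data

The generator emulates the two things the pipeline needs from the world:
an annotated-genome reference and an amplicon survey.

* Reference: i.i.d. random 16S sequences (length within ±min(50, L/10)
  of `rrna_len`, default 1500), 16S copy numbers uniform on {1..7} with
  identical copies, ortholog copy numbers uniform on {0..5} over the
  requested KO set (zeros stored implicitly). Cross-genome identities
  are verified below 0.90 at build time so nearest-neighbor assignment
  is unambiguous at high cutoffs; an unseparable request raises an error
  suggesting a longer `rrna_len`.
* Community: each OTU representative is a window (default 250 nt,
  emulating a V4 amplicon) of one genome's 16S, mutated by substitutions
  at exactly `round(divergence · L)` positions, each to a different
  base — so its identity to the source is exactly `(L−k)/L` and cutoff
  behavior is provable arithmetic, not a statistical tendency. Abundances
  are log-uniform on [1, 10^4], rounded to integers. Ground truth is
  computed by an independent triple-loop implementation of the formula
  (`naive_ko_abundance`) from the true source genomes.

What the generator does **not** emulate: indels and sequencing error
profiles, chimeras, phylogenetically correlated sequence evolution,
uneven reference coverage, compositional effects of library size. A
passing test suite therefore demonstrates that the algorithm computes
its defined quantities correctly and behaves monotonically in its
cutoff — not that inferences on real communities are accurate, which
depends on reference coverage of the biome.

## Determinism and exactness

All generator draws come from a seeded PRNG with a documented draw
order, so identical spec + seed give byte-identical artifacts. The
production inference accumulates contributions in a fixed order (OTUs in
table order, genomes in sorted order), performing the same scalar
operations as the naive reference implementation; divergence-0
communities at cutoff 1.0 are therefore recovered bit-exactly, and the
oracle-agreement check measures a relative error of exactly 0 rather
than merely < 1e-9.

Problem sizes used in the test suite and the reproduction script (6–20
genomes, 12–50 OTUs, up to 200 orthologs, 100 random communities for the
oracle check) were chosen to exercise every code path — multi-copy
genomes, ties up to m = 3, dropped OTUs, all ten sweep cutoffs — at
desk scale; the algorithm itself is O(|OTUs| · |reference 16S| · L²) in
alignment work and scales to real references without modification.

## Known limitations

* The identity definition approximates, but is not bit-compatible with,
  the identity of any particular external search tool; cutoffs calibrated
  elsewhere may shift slightly.
* Exhaustive alignment against every reference 16S is quadratic; for
  genome databases of >10^4 sequences a k-mer prefilter would be wanted
  (any such speedup must reproduce the exhaustive hit sets, which is what
  the oracle-equivalence tests enforce on small databases).
* Fractional counts floored to integers slightly deflate low-abundance
  orthologs; this mirrors the standard preparation for count-based
  differential tests and is kept explicit.
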