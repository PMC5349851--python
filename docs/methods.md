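# Methods

`csikit` implements cognate-site identification (CSI) for obligate-dimer
transcription factors — the bZIP family is the motivating case — from
SELEX-seq data: iterative in vitro selection of protein-bound sequences from
a randomized DNA library, read out by deep sequencing.  This note documents
the statistical model, the tunable parameters, the synthetic-data generator
and its limits, and the numerical choices made where the design was open.

## CSI intensities

A selection experiment yields reads from an unselected starting library
(round 0) and from an enriched round (round 3 by default).  For a chosen
k (8–14, default 10), every read of length L contributes L−k+1 sliding
windows.  Observed counts are compared against the count expected under an
order-m Markov model of the starting library (default m = 5, pseudocount 1
on all transition and initial counts), which absorbs synthesis and
sequencing composition bias:

    P(w) = P_init(w[1..m]) · ∏_{i=m+1..k} P(w_i | w_{i−m..i−1})
    expected(w) = n_windows · P(w)
    enrichment(w) = observed(w) / expected(w)
    csi(w) = (enrichment(w) − μ) / σ

μ and σ are the mean and **population** standard deviation of the
enrichment values over all 4^k k-mers — the table is the full population,
not a sample.  The initial distribution pools m-mer frequencies over all
read positions (a stationary model; nothing position-specific is claimed
about the library).  If the enrichment vector is constant (σ < 1e−12) all
CSI values are set to 0 and a warning is logged.

Double-stranded probes make binding orientation-free, so the default strand
mode is `collapsed`: a k-mer is pooled with its reverse complement in both
the observed and expected counts before the ratio is taken, which makes
csi(w) = csi(revcomp(w)) exact, not approximate.  A `forward` mode is kept
for exactness tests and for single-stranded designs.  Whether published
"normalized k-mer" tables collapse strands is generally not stated; both
modes are first-class here.  Z-scores are computed over all 4^k k-mers, not
only observed ones — unseen k-mers carry information (they are depleted).

## Profile comparison and heterodimer assignment

Profiles are compared on the union of each dimer's 50 top-ranked k-mers
(collapsed-mode reverse-complement pairs contribute one canonical
representative), with Pearson's r on the CSI values restricted to that set.
Hierarchical clustering uses Euclidean distance between correlation-matrix
rows with complete linkage — the distance/linkage is otherwise
unconstrained by the method, so it is fixed and documented here.

A heterodimer experiment pulls the complex down via one biotinylated
partner, so the recovered motif may belong to that partner's homodimer.
The decision rule: if the biotinylated partner binds no DNA as a homodimer,
the profile is credited to the heterodimer outright.  Otherwise the
heterodimer–homodimer correlation r is compared against replicate-experiment
correlations (typically r ≈ 0.8 ± 0.1 over eight replicate pairs) with a
two-sided one-sample t-test on Fisher-z transformed values (variance
stabilization), α = 0.05.  Significantly below the replicate mean →
heterodimer; significantly above → homodimer (the profile resembles the
homodimer even more than replicates resemble each other); otherwise →
ambiguous.  The exact test behind the published p < 0.05 rule is not
specified anywhere; the Fisher-z one-sample test is this package's choice.
The rule is monotone: lowering r never demotes a heterodimer verdict.

Motif architecture is a formalization of what is usually done by eye.
Given the heterodimer's top k-mer and the two monomer half-sites (3–5 bp),
all arrangements are enumerated — both orders, both orientations of each
half-site, overlaps 0..3 with exact agreement of the shared bases — and
matched against the k-mer and its reverse complement.  Zero-overlap match →
conjoined; smallest overlap in [1, 3] → variably spaced; no match →
emergent.  Classification is invariant to reverse-complementing the k-mer.

## Specificity-and-energy landscapes (SELs)

A SEL places every k-mer on concentric rings around a seed motif of length
m ≤ k; ring h holds k-mers whose best alignment to the seed — minimum
Hamming distance over all offsets and, by default, the reverse complement —
has exactly h mismatches.  Ties prefer the smaller offset, then the forward
orientation, so each k-mer is placed exactly once.  Ring sizes at m = k are
C(m,h)·3^h.  Ordering within rings is deterministic: ring 0 by descending
5′-flank length then lexicographic flanks; rings h ≥ 1 by the tuple of
mismatch positions (lexicographic), then substituted bases (A<C<G<T), then
offset, then flanks.  Only the 1-mismatch ordering is conventionally
specified; the extension to multi-mismatch rings (position tuples first) is
frozen here for reproducibility — two runs produce byte-identical layouts.
Radius equals the ring index and angles are uniform within a ring,
clockwise from 12 o'clock; any rotation is visually equivalent.

## Genomescapes, ROC and FPR cutoffs

A genomic interval's score under a profile is the maximum CSI of its
k-mer windows; windows containing non-ACGT letters (assembly gaps) are
excluded, and an interval with no valid window gets a missing score.
Coordinates are BED-style 0-based half-open everywhere internally; 1-based
conventions appear only at the SNP/VCF boundary.

Negatives for ROC analysis are the two equal-length regions ±5 kb from each
peak center that do not overlap any peak; candidates that run off the
chromosome are dropped rather than truncated, keeping "equal length"
literal.  TPR and FPR at threshold t are the fractions of positive and
negative scores ≥ t (so a peak tied with the best negative has FPR > 0);
the trapezoidal AUC over the union-of-scores sweep equals the Mann–Whitney
statistic with half-credit for ties.  A peak's FPR cutoff is the fraction
of negative scores at or above its score — the lowest FPR at which it would
be called positive — and the peaks × dimers cutoff matrix feeds the same
clustering used for profiles.  Quantile normalization (for cross-dimer
comparisons) replaces each profile's CSI vector by the rank-aligned mean of
the sorted vectors; collapsed profiles are re-symmetrized by averaging
reverse-complement pairs, since ties would otherwise break arbitrarily.
ROC analysis accepts raw or quantile-normalized intensities; both are
exposed because published practice varies by figure.

## SNP impact

Each single-base variant is scored on the 21-bp context centered on the SNP
(10 bp of flank per side): twelve 10-mer windows per allele, max CSI per
allele.  The predicted change is a noise-buffered fold-change

    FC = (z_alt − z_min + A) / (z_ref − z_min + A),  A = (z_max − z_min)·F

with z_min/z_max taken over all allele scores of the scanned SNP set.  The
noise factor F is a *fraction of the CSI dynamic range* (the percent
convention F = 25 means 0.25 here; the CLI takes percent).  The buffer
damps instability at low scores: FC → 1 as F grows, swapping alleles maps
FC → 1/FC exactly, and hit counts are non-increasing in F.  z_min/z_max are
per dimer by default; a global-across-dimers scope is available but off, as
the original wording ("among the scored SNPs") is ambiguous on this point.
FC ≥ threshold (default 2) is a predicted gain relative to the reference
genome, FC ≤ 1/threshold a loss.  A dimer with no dynamic range among the
scored alleles yields no hits.  Indels are rejected.

## Synthetic data: what is emulated, and what is not

The generator provides ground truth for every stage.  A dimer is reduced to
one cognate site — half-site concatenation for conjoined, overlapped
half-sites for variably-spaced, a palindrome half + revcomp(half) for
homodimers, or a literal site for emergent binders — plus a geometric
affinity model: affinity = peak_affinity · mismatch_decay^d, where d is the
best-match Hamming distance of the site to the read.  Defaults
peak_affinity = 500 and mismatch_decay = 0.2 give a ~500-fold occupancy
advantage to the perfect site and ~100-fold to single-mismatch sites,
consistent with the order-of-magnitude affinity ranges seen for
high-affinity versus mutated sites in gel-shift work.  The per-round
retention weight is max(1, affinity): occupancy cannot drop below the
nonspecific background, normalized to 1.  peak_affinity = 1 is therefore an
exact null.

Because the physical library (~1e12 molecules) is astronomically larger
than a sequencing sample, sequenced reads are essentially never siblings.
Literal finite-pool resampling would duplicate reads and overdisperse
k-mer counts, so each round r is instead an exact importance sample of the
selected distribution p_r ∝ p0 · w^r: fresh candidates are drawn from the
library model, resampled with weight w^r, and then specifically-bound
molecules keep their matched site window with all other bases refreshed
from the library marginal, while baseline-weight molecules become entirely
fresh draws (nonspecific carryover is exchangeable background).  Under the
null this reproduces the round-0 spectrum exactly; under selection the
planted classes enrich with the correct per-round factors and full flank
diversity.  A uniform capture efficiency multiplies every weight and
cancels under normalization, so `capture_fraction` is recorded in the
provenance JSON but does not alter sampled distributions.  Rounds are
independent samples of their marginal distributions, not a propagated
lineage.

Not modeled: PCR jackpots and duplicate reads, sequencing errors,
protein-concentration titration and cooperative or multi-site occupancy,
position-specific synthesis bias beyond the Markov model, and chromatin
context for the genomic simulations.  Passing tests therefore demonstrate
correctness of the estimators under a clean generative model, not
robustness to every artifact of real libraries.

Synthetic genomes plant full-length sites (random strand, jittered grid
spacing that keeps peaks and their ±5 kb flank negatives from colliding)
in background drawn from the library model, with truth peaks of ±100 bp
around each site.  SNP panels plant, on a dedicated chromosome:
site-with-one-core-mismatch loci whose alternate allele restores the site
(create), intact sites broken by the alternate allele (destroy), and plain
background variants at least a site length from anything planted (neutral).

## Reference study sizes and numerical choices

End-to-end validation uses 20 seeded runs per condition at 1e5 reads ×
3 selection rounds and k = 10 — large enough that planted conjoined,
variably-spaced and emergent sites are recovered as argmax-CSI 10-mers and
correctly classified in ≥95% of runs, that the emergent heterodimer's
peak-vs-flank AUC exceeds 0.9 and both parental homodimer AUCs, and that
≥95% of site-creating variants are flagged as ≥2-fold gains at F = 25%.
Site models reuse motifs from the bZIP literature (conjoined CRE-CAAT
TGACGCAA, variably-spaced TRE-CAAT TGAGCAA, emergent TGACGCAT with
CRE-palindrome parents).

Other fixed choices: reads containing N are discarded, not imputed;
ranking ties are broken lexicographically everywhere a deterministic order
is needed; unobserved Markov contexts at pseudocount 0 get a uniform
transition row; all randomness flows from integer seeds through numpy
`SeedSequence` spawning, with no dependence on hash ordering.

## Known limitations

- One site model per truth entry; dimers that genuinely enrich two motifs
  are represented as a list of truths with max-affinity combination.
- The t-test assignment rule assumes replicate correlations are roughly
  exchangeable across dimers; with fewer than two replicate values the
  verdict is ambiguous by construction.
- `quantile_normalize` leaves counts/expected untouched (only CSI values
  are aligned), so normalized profiles should not be re-standardized.
- Architecture classification requires half-sites of 3–5 bp and reports
  the smallest consistent overlap; degenerate half-sites that occur inside
  each other can shadow larger overlaps.
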