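# Methods

## Model and assumptions

svmix treats structural-variant calling as a two-stage inference. Stage one
is geometric: read pairs are classified from their orientation and mapped
separation d against an insert-size model N(μ, σ²), and same-class
discordant pairs are grouped into candidate clusters. Stage two is
statistical: each candidate cluster is summarized by a two-dimensional
feature vector and the candidate set is modeled as a finite mixture of G
bivariate normal components with weights τ_k, means μ_k, and unrestricted
covariance matrices Σ_k,

    p(x_i) = Σ_k τ_k φ(x_i; μ_k, Σ_k),

fitted by expectation–maximization. The E-step computes responsibilities
z_ik = τ_k φ_k(x_i) / Σ_j τ_j φ_j(x_i); the M-step re-estimates weighted
moments. G is fixed by the biology, not selected from data: deletions form
three interpretable classes (homozygous event, heterozygous event, normal
region), inversions two (event, normal region) because orientation evidence
is too noisy to resolve inversion zygosity. A candidate's label is its
argmax component, mapped to a class by the component means (deletions:
lowest mean concordant depth → homozygous; of the rest, higher depth →
normal; inversions: higher mean pair support → event); its uncertainty is
1 − max_k z_ik, which is largest near class boundaries and near the origin
of feature space where no class has distinctive evidence.

Features enter the mixture untransformed. The normality assumption is a
modeling convenience — count-valued features are only approximately
Gaussian — and is kept deliberately; no variance-stabilizing transformation
is applied.

### Deletion features

For a candidate cluster the inner region is the intersection of the
members' inner intervals [left_end, right_start): every supporting pair
must bracket the deleted segment, so the intersection is the tightest
interval implied by all of them and is used as the reported call interval.
The features are (number of discordant pairs, mean concordant-pair read
depth over the inner region). Expected geometry at coverage c: homozygous
deletions near (c·w/(2·r), ~0), heterozygous near (c·w/(4·r), c/2), normal
regions near (small, c), where r is the read length and w the expected
inner gap of a spanning fragment.

### Inversion features

f1 = max(N(FF), N(RR)). A sum or minimum would under-score the real events
that are supported by only one orientation (documented in validated data);
the maximum is robust to one-sided support. f2 is the peak per-base depth
of quality-passing singleton reads over four windows anchored on each
member pair — [L−α, L), [L, L+α), [R−α, R), [R, R+1.5α) for left/right
mate start positions L and R, with α = 300 bp (slightly above the insert
length). Mates of reads that straddled a breakpoint fail to map, so their
anchored partners pile up in exactly these windows. One-sided windows (W1,
W3) count only the strand whose mates point into the breakpoint: + for FF
pairs, − for RR pairs (mirrored geometry); W2 and W4 count both strands,
and W4 is extended to 1.5α because the right breakpoint may fall beyond
the FF pair's span. A read cannot cover a 300 bp window entirely, so
"singletons covering the window" is operationalized per base and maximized
over bases, windows, and member pairs — a statistic insensitive to window
de-duplication.

## Candidate generation

Deletion pairs (FR, d > μ + xσ, mapping quality ≥ 30, d ≤ 100 kb) are
split into components connected by inner-interval overlap; within a
component, the pair with the most conflicts — overlapping some members but
not all, or differing in mapped distance by more than the span tolerance —
is removed iteratively until a clique remains, and removed pairs are
reprocessed the same way. This is order-independent and deterministic,
assigns each pair to at most one cluster, and directly implements
"remove pairs that overlap one pair but not others". Compatibility of two
pairs requires three things: their inner intervals intersect; |d_i − d_j| ≤
span tolerance (default 2xσ — two pairs from one event differ only by
insert noise, bounded at the same confidence used to declare discordance);
and their joint inner region is wide enough to contain the deletion the
larger stretch implies, d − width ≤ μ + xσ. The last condition exists
because a borderline-stretched pair lying just outside a real event can
otherwise join the event's cluster and pin the intersection to a sliver
that could not have produced the observed separations. Clusters with fewer
than 3 members are dropped.

Inversion clustering groups FF/RR pairs (quality ≥ 30, d ≤ 500 kb) by
mutual outer-span overlap — members need not share an inner gap — and then
applies geometry filters: within each orientation group ordered by
left-mate start, mapped distances must be non-increasing up to a slack
(default 2xσ; the idealized geometry predicts strictly non-increasing
distances, but with insert noise of sd σ√2 between pairs a strict test
rejects essentially every true cluster); the left-mate spread of a group
must not exceed the first pair's mapped distance (a variant bound, the
mean insert size, is available behind the `spread_limit` option); and when
both orientations are present, all FF left (and right) mates must precede
their RR counterparts.

Calls that reciprocally overlap a better-supported call of the same type by
≥ 50% are suppressed before output: insert-size noise occasionally splits
one event's pairs into two clique clusters, and a caller should not report
the same event twice.

## Numerical choices

* **Insert model.** μ, σ from FR separations after a 1st–99th percentile
  trim, iterated once; the trim shrinks a normal sample's sd by a known
  truncated-normal factor (0.935 per stage, 0.891 after both), which is
  divided back out for each stage that actually removed points. Without the
  correction σ is underestimated by ~11% and every xσ-derived threshold
  tightens accordingly.
* **EM initialization.** Deterministic quantile seeding: points sorted by
  the second (depth-like) feature are split into G equal groups whose
  moments initialize the components. Different initializations give nearly
  identical fits on this problem; a deterministic scheme makes runs
  reproducible. Seeded random restarts are available (`em_restarts`).
* **Covariance regularization.** Component covariances are constrained to
  eigenvalues ≥ ε = 10⁻⁶ × mean feature variance by eigenvalue clamping.
  Clamping is the exact M-step maximizer over that constraint set, so the
  observed log-likelihood is provably non-decreasing across iterations
  (asserted in tests to 10⁻⁹ relative); an additive diagonal ridge, the
  more common alternative, perturbs the M-step optimum and measurably broke
  monotonicity when a component's depth variance collapsed toward zero.
* **Convergence.** Relative log-likelihood improvement < 10⁻⁶ (the
  criterion is scale-free; an absolute threshold would depend on n).
* **Degenerate cases.** Responsibilities are computed in log space with a
  uniform fallback if all components underflow; a component whose weight
  collapses is re-seeded from the most uncertain point; identical component
  means are labeled in index order with a logged warning. BIC is provided
  as a reporting utility only — the unrestricted-covariance model is always
  used.
* **Coordinates.** 0-based half-open everywhere, matching BED/BAM. Pair
  quality defaults to the minimum of the two mates' MAPQ (the
  minimum-of-single-end convention); the leftmost record's own MAPQ is
  available via `quality_mode="record"`. Duplicate-flagged records are
  skipped; reads with unmapped (or split) mates are singletons.

## The simulator

`svmix.simulate` emulates the *mapping consequences* of sequencing a
diploid donor genome, without synthesizing sequence or running an aligner.
Default conditions: one 20 Mb chromosome; 190 non-overlapping deletions
(94 homozygous, 96 heterozygous; sizes log-uniform 100 bp–75 kb) and 202
inversions (log-uniform 500 bp–50 kb); 36 bp read pairs with inserts
N(200, 20) at ~31× total depth; 0.1% point-mutation and 0.5%
sequencing-error rates. Event intervals are separated by ≥ 500 bp so
neighbouring breakpoint signals cannot blend within one insert length.
Inversions shorter than ~2 insert lengths are not simulated because
read-pair orientation cannot localize them and their outer-span call
interval fails 50% reciprocal overlap by geometry alone.

Per haplotype, fragments are sampled uniformly from the donor coordinate
system (deletions excised, inversions reversed) and mapped back
analytically: fragments spanning an excised junction reappear as FR pairs
stretched by the deletion length; fragments crossing an inversion boundary
become FF (left) or RR (right) pairs whose distances shrink as coordinates
advance; reads straddling a breakpoint by more than 5 bp fail to map and
surrender their mates as strand-annotated singletons. Mutation and error
rates act through their mapping consequences: a read with ≥ 2 altered
bases (Poisson approximation) maps with quality below the 30 threshold, a
read with ≥ 3 fails to map entirely (producing background singletons).

Real aligners also produce *coherent* discordant clusters over perfectly
normal sequence — around segmental duplications and inverted repeats —
and these artifact candidates are what the mixture's normal-region
component describes. The generator emulates them as "decoy" clusters
(70 deletion-like, 80 inversion-like per genome, Poisson(5) supporting
pairs each, matching the roughly 25–45% normal-class share of candidates
seen in real data): geometrically valid discordant pairs over unaffected
regions, with no breakpoint singleton pile-ups and no effect on concordant
depth. Without them an emulated candidate set contains only true events,
and a fixed-G mixture would be forced to carve the true-event cloud in two.

What the emulation does *not* reproduce: base-level sequence and quality
strings, GC- and mappability-driven depth waves, chimeric/split-read
alignments, and the heavy-tailed mapping-quality landscape of a real
repeat-rich genome. Consequently, passing the simulated benchmarks shows
that the clustering, features, and mixture classification recover planted
signals under calibrated noise — not that real-genome artifact modes are
handled; on real data precision is expected to be lower than the
essentially perfect values reached under emulation.

## Benchmarking

Two call sets are compared by 50% reciprocal overlap
(min(|a∩b|/|a|, |a∩b|/|b|) ≥ 0.5), with greedy one-to-one matching in
decreasing-overlap order — equal to optimal matching whenever overlaps are
distinct. Precision, recall, and the F-score (harmonic mean) come from the
matched counts; genotype concordance is tallied over matched deletion
pairs only. The acceptance script runs the deletion study on a genome
carrying only the 190 deletions and the inversion study on the full
190 + 202 genome, at the default conditions above.

## Known limitations

* Insertions, tandem duplications, and translocations are classified at
  the pair level but never clustered or called.
* One insert-size model per input file; multi-library inputs should be
  split by read group upstream.
* No split-read breakpoint refinement; call intervals are cluster-derived
  (inner intersection for deletions, outer span for inversions).
* No CRAM input; no multi-sample joint calling; no G+C or mappability
  correction of depth.
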