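# svmix

Model-based structural-variant calling and genotyping from paired-end
sequencing alignments.

## The problem

When a sequenced genome carries a structural variant, the read pairs that
straddle it betray the event after mapping to the reference: a deletion
stretches the apparent separation of a pair beyond the library insert size,
while an inversion flips one read's strand so both mates map to the same
strand (FF near the left breakpoint, RR near the right). Calling variants
from discordant-pair clusters alone, however, confounds real events with
mapping artifacts, and says nothing about whether an event sits on one or
both haplotypes. svmix is for researchers who have coordinate-sorted
paired-end alignments (SAM/BAM) and want deletion and inversion calls with
per-call confidence and, for deletions, a homozygous/heterozygous genotype.

## The method

1. **Insert-size model.** The separation d of concordant FR pairs is modeled
   as N(μ, σ²); μ and σ are estimated from the data (percentile-trimmed,
   with the trim-induced shrinkage of σ corrected analytically). A pair is
   discordant for deletions when d > μ + xσ (x = 4 by default).
2. **Candidate generation.** Deletion-supporting pairs with mapping quality
   ≥ 30 and d ≤ 100 kb are grouped into cliques: every pair in a cluster
   must overlap every other and have a similar mapped distance; clusters
   with at least 3 pairs become candidates. FF/RR pairs (d ≤ 500 kb) are
   clustered by mutual span overlap and must pass inversion-geometry
   filters (mapped distances non-increasing along the cluster; FF pairs
   left of RR pairs).
3. **Features.** Each deletion candidate i becomes x_i = (number of
   discordant pairs, mean concordant read depth over the cluster's inner
   region); each inversion candidate becomes x_i = (max(N(FF), N(RR)), peak
   singleton depth over four α = 300 bp windows anchored at the expected
   breakpoints).
4. **Classification.** Candidates are modeled as draws from a mixture of G
   bivariate normals with weights τ_k, means μ_k and unrestricted
   covariances Σ_k, fitted by EM (convergence 10⁻⁶). G = 3 for deletions
   (homozygous: depth ≈ 0; heterozygous: depth ≈ half coverage; normal
   region) and G = 2 for inversions (event / normal region). Each candidate
   receives membership probabilities z_ik and an uncertainty score
   1 − max_k z_ik; the argmax component is its label, and non-normal labels
   are reported as calls.

A truth-annotated simulator (diploid genome, emulated mapping with
breakpoint singletons and repeat-artifact decoy clusters) and a 50%
reciprocal-overlap benchmark module round out the package.

## Worked example

```bash
python examples/call_deletions_from_simulation.py
```

```
simulated 1,568,176 read-pair records, 40 planted deletions
estimated insert model: mu=200.0 sigma=20.3 (discordance above d > 281)
54 candidate clusters -> 40 deletion calls
precision=1.000 recall=1.000 F=1.000 genotype concordance=1.000

first three calls (chrom:start-end genotype n_discordant depth uncertainty):
  sim1:31746-31867 HET n=26 depth=13.51 u=0.000
  sim1:52897-53252 HET n=30 depth=13.15 u=0.000
  sim1:147793-200362 HET n=26 depth=14.79 u=0.000
```

The script plants 40 deletions in a 4 Mb diploid genome, emulates 31×
paired-end alignment, and runs the deletion pipeline. Every call that
reciprocally overlaps a planted event by ≥ 50% counts as a true positive;
here all 40 events are recovered with correct genotypes. Each call row
shows its supporting discordant-pair count, the mean concordant depth in
the called interval (≈ half coverage for the heterozygous calls shown), and
the mixture uncertainty. The other examples cover inversion calling and
direct use of the mixture model; `examples/cli_workflow.sh` runs the same
workflow through the `svmix` command-line interface on SAM/TSV files.

## Command-line interface

```
svmix simulate        --out-pairs sim.sam --out-truth truth.bed --seed 1 ...
svmix call-deletions  ALIGNMENT.bam --out calls.tsv [--min-mapq 30 --x-sd 4 ...]
svmix call-inversions ALIGNMENT.bam --out calls.tsv [--alpha 300 ...]
svmix evaluate        --calls calls.tsv --truth truth.bed --threshold 0.5
```

Calls are written as a BED-like TSV (0-based half-open coordinates) with
genotype, feature values, per-component membership probabilities, and the
uncertainty score.
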