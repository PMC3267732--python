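# codonbin

Codon-usage-based species binning for metagenomic fosmid libraries.

When a mixed microbial community is cloned into a fosmid library, each ~40 kb
insert comes from exactly one genome, but nothing on the clone says which one.
`codonbin` sorts such libraries into species bins using nothing but the
composition of their protein-coding sequence, the approach used to reconstruct
composite genomes of uncultivated organisms from environmental libraries. It is
aimed at microbiologists and bioinformaticians doing composition-based binning
of clone libraries or contig sets, and at anyone who wants a tested, scriptable
implementation of the underlying statistics.

## The method

**Codon-usage vectors.** Every clone is summarised by the frequencies of the 61
sense codons (standard bacterial code; stops TAA/TAG/TGA excluded) over the
*internal* codons of its annotated CDSs — the positional start codon and the
terminal stop are removed. With N internal codons the sampling error of the
frequency estimate is E‖p̂ − p‖ ≈ √(Σᵢ pᵢ(1−pᵢ)/N) ≈ 0.011 at N = 8,000, small
compared with typical inter-genome distances.

**Species grouping.** Pairwise Euclidean distances between clone vectors are
clustered by UPGMA (unweighted average linkage), and the tree is cut at a
cophenetic height of **0.04**: simulation with 8,000-codon artificial fosmids
shows same-genome distances concentrate near 0.016 and essentially never reach
0.04, while different genomes usually lie beyond it
(`codonbin.calibrate_threshold` reproduces this calibration for any input).

**Short-fragment classification.** A ~600 bp clone-end read (~200 codons) is
far too noisy for distance binning, so its codon counts n₁…n₆₁ are scored under
a multinomial model for each species group k:

P(read | Sₖ) = N!/(∏ᵢ nᵢ!) · ∏ᵢ p̂ᵢₖ^{nᵢ},  p̂ᵢₖ = (cᵢₖ + α)/(Cₖ + 61α),

with pseudocount α = 0.5, and the read (or a pooled mate pair) is attributed to
the most probable group.

**Extras.** A synthetic community generator with full ground truth (FASTA +
GFF3 + truth table), accuracy benchmarking on 100/200/400-codon artificial
fragments, genome summary statistics, and an OLS regression predicting maximum
growth temperature from 16S rRNA G+C content.

All core steps are scikit-learn-style estimators (`CodonUsageVectorizer`,
`CodonUsageClusterer`, `MultinomialCodonClassifier`, `GCTemperatureRegressor`)
and compose with sklearn pipelines; a `codonbin` CLI wraps them
(`profile`, `cluster`, `classify`, `simulate-fosmids`, `calibrate`,
`benchmark`, `synth`, `tempest`, `summarize`).

## Worked example

Bin a synthetic 20-species library and re-attribute its end reads:

```python
import numpy as np
from codonbin import (CommunitySpec, CodonUsageClusterer, MultinomialCodonClassifier,
                      FragmentCounts, build_profile, generate_library)

lib = generate_library(CommunitySpec(seed=11))          # 20 species, skewed abundance
profiles = [build_profile(r) for r in lib.clone_records]
est = CodonUsageClusterer(threshold=0.04).fit(profiles)
print(f"{len(profiles)} clones -> {est.n_groups_} species groups "
      f"(largest: {max(est.grouping_.group_sizes.values())} clones)")

model = MultinomialCodonClassifier.from_grouping(est.grouping_, profiles)
frags = [FragmentCounts.from_sequence(r.cds_sequences[0], r.clone_id, mate_id=r.mate_id)
         for r in lib.end_reads]
result = model.classify_fragments(frags, paired=True)
print(result.head(3).to_string(index=False))
```

prints

```
158 clones -> 20 species groups (largest: 34 clones)
              read_id assigned_group  log_prob_best     margin  tie_flag
C0001_end5+C0001_end3           G001    -122.102253 223.528372     False
C0002_end5+C0002_end3           G001    -117.985268 235.664596     False
C0003_end5+C0003_end3           G001    -128.322978 198.541140     False
```

Every clone lands in its true species group (the dominant group holds 34 of
158 clones by design) and all 158 pooled end-read pairs are re-attributed to
the correct group: with species ≥ 0.08 apart, a 400-codon pooled pair is
decisive — note the log-probability margins of ~200 nats over the runner-up
group. The same pipeline runs from the shell via `codonbin synth`,
`codonbin profile`, `codonbin cluster` and `codonbin classify`.

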