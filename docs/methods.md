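# Methods

## Codon-usage vectors

The compositional signature of a clone, contig or species group is its usage
of the 61 sense codons of the standard bacterial genetic code. Dimensionality
is fixed at 61 by excluding the three stops (TAA, TAG, TGA). Counting rules:

- **Start exclusion is positional**: the first codon of a CDS is dropped
  whatever its identity, because bacterial starts are frequently GTG or TTG
  and removing those *by identity* anywhere in the gene would bias valine and
  leucine codon counts.
- **Stop exclusion is by identity at the terminal position only**; a
  stop-like triplet in the interior (usually a misannotation) survives
  extraction but is ignored by counting, which tallies sense codons only.
- Codons containing any non-ACGT character are skipped, never imputed; a
  trailing partial codon is discarded with a warning.
- Frequencies are counts normalised over the 61 sense codons, so every
  profile sums to 1.

The frequency estimate from N internal codons has RMS error
E‖p̂ − p‖ ≈ √(Σᵢ pᵢ(1−pᵢ)/N); between two independent estimates of the same
genome the factor under the root doubles. At N = 8,000 (a typical fosmid)
this is ≈ 0.016 between two fosmids of one genome — the quantitative basis of
the clustering threshold below. `min_internal_codons` (default 100) only
flags profiles as "unclustered" rather than silently including hopelessly
shallow ones; the default is far below the shallowest real fosmid (1,685
internal codons), so no sequenced clone is excluded by default.

## Species grouping (UPGMA at 0.04)

Pairwise Euclidean distances between clone frequency vectors are clustered
with unweighted average linkage (UPGMA): the distance between two clusters is
the arithmetic mean of the original pairwise distances over all cross pairs,
which makes merge heights monotone and the tree ultrametric. The
implementation delegates to `scipy.cluster.hierarchy.linkage(method="average")`;
the test suite holds it to a naive O(n³) recomputation from the original
matrix to 1e-12 on hundreds of random inputs. Equal-height merge ties follow
scipy's deterministic nearest-neighbor-chain order; any flat cut yields the
same partition regardless of the order in which equal-height merges are
listed, so tie order does not affect results.

Flat species groups are the maximal clusters whose merge (cophenetic) heights
are ≤ the threshold, i.e. a "distance" criterion cut. The default threshold
0.04 sits between the same-genome sampling-noise distribution (~0.016 median
for 8,000-codon fosmids; its 99th percentile is ~0.02) and typical
inter-genome distances. `calibrate_threshold` recomputes both distributions
for any species set and suggests the midpoint between the 99th percentile of
same-species distances and the 1st percentile of different-species distances;
it also reports whether 0.04 falls inside the gap. Group ids are assigned
deterministically (decreasing size, ties by smallest member label).

The homogeneity check re-clusters query profiles (e.g. assembled contigs)
together with a base clone set and reports whether the queries land in a
single group at the threshold, plus the minimum query-to-base distance.

## Multinomial fragment classifier

Codon counts n₁…n₆₁ of a short coding fragment are modelled as a multinomial
draw from a species group's codon frequencies; the log-probability is
computed in log-space via log-gamma, so it is finite and stable for any
fragment length. Group frequencies come from the pooled counts of the
group's clones with an additive pseudocount α per codon
(p̂ᵢₖ = (cᵢₖ + α)/(Cₖ + 61α)). Choices that were genuinely open:

- **α = 0.5** (Jeffreys-style). Any strictly positive value prevents −∞
  scores for codons unseen in a group; at fosmid-scale training counts
  (≥ thousands of codons) the choice is numerically immaterial.
- **Uniform prior over groups** — no abundance weighting; an explicit prior
  may be supplied.
- **Paired ends are pooled by summing counts** before scoring — the
  maximum-likelihood treatment when both reads derive from the same genome
  independently.
- **Frame handling**: fragments are expected as in-frame coding sequence
  from an upstream gene caller. A best-of-frames mode could be added by
  scoring all six frames and taking the maximum, but is deliberately not the
  default since frame choice then becomes part of the classification.
- **No rejection by default**: every fragment is attributed to its most
  probable group; `min_margin` optionally labels low-margin reads
  "ambiguous". Exact score ties are broken toward the lexicographically
  smallest group id and flagged.

The argmax coincides with multinomial naive Bayes (the count-permutation
coefficient is constant per fragment); the test suite uses sklearn's
`MultinomialNB` as an independent cross-check of the argmax and brute-force
enumeration over toy alphabets to verify that the probabilities normalise.

## Simulation experiments

`make_artificial_fosmid` has two modes. *Synthetic*: n i.i.d. codon draws
from a profile — matching the multinomial assumptions exactly. *Real*: a
contiguous window of n codons at a uniform random offset in a source's
ordered CDS codon stream, because fosmids are contiguous genomic inserts and
window sampling preserves local compositional heterogeneity.

`benchmark_classifier` draws fragments of 100/200/400 codons (defaults) from
each species' generating profile, classifies them, and reports per-length
confusion matrices, overall accuracy, and accuracy restricted to fragments
whose true species lies more than 0.04 from the best-scoring alternative
species (both are reported because "accuracy above the distance threshold"
can be read per-pair or overall). Unless a model is supplied, model profiles
are estimated from one 8,000-codon artificial fosmid per species, so the
classifier never sees the generating frequencies. All randomness flows from
one seed through `numpy.random.SeedSequence` spawning; identical designs give
bit-identical reports.

Problem sizes used by the shipped validation experiment (50 species, 100
fragments per species and length, 1,000 calibration replicates) keep every
experiment in the seconds-to-a-minute range while leaving Monte-Carlo error
on reported accuracies near ±1 point.

## Synthetic community generator

The generator emulates the features of a mixed-community fosmid library that
matter to binning, with full ground truth:

- **Species profiles** are symmetric-Dirichlet draws over the 61 sense
  codons. The concentration is derived from the midpoint of the requested
  pairwise-distance window via E‖p − q‖² = 2·Σmᵢ(1−mᵢ)/(61a + 1) (m = 1/61),
  and a window is enforced by sequential rejection: a candidate is accepted
  only if its distance to every accepted profile falls inside the window.
  Pairwise distance is the one covariate that controls binning difficulty,
  which is why it is the controlled quantity.
- **Library structure** defaults: 20 species; geometric clone abundance with
  a dominant group of 34 clones (total ~158) mirroring the skew of real
  libraries; clone coding content uniform in 1,700–14,300 internal codons;
  default inter-species window [0.08, 0.25], comfortably above the 0.04
  cutoff as real genome pairs usually are.
- **Clones**: CDSs of ~150–450 codons are generated as start codon + i.i.d.
  sense codons + stop (hence no in-frame internal stops, by construction),
  placed on random strands, and packed with fixed-length N spacers so
  accidental ORFs cannot appear between genes. GFF3 coordinates are written
  1-based inclusive and round-trip exactly through the reader.
- **End reads**: the first and last 200 codons (default) of each clone's
  codon stream, mate-linked — contiguous windows off both insert ends, not
  fresh i.i.d. draws.

What the generator does *not* emulate — and therefore what passing tests do
not demonstrate about real data: sequencing error and frameshifts, gene
prediction errors, horizontally transferred regions with alien codon usage,
strand- and position-dependent compositional bias, rRNA operons, and
within-genome codon-usage heterogeneity (real clones of one species scatter
somewhat more than pure multinomial noise). Accuracies measured here are
upper bounds with respect to those effects.

## Growth-temperature regression

Maximum growth temperature is regressed on 16S rRNA G+C content by ordinary
least squares (GC pairing stabilises rRNA secondary structure at high
temperature, producing an approximately linear relation across prokaryotes).
Plain OLS, no weighting or robust variants; predictions outside the fitted
GC range warn about extrapolation. Published calibration tables for this
relation are typically not machine-readable, so the module accepts a user
TSV and ships a synthetic point generator. The generator's default line
(slope 3.0 °C per GC point, intercept −101 °C) is anchored so that a 16S GC
of 61.9% maps to 84.7 °C — a published prediction for a thermophilic,
deeply branching bacterium — with the default GC range spanning typical
mesophile-to-hyperthermophile compositions; the noise default (σ = 2 °C) is
of the order of strain-to-strain growth-temperature uncertainty.

## Genome summaries and formats

`summarize_contigs` reports per-record length and G+C (one decimal, round
half up, matching genome-table conventions) plus a totals row and, given a
GFF3, counts of CDS/rRNA/tRNA features. Internal coordinates are 0-based
half-open; the single 1-based-inclusive GFF3 conversion lives in the CDS
reader. TSV outputs are tab-separated with a '#'-prefixed header and no
quoting, and every writer round-trips through its paired reader. Runs log
the package version, a hash of the configuration, and the seed.

## Known limitations

- Composition-based binning cannot separate genomes with near-identical
  codon usage (e.g. very close relatives); the calibration report flags
  non-separable inputs rather than inventing a threshold.
- The 0.04 default is calibrated for fosmid-scale profiles (~8,000 codons);
  much shallower units need a larger threshold, which `calibrate_threshold`
  will suggest from their actual sampling noise.
- The classifier assumes in-frame, error-free coding sequence; indels or
  wrong frames degrade it sharply (no frameshift correction is attempted).
- Accuracy near the decision boundary is intrinsically limited: when many
  species crowd within ~0.04–0.08 of each other, the Bayes-optimal error for
  100-codon fragments is of order 20%, and no classifier can do better;
  longer fragments (200–400 codons) restore near-perfect accuracy.
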