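# Methods

This note records the statistical procedures implemented in `coibarcode`,
the conventions chosen where the field leaves room, and what the synthetic
data generator does and does not emulate.

## Distances

Pairwise distances are computed under pairwise deletion: for each sequence
pair, only sites where both members carry an unambiguous base (A/C/G/T)
are compared. Transitions are A↔G and C↔T; everything else is a
transversion. With proportions P (transitions) and Q (transversions) over
the compared sites, the K2P distance is

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)).

When the logarithm's argument is non-positive the pair is saturated: the
distance is recorded as NaN, counted, logged and excluded from summaries —
never raised as an error. A pair with *zero* comparable sites, by
contrast, is a data defect and is an error naming the pair. The p-distance
(P + Q) is available under the same interface. The implementation was
checked against `ape::dist.dna(model = "K80", pairwise.deletion = TRUE)`
to 1e-8 on a random fixture.

## Level summaries and their accounting

Distances are summarized at three levels, outgroup always excluded,
percent scale, one decimal in the exported tables (full precision
internally):

* **intraspecific** — per species with ≥ 2 individuals, all within-species
  individual pairs, plus a pooled row; the pooled comparison count is
  Σᵢ C(nᵢ, 2).
* **interspecific** — one comparison per unordered *species pair*; the
  distance between two species is the arithmetic mean of all
  cross-individual distances. This species-pair accounting is what makes
  the pooled count C(S, 2) for S species, which is how barcoding surveys
  conventionally report it; pooling over individual pairs instead is
  available behind `species_pair_accounting=False`.
* **intrageneric** — per genus with ≥ 2 species, species-pair distances
  within the genus, within-species pairs excluded. The same accounting
  flag applies. (Counting individual pairs here would be inconsistent with
  the interspecific convention and does not reproduce the
  single-comparison rows seen for two-species genera.)

SE is the sample standard deviation of the comparison set divided by
√n_comparisons. Distance-software packages often report an analytic or
bootstrap variance instead; values can differ in the second decimal.

The barcode-gap report gives the maximum intraspecific distance, the
minimum interspecific distance, per-level histograms (default bin width 1
percentage point) and the number of interspecific comparisons *strictly
below* the maximum intraspecific distance. Species whose mean
intraspecific distance exceeds a threshold (default 1.3%, the minimum
interspecific divergence seen in temperate-bird COI surveys; 1.5% is a
common alternative) are flagged as deep-divergent.

## Trees and monophyly

The tree is built by Saitou–Nei neighbor joining on the K2P matrix. NJ is
a deliberate, documented stand-in for a maximum-likelihood search:
likelihood tree inference and substitution-model selection are out of
scope, and at barcode-scale divergences monophyly conclusions are
ordinarily robust to this substitution; the run log states it. The
implementation is authored in-package so tie-breaking is deterministic
(labels pre-sorted, first minimal Q-entry wins) and is tested against an
exhaustive least-squares oracle over all 15 five-taxon topologies and
against closed-form three-point branch lengths. Negative branch-length
estimates are clamped to zero. Bootstrap support resamples alignment
columns with replacement, rebuilds NJ per replicate, and scores each
internal edge by the percentage of completed replicates containing its
bipartition; replicates whose resampled matrix contains an undefined pair
are skipped and the denominator shrinks accordingly. Rooting places the
root at the midpoint of the outgroup's pendant edge. A species is
monophyletic iff some node's descendant leaves are exactly its
individuals; singletons are monophyletic by convention.

## Identification criterion

Distinguishable ⇔ monophyletic on the rooted point tree AND no individual
within `share_threshold` (default 0 = identical over compared sites) of
another species' individual. Bootstrap supports are reported but do not
gate the verdict — the criterion concerns topology, not support. The
identification rate is 100 · distinguishable/species, one decimal;
single-individual species count toward the denominator.

## Saturation test

Per-site Shannon entropy (natural log) is computed over unambiguous bases;
the index of substitution saturation is

    ISS = mean(H_site) / H_FSS,   H_FSS = -Σ_b f_b ln f_b,

with f the alignment-wide base composition — the entropy the data would
show if every site were randomized to that composition. The critical value
ISSc is an *input*: it depends on taxon number and topology and comes from
published simulation tables; the package carries 0.696 as a labeled
example default appropriate to a ~450-site, survey-sized alignment. The
test statistic is t = (ISSc − ISS)/SE with SE = sd(H_site)/(H_FSS √L), two
sided, on df = L (whether reference software uses L or L − 1 is not
documented; the difference is negligible at L ≈ 443). The exact variance
used by DAMBE is unpublished, so t and p are approximations to its output.

## Pseudogene (NUMT) screen

The degapped sequence is read in the three forward frames under the
vertebrate mitochondrial code; the best frame minimizes the number of stop
codons (TAA, TAG, AGA, AGG), ties resolving to the lowest frame index. Any
stop in the best frame flags the sequence: the barcode window lies inside
the COI open reading frame, so a genuine barcode has a stop-free frame.
Reverse frames are only scanned on request since COI amplicons are
submitted in coding orientation. Frameshift and unusual-substitution
heuristics are not implemented — only the stop-codon test is
operationalizable without curator judgment.

## Synthetic data generator

The generator emulates the statistical shape of a temperate-zone
multi-species COI survey, not any particular fauna:

* **Species tree** — Yule (pure birth), rescaled so the mean pairwise
  species path length equals 2 × `interspecific_height`; a floor
  (`min_species_separation`, default 0.013 substitutions/site) is added to
  species pendant edges because a pure Yule tree yields sister species
  with arbitrarily recent splits, which real surveys of described species
  rarely contain.
* **Within species** — star subtrees of depth `intraspecific_height`
  (pairwise divergence ≈ that height). A configurable fraction of species
  instead receives a two-cluster split at `deep_split_height`, emulating
  the occasional deeply divergent intraspecific lineage; these are planted
  preferentially in lightly sampled species, where surveys typically
  observe them. Individuals per species follow a truncated geometric
  distribution on 1..17 (p = 0.4 ⇒ ≈ 2.5 sequences/species, ≈ 40%
  singletons).
* **Sequences** — HKY with transition/transversion ratio κ (default 8,
  typical for bird COI), empirical-style base composition
  (A .247, C .333, G .154, T .265), a proportion of invariant sites and
  gamma rate multipliers normalized to mean 1 across sites; per-branch
  transition matrices come from the spectral decomposition of the
  reversible rate matrix. No indels. With `preserve_reading_frame`, the
  root is drawn stop-free in frame 0 and stop-creating substitutions are
  reverted, so clean sequences always pass the NUMT screen.
* **Contaminants** — `numt_rate` of the ingroup sequences receive one
  random in-frame stop codon; truth tables record contaminant ids, planted
  deep-split species and generating-tree distances.
* **Outgroup** — a single basal taxon on a long pendant edge
  (2.5 × `interspecific_height`).

The `chile-coi` preset (76 species, 443 sites, seed-reproducible) was
calibrated once so that the *observed* K2P regime matches a temperate bird
survey: interspecific mean ≈ 25% spanning ≈ 1–35%, intraspecific mean
≈ 0.3–0.4% with planted deep splits up to ≈ 8%, ISS ≈ 0.27, ≈ 200 variable
sites. That required `interspecific_height = 0.35` with gamma α = 1.0 and
p_inv = 0.5: under site-rate heterogeneity the K2P estimate sits well
below the true expected number of substitutions, so the tree height must
exceed the target observed distance. The preset under-disperses the upper
distance tail (real surveys reach ~43%); family-level structure, selection,
migration and indels are not modeled.

What passing tests on simulated data do show: the estimators and the
identification logic recover planted truth under the model's assumptions.
What they do not show: robustness to alignment error, heterogeneous
sampling effort, contamination beyond stop-codon NUMTs, or introgression —
real-data phenomena outside the generator.

## Numerical and reporting conventions

* Coordinates 0-based half-open internally, 1-based in reports.
* Ambiguity codes are kept in sequences but excluded from base counts,
  site classification and distances.
* Percent values are rounded to 1 decimal in tables; fractions such as the
  gap overlap to 2 decimals.
* `-0.0` distances (log of exactly 1) are normalized to `+0.0`.
* All randomness flows through `numpy.random.default_rng(seed)`; a fixed
  seed makes FASTA output and the whole report bundle byte-identical
  across reruns.
* Problem sizes in the test-suite and acceptance script (12–76 species,
  25–100 bootstrap replicates, 25-dataset recovery batches) were chosen so
  each check completes in seconds while keeping Monte-Carlo error well
  inside the asserted tolerances.

## Known limitations

* NJ instead of ML: very short internal edges can flip monophyly verdicts
  that a likelihood method would resolve differently.
* ISSc is not derived; the example default applies only to datasets
  resembling the calibration scale.
* The interspecific SE reflects the species-pair distance spread, not the
  analytic variance of the distance estimator.
* Metadata join trusts the `id` column; no fuzzy matching.
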