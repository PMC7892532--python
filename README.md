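# coibarcode

DNA-barcoding divergence analysis for COI datasets: from aligned
cytochrome c oxidase subunit I (COI) sequences and a taxon table to
distance summaries, barcode-gap analysis, tree-based species
identification, pseudogene screening and a substitution-saturation test —
with a synthetic-data generator so the whole pipeline can be exercised and
validated at desk scale.

## The problem

DNA barcoding asks whether a short standardized mitochondrial fragment
(COI in animals) is enough to tell species apart. That works when the
distribution of within-species distances and the distribution of
between-species distances barely overlap — the *barcode gap*. A barcoding
survey therefore needs, for a multi-species reference alignment:

* pairwise genetic distances under the **Kimura 2-parameter (K2P)** model,
  which corrects the observed transition proportion *P* (A↔G, C↔T) and
  transversion proportion *Q* for multiple hits:

  ```
  d = -1/2 · ln((1 - 2P - Q) · sqrt(1 - 2Q))
  ```

  computed with pairwise deletion (sites with a gap or ambiguity in either
  sequence are skipped for that pair);
* distance summaries at three taxonomic levels (intraspecific,
  interspecific, intrageneric), with interspecific comparisons counted
  **per species pair** (the distance between two species is the mean over
  their cross-individual distances);
* a **two-part distinguishability criterion**: a species is identified by
  its barcode iff (a) its individuals are monophyletic on the
  outgroup-rooted tree and (b) no individual shares a barcode (distance ≤
  threshold, default 0) with another species. The dataset-level
  identification rate is the percentage of species passing both parts;
* a neighbor-joining tree with column-resampling **bootstrap** support for
  the monophyly assessment;
* a **NUMT screen**: nuclear pseudogene copies of COI betray themselves by
  in-frame stop codons under the vertebrate mitochondrial code
  (TAA, TAG, AGA, AGG) — sequences whose best forward reading frame still
  contains a stop are flagged and excluded;
* an entropy-based **index of substitution saturation** (ISS), compared
  against a user-supplied critical value ISSc with a t-test: ISS
  significantly below ISSc means the alignment still carries usable
  phylogenetic signal.

The `simulate` module generates surveys with known truth (Yule species
tree, HKY+I+G sequence evolution, planted deep intraspecific splits,
injected pseudogene contaminants), so every stage can be tested without
downloading reference data.

## Worked example

Simulate a 12-species survey with the survey-scale `chile-coi` parameter
preset, then run the full pipeline:

```bash
coibarcode simulate --preset chile-coi --n-species 12 --seed 4 --out demo/sim
coibarcode all demo/sim/alignment.fasta \
    --metadata demo/sim/metadata.tsv --outgroup outgroup_i1 \
    --bootstrap 100 --seed 4 --out demo/report
```

which prints

```
12 of 12 species distinguishable (100.0%)
report bundle written to demo/report
```

and writes, among other tables, `table_levels.tsv`:

```
level          group  n_individuals  n_taxa  n_comparisons  mean  SE   min  max
intraspecific  ALL    33             9       61             0.3   0.0  0.0  0.7
interspecific  ALL    36             12      66             28.8  0.9  4.9  37.9
```

Within-species divergence (0.3% mean) sits two orders of magnitude below
between-species divergence (28.8% mean over the 66 species pairs), the
barcode gap is clean, and all 12 species pass both identification
criteria. `saturation.txt` reports

```
ISS = 0.268  ISSc = 0.696  T = 28.5  d.f. = 443  P = 2.3e-102
verdict: no significant substitution saturation (usable signal)
```

The same analyses are available as library calls (`distance_matrix`,
`summarize_level`, `barcode_gap`, `nj_tree`, `identification_report`,
`iss_test`, …) on `Alignment` objects; see the module docstrings.

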