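# lfqpanel

A pipeline for turning a replicate-structured label-free (LFQ) protein
intensity matrix into verified biomarker candidate panels and targeted-MS
assays. It covers:

- **Synthetic studies** (`lfqpanel.simulate`) — generate a full discovery
  experiment (3 cell lines x treatment x 2 timepoints x 3 biological
  replicates, plus pre-digestion SR and post-preparation TR injections)
  with known ground truth, and write every pipeline input file:
  proteinGroups-style TSV, design TSV, annotation flags, housekeeping
  list, FASTA, spectral-library table.
- **Quality control** (`lfqpanel.qc`) — MaxQuant-dialect parsing (0 =
  missing, "+" flags), removal of reverse / contaminant / only-by-site
  rows and <2-peptide identifications, pairwise Pearson correlation on
  log2 intensities, identification overlap across biological replicates,
  and per-protein SR/TR coefficients of variation.
- **Differential analysis** (`lfqpanel.stats`) — log2 transform,
  constant-value left-censored imputation, per-cell-line
  treated-vs-control Student's t-tests, one-way ANOVA with a Fisher
  least-significant-difference fold-change cutoff, PCA on mean-centered
  log2 values, and z-score / Euclidean hierarchical clustering with
  Newick export.
- **Panel building** (`lfqpanel.panel`) — CV-gated (SR and TR < 20%)
  candidate assembly for hypoxia (Hx) and androgen-sensitivity (AS)
  panels, a five-criterion additive evidence score (prior evidence,
  biomarker/drug target, secreted, exosome database, expression-database
  match; +1 each), and score >= 2 selection with deterministic ordering.
- **Normalizer selection** (`lfqpanel.normalize`) — housekeeping proteins
  present in every sample with CV < 20%, ranked by abundance (top 17),
  and geometric-mean per-sample normalization.
- **MRM design** (`lfqpanel.mrm`) — tryptic digestion (K/R, not before
  P), peptide eligibility (length 7–25, no C/M, no missed cleavages or
  ragged ends, proteotypic in the background FASTA), charge-2 monoisotopic
  precursors, singly charged y-ion products (m/z <= 1000, outside a ±5 Th
  precursor window), 2–3 peptides per protein and 4–5 transitions per
  peptide, exported as a vendor-style transition list CSV.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance-level checks: exact
reproduction of the published panel scores, type-I-error calibration,
power/recovery on injected effects, F = t² equivalence, digestion and
mass oracles, the normalization round trip, transition-constraint
properties, and an end-to-end smoke run.

## Command line

```sh
lfqpanel simulate --config config.yaml --out study/inputs --seed 7
lfqpanel qc --matrix study/inputs/proteinGroups.tsv --design study/inputs/design.tsv --out study/qc
lfqpanel diff --matrix study/inputs/proteinGroups.tsv --design study/inputs/design.tsv --out study/diff
lfqpanel panel --kind hx --diff study/diff/differential.tsv --cv study/qc/qc_cv.tsv \
    --annotations study/inputs/annotations.tsv --out study/panel_hx.tsv
lfqpanel normalizers --matrix study/inputs/proteinGroups.tsv --design study/inputs/design.tsv \
    --hk-list study/inputs/housekeeping.txt --out study/norm
lfqpanel mrm --panel study/panel_hx.tsv --fasta study/inputs/proteins.fasta \
    --library study/inputs/library.tsv --out study/transitions.csv
lfqpanel run --out study  # end-to-end on a synthetic study
```

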