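# prmquant

Absolute protein quantitation from targeted mass-spectrometry transition
areas, end to end:

* **formats_io** — Skyline-style transition CSV, sample-design TSV, peptide
  catalog, gene counts TSV, protein FASTA; remappable column dialects.
* **synthetic_data** — ground-truthed generator: log-uniform protein
  abundances, per-transition response factors, lognormal technical (~15% CV)
  and biological (~10% CV) noise, heavy-standard bleed-through (0–1%), a
  spiked luciferase-style control, Table-style dilution design, mass
  accounting of the standards, and RNA counts log-linearly tied to protein
  truth.
* **peptide_selection** — in-silico tryptic digestion (Keil rule) and a
  ten-criterion quantotypic candidate filter with hard/soft rules, a
  configurable weighted score and deterministic ranking, plus an
  I/L-collapsed uniqueness index.
* **prm_quantitation** — common-transition light/heavy ratios, conversion to
  fmol/injection via the heavy spike level, blank-based bleed-through
  estimation and subtraction (discard when bleed > 20% of the light signal),
  and the Good / Maybe Poor / Discarded quality classifier.
* **abundance_rollup** — QC-aware retention, geometric-mean aggregation over
  technical replicates and spike levels, then over biological replicates,
  peptide-form merging, catalog discard rules, copies/cell conversion
  (Avogadro + pg protein per cell) and protein-level rollup with a
  consistency class; RADM, CV and Tier-2 (CV < 35%) diagnostics.
* **proteome_estimation** — TPM, OLS of log10(copies/cell) on log10(TPM),
  proteome-wide prediction, symmetric fold-error summaries.
* **dataset_comparison** — per-protein ratios between two datasets, their
  geometric mean, and the protein-mass-per-cell consistency check.

## CLI

```bash
# ground-truthed synthetic dataset
prmquant simulate --seed 7 --out sim/

# transition areas -> per-run peptide measurements
prmquant quantify --transitions sim/transitions.csv --design sim/design.tsv \
    --catalog sim/catalog.tsv --out measurements.csv

# measurements -> peptide and protein abundance tables (copies/cell)
prmquant rollup --measurements measurements.csv --catalog sim/catalog.tsv \
    --out-peptides peptides.csv --out-proteins proteins.csv \
    --out-diagnostics diagnostics.csv

# transcript-based proteome-wide estimates
prmquant estimate-proteome --counts sim/counts.tsv --proteins proteins.csv \
    --out estimates.csv --out-model model.json

# candidate peptide selection from a FASTA
prmquant select-peptides --fasta proteome.fasta --out candidates.csv

# compare two protein-level datasets
prmquant compare --a proteins_a.csv --b proteins_b.csv \
    --mass-a 230 --mass-b 136 --out ratios.csv
```

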