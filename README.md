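# methylsieve

Discovery of lysine/arginine methylation sites from scored shotgun-proteomics
peptide-spectrum matches (PSMs). The package implements a six-step candidate
filter with methyl-specific target-decoy FDR estimation, chemistry-aware
disambiguation of confusable assignments (isobaric single-residue
substitutions; trimethylation vs. acetylation via precursor mass accuracy and
the −59 Da trimethylamine neutral loss), site-level aggregation with
spectral-count stoichiometry, and a seeded synthetic-data generator for
ground-truth benchmarking. A curated site inventory is packaged as a fixture
and drives the count-level regression suite.

## Modules

| module | purpose |
| --- | --- |
| `masschem` | monoisotopic masses for residues/modifications, peptide and fragment m/z, ppm errors — all derived from one atomic-mass table |
| `digestion_decoy` | Trypsin/P in-silico digestion with missed cleavages, reversed-decoy databases, FASTA I/O |
| `dataset_io` | PSM TSV and MGF readers/writers, pre-pipeline parsing filters (score cutoff, rank-1, homology), run compilation into protein groups |
| `isobar` | isobaric-substitution enumeration, trimethyl/acetyl adjudication, precursor-error calibration, neutral-loss detection |
| `filter_pipeline` | the six-step filter (seed → quality → corroborate → min-spectra → substitution → trimethyl/acetyl) with target-decoy FDR and an audit log |
| `inventory_report` | site inventory records, stoichiometry, ±6-residue motif windows, summary counts, packaged curated inventory |
| `synthetic_data` | seeded ground-truth dataset generator (true sites, spurious single-PSM sites, acetyl and substitution mimics, decoy PSMs) |
| `cli` | `methylsieve simulate / filter / report` |

## CLI

```sh
# generate a synthetic dataset (deterministic for a given seed)
methylsieve simulate --seed 17 --outdir data/

# run the six-step filter
methylsieve filter --psms data/psms.tsv --mgf data/spectra.mgf \
    --fasta data/proteome.fasta --out sites.tsv --audit audit.json

# summarize the validated sites and extract motif windows
methylsieve report --sites sites.tsv --fasta data/proteome.fasta \
    --out summary.json --windows windows.tsv
```

Each invocation writes a `*.manifest.json` beside its outputs recording the
command, configuration snapshot, input checksums, seed, and tool version.
Pipeline and simulation configs can be supplied as TOML files mirroring
`PipelineConfig` / `SimulationConfig` field-for-field.

## Notes

- All constants (atomic masses, proton mass) are hard-coded in
  `masschem` so results are bit-reproducible with no runtime dependency on
  external mass tables.
- The synthetic generator draws every random quantity from a single seeded
  NumPy generator in a fixed order; identical configs produce byte-identical
  output files.
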