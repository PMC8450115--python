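# codonflux

Analytics for codon usage and translation kinetics: gene-level codon usage
indices (CAI, CBI, tAI), ribosome-profiling quantification (A-site codon
occupancy, TPM, ribosome density, relative codon decoding times), genome-scale
scanning-window statistics, and a synthetic data generator that plants the
statistical structure every analysis stage is meant to recover.

## Modules

- `codonflux.codon_metrics` — genetic code tables, codon usage table parsers
  (Kazusa flat format and a two-column TSV), CAI (Sharp–Li geometric mean of
  relative adaptiveness), CBI (Bennetzen–Hall), tAI weights from anticodon
  copy numbers with wobble penalties, optimal-codon set derivation, and
  synonymous codon optimization.
- `codonflux.ribo_quant` — footprint-to-A-site assignment
  (`codon = (five_prime + offset(read_length)) // 3`), TPM, ribosome density
  (RPF TPM / mRNA TPM), relative codon decoding time (RCDT) overall and by
  CDS-length stratum, and per-codon RCDT differences.
- `codonflux.genome_scan` — ranked scanning-window Pearson correlations,
  subset correlations, CBI × length gene grouping, differential ribosome
  density (Welch/Student t + Benjamini–Hochberg, fold-change calls), and
  length-ranked fold-change proportion / mean-length curves.
- `codonflux.synthetic_data` — deterministic simulation of transcriptomes with
  per-gene codon bias, proteomes with a planted length × optimality abundance
  model, and two-condition replicated footprint studies whose ground truth is
  serialized next to the data.
- `codonflux.io_cli` — FASTA / SAM / TSV readers and writers, strict YAML run
  configuration, workflow composition, checksum manifests, and the CLI.

## CLI

```bash
# simulate a two-condition study into a run directory
codonflux simulate --config sim.yaml --out rundir --seed 17

# per-gene indices and codon optimization
codonflux indices --fasta cds.fasta --usage-table usage.tsv --trna trna.tsv --out indices.tsv
codonflux optimize --fasta cds.fasta --usage-table usage.tsv --out optimized.fasta

# analysis workflows over a run directory
codonflux density     --run-dir rundir --out out/
codonflux rcdt        --run-dir rundir --out out/ --strata 600:inf,0:300
codonflux diffdensity --run-dir rundir --out out/ --fc 2 --alpha 0.05
codonflux windows     --run-dir rundir --out out/ --window 500 --step 1
codonflux groups      --run-dir rundir --out out/ --cbi-high 0.3 --cbi-low 0.15 --size 1000
codonflux full        --run-dir rundir --out out/
```

Every workflow writes TSV tables plus a `manifest.json` with SHA-256
checksums; reruns with identical config and inputs are byte-identical.

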