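# hydrotemp

Extracts the temperature dependence of amino-acid hydrophobicity from
solvent-accessibility statistics of NMR protein structure ensembles.

Chains annotated with an acquisition temperature are assigned to five
temperature bins (265–290, 291–296, 297–299, 300–305, 306–340 K). For
each bin, four knowledge-based estimators of the core→surface transfer
free energy are computed per residue type or pooled class, in kT units,
positive = burial-favouring:

- **contact** — quasi-chemical solvent-contact energy with coordination
  number q = 4; water contacts per residue are `q · α`, where
  `α = area / max_area` is the relative exposed surface.
- **surface** — burial propensity as a partition coefficient at a strict
  7% exposure cutoff, `ln[(N_buried/N_exposed) / (totals ratio)]`;
  exactly antisymmetric under swapping the buried/exposed labels.
- **area** — continuous exposed-area variant (infinite coordination).
- **scaled_area** — the area energy scaled by the type's maximum
  accessible surface area.

On top of the per-bin energies the package provides: a reference
correction (pooled charged+polar residues per bin), the room-vs-low
temperature difference ΔΔG (297–299 K minus 265–290 K), label-shuffle
resampling p-values (whole chains permuted between the two bins),
split-sample standard errors (random 5-way split), and weighted
least-squares parabola fits of ΔG(T) with per-bin residue counts as
weights.

A synthetic-data generator produces chain sets whose class-level
transfer energy follows a configurable parabola `g(T) = g_max −
κ(T−T_peak)²` mapped to mean exposure through a logistic link, with
Beta-distributed exposure noise — plus closed-form expected energies
(`truth_report`) so the whole pipeline is testable without downloads.

## CLI

```sh
# synthetic dataset -> counts table (+ closed-form truth)
hydrotemp simulate --seed 1 --n-chains 500 --out counts.tsv --truth truth.tsv

# full pipeline from a counts table (or omit --counts for synthetic input)
hydrotemp run-all --counts counts.tsv --seed 1 --outdir out/

# individual stages
hydrotemp potentials --counts counts.tsv --out potentials.tsv
hydrotemp significance --counts counts.tsv --entity hydrophobic --method contact
hydrotemp fit --counts counts.tsv --out fits.tsv
hydrotemp ingest --dssp model1.dssp --dssp model2.dssp \
    --header 1abc.pdb --structure-id 1ABC --select25 select25.txt --out counts.tsv
```

`run-all` writes `potentials.tsv` (raw + reference-corrected energies),
`ddg_significance.tsv` (ΔΔG, split-SE, resampling p-values),
`parabola_fits.tsv`, `temperature_histogram.tsv`, and `manifest.json`.
Configuration (burial cutoff, q, resample count, reference classes,
generator parameters, …) is a YAML file passed via `--config`.

### Input formats

- accessibility: standard DSSP output files, one per NMR model (the ACC
  column); per-residue areas are averaged over models before the
  exposure fraction is formed.
- temperature: PDB-format header (`REMARK 210 TEMPERATURE (KELVIN)`
  field). Entries that are missing, disagree across data-collection
  sessions, or are ≤ 150 K (celsius typed into the kelvin field) are
  rejected and tallied.
- redundancy list: plain text, one `1ABC_A` chain identifier per line
  (PDB-select-25 style).
- counts table: TSV with one row per chain — `structure_id`, `chain_id`,
  `temperature_K`, and per residue type `*_n`, `*_buried` (at the 7%
  cutoff), `*_alpha_sum` columns. Written by `simulate`/`ingest`, read
  back by every downstream stage.

Exposure fractions are normalised by a configurable max-ASA table
defaulting to the theoretical Gly-X-Gly scale of Tien et al. 2013.

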