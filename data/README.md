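# data/

Optional external inputs. Nothing here is required for the test suite's
download-free criteria.

- `s1_counts.tsv` (not bundled): the original study's supplementary
  per-structure counts file, converted to the package's counts-table
  schema (`structure_id`, `chain_id`, `temperature_K`, and per residue
  type `*_n`, `*_buried`, `*_alpha_sum` columns, tab-separated). When
  present, `scripts/acceptance.py` and the conditional acceptance test
  compute the published-table reproduction targets from it.
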