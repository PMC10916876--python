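# Registry file schema (version 1)

A term registry is a single JSON object:

```json
{
  "schema_version": 1,
  "provenance": {
    "seed": 5,
    "r2_threshold": 0.25,
    "mcc_threshold": 0.5,
    "selection": {"max_iter": 30, "alpha": 0.05, "...": "..."},
    "profiles_digest": "0123abcd...",
    "readouts_digest": "4567ef01...",
    "n_profiles": 110,
    "n_features": 200,
    "n_readouts": 5
  },
  "terms": [
    {
      "term_id": "viability_cell_death_vb_percent_dead_Chromatin Modifiers",
      "level1_assay": "viability",
      "level2_measurement": "cell_death",
      "level3_phenotype": "vb_percent_dead",
      "level4_process": "Chromatin Modifiers",
      "level5_features": ["Cells_Intensity_DNA_000", "..."],
      "regression_gate": {
        "metric_name": "r_squared", "value": 0.93,
        "passed": true, "split_seed": 1005
      },
      "classifier_gate": {
        "metric_name": "mcc", "value": 0.78,
        "passed": true, "split_seed": 1006
      }
    }
  ]
}
```

Rules:

* `term_id` is the underscore concatenation of the four label levels and
  must be unique within a file; readers reject duplicates.
* `level5_features` is sorted and non-empty.
* Terms are sorted by `term_id`; keys are sorted — two registries built
  from identical inputs serialize to identical bytes.
* Readers reject any `schema_version` other than 1.
* `provenance` is round-tripped verbatim; digests are SHA-256 prefixes of
  the input tables' CSV serialization.

The readout-annotation map consumed by the builder is a CSV with header
`readout_name,level1_assay,level2_measurement`.
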