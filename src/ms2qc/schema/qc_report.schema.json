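{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "ms2qc QC report",
  "description": "Bulk MS2 identification-rate QC report at run, dataset and corpus level. Optional metrics are null with a sibling *_reason code when they cannot be computed.",
  "type": "object",
  "required": ["schema_version", "generated_at", "provenance", "corpus", "datasets"],
  "properties": {
    "schema_version": {"type": "string"},
    "generated_at": {"type": "string"},
    "provenance": {"type": "object"},
    "corpus": {
      "type": "object",
      "required": [
        "n_datasets", "total_submitted", "total_assigned",
        "pooled_rate_pct", "mean_dataset_rate_pct", "pct_unidentified",
        "baselines", "baseline_comparisons"
      ],
      "properties": {
        "n_datasets": {"type": "integer"},
        "total_submitted": {"type": "integer"},
        "total_assigned": {"type": "integer"},
        "pooled_rate_pct": {"type": "number"},
        "mean_dataset_rate_pct": {"type": "number"},
        "pct_unidentified": {"type": "number"},
        "baselines": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["name", "rate_pct"],
            "properties": {
              "name": {"type": "string"},
              "rate_pct": {"type": "number"},
              "source_note": {"type": "string"}
            }
          }
        },
        "baseline_comparisons": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["name", "baseline_rate_pct", "delta_pct", "below"],
            "properties": {
              "name": {"type": "string"},
              "baseline_rate_pct": {"type": "number"},
              "delta_pct": {"type": "number"},
              "below": {"type": "boolean"}
            }
          }
        }
      }
    },
    "datasets": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "dataset_id", "engine", "n_submitted", "n_assigned",
          "pooled_rate_pct", "mean_rate_pct", "runs"
        ],
        "properties": {
          "dataset_id": {"type": "string"},
          "engine": {"type": "string"},
          "n_submitted": {"type": "integer"},
          "n_assigned": {"type": "integer"},
          "pooled_rate_pct": {"type": "number"},
          "mean_rate_pct": {"type": "number"},
          "n_psms_at_fdr": {"type": ["integer", "null"]},
          "n_peptides": {"type": ["integer", "null"]},
          "n_protein_groups": {"type": ["integer", "null"]},
          "n_contaminant_spectra": {"type": ["integer", "null"]},
          "runs": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["run_id", "n_submitted", "n_assigned", "rate_pct"],
              "properties": {
                "run_id": {"type": "string"},
                "n_submitted": {"type": "integer"},
                "n_assigned": {"type": "integer"},
                "rate_pct": {"type": "number"},
                "n_psms_at_fdr": {"type": ["integer", "null"]},
                "n_peptides": {"type": ["integer", "null"]},
                "n_protein_groups": {"type": ["integer", "null"]},
                "n_contaminant_spectra": {"type": ["integer", "null"]}
              }
            }
          }
        }
      }
    }
  }
}
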