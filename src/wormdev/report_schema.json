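{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "wormdev run report",
  "type": "object",
  "required": ["provenance", "analyses"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["version", "seed", "n_trials", "source", "n_neurons", "n_connections"],
      "properties": {
        "version": {"type": "string"},
        "seed": {"type": "number"},
        "n_trials": {"type": "number"},
        "source": {"type": "string"},
        "n_neurons": {"type": "number"},
        "n_connections": {"type": "number"},
        "stage_times": {"type": "array"},
        "hatch_time": {"type": "number"}
      }
    },
    "analyses": {
      "type": "object",
      "properties": {
        "temporal": {
          "type": "object",
          "required": [
            "birth_time_difference_histogram",
            "phase_fractions",
            "degree_birth_correlation",
            "hub_reports"
          ],
          "properties": {
            "birth_time_difference_histogram": {"type": "object"},
            "phase_fractions": {"type": "object"},
            "degree_birth_correlation": {"type": "object"},
            "hub_reports": {"type": "object"},
            "bilateral_timing": {"type": "object"},
            "type_growth_curves": {"type": "object"}
          }
        },
        "spatial": {
          "type": "object",
          "required": ["class_counts", "appearance_curves", "prehatch_pct"],
          "properties": {
            "class_counts": {"type": "object"},
            "appearance_curves": {"type": "object"},
            "synapse_breakdown": {"type": "array"},
            "region_connectivity": {"type": "object"},
            "prehatch_pct": {"type": "object"}
          }
        },
        "circuits": {
          "type": "object",
          "required": ["curves"],
          "properties": {"curves": {"type": "object"}}
        },
        "topology": {
          "type": "object",
          "required": ["stages"],
          "properties": {"stages": {"type": "array"}}
        }
      }
    }
  }
}
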