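{
  "description": "Packaged source grouping for the somatic variant refinement layout: 71 features in 8 groups. Group sizes are authoritative; feature names for the read-level groups are positional placeholders that callers may override with their own manifest.",
  "groups": [
    {
      "name": "Disease",
      "kind": "onehot",
      "features": [
        "disease_1", "disease_2", "disease_3", "disease_4", "disease_5",
        "disease_6", "disease_7", "disease_8", "disease_9"
      ]
    },
    {
      "name": "Reviewer",
      "kind": "onehot",
      "features": ["reviewer_1", "reviewer_2", "reviewer_3", "reviewer_4"]
    },
    {
      "name": "Normal_pro",
      "kind": "numeric",
      "features": ["normal_VAF", "normal_depth", "normal_other_bases_count"]
    },
    {
      "name": "Normal_ref",
      "kind": "numeric",
      "features": [
        "normal_ref_01", "normal_ref_02", "normal_ref_03", "normal_ref_04",
        "normal_ref_05", "normal_ref_06", "normal_ref_07", "normal_ref_08",
        "normal_ref_09", "normal_ref_10", "normal_ref_11", "normal_ref_12",
        "normal_ref_13"
      ]
    },
    {
      "name": "Normal_var",
      "kind": "numeric",
      "features": [
        "normal_var_01", "normal_var_02", "normal_var_03", "normal_var_04",
        "normal_var_05", "normal_var_06", "normal_var_07", "normal_var_08",
        "normal_var_09", "normal_var_10", "normal_var_11", "normal_var_12",
        "normal_var_13"
      ]
    },
    {
      "name": "Tumor_pro",
      "kind": "numeric",
      "features": ["tumor_VAF", "tumor_depth", "tumor_other_bases_count"]
    },
    {
      "name": "Tumor_ref",
      "kind": "numeric",
      "features": [
        "tumor_ref_01", "tumor_ref_02", "tumor_ref_03", "tumor_ref_04",
        "tumor_ref_05", "tumor_ref_06", "tumor_ref_07", "tumor_ref_08",
        "tumor_ref_09", "tumor_ref_10", "tumor_ref_11", "tumor_ref_12",
        "tumor_ref_13"
      ]
    },
    {
      "name": "Tumor_var",
      "kind": "numeric",
      "features": [
        "tumor_var_01", "tumor_var_02", "tumor_var_03", "tumor_var_04",
        "tumor_var_05", "tumor_var_06", "tumor_var_07", "tumor_var_08",
        "tumor_var_09", "tumor_var_10", "tumor_var_11", "tumor_var_12",
        "tumor_var_13"
      ]
    }
  ]
}
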