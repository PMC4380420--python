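{
  "thf_downstream_total": {"value": 18},
  "thf_near_lesion_count": {"value": 7},
  "thf_near_lesion_rate": {"value": 8.1e-05, "rel_tol": 0.05},
  "thf_msh2_rate_bound": {"value": 9.7e-05, "rel_tol": 0.05},
  "thf_fisher_p": {"value": 0.0045, "rel_tol": 0.05},
  "thf_insertion_counts": {"value": {"A": 243, "C": 80, "T": 71}},
  "uv_downstream_total": {"value": 15},
  "uv_near_lesion_count": {"value": 12},
  "uv_background_rate": {"value": 6.0e-06, "rel_tol": 0.05},
  "uv_net_rate": {"value": 6.7e-05, "rel_tol": 0.05},
  "uv_rad30_rate": {"value": 3.0e-05, "rel_tol": 0.05},
  "uv_rev3_downstream_total": {"value": 0},
  "uv_enrichment_table": {"value": [[12, 153], [1, 160]]},
  "fold_over_genomewide_spontaneous": {"value": 370000, "rel_tol": 0.05}
}
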