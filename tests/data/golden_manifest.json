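{
 "config_hash": "25b2e34beeb2f408",
 "counts": {
  "chosen_k": 2,
  "dcl": 4016,
  "dcp": 107,
  "de_down": 53,
  "de_up": 36,
  "enriched_sets": {
   "dcp": 0,
   "de": 1,
   "links": 4,
   "unified": 1
  },
  "links_tested": 44850,
  "proteins_retained": 300,
  "samples": 52,
  "stars_retained": 10,
  "stars_scored": 300,
  "stars_significant": 10,
  "subtype_markers": 113,
  "unified_edges": 23,
  "unified_nodes": 10
 },
 "package_version": "0.1.0",
 "seed": 7,
 "survival": {
  "discovery_logrank_chi2": 11.001738,
  "discovery_logrank_p": 0.00091,
  "mirror_logrank_chi2": 22.971566,
  "mirror_logrank_p": 2e-06
 }
}
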