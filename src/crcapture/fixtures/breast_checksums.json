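{
  "total": 787,
  "source_totals": {"HR": 729, "MTM": 537, "CSP": 207},
  "exactly_two_sources": 470,
  "all_three_sources": 108
}
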