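{
  "total": 512,
  "source_totals": {"HR": 481, "MTM": 328, "CSP": 81},
  "two_or_more_sources": 337,
  "all_three_sources": 41
}
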