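# Packaged record-linkage tables

Two three-source capture-pattern tables of cancer cases aged 50-75 notified in
2008 (Alpes-Maritimes): breast and colorectal cancer, with sources

* `HR`  - histopathological cancer registry
* `MTM` - hospital multidisciplinary team meetings
* `CSP` - coordinated cancer screening programme

Pattern strings are ordered `HR, MTM, CSP` (leftmost digit = HR), so `110`
counts cases recorded by HR and MTM but not by the screening programme.

Each table ships with a `*_checksums.json` sidecar holding the published
marginal totals (total distinct cases, per-source list sizes, multi-source
overlap counts).  `crcapture.capture_data.load_fixture` re-validates the cells
against these checksums on every load.  Note the two sidecars pin the
multi-source overlap differently: for the breast table the published figure
470 counts cases in *exactly* two sources (108 more appear in all three),
whereas the colorectal figure 337 counts cases in *at least* two.
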