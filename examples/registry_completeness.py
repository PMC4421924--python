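"""Estimate cancer-registry completeness from three overlapping case lists.

Loads the packaged breast-cancer record-linkage table (histopathological
registry HR, multidisciplinary team meetings MTM, screening programme CSP),
selects a log-linear model by stepwise deviance descent, projects the number
of cases missed by all three lists, and converts the population estimate into
the registry's completeness.
"""

from crcapture import completeness, load_fixture, stepwise_select

cells = load_fixture("breast")
print(f"observed cases: {cells.total} "
      f"(HR {cells.source_total('HR')}, MTM {cells.source_total('MTM')}, "
      f"CSP {cells.source_total('CSP')})")

result = stepwise_select(cells, alpha=0.05)
for f in result.fits:
    mark = " <-- selected" if f.selected else ""
    print(f"  {f.model.formula:<55s} N = {f.N_hat:6.1f} "
          f"[{f.ci[0]:.0f}-{f.ci[1]:.0f}]  G2 = {f.G2:5.2f} df = {f.df}{mark}")

best = result.selected
comp = completeness(cells.source_total("HR"), best.N_hat, best.ci)
print(f"\nselected model projects {best.x000_hat:.1f} cases missed by every list,")
print(f"so the estimated population is {best.N_hat:.0f} cases "
      f"[{best.ci[0]:.0f}-{best.ci[1]:.0f}]")
print(f"histopathological registry completeness: {comp.percent}% "
      f"({comp.ci[0]}%-{comp.ci[1]}%)")
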