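"""Set arithmetic on the published top-20 correlating gene lists.

The embedded reference tables hold the published top-20 positively and
negatively correlating genes for gas plasma, H2O2 and HOCl sensitivity
(n = 35 cell lines). Their overlap structure is fully determined by the
printed lists and is reproduced here.
"""

from rospanel import overlap_report
from rospanel.reference_tables import reference_gene_sets

for direction in ("positive", "negative"):
    report = overlap_report(reference_gene_sets(direction), universe_size=None)
    print(f"{direction} top-20 lists:")
    for (a, b), (size, members, _) in report.pairwise.items():
        label = f"  {a.split('_')[0]} & {b.split('_')[0]}"
        print(f"{label}: {size} shared" + (f" -> {', '.join(members)}" if members else ""))
    print(f"  all three: {len(report.full_intersection)} shared\n")
# Only the gas plasma and H2O2 positive lists overlap (4 genes: AREG,
# BLVRB, CFAP300, ME1) - consistent with H2O2 being a main effector of
# gas plasma cytotoxicity while HOCl acts through different routes.
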