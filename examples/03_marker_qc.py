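"""Completeness and contamination of a bin from single-copy markers.

Completeness = identified markers / 107 as a percentage; redundancy =
markers present in >= 2 copies / identified markers. A curated bin is
considered high quality above 96 % completeness with < 5 % redundancy.
"""

from covbin import GenomeBin, load_marker_set, qc_report, simulate_community

community = simulate_community(seed=7)
escg = load_marker_set("ESCG107")
truth = community.truth.scaffold_to_genome

for gid in ("g1", "g2", "g3", "g4"):
    members = {s for s, g in truth.items() if g == gid}
    report = qc_report(GenomeBin(gid, members), community.markers, escg)
    planted = community.truth_qc[gid]
    print(f"{gid}: completeness {report.completeness_pct}% "
          f"redundancy {report.redundancy_pct}% "
          f"(planted {planted['completeness_pct']:.1f}/"
          f"{planted['redundancy_pct']:.1f}) "
          f"pass={report.passes_quality}")

# The recovered percentages equal the planted truth exactly: e.g. a
# genome missing 1 of 107 markers reports 99.1 % completeness, and 4
# duplicated among 106 identified reports 3.8 % redundancy.
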