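"""Read a BED file of TF-binding regions, merge overlaps, sort positionally.

Overlapping or abutting ChIP peaks from pooled experiments are collapsed so
each genomic base is covered at most once before any downstream scoring.
"""

import tempfile
from pathlib import Path

import trsnmatch as tm

bed_text = """\
track name=demo_peaks
chr2\t150\t260
chr1\t100\t200
chr1\t180\t300
chr1\t300\t400
chr10\t50\t120
"""

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "peaks.bed"
    path.write_text(bed_text)
    peaks = tm.read_bed(path, tf="DEMO_TF", cell_line="MCF7")

print(f"parsed {len(peaks)} raw peaks")
merged = tm.merge_overlapping(peaks)
print(f"after merging overlaps/abutments: {len(merged)} peaks")
for iv in tm.sort_peaks(merged):
    print(f"  {iv.chrom}:{iv.start}-{iv.end}  ({len(iv)} bp)")

# chr1:100-200 + chr1:180-300 overlap and chr1:300-400 abuts them, so the
# three collapse into one 300 bp region; chromosomes sort naturally
# (chr1 < chr2 < chr10), not lexicographically.
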