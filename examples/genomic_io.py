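"""Read ChromHMM-style BED and BEDPE loop files into model inputs.

Writes a toy 15-state segmentation and a loop file, then shows how beads are
labeled (states 1-11 -> active A, 12-15 -> repressive B, majority overlap
per 1200-bp bin) and how loop anchors map to bead indices by midpoint.
"""

import tempfile
from pathlib import Path

from ccmpoly.core import CCMParameters
from ccmpoly.genome_io import GenomicInterval, read_chromhmm_bed, read_loops_bedpe

tmp = Path(tempfile.mkdtemp())
bed = tmp / "chromhmm.bed"
bed.write_text(
    "chr5\t0\t3600\t5_Strong_Enhancer\n"
    "chr5\t3600\t8400\t13_Heterochrom\n"
    "chr5\t8400\t12000\t2_Weak_Promoter\n"
)
bedpe = tmp / "loops.bedpe"
bedpe.write_text("chr5\t300\t900\tchr5\t9300\t9900\n")

region = GenomicInterval("chr5", 0, 12000)
params = CCMParameters(n_beads=10)
ann = read_chromhmm_bed(bed, region, params)
loops = read_loops_bedpe(bedpe, region, params)

print("per-bead labels:", "".join(ann.labels))
print("source states:  ", " ".join(map(str, ann.states)))
print("loop anchors (bead indices):", loops.anchors.tolist())
print(f"active fraction: {ann.fraction_a:.2f}")
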