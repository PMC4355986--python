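"""Bin-level quantification: from aligned reads to a normalized track.

Builds a handful of 36-bp reads on a toy chromosome, counts them into
100-bp bins (a read credits every bin it overlaps), and normalizes by
the library-size mantissa factor N_U / 10^floor(log10 N_U).
"""
from methclust import GenomicInterval, normalization_factor, quantify_sample

reads = [
    GenomicInterval("chr1", 95, 131),   # spans bins 0 and 1
    GenomicInterval("chr1", 100, 136),  # bin 1 only (half-open bins)
    GenomicInterval("chr1", 250, 286),  # bin 2
]
track = quantify_sample(reads, {"chr1": 1_000}, sample_id="demo")

print("raw bin counts:", track.raw["chr1"][:4].tolist())
print("library size:", track.n_unique_reads,
      "-> normalization factor:", track.norm_factor)
print("normalized bins:", [round(float(v), 4) for v in track.normalized["chr1"][:4]])
print("factor for a 23,456,789-read library:", normalization_factor(23_456_789))
# The factor is the mantissa of the library size, so normalized values of
# libraries sequenced to different depths live on a comparable scale.
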