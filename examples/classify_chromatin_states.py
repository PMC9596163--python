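"""Classify promoters and enhancers from histone-mark peaks.

Builds a three-gene toy annotation by hand, overlays mark peaks, and
prints the classified regulatory elements. Promoter windows span
1000 bp upstream to 10 bp downstream of each TSS.
"""

from regscreen import GeneModel, GeneTable, GenomicInterval, IntervalSet, annotate_landscape

genes = GeneTable([
    GeneModel("actively_transcribed", "chr1", "+", 5_000, "protein_coding"),
    GeneModel("polycomb_silenced", "chr1", "-", 60_000, "protein_coding"),
    GeneModel("unmarked", "chr1", "+", 120_000, "protein_coding"),
])

marks = {
    # both activation marks on the first promoter
    "H3K4me3": IntervalSet([GenomicInterval("chr1", 4_200, 4_900)]),
    "H3K27ac": IntervalSet([GenomicInterval("chr1", 4_300, 5_200),
                            GenomicInterval("chr1", 90_000, 90_600)]),  # distal
    # repressive mark over the second promoter
    "H3K27me3": IntervalSet([GenomicInterval("chr1", 59_800, 60_900)]),
    "H3K4me1": IntervalSet([GenomicInterval("chr1", 150_000, 150_500)]),
}

for element in annotate_landscape(marks, genes):
    iv = element.interval
    who = f" ({element.gene_id})" if element.gene_id else ""
    print(f"{iv.chrom}:{iv.start}-{iv.end}  {element.state:12s} "
          f"{element.locus_kind}{who}  marks={sorted(element.marks)}")

print("\nH3K4me3+H3K27ac => active promoter; H3K27me3 alone => repressed;")
print("mark coverage outside promoter windows becomes enhancer elements")
print("(H3K27ac => active enhancer, H3K4me1 alone => poised enhancer).")
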