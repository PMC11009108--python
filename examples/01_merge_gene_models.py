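"""Collapse a redundant lncRNA transcript collection into gene models.

Builds a small simulated annotation (isoform families, one deliberately
split locus pair, coding-gene overlaps), excises protein-coding overlap
and clusters the survivors into non-redundant lncRNA genes.
"""

from lncscreen.annotation import cluster_into_genes, subtract_coding_overlap
from lncscreen.simulate import SimulationConfig, simulate_locus_set

cfg = SimulationConfig(seed=42, n_loci=12, split_locus_fraction=0.25,
                       coding_overlap_fraction=0.25)
genome, transcripts, coding, truth = simulate_locus_set(cfg)
print(f"simulated {len(transcripts)} transcripts on {len(genome)} chromosome(s)")

trimmed, report = subtract_coding_overlap(transcripts, coding, max_loss_fraction=0.70)
print(f"coding-overlap subtraction dropped {len(report['dropped_transcripts'])} "
      f"transcript(s) that lost >70% of their exonic bases")

genes = cluster_into_genes(trimmed)
print(f"clustered into {len(genes)} lncRNA genes\n")
print(f"{'gene_id':28s} {'members':>7s} {'exons':>5s} {'span':>6s} {'complexity':>10s}")
for g in genes[:8]:
    print(f"{g.gene_id:28s} {len(g.member_transcript_ids):7d} {g.n_exons:5d} "
          f"{g.span_bp:6d} {g.complexity:10d}")
print("...")
print("\nEach line is one putative functional unit: its merged exon count,")
print("genomic span (bp) and structural complexity (exons x span), the")
print("quantity that later scales how many gRNA arrays the gene receives.")
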