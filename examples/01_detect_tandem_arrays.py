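"""Detect tandem duplicated genes on a small simulated genome.

Plants four tandem arrays on two chromosomes, emulates the all-vs-all
protein search, and runs the detection pass (E < 1e-10, top 10 matches,
rank gap <= 1).  Prints the recovered clusters and the chromosome summary:
the counts/percentages say how many genes sit in tandem arrays and where.
"""

from tandemscape import (
    PlantedCluster,
    SimConfig,
    chromosome_distribution,
    detect,
    generate_genome,
    generate_homology_table,
    tdg_fraction,
    tdg_genes,
)
from tandemscape.tandem_finder import assign_ranks

sim = SimConfig(
    n_chromosomes=2,
    genes_per_chromosome=100,
    planted_clusters=[
        PlantedCluster(0, 5, 3, true_ks=0.6),
        PlantedCluster(0, 40, 9, true_ks=0.6),
        PlantedCluster(1, 10, 2, true_ks=0.6),
        PlantedCluster(1, 50, 5, true_ks=0.6),
    ],
    rng_seed=42,
)
genes, cds, proteins, manifest = generate_genome(sim)
hits = generate_homology_table(genes, manifest, noise=0.0)

clusters, pairs = detect(genes, hits, evalue_max=1e-10, top_n=10, max_gap=1)
tdgs = tdg_genes(clusters)
ranked = assign_ranks(genes)

print(f"genes: {len(genes)}, tandem pairs: {len(pairs)}, clusters: {len(clusters)}")
print(f"TDGs: {len(tdgs)} ({tdg_fraction(tdgs, ranked)}% of the gene set)")
for i, c in enumerate(clusters):
    print(f"  cluster {i}: {c.chromosome} size {c.size}: {', '.join(c.members)}")
print(chromosome_distribution(tdgs, ranked).to_string(index=False))
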