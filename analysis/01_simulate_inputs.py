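"""Generate the synthetic study inputs.

Emulates the wet-lab inputs of a genome-reduced bacterium study: a
circular 816,394 bp genome with 869 genes, planted interaction domains
every ~15 kb (boost 3), five replicate Hi-C libraries at 3 kb bins, a
deeper 10 kb map generated from a known 82-particle circular structure
(for 3D-recovery benchmarking), and a 869-gene x 282-sample expression
compendium with within-domain co-variation 0.5 over 141 conditions.

Writes everything under results/synthetic/.
"""

import json
from pathlib import Path

import numpy as np

import nucleoid3d as n3
from nucleoid3d import io as nio

SEED = 1
OUT = Path("results/synthetic")

GENOME_LENGTH = 816_394
N_GENES = 869
BIN_3KB = 3000
BIN_10KB = 10_000
BORDER_SPACING_BINS = 5       # ~15 kb domains at 3 kb bins
DOMAIN_BOOST = 3.0
DECAY_EXPONENT = -1.0
DEPTH_3KB = 50.0              # mean counts at 1-bin distance
DEPTH_STRUCTURE = 200.0       # mean counts for the closest particle pair
RHO_WITHIN = 0.5
N_CONDITIONS = 141


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    ann = n3.generate_genome_annotation(GENOME_LENGTH, N_GENES, BIN_3KB, seed=SEED)
    borders = np.arange(0, ann.n_bins - BORDER_SPACING_BINS + 1, BORDER_SPACING_BINS)
    truth = n3.PlantedTruth(n_bins=ann.n_bins, true_borders=borders,
                            decay_exponent=DECAY_EXPONENT, domain_boost=DOMAIN_BOOST,
                            noise_seed=SEED)
    print(f"genome: {GENOME_LENGTH} bp, {ann.n_bins} bins at {BIN_3KB} bp, "
          f"{len(ann.genes)} genes, {truth.true_borders.size} planted domains")

    nio.write_truth_json(truth, OUT / "truth.json")
    nio.write_bedgraph(ann.gc_track, BIN_3KB, OUT / "gc.bedgraph")
    nio.write_bedgraph(ann.site_track, BIN_3KB, OUT / "sites.bedgraph")
    with open(OUT / "genes.bed", "w") as fh:
        for k, (s, e, strand) in enumerate(ann.genes):
            fh.write(f"chr\t{s}\t{e}\tgene_{k}\t0\t{strand}\n")

    reps = n3.simulate_replicates(truth, 5, depth_variation=0.2, seed=SEED,
                                  mean_depth=DEPTH_3KB, bin_size=BIN_3KB)
    for r, m in enumerate(reps):
        nio.write_dense_matrix(m, OUT / f"replicate{r + 1}_3kb.tsv")
    pooled = n3.sum_replicates(reps)
    nio.write_dense_matrix(pooled, OUT / "pooled_3kb.tsv")
    print(f"5 replicate 3 kb maps, total counts "
          f"{[int(m.values.sum()) for m in reps]}")

    structure = n3.generate_true_structure(82, n3.particle_radius(BIN_10KB, 0.0201),
                                           seed=SEED)
    np.savetxt(OUT / "true_structure_nm.tsv", structure, delimiter="\t", fmt="%.3f")
    map10 = n3.contact_map_from_structure(structure, DEPTH_STRUCTURE, seed=SEED,
                                          bin_size=BIN_10KB)
    nio.write_dense_matrix(map10, OUT / "structure_map_10kb.tsv")
    nio.write_sparse_matrix(map10, OUT / "structure_map_10kb.triplets.tsv")
    print(f"10 kb structure-derived map: {map10.n_bins} bins, "
          f"{int(map10.values.sum())} total counts")

    expr = n3.simulate_expression(ann, borders, n_conditions=N_CONDITIONS,
                                  rho_within=RHO_WITHIN, seed=SEED)
    nio.write_expression(expr["matrix"], expr["gene_midpoints"], OUT / "expression.tsv")
    print(f"expression: {expr['matrix'].shape[0]} genes x {expr['matrix'].shape[1]} samples "
          f"({N_CONDITIONS} conditions), planted within-domain correlation {RHO_WITHIN}")

    (OUT / "parameters.json").write_text(json.dumps({
        "seed": SEED, "genome_length": GENOME_LENGTH, "n_genes": N_GENES,
        "bin_3kb": BIN_3KB, "bin_10kb": BIN_10KB, "domain_boost": DOMAIN_BOOST,
        "decay_exponent": DECAY_EXPONENT, "depth_3kb": DEPTH_3KB,
        "depth_structure": DEPTH_STRUCTURE, "rho_within": RHO_WITHIN,
        "n_conditions": N_CONDITIONS,
        "planted_borders": borders.tolist(),
    }, indent=1))


if __name__ == "__main__":
    main()
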