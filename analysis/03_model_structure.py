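"""Reconstruct the 3D chromosome from the 10 kb map and validate it.

Builds spatial restraints from the normalized structure-derived map
(0.0201 nm/bp scale, 250 nm proximal distance, -0.6/-0.2 z-score
cutoffs), samples 500 conformations by simulated annealing, keeps the
100 lowest-penalty models, clusters them (reflection-sensitive RMSD, so
mirror solutions separate), and reports: recovery of the generating
structure (Spearman of distance matrices), the model-map correlation,
ensemble geometry (length, width, prolate-ellipsoid volume), and the
centre-of-mass profile whose maxima mark the two poles.

Writes results/models/.
"""

import json
from pathlib import Path

import numpy as np
from scipy import stats

import nucleoid3d as n3
from nucleoid3d import io as nio

SEED = 1
IN_MAP = Path("results/hic/structure_map_10kb_normalized.tsv")
IN_TRUTH = Path("results/synthetic/true_structure_nm.tsv")
OUT = Path("results/models")

N_MODELS = 500
N_KEEP = 100


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    norm = nio.read_dense_matrix(IN_MAP)
    true = np.loadtxt(IN_TRUTH, delimiter="\t")

    config = n3.ModelingConfig(n_models=N_MODELS, n_keep=N_KEEP, seed=SEED)
    restraints = n3.build_restraints(norm, config)
    kinds = {0: "adjacent", 1: "attract", 2: "lower-bound"}
    counts = {kinds[k]: int((restraints.kind == k).sum()) for k in kinds}
    print(f"restraints: {counts}")

    ensemble = n3.optimize_ensemble(restraints, config)
    kept = n3.select_models(ensemble, N_KEEP)
    kept = n3.cluster_models(kept)
    nio.write_models_xyz(kept, norm.bin_size, OUT / "kept_models.xyz.tsv")

    sizes = np.bincount(kept.cluster_labels)
    print(f"kept {N_KEEP}/{N_MODELS} models; {sizes.size} structural clusters "
          f"(largest {sizes[0]})")

    td = np.sqrt(((true[:, None] - true[None, :]) ** 2).sum(-1))
    iu = np.triu_indices(norm.n_bins, 1)
    rho = float(stats.spearmanr(kept.median_distance_matrix()[iu], td[iu]).statistic)
    frac, corr = n3.model_contact_map(kept, reference=norm)
    np.savetxt(OUT / "model_contact_map.tsv", frac, delimiter="\t", fmt="%.3f")
    print(f"true-vs-ensemble distance Spearman {rho:.3f}; model-map Pearson {corr:.3f}")

    geo = n3.ensemble_geometry(kept)
    with open(OUT / "geometry.tsv", "w") as fh:
        fh.write("model\tlength_nm\twidth_nm\tvolume_um3\n")
        for m in range(kept.n_models):
            fh.write(f"{m}\t{geo['length_nm'][m]:.1f}\t{geo['width_nm'][m]:.1f}"
                     f"\t{geo['volume_um3'][m]:.4f}\n")
    print(f"median length {geo['median_length_nm']:.0f} nm, width "
          f"{geo['median_width_nm']:.0f} nm, volume {geo['median_volume_um3']:.3f} um^3")

    prof = n3.center_of_mass_profile(kept)["median"]
    nio.write_bedgraph(prof, norm.bin_size, OUT / "center_of_mass_profile.bedgraph")
    poles = np.argsort(prof)[-2:]
    print(f"centre-of-mass profile maxima at bins {sorted(poles.tolist())} "
          f"(origin pole at bin 0, opposite pole near bin {norm.n_bins // 2})")

    # distances between the six probe-like loci used for imaging comparison
    loci = {"ori": 0, "N1": 10, "right": 20, "N2": 30, "midpoint": 39, "N3": 50,
            "left": 61}
    ld = n3.locus_distances(kept, list(loci.values()))
    summary = {
        "n_models": N_MODELS, "n_keep": N_KEEP, "seed": SEED,
        "cluster_sizes": sizes.tolist(),
        "distance_spearman_vs_truth": rho,
        "model_map_pearson": corr,
        "median_length_nm": geo["median_length_nm"],
        "median_width_nm": geo["median_width_nm"],
        "median_volume_um3": geo["median_volume_um3"],
        "loci": loci,
        "locus_median_distances_nm": np.round(ld["median"], 1).tolist(),
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
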