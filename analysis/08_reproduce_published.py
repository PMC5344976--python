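"""Optional reproduction of the published analysis from deposited matrices.

Point this at a folder containing the archived dense contact matrices
(3 kb untreated and gyrase-inhibited maps, per-replicate 3 kb maps, and
optionally the pooled 10 kb map), e.g.:

    python analysis/08_reproduce_published.py --matrices-dir path/to/matrices \\
        --bic 1.0 --n-models 5000 --n-keep 1000

Matrix stems expected (extensions .tsv/.txt/.mat): stationary_3kb,
novobiocin_3kb, replicate{1..5}_3kb, stationary_10kb.  Rename or symlink
the deposited files accordingly.  The summary reports domain counts,
median sizes and confidences, cross-condition conservation, replicate
border conservation, and (if the 10 kb map is present) the model-map
correlation and ensemble geometry, next to the published targets and
their documented tolerances (see nucleoid3d.reproduce.TOLERANCES).
The BIC multiplier is exposed because the reference implementation's
effective penalty is not printed; matching the published domain counts
exactly may require tuning it.
"""

import argparse
import json

from nucleoid3d.reproduce import run_reproduction


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--matrices-dir", required=True)
    parser.add_argument("--out-dir", default="results/reproduction")
    parser.add_argument("--bic", type=float, default=1.0,
                        help="BIC penalty multiplier for domain calling")
    parser.add_argument("--n-models", type=int, default=5000)
    parser.add_argument("--n-keep", type=int, default=1000)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    summary = run_reproduction(args.matrices_dir, args.out_dir,
                               bic_multiplier=args.bic, n_models=args.n_models,
                               n_keep=args.n_keep, seed=args.seed)
    print(json.dumps({k: v for k, v in summary.items() if k != "tolerances"},
                     indent=1, default=str))


if __name__ == "__main__":
    main()
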