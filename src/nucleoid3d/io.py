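"""Plain-text readers/writers for matrices, tracks, segmentations and models.

Formats are deliberately simple and diff-friendly: dense and sparse
triplet TSV for contact matrices, BEDGRAPH for per-bin tracks, BED for
domain segmentations (0-based half-open), XYZ-style TSV for model
coordinates, and genes x samples TSV for expression.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .domains import DomainSegmentation
from .hic import ContactMatrix


def write_dense_matrix(matrix: ContactMatrix, path) -> None:
    header = {
        "bin_size": matrix.bin_size,
        "state": matrix.state,
        "total_reads": matrix.total_reads,
        "blacklist": sorted(matrix.blacklist),
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        np.savetxt(fh, matrix.values, delimiter="\t", fmt="%.10g")


def read_dense_matrix(path) -> ContactMatrix:
    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first[1:].strip()) if first.startswith("#") else {}
        values = np.loadtxt(fh if first.startswith("#") else path, delimiter="\t", ndmin=2)
    return ContactMatrix(
        values=values,
        bin_size=int(meta.get("bin_size", 1)),
        blacklist=frozenset(meta.get("blacklist", [])),
        state=meta.get("state", "raw"),
        total_reads=meta.get("total_reads"),
    )


def write_sparse_matrix(matrix: ContactMatrix, path) -> None:
    """Upper-triangle (incl. diagonal) nonzero cells as bin_i/bin_j/value TSV."""
    iu = np.triu_indices(matrix.n_bins)
    vals = matrix.values[iu]
    nz = vals != 0
    df = pd.DataFrame({"bin_i": iu[0][nz], "bin_j": iu[1][nz], "value": vals[nz]})
    with open(path, "w") as fh:
        fh.write(f"# n_bins={matrix.n_bins} bin_size={matrix.bin_size} state={matrix.state}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_sparse_matrix(path) -> ContactMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(kv.split("=") for kv in header[1:].split())
        df = pd.read_csv(fh, sep="\t")
    n = int(meta["n_bins"])
    m = np.zeros((n, n))
    m[df["bin_i"], df["bin_j"]] = df["value"]
    m = np.triu(m) + np.triu(m, 1).T
    return ContactMatrix(values=m, bin_size=int(meta["bin_size"]), state=meta.get("state", "raw"))


def write_blacklist(bins, path) -> None:
    Path(path).write_text("".join(f"{int(b)}\n" for b in sorted(bins)))


def read_blacklist(path) -> frozenset:
    text = Path(path).read_text().split()
    return frozenset(int(t) for t in text)


def write_bedgraph(track, bin_size: int, path, chrom: str = "chr") -> None:
    n = len(track)
    df = pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(n) * bin_size,
        "end": (np.arange(n) + 1) * bin_size,
        "value": np.asarray(track),
    })
    df.to_csv(path, sep="\t", index=False, header=False)


def read_bedgraph(path) -> tuple:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    bin_size = int(df["end"].iloc[0] - df["start"].iloc[0])
    return df["value"].to_numpy(), bin_size


def write_segmentation_bed(seg: DomainSegmentation, path, chrom: str = "chr") -> None:
    """One BED record per domain; score = 100 x the smaller flanking-border confidence."""
    rows = []
    conf = seg.confidence if seg.confidence is not None else np.full(seg.n_domains, 10)
    for k, (s, e) in enumerate(seg.domain_spans()):
        c1 = conf[k]
        c2 = conf[(k + 1) % seg.n_domains]
        rows.append({
            "chrom": chrom,
            "start": s * seg.bin_size,
            "end": min(e * seg.bin_size, seg.n_bins * seg.bin_size),
            "name": f"domain_{k}",
            "score": int(min(c1, c2)) * 100,
            "strand": ".",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_models_xyz(ensemble, bin_size: int, path) -> None:
    """All conformations as TSV records: model, particle, genomic start bp, x, y, z (nm)."""
    rows = []
    for m in range(ensemble.n_models):
        for p in range(ensemble.n_particles):
            x, y, z = ensemble.coords[m, p]
            rows.append((m, p, p * bin_size, x, y, z))
    df = pd.DataFrame(rows, columns=["model", "particle", "start_bp", "x_nm", "y_nm", "z_nm"])
    df.to_csv(path, sep="\t", index=False)


def write_expression(matrix, gene_midpoints, path) -> None:
    df = pd.DataFrame(matrix,
                      index=[f"gene_{k}" for k in range(len(gene_midpoints))],
                      columns=[f"sample_{s}" for s in range(np.asarray(matrix).shape[1])])
    df.insert(0, "midpoint_bp", np.asarray(gene_midpoints))
    df.to_csv(path, sep="\t", index_label="gene")


def read_expression(path) -> tuple:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    mids = df.pop("midpoint_bp").to_numpy()
    return df.to_numpy(), mids


def write_truth_json(truth, path) -> None:
    payload = {
        "n_bins": truth.n_bins,
        "true_borders": truth.true_borders.tolist(),
        "decay_exponent": truth.decay_exponent,
        "domain_boost": truth.domain_boost,
        "antidiagonal_eps": truth.antidiagonal_eps,
        "noise_seed": truth.noise_seed,
    }
    if truth.true_structure is not None:
        payload["true_structure"] = np.asarray(truth.true_structure).tolist()
    Path(path).write_text(json.dumps(payload, indent=1))
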