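"""Binned Hi-C contact matrices: construction, filtering, ICE balancing, scoring.

The container is a symmetric matrix of contact counts (or balanced scores)
between genomic bins on a circular chromosome.  Normalization follows the
iterative-correction (ICE) update

    m_ij <- m_ij * T / (r_i * r_j)

with T the grand total and r_i the bin totals, repeated until the maximum
relative deviation of the bin totals from their mean falls below a
tolerance (default 1e-5), and a final rescale of the balanced scores to
mean 1 over usable entries so magnitudes are comparable across maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from ._util import check_symmetric, circular_distance, n_bins_for

DEFAULT_ICE_TOLERANCE = 1e-5


@dataclass
class ContactMatrix:
    """Symmetric binned contact map on a circular genome.

    ``state`` tracks the processing stage: ``raw`` counts, ``filtered``
    (control-library artefacts removed), or ``normalized`` (ICE-balanced
    scores).  ``blacklist`` bins are excluded from normalization and all
    statistics; their rows/columns are retained so bin indexing is stable.
    """

    values: np.ndarray
    bin_size: int
    blacklist: frozenset = field(default_factory=frozenset)
    state: str = "raw"
    total_reads: float | None = None
    circular: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        check_symmetric(self.values, tol=1e-9)
        if np.any(self.values < 0):
            raise ValueError("contact values must be nonnegative")
        self.blacklist = frozenset(int(b) for b in self.blacklist)
        if any(b < 0 or b >= self.n_bins for b in self.blacklist):
            raise IndexError("blacklisted bin index out of range")
        if self.total_reads is None:
            self.total_reads = float(self.values.sum())

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def active_bins(self) -> np.ndarray:
        """Indices of non-blacklisted bins."""
        mask = np.ones(self.n_bins, dtype=bool)
        mask[list(self.blacklist)] = False
        return np.flatnonzero(mask)

    def active_mask(self) -> np.ndarray:
        mask = np.ones(self.n_bins, dtype=bool)
        mask[list(self.blacklist)] = False
        return mask

    def pair_mask(self, include_diagonal: bool = False) -> np.ndarray:
        """Boolean matrix of usable (non-blacklisted) cells."""
        m = self.active_mask()
        out = m[:, None] & m[None, :]
        if not include_diagonal:
            np.fill_diagonal(out, False)
        return out

    def distance_matrix(self) -> np.ndarray:
        idx = np.arange(self.n_bins)
        return circular_distance(idx[:, None], idx[None, :], self.n_bins)

    def copy(self, **changes) -> "ContactMatrix":
        out = replace(self, **{"values": self.values.copy(), **changes})
        return out


def bin_contacts(contacts, genome_length: int, bin_size: int) -> ContactMatrix:
    """Pool fragment-level contacts into a binned matrix.

    ``contacts`` is an iterable of ``(pos_i, pos_j, count)`` with positions
    in bp in ``[0, genome_length)``.  Counts are accumulated symmetrically;
    the total count is conserved exactly (a pair contributes once, on the
    cell ``(bin_i, bin_j)`` and its mirror).
    """
    n = n_bins_for(genome_length, bin_size)
    m = np.zeros((n, n))
    for rec_idx, (pi, pj, c) in enumerate(contacts):
        if not (0 <= pi < genome_length and 0 <= pj < genome_length):
            raise IndexError(
                f"contact record {rec_idx} has position outside [0, {genome_length}): ({pi}, {pj})"
            )
        bi, bj = int(pi // bin_size), int(pj // bin_size)
        m[bi, bj] += c
        if bi != bj:
            m[bj, bi] += c
    total = float(np.triu(m).sum())
    return ContactMatrix(values=m, bin_size=bin_size, state="raw", total_reads=total)


def classify_pairs(pairs, n_fragments: int) -> dict:
    """Partition read pairs into valid / non-ligation / self-ligation products.

    ``pairs`` is an iterable of ``(fragment_i, fragment_j, strand_i,
    strand_j)``.  Rules (standard Hi-C practice): reads on the same or
    circularly adjacent fragments facing inward (lower-index read on ``+``,
    higher on ``-``) are non-ligation (dangling-end/re-ligation) products;
    remaining same-fragment pairs are self-ligation circles; everything
    else is a valid product.  The partition is exhaustive and disjoint.
    """
    out = {"valid": [], "non_ligation": [], "self_ligation": []}
    for rec_idx, (fi, fj, si, sj) in enumerate(pairs):
        if not (0 <= fi < n_fragments and 0 <= fj < n_fragments):
            raise IndexError(f"pair record {rec_idx} has unknown fragment index ({fi}, {fj})")
        if si not in "+-" or sj not in "+-":
            raise ValueError(f"pair record {rec_idx} has invalid strand ({si!r}, {sj!r})")
        # canonical order: lower fragment index first
        if fi <= fj:
            lo_s, hi_s = si, sj
        else:
            lo_s, hi_s = sj, si
        gap = min(abs(fi - fj), n_fragments - abs(fi - fj))
        if abs(fi - fj) == n_fragments - 1 and n_fragments > 2:
            # adjacency across the circular origin: the higher fragment precedes
            inward = lo_s == "-" and hi_s == "+"
        else:
            inward = lo_s == "+" and hi_s == "-"
        if gap <= 1 and inward:
            out["non_ligation"].append((fi, fj, si, sj))
        elif fi == fj:
            out["self_ligation"].append((fi, fj, si, sj))
        else:
            out["valid"].append((fi, fj, si, sj))
    return out


def filter_with_control(
    matrix: ContactMatrix,
    control: ContactMatrix,
    affected_bins,
    quantile: float = 0.99,
) -> ContactMatrix:
    """Remove off-diagonal contacts supported by a non-crosslinked control.

    Among bin pairs with both ends in ``affected_bins`` and circular
    separation >= 2 (diagonal and first off-diagonal untouched), cells whose
    depth-normalized control value exceeds the given quantile of the
    control's off-diagonal values are zeroed.  Returns a ``filtered``
    matrix carrying the removed pairs and the fraction of matrix cells
    affected in ``.removed_pairs`` / ``.removed_fraction`` attributes.
    """
    if matrix.n_bins != control.n_bins or matrix.bin_size != control.bin_size:
        raise ValueError("matrix and control must share shape and bin size")
    affected = sorted(int(b) for b in affected_bins)
    n = matrix.n_bins
    out = matrix.copy(state="filtered")
    d = matrix.distance_matrix()
    ctrl = control.values / max(control.total_reads, 1e-300)
    offdiag = ctrl[d >= 2]
    removed = []
    if affected and offdiag.size:
        thresh = np.quantile(offdiag, quantile)
        for a_idx, i in enumerate(affected):
            for j in affected[a_idx + 1:]:
                if d[i, j] >= 2 and ctrl[i, j] > thresh:
                    out.values[i, j] = 0.0
                    out.values[j, i] = 0.0
                    removed.append((i, j))
    out.removed_pairs = removed
    out.removed_fraction = 2 * len(removed) / (n * n)
    return out


def ice_normalize(
    matrix: ContactMatrix,
    tolerance: float = DEFAULT_ICE_TOLERANCE,
    max_iter: int = 2000,
    n_iter: int | None = None,
    on_zero_total: str = "blacklist",
    rescale: bool = True,
) -> ContactMatrix:
    """Iterative-correction balancing of a contact matrix.

    Repeats ``m_ij <- m_ij * T / (r_i * r_j)`` over non-blacklisted bins
    until ``max_i |r_i - mean(r)| / mean(r) < tolerance``, or for exactly
    ``n_iter`` cycles when given (the domain caller uses a single cycle).
    Non-blacklisted bins with zero total are auto-blacklisted with a
    warning (``on_zero_total="blacklist"``) or raise
    (``on_zero_total="error"``).  With ``rescale`` the converged scores are
    divided by their mean over usable cells.
    """
    blacklist = set(matrix.blacklist)
    values = matrix.values.copy()
    n = matrix.n_bins

    def active():
        m = np.ones(n, dtype=bool)
        m[list(blacklist)] = False
        return m

    mask = active()
    totals = values[np.ix_(mask, mask)].sum(axis=1)
    zero = np.flatnonzero(mask)[totals <= 0]
    if zero.size:
        if on_zero_total == "error":
            raise ValueError(f"bins {zero.tolist()} have zero total and are not blacklisted")
        warnings.warn(f"auto-blacklisting zero-total bins {zero.tolist()}", stacklevel=2)
        blacklist.update(int(b) for b in zero)
        mask = active()
    if mask.sum() < 2:
        raise ValueError("need at least 2 non-blacklisted bins with positive totals")

    sub = values[np.ix_(mask, mask)]
    n_cycles = 0
    converged = n_iter is not None
    limit = n_iter if n_iter is not None else max_iter
    for _ in range(limit):
        r = sub.sum(axis=1)
        total = r.sum()
        sub = sub * total / np.outer(r, r)
        n_cycles += 1
        r = sub.sum(axis=1)
        err = np.max(np.abs(r - r.mean())) / r.mean()
        if n_iter is None and err < tolerance:
            converged = True
            break
    if not converged:
        r = sub.sum(axis=1)
        err = np.max(np.abs(r - r.mean())) / r.mean()
        warnings.warn(f"ICE did not converge in {max_iter} cycles; residual {err:.3g}", stacklevel=2)

    if rescale:
        offdiag = ~np.eye(mask.sum(), dtype=bool)
        mean_val = sub[offdiag].mean() if mask.sum() > 1 else sub.mean()
        if mean_val > 0:
            sub = sub / mean_val

    out_values = np.zeros_like(values)
    out_values[np.ix_(mask, mask)] = sub
    out = ContactMatrix(
        values=out_values,
        bin_size=matrix.bin_size,
        blacklist=frozenset(blacklist),
        state="normalized",
        total_reads=matrix.total_reads,
        circular=matrix.circular,
    )
    out.n_ice_cycles = n_cycles
    return out


def sum_replicates(matrices: list) -> ContactMatrix:
    """Depth-normalized sum of replicate maps (each divided by its total reads)."""
    if not matrices:
        raise ValueError("need at least one replicate")
    ref = matrices[0]
    acc = np.zeros_like(ref.values)
    blacklist = set()
    for m in matrices:
        if m.n_bins != ref.n_bins or m.bin_size != ref.bin_size or m.state != ref.state:
            raise ValueError("replicates must share shape, bin size and state")
        total = m.total_reads if m.total_reads else m.values.sum()
        if total <= 0:
            raise ValueError("replicate with zero total reads")
        acc = acc + m.values / total
        blacklist |= set(m.blacklist)
    return ContactMatrix(
        values=acc,
        bin_size=ref.bin_size,
        blacklist=frozenset(blacklist),
        state=ref.state,
        total_reads=float(acc.sum()),
        circular=ref.circular,
    )


def replicate_correlation(a: ContactMatrix, b: ContactMatrix) -> float:
    """Pearson correlation of two maps vectorized row-by-row.

    Blacklisted bins (union of both maps) are excluded pairwise.
    """
    if a.n_bins != b.n_bins:
        raise ValueError("matrices must share shape")
    mask = a.active_mask() & b.active_mask()
    sel = np.ix_(mask, mask)
    va, vb = a.values[sel].ravel(), b.values[sel].ravel()
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("undefined correlation: zero variance in a vectorized map")
    r, _ = stats.pearsonr(va, vb)
    return float(r)


@dataclass
class MmpReport:
    """Matrix-modelling-potential decomposition.

    A 0-1 score of how suitable a contact map is for accurate 3D
    reconstruction, combining matrix size, the number of eigenvalues
    exceeding the randomized-matrix background, and the shape (skewness /
    kurtosis) of the z-score distribution of log contact values.
    """

    mmp_score: float
    size_term: float
    eigenvector_term: float
    skewness_term: float
    kurtosis_term: float
    n_significant_eigenvectors: int
    predicted_accuracy: tuple  # (point estimate, lower, upper), correlation scale


#: default linear combination of MMP components; calibratable config
MMP_WEIGHTS = {
    "intercept": 0.10,
    "size": 0.20,
    "eigen": 0.50,
    "skewness": 0.10,
    "kurtosis": 0.10,
}


def mmp_score(
    matrix: ContactMatrix,
    n_randomizations: int = 10,
    seed: int = 0,
    weights: dict | None = None,
) -> MmpReport:
    """Score the modelling potential of a normalized contact map.

    z-scores are computed from log10 of the positive off-diagonal entries.
    The eigenvector term counts eigenvalues of the (z-scored) matrix larger
    than the maximum leading eigenvalue over ``n_randomizations`` shuffled
    matrices (upper-triangle entries permuted, resymmetrized).  Components
    are combined by a configurable linear map and clipped to [0, 1].
    """
    if matrix.n_bins < 8:
        raise ValueError("matrix too small for MMP scoring (< 8 bins)")
    w = dict(MMP_WEIGHTS, **(weights or {}))
    rng = np.random.default_rng(seed)
    mask = matrix.pair_mask(include_diagonal=False)
    vals = matrix.values[mask & np.triu(np.ones_like(mask), 1).astype(bool)]
    pos = vals[vals > 0]
    if pos.size < 8:
        raise ValueError("not enough positive entries for MMP scoring")
    logv = np.log10(pos)
    z = (logv - logv.mean()) / logv.std()
    skew = float(stats.skew(z))
    kurt = float(stats.kurtosis(z))

    # z-transformed full matrix for the spectral term
    active = matrix.active_bins()
    sub = matrix.values[np.ix_(active, active)].copy()
    with np.errstate(divide="ignore"):
        logm = np.where(sub > 0, np.log10(np.where(sub > 0, sub, 1.0)), np.nan)
    off = ~np.eye(len(active), dtype=bool)
    mu, sd = np.nanmean(logm[off]), np.nanstd(logm[off])
    zm = np.where(np.isnan(logm), 0.0, (logm - mu) / (sd if sd > 0 else 1.0))
    np.fill_diagonal(zm, 0.0)
    eigvals = np.sort(np.abs(np.linalg.eigvalsh(zm)))[::-1]

    iu = np.triu_indices(len(active), 1)
    null_max = []
    for _ in range(n_randomizations):
        shuf = zm[iu].copy()
        rng.shuffle(shuf)
        r = np.zeros_like(zm)
        r[iu] = shuf
        r = r + r.T
        null_max.append(np.max(np.abs(np.linalg.eigvalsh(r))))
    n_sig = int(np.sum(eigvals > max(null_max)))

    size_term = min(len(active), 250) / 250.0
    eigen_term = min(n_sig, 10) / 10.0
    skew_term = 1.0 / (1.0 + abs(skew))
    kurt_term = 1.0 / (1.0 + abs(kurt))
    score = float(
        np.clip(
            w["intercept"]
            + w["size"] * size_term
            + w["eigen"] * eigen_term
            + w["skewness"] * skew_term
            + w["kurtosis"] * kurt_term,
            0.0,
            1.0,
        )
    )
    # crude accuracy interval on the correlation scale, linear in the score
    acc = 0.1 + 0.8 * score
    report = MmpReport(
        mmp_score=score,
        size_term=size_term,
        eigenvector_term=eigen_term,
        skewness_term=skew_term,
        kurtosis_term=kurt_term,
        n_significant_eigenvectors=n_sig,
        predicted_accuracy=(acc, max(0.0, acc - 0.12), min(1.0, acc + 0.12)),
    )
    return report
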