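"""Gene-gene co-expression and its coupling to chromosome domains.

The co-expression tendency of two genes counts, over all unordered pairs
of samples, how often the genes change in the same direction minus how
often they change in opposite directions, normalized by the total number
of sample pairs.  Compared with the Pearson correlation, this basal
statistic is insensitive to the magnitude of expression shifts.  Ties
count to neither side but stay in the denominator, so constant profiles
score 0 and |value| <= 1 always.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._util import child_seed
from .domains import DomainSegmentation


@dataclass
class CoexpressionMatrix:
    """Symmetric gene x gene co-variation values in [-1, 1], unit diagonal."""

    values: np.ndarray
    gene_midpoints: np.ndarray  # bp
    method: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_midpoints = np.asarray(self.gene_midpoints, dtype=int)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or self.gene_midpoints.shape != (n,):
            raise ValueError("values must be square with one midpoint per gene")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("co-expression matrix must be symmetric")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("co-expression values must lie in [-1, 1]")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


def _collapse_replicates(expr: np.ndarray, condition_of) -> np.ndarray:
    condition_of = np.asarray(condition_of)
    conds = np.unique(condition_of)
    return np.column_stack([expr[:, condition_of == c].mean(axis=1) for c in conds])


def coexpression_tendency(expr, gene_midpoints, condition_of=None,
                          collapse_replicates: bool = False) -> CoexpressionMatrix:
    """Pairwise concordance of expression changes over sample pairs.

    For genes g, h and all unordered sample pairs (s, t): concordant when
    ``(g_s - g_t)(h_s - h_t) > 0``, discordant when ``< 0``; the value is
    (concordant - discordant) / total pairs.  With ``collapse_replicates``
    replicate columns of a condition are averaged first.  Constant genes
    score 0 against every other gene (logged note); diagonal is set to 1
    by convention.
    """
    expr = np.asarray(expr, dtype=float)
    if expr.ndim != 2 or expr.shape[0] < 2 or expr.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    if collapse_replicates:
        if condition_of is None:
            raise ValueError("collapse_replicates requires condition_of")
        expr = _collapse_replicates(expr, condition_of)
    n_genes, n_samples = expr.shape
    iu, jv = np.triu_indices(n_samples, 1)
    total_pairs = iu.size
    # sign of the change over every sample pair, per gene
    signs = np.sign(expr[:, iu] - expr[:, jv])
    values = (signs @ signs.T) / total_pairs
    constant = np.ptp(expr, axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s): tendency set to 0 against all genes",
            stacklevel=2,
        )
        values[constant, :] = 0.0
        values[:, constant] = 0.0
    np.fill_diagonal(values, 1.0)
    return CoexpressionMatrix(values=values, gene_midpoints=np.asarray(gene_midpoints),
                              method="tendency")


def pearson_coexpression(expr, gene_midpoints, condition_of=None,
                         collapse_replicates: bool = False) -> CoexpressionMatrix:
    """Product-moment correlation per gene pair (zero-variance genes -> 0)."""
    expr = np.asarray(expr, dtype=float)
    if expr.ndim != 2 or expr.shape[0] < 2 or expr.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    if collapse_replicates:
        if condition_of is None:
            raise ValueError("collapse_replicates requires condition_of")
        expr = _collapse_replicates(expr, condition_of)
    constant = np.std(expr, axis=1) == 0
    safe = expr.copy()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance gene(s): correlation set to 0", stacklevel=2
        )
        safe[constant] += np.arange(expr.shape[1])  # placeholder, rows zeroed below
    values = np.corrcoef(safe)
    values[constant, :] = 0.0
    values[:, constant] = 0.0
    np.fill_diagonal(values, 1.0)
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    return CoexpressionMatrix(values=values, gene_midpoints=np.asarray(gene_midpoints),
                              method="pearson")


def _gene_domains(coexpr: CoexpressionMatrix, segmentation: DomainSegmentation) -> np.ndarray:
    bins = (coexpr.gene_midpoints // segmentation.bin_size) % segmentation.n_bins
    return segmentation.domain_of_bin(bins)


def within_between_domains(coexpr: CoexpressionMatrix,
                           segmentation: DomainSegmentation) -> dict:
    """Mean |co-expression| for gene pairs within vs between domains.

    Genes are assigned to the domain of their midpoint bin.  Reports the
    global means, Mann-Whitney and Welch t-test p-values comparing the
    two pair populations, and per-domain within means (domains with fewer
    than 2 genes are excluded with a note).
    """
    dom = _gene_domains(coexpr, segmentation)
    n = coexpr.n_genes
    iu, jv = np.triu_indices(n, 1)
    vals = np.abs(coexpr.values[iu, jv])
    same = dom[iu] == dom[jv]
    within, between = vals[same], vals[~same]
    if within.size == 0 or between.size == 0:
        raise ValueError("need both within-domain and between-domain gene pairs")
    mw = stats.mannwhitneyu(within, between, alternative="greater")
    tt = stats.ttest_ind(within, between, equal_var=False, alternative="greater")
    per_domain = {}
    excluded = []
    for k in range(segmentation.n_domains):
        members = np.flatnonzero(dom == k)
        if members.size < 2:
            excluded.append(k)
            continue
        sub = np.abs(coexpr.values[np.ix_(members, members)])
        per_domain[k] = float(sub[np.triu_indices(members.size, 1)].mean())
    if excluded:
        warnings.warn(f"domains with <2 genes excluded from per-domain list: {excluded}",
                      stacklevel=2)
    between_mean = float(between.mean())
    return {
        "within_mean": float(within.mean()),
        "between_mean": between_mean,
        "mannwhitney_p": float(mw.pvalue),
        "ttest_p": float(tt.pvalue),
        "per_domain_within_mean": per_domain,
        "n_domains_above_between": int(sum(v > between_mean for v in per_domain.values())),
        "within_values": within,
        "between_values": between,
    }


def border_low_coexpression_test(coexpr: CoexpressionMatrix,
                                 segmentation: DomainSegmentation,
                                 n_perm: int = 1000, seed: int = 0,
                                 absolute: bool = True) -> dict:
    """Permutation test for depleted co-expression across domain borders.

    The observed statistic is the mean (|)co-expression(|) over gene
    pairs facing each other across a border: one gene in the last bin of
    the preceding domain, the other in the first bin of the following
    domain.  The null jointly rotates the border set; the p-value is
    lower-tail (fraction of null values <= observed).
    """
    n = segmentation.n_bins
    bins = (coexpr.gene_midpoints // segmentation.bin_size) % n
    genes_in_bin = {b: np.flatnonzero(bins == b) for b in range(n)}

    def statistic(borders):
        acc = []
        for b in borders:
            left = genes_in_bin.get((int(b) - 1) % n, np.array([], dtype=int))
            right = genes_in_bin.get(int(b) % n, np.array([], dtype=int))
            for g in left:
                for h in right:
                    if g != h:
                        v = coexpr.values[g, h]
                        acc.append(abs(v) if absolute else v)
        return float(np.mean(acc)) if acc else np.nan

    observed = statistic(segmentation.borders)
    if np.isnan(observed):
        raise ValueError("no gene pairs found at any domain border")
    rng = np.random.default_rng(child_seed(seed, 7))
    null = np.array([
        statistic((segmentation.borders + off) % n)
        for off in rng.integers(0, n, size=n_perm)
    ])
    valid = null[~np.isnan(null)]
    p = float(np.mean(valid <= observed)) if valid.size else 1.0
    return {"observed": observed, "null": null, "p_value": p, "n_permutations": n_perm}


def distance_stratified_coexpression(coexpr: CoexpressionMatrix,
                                     segmentation: DomainSegmentation,
                                     genome_length: int,
                                     max_distance: int = 30000,
                                     split_distance: int = 12000,
                                     bin_width: int = 3000) -> dict:
    """Mean |co-expression| vs circular genomic distance, stratified by CID.

    Gene pairs up to ``max_distance`` apart are bucketed by distance;
    curves are reported for same-CID pairs, cross-CID pairs and all
    pairs, plus a same-vs-cross contrast (Welch t-test) restricted to
    pairs closer than ``split_distance``.  Empty strata are reported as
    NaN, not errors.
    """
    dom = _gene_domains(coexpr, segmentation)
    n = coexpr.n_genes
    iu, jv = np.triu_indices(n, 1)
    raw = np.abs(coexpr.gene_midpoints[iu] - coexpr.gene_midpoints[jv])
    dist = np.minimum(raw, genome_length - raw)
    vals = np.abs(coexpr.values[iu, jv])
    same = dom[iu] == dom[jv]
    close = dist <= max_distance
    edges = np.arange(0, max_distance + bin_width, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0

    def curve(sel):
        out = np.full(centers.size, np.nan)
        for k in range(centers.size):
            inbin = sel & close & (dist >= edges[k]) & (dist < edges[k + 1])
            if inbin.any():
                out[k] = vals[inbin].mean()
        return out

    prox = close & (dist < split_distance)
    same_prox, cross_prox = vals[prox & same], vals[prox & ~same]
    contrast_p = np.nan
    if same_prox.size > 1 and cross_prox.size > 1:
        contrast_p = float(stats.ttest_ind(same_prox, cross_prox, equal_var=False,
                                           alternative="greater").pvalue)
    return {
        "distance_centers_bp": centers,
        "same_cid_curve": curve(same),
        "cross_cid_curve": curve(~same),
        "all_pairs_curve": curve(np.ones_like(same, dtype=bool)),
        "proximal_same_mean": float(same_prox.mean()) if same_prox.size else np.nan,
        "proximal_cross_mean": float(cross_prox.mean()) if cross_prox.size else np.nan,
        "proximal_contrast_p": contrast_p,
    }
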