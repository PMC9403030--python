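"""Between-gene and within-gene association machinery.

Implements the statistical toolbox used around the folding-specificity
statistic: rank-binned trends with correlation, bootstrap standard errors,
read down-sampling with a covariate-permutation test, per-gene pseudocounted
2x2 odds ratios (specificity vs conservation, OR1, or vs melting temperature,
OR2) with Mantel-Haenszel combination across genes, site-shuffle null
distributions with Kolmogorov-Smirnov comparison, exact binomial sign tests
and rank-sum group comparisons.

Scalar tests come from scipy; the Mantel-Haenszel common odds ratio and the
Cochran-Mantel-Haenszel chi-square are implemented explicitly (and
cross-checked against statsmodels in the test suite).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .io import AnchorRecord, GeneModel, bin_contact_map, build_contact_map
from .specificity import SiteSpecificityTrack, gene_specificity

__all__ = [
    "ContingencyTable",
    "TrendResult",
    "NullDistribution",
    "DownsampleResult",
    "binned_trend",
    "bootstrap_se",
    "downsample_specificity",
    "build_or_table",
    "odds_ratio",
    "mantel_haenszel",
    "shuffle_null",
    "sign_binomial_test",
    "group_compare",
    "spearman",
    "expression_tertiles",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """Pseudocounted 2x2 site-classification table for one gene.

    ``a``: high specificity & covariate "yes"; ``b``: high specificity only;
    ``c``: covariate "yes" only; ``d``: neither.  All cells include the +1
    pseudocount, so every cell is >= 1 and ``a+b+c+d = sites + 4``.
    """

    a: float
    b: float
    c: float
    d: float
    label: str = "OR1"
    gene_id: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 1:
            raise ValueError("cells must be >= 1 after pseudocount")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass
class TrendResult:
    """Equal-size rank-binned trend of y against x plus unbinned correlations."""

    bin_means: np.ndarray
    bin_se: np.ndarray
    bin_sizes: np.ndarray
    rho: float          # Spearman on unbinned data
    p: float
    pearson_r: float
    pearson_p: float
    rho_defined: bool = True


@dataclass
class NullDistribution:
    """Statistic values over shuffles, with the observed per-gene statistics
    and their two-sample KS comparison against the pooled null."""

    values: np.ndarray
    observed: np.ndarray
    seed: int
    reps: int
    ks_stat: float
    ks_p: float


@dataclass
class DownsampleResult:
    mean_rho: float
    p: float
    rho_per_rep: np.ndarray
    null_rho: np.ndarray
    genes_used: list[str]
    genes_excluded: list[str]


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Spearman rho and p; (0, nan, False) when either input is constant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0, float("nan"), False
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p), True


def binned_trend(x: Sequence[float], y: Sequence[float], n_bins: int = 20) -> TrendResult:
    """Mean +/- SE of y in equal-size rank bins of x, plus unbinned SCC/PCC.

    Bin sizes differ by at most one; the remainder goes to the leading bins.
    An undefined correlation (constant input) is reported as rho = 0 with
    ``rho_defined=False``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    n = len(x)
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} points, got {n}")
    order = np.argsort(x, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:rem] += 1
    means = np.empty(n_bins)
    ses = np.empty(n_bins)
    start = 0
    for b in range(n_bins):
        idx = order[start : start + sizes[b]]
        vals = y[idx]
        means[b] = vals.mean()
        ses[b] = vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0
        start += sizes[b]
    rho, p, defined = spearman(x, y)
    if defined:
        r, rp = sps.pearsonr(x, y)
    else:
        r, rp = 0.0, float("nan")
    return TrendResult(means, ses, sizes, rho, p, float(r), float(rp), defined)


def bootstrap_se(
    values: Sequence[float] | np.ndarray,
    stat: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> float:
    """SE of ``stat`` by resampling genes with replacement ``n_boot`` times."""
    values = np.asarray(values)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    n = len(values)
    reps = np.array([
        stat(values[rng.integers(0, n, n)]) for _ in range(n_boot)
    ])
    return float(reps.std(ddof=1))


def _gene_s_from_reads(
    records: Sequence[AnchorRecord], model: GeneModel, mode: str, halfwidth: int
) -> float:
    cmap = build_contact_map(records, model)
    if mode == "binned":
        cmap = bin_contact_map(cmap, halfwidth)
    res = gene_specificity(cmap, mode=mode)
    return res.s if res is not None else float("nan")


def downsample_specificity(
    records_by_gene: Mapping[str, Sequence[AnchorRecord]],
    models: Mapping[str, GeneModel],
    covariate: Mapping[str, float],
    k: int = 5,
    reps: int = 1000,
    seed: int = 0,
    mode: str = "binned",
    halfwidth: int = 10,
) -> DownsampleResult:
    """Down-sample each gene to ``k`` reads, recompute S, correlate with a
    per-gene covariate, and assess significance by covariate permutation.

    Each replicate samples ``k`` reads per gene without replacement and
    correlates the recomputed S with the covariate (Spearman); the observed
    statistic is the mean correlation over replicates.  The null statistic is
    of the same form: for each of ``reps`` covariate permutations, the mean
    over the same down-sampled replicates of the correlation with the
    permuted covariate (so observed and null are exchangeable under H0).  The
    p-value is the smoothed one-sided fraction
    ``(1 + #{null >= observed}) / (reps + 1)``.  Genes with fewer than ``k``
    reads are excluded with a log entry.
    """
    if k < 1 or reps < 1:
        raise ValueError("k and reps must be positive")
    used, excluded = [], []
    for gid in records_by_gene:
        if len(records_by_gene[gid]) >= k and gid in covariate:
            used.append(gid)
        else:
            excluded.append(gid)
    if excluded:
        logger.info("down-sampling: excluded %d gene(s) with < %d reads", len(excluded), k)
    if len(used) < 3:
        raise ValueError("need at least 3 genes with enough reads")
    rng = np.random.default_rng(seed)
    n = len(used)
    cov = np.array([covariate[g] for g in used])
    s_mat = np.empty((reps, n))
    for rep in range(reps):
        for gi, gid in enumerate(used):
            recs = records_by_gene[gid]
            idx = rng.choice(len(recs), size=k, replace=False)
            s_mat[rep, gi] = _gene_s_from_reads(
                [recs[i] for i in idx], models[gid], mode, halfwidth
            )
    # Spearman = Pearson on (tie-averaged) ranks; standardize rank rows so a
    # correlation is a dot product, and the mean over replicates collapses to
    # a single averaged rank vector.
    ranks = sps.rankdata(s_mat, axis=1)
    sd = ranks.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0  # replicate with all genes tied: rho contributes 0
    sd[flat] = 1.0
    z_s = (ranks - ranks.mean(axis=1, keepdims=True)) / sd
    z_s[flat] = 0.0

    def z_of(v: np.ndarray) -> np.ndarray:
        r = sps.rankdata(v)
        sdv = r.std()
        return np.zeros_like(r) if sdv == 0 else (r - r.mean()) / sdv

    z_cov = z_of(cov)
    rhos = z_s @ z_cov / n
    mean_rho = float(rhos.mean())
    z_bar = z_s.mean(axis=0)
    null = np.empty(reps)
    for b in range(reps):
        null[b] = z_bar @ z_of(rng.permutation(cov)) / n
    p = (1 + int((null >= mean_rho).sum())) / (reps + 1)
    return DownsampleResult(mean_rho, float(p), rhos, null, used, excluded)


# ---------------------------------------------------------------------------
# odds ratios

def build_or_table(
    site_s: SiteSpecificityTrack | np.ndarray,
    site_covariate: np.ndarray,
    orientation: str = "OR1",
    gene_id: str = "",
) -> ContingencyTable:
    """Cross-classify sites by specificity and a per-site covariate.

    A site is "high specificity" when its S strictly exceeds the mean S over
    the classified sites (ties at the mean go to the low class).  For OR1 the
    covariate axis is "strictly above its mean" (conservation); for OR2 it is
    "strictly below its mean" (melting temperature, so OR2 > 1 marks
    co-occurrence of low Tm and high specificity).  Each cell gets a +1
    pseudocount.  Only sites where both tracks are defined are classified.
    """
    s = site_s.s if isinstance(site_s, SiteSpecificityTrack) else np.asarray(site_s, float)
    cov = np.asarray(site_covariate, float)
    if s.shape != cov.shape:
        raise ValueError("site tracks must have equal length")
    ok = np.isfinite(s) & np.isfinite(cov)
    if not ok.any():
        raise ValueError("no common defined sites")
    s = s[ok]
    cov = cov[ok]
    hi_s = s > s.mean()
    if orientation == "OR1":
        hi_c = cov > cov.mean()
    elif orientation == "OR2":
        hi_c = cov < cov.mean()
    else:
        raise ValueError(f"orientation must be 'OR1' or 'OR2', got {orientation!r}")
    a = int(np.sum(hi_s & hi_c)) + 1
    b = int(np.sum(hi_s & ~hi_c)) + 1
    c = int(np.sum(~hi_s & hi_c)) + 1
    d = int(np.sum(~hi_s & ~hi_c)) + 1
    return ContingencyTable(a, b, c, d, label=orientation, gene_id=gene_id)


def odds_ratio(table: ContingencyTable) -> float:
    """``ad / bc`` of a pseudocounted table (always finite and positive)."""
    return (table.a * table.d) / (table.b * table.c)


def mantel_haenszel(
    tables: Sequence[ContingencyTable], correction: bool = True
) -> tuple[float, float, float]:
    """Mantel-Haenszel common odds ratio with the CMH chi-square test.

    Returns ``(OR_mh, chi2, p)`` where
    ``OR_mh = sum_i(a_i d_i / N_i) / sum_i(b_i c_i / N_i)`` and the chi-square
    uses the hypergeometric mean/variance of ``a_i`` with an optional 0.5
    continuity correction (the default, matching common practice).
    """
    if not tables:
        raise ValueError("need at least one table")
    num = sum(t.a * t.d / t.n for t in tables)
    den = sum(t.b * t.c / t.n for t in tables)
    or_mh = num / den
    a_sum = sum(t.a for t in tables)
    e_sum = sum((t.a + t.b) * (t.a + t.c) / t.n for t in tables)
    v_sum = sum(
        (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d) / (t.n**2 * (t.n - 1))
        for t in tables
    )
    dev = abs(a_sum - e_sum)
    if correction:
        dev = max(dev - 0.5, 0.0)
    chi2 = dev**2 / v_sum if v_sum > 0 else 0.0
    p = float(sps.chi2.sf(chi2, df=1))
    return float(or_mh), float(chi2), p


def expression_tertiles(expression: Mapping[str, float]) -> dict[str, list[str]]:
    """Split genes into equal-size rank tertiles of expression.

    Remainder genes go to the lower strata; returns {'low','mid','high'} lists.
    """
    genes = sorted(expression, key=lambda g: (expression[g], g))
    n = len(genes)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    out = {}
    start = 0
    for name, size in zip(("low", "mid", "high"), sizes):
        out[name] = genes[start : start + size]
        start += size
    return out


# ---------------------------------------------------------------------------
# null distributions

def shuffle_null(
    tracks: Mapping[str, tuple[np.ndarray, np.ndarray]],
    stat: str = "rho",
    reps: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Site-shuffle null for per-gene (specificity, covariate) tracks.

    ``tracks`` maps gene -> (per-site S, per-site covariate); undefined sites
    are NaN.  The observed statistic (within-gene Spearman rho, or the
    pseudocounted OR1) is computed per gene; each null replicate permutes the
    covariate over the gene's defined sites and recomputes it.  Genes whose
    statistic is undefined (constant track) are flagged and skipped.  Returns
    the pooled null together with a two-sample KS comparison against the
    observed per-gene values.
    """
    if stat not in ("rho", "OR"):
        raise ValueError(f"stat must be 'rho' or 'OR', got {stat!r}")
    rng = np.random.default_rng(seed)
    observed = []
    per_gene: list[tuple[np.ndarray, np.ndarray]] = []
    for gid, (s, cov) in tracks.items():
        s = np.asarray(s, float)
        cov = np.asarray(cov, float)
        ok = np.isfinite(s) & np.isfinite(cov)
        if ok.sum() < 3:
            continue
        sv, cv = s[ok], cov[ok]
        if stat == "rho":
            rho, _, defined = spearman(sv, cv)
            if not defined:
                logger.info("shuffle null: %s has a constant track, skipped", gid)
                continue
            observed.append(rho)
        else:
            observed.append(odds_ratio(build_or_table(sv, cv, gene_id=gid)))
        per_gene.append((sv, cv))
    if not per_gene:
        raise ValueError("no gene with enough defined sites")
    null = np.empty(reps * len(per_gene))
    pos = 0
    for _ in range(reps):
        for sv, cv in per_gene:
            perm = rng.permutation(cv)
            if stat == "rho":
                null[pos], _, _ = spearman(sv, perm)
            else:
                null[pos] = odds_ratio(build_or_table(sv, perm))
            pos += 1
    observed_arr = np.asarray(observed)
    ks = sps.ks_2samp(observed_arr, null)
    return NullDistribution(
        null, observed_arr, seed, reps, float(ks.statistic), float(ks.pvalue)
    )


def sign_binomial_test(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value (minimum-likelihood method)."""
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"invalid counts k={k}, n={n}")
    return float(sps.binomtest(k, n, p0).pvalue)


def group_compare(
    x: Sequence[float], y: Sequence[float], test: str = "mann_whitney"
) -> tuple[float, float]:
    """Two-sided rank-sum comparison of two groups; returns (U, p).

    ``test`` accepts 'mann_whitney' or 'wilcoxon_rank_sum' (the same
    statistic under its other common name).  An all-tied degenerate input
    raises a ValueError flag.
    """
    if test not in ("mann_whitney", "wilcoxon_rank_sum"):
        raise ValueError(f"unknown test {test!r}")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate all-tied input")
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
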