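"""Time-course differential expression without replicates.

Libraries are normalized by relative log expression (RLE): each library's
size factor is the median, over genes positive in every library, of the
ratio of its count to the gene's across-library geometric mean, rescaled so
the factors' geometric mean is 1.

Because each regeneration time window was sequenced once, per-timepoint
testing is exact and conditional: given the total count of a timepoint/
control pair, the timepoint count is binomial with success probability
proportional to the effective library sizes (the Poisson two-sample exact
test). When two control replicates are available, a common negative-binomial
dispersion is estimated from them by conditional maximum likelihood on
counts adjusted to a common library size (the qCML idea), and the exact test
conditions on the adjusted pair total under that NB model; dispersion zero
reduces exactly to the Poisson test.

Two-sided p-values use minimum-likelihood ordering: the probabilities of all
outcomes no more likely than the observed one are summed ("doubled tail"
available as an alternative). A gene is called significant in a comparison
when its Benjamini-Hochberg adjusted p is below alpha AND its |log2 fold
change| (on pseudocounted normalized counts) exceeds the cutoff; batches are
analyzed separately, each timepoint against its own batch's control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .models import CountMatrix

DEFAULT_ALPHA = 0.001
DEFAULT_LFC_CUTOFF = 0.7
DEFAULT_PSEUDOCOUNT = 0.5
_LOG_TIE_TOL = 1e-9  # relative tolerance when comparing outcome likelihoods


@dataclass
class DispersionEstimate:
    phi: float
    method: str = "qCML"

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("dispersion must be non-negative")


# ---------------------------------------------------------------------------
# Normalization


def rle_size_factors(counts) -> pd.Series:
    """Median-of-ratios (RLE) size factors, geometric mean rescaled to 1.

    Genes with a zero count in any library are excluded from the geometric-
    mean reference. Accepts a CountMatrix or a genes x libraries DataFrame.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if counts.shape[1] < 2:
        raise ValueError("need at least two libraries")
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every library")
    logs = np.log(mat[positive])
    log_geomean = logs.mean(axis=1)
    log_ratios = logs - log_geomean[:, None]
    log_factors = np.median(log_ratios, axis=0)
    log_factors = log_factors - log_factors.mean()  # geometric mean -> 1
    return pd.Series(np.exp(log_factors), index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# Exact tests


def _minlik_pvalue(logpmf: np.ndarray, observed: int) -> float:
    """Two-sided exact p by minimum-likelihood ordering."""
    cutoff = logpmf[observed] + _LOG_TIE_TOL
    return float(min(1.0, np.exp(logsumexp(logpmf[logpmf <= cutoff]))))


def _doubled_tail_pvalue(logpmf: np.ndarray, observed: int) -> float:
    pmf = np.exp(logpmf - logsumexp(logpmf))
    lower = pmf[: observed + 1].sum()
    upper = pmf[observed:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def exact_poisson_test(
    c1: int, c2: int, s1: float = 1.0, s2: float = 1.0, tail: str = "minlik"
) -> float:
    """Two-sample exact Poisson test.

    Conditional on n = c1 + c2, c1 is binomial(n, s1/(s1+s2)); the two-sided
    p-value sums outcome probabilities no larger than the observed one.
    Invariant under rescaling both sizes; n = 0 gives p = 1.
    """
    if c1 < 0 or c2 < 0:
        raise ValueError("counts must be non-negative")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("sizes must be positive")
    n = c1 + c2
    if n == 0:
        return 1.0
    p = s1 / (s1 + s2)
    k = np.arange(n + 1)
    logpmf = (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + k * np.log(p)
        + (n - k) * np.log1p(-p)
    )
    if tail == "minlik":
        return _minlik_pvalue(logpmf, c1)
    if tail == "doubled":
        return _doubled_tail_pvalue(logpmf, c1)
    raise ValueError(f"unknown tail rule {tail!r}")


def _quantile_adjust(counts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Deterministic proportional scaling of counts to the geometric-mean
    library size (the stochastic-rounding-free stand-in for full quantile
    adjustment)."""
    sizes = np.asarray(sizes, dtype=float)
    common = np.exp(np.mean(np.log(sizes)))
    return np.rint(np.asarray(counts, dtype=float) * (common / sizes)).astype(np.int64)


def exact_nb_test(
    c1: int,
    c2: int,
    s1: float = 1.0,
    s2: float = 1.0,
    phi: float = 0.0,
    tail: str = "minlik",
) -> float:
    """Exact two-sample negative-binomial test with common dispersion phi.

    Counts are first adjusted to a common library size; conditional on the
    adjusted total z, the first count follows the NB conditional law
    P(k | z) ∝ C(k+r-1, k) C(z-k+r-1, z-k) with r = 1/phi, which is free of
    the mean. phi = 0 is exactly the Poisson test (no adjustment needed:
    conditioning Poisson on the total gives the size-proportional binomial).
    """
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    if phi == 0:
        return exact_poisson_test(c1, c2, s1, s2, tail=tail)
    if c1 < 0 or c2 < 0:
        raise ValueError("counts must be non-negative")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("sizes must be positive")
    y1, y2 = _quantile_adjust(np.array([c1, c2]), np.array([s1, s2]))
    z = int(y1 + y2)
    if z == 0:
        return 1.0
    r = 1.0 / phi
    k = np.arange(z + 1)
    logpmf = (
        gammaln(k + r)
        - gammaln(k + 1)
        + gammaln(z - k + r)
        - gammaln(z - k + 1)
    )
    logpmf = logpmf - logsumexp(logpmf)
    if tail == "minlik":
        return _minlik_pvalue(logpmf, int(y1))
    if tail == "doubled":
        return _doubled_tail_pvalue(logpmf, int(y1))
    raise ValueError(f"unknown tail rule {tail!r}")


# ---------------------------------------------------------------------------
# Common dispersion (qCML)


def _conditional_loglik(phi: float, y1: np.ndarray, y2: np.ndarray) -> float:
    """Sum over genes of the exact NB conditional log-likelihood given the
    per-gene totals, for two equal-size libraries."""
    z = y1 + y2
    if phi <= 0:
        # Poisson limit: y1 | z ~ Binomial(z, 1/2)
        ll = (
            gammaln(z + 1)
            - gammaln(y1 + 1)
            - gammaln(y2 + 1)
            - z * np.log(2.0)
        )
        return float(ll.sum())
    r = 1.0 / phi
    ll = (
        gammaln(y1 + r)
        - gammaln(y1 + 1)
        + gammaln(y2 + r)
        - gammaln(y2 + 1)
        - 2.0 * gammaln(r)
        + gammaln(2.0 * r)
        - gammaln(z + 2.0 * r)
        + gammaln(z + 1)
    )
    return float(ll.sum())


def estimate_common_dispersion_qcml(
    control_counts, sizes=None, phi_max: float = 10.0
) -> DispersionEstimate:
    """Common NB dispersion from two replicate control libraries.

    Counts are adjusted to the geometric-mean library size (deterministic
    proportional scaling), then the conditional likelihood given per-gene
    totals is maximized over phi in [0, phi_max] by bounded 1-D search,
    comparing against the Poisson boundary.
    """
    counts = np.asarray(control_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("need exactly two control libraries (genes x 2)")
    if sizes is None:
        sizes = counts.sum(axis=0)
    sizes = np.asarray(sizes, dtype=float)
    common = np.exp(np.mean(np.log(sizes)))
    adj = np.rint(counts * (common / sizes)[None, :]).astype(np.int64)
    y1, y2 = adj[:, 0], adj[:, 1]
    keep = (y1 + y2) > 0
    y1, y2 = y1[keep], y2[keep]
    if y1.size == 0:
        raise ValueError("all genes have zero total count")

    res = minimize_scalar(
        lambda phi: -_conditional_loglik(phi, y1, y2),
        bounds=(1e-8, phi_max),
        method="bounded",
        options={"xatol": 1e-6},
    )
    phi_hat = float(res.x)
    if _conditional_loglik(0.0, y1, y2) >= -res.fun:
        phi_hat = 0.0
    return DispersionEstimate(phi=phi_hat, method="qCML")


# ---------------------------------------------------------------------------
# Fold changes and calling


def log2_fc(
    c_t: float, c_0: float, s_t: float = 1.0, s_0: float = 1.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """log2 of pseudocounted normalized counts: timepoint vs control."""
    if s_t <= 0 or s_0 <= 0:
        raise ValueError("sizes must be positive")
    return float(np.log2((c_t / s_t + pseudocount) / (c_0 / s_0 + pseudocount)))


def adjust_and_call(
    cm: CountMatrix,
    size_factors: pd.Series | None = None,
    alpha: float = DEFAULT_ALPHA,
    lfc_cutoff: float = DEFAULT_LFC_CUTOFF,
    test: str = "poisson",
    phi: float | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    tail: str = "minlik",
) -> pd.DataFrame:
    """Run every timepoint-vs-batch-control comparison and call significance.

    Benjamini-Hochberg adjustment is applied within each comparison; a gene
    is significant in a comparison iff padj < alpha and |lfc| > lfc_cutoff.
    ``test`` is "poisson" or "nb" (the latter requires ``phi``, typically
    from :func:`estimate_common_dispersion_qcml`). Returns one row per gene
    per comparison.
    """
    if test not in ("poisson", "nb"):
        raise ValueError("test must be 'poisson' or 'nb'")
    if test == "nb" and phi is None:
        raise ValueError("nb test requires a dispersion estimate")
    if size_factors is None:
        size_factors = rle_size_factors(cm)
    frames = []
    genes = cm.counts.index.to_numpy()
    for lib in cm.timepoint_libraries():
        ctl = cm.control_for(lib)
        s_t, s_0 = float(size_factors[lib]), float(size_factors[ctl])
        ct = cm.counts[lib].to_numpy()
        c0 = cm.counts[ctl].to_numpy()
        if test == "poisson":
            pvals = np.array(
                [exact_poisson_test(a, b, s_t, s_0, tail=tail) for a, b in zip(ct, c0)]
            )
        else:
            pvals = np.array(
                [exact_nb_test(a, b, s_t, s_0, phi=phi, tail=tail) for a, b in zip(ct, c0)]
            )
        padj = multipletests(pvals, method="fdr_bh")[1]
        lfc = np.log2((ct / s_t + pseudocount) / (c0 / s_0 + pseudocount))
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "library": lib,
                    "time_window": cm.libraries[lib].time_window,
                    "control": ctl,
                    "lfc": lfc,
                    "pvalue": pvals,
                    "padj": padj,
                    "significant": (padj < alpha) & (np.abs(lfc) > lfc_cutoff),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def significant_genes(results: pd.DataFrame) -> list[str]:
    """Union over comparisons of genes significant at one or more
    timepoints."""
    return sorted(results.loc[results["significant"], "gene_id"].unique())


def lfc_matrix(results: pd.DataFrame, genes: list[str] | None = None) -> pd.DataFrame:
    """Genes x timepoint-libraries matrix of log2 fold changes (input to
    temporal classification)."""
    wide = results.pivot(index="gene_id", columns="library", values="lfc")
    order = [lib for lib in results["library"].unique()]
    wide = wide[order]
    if genes is not None:
        wide = wide.loc[genes]
    return wide
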