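"""TMM normalization and negative-binomial GLM likelihood-ratio testing.

The factorial design (genotype x treatment, log link) is fitted per gene by
iteratively reweighted least squares, vectorized across genes.  Dispersions
are estimated by maximizing the Cox-Reid adjusted profile likelihood (APL):
a common value over all genes, a trend over average-abundance bins, and
tagwise values shrunk towards the trend by weighting the local mean APL with
``prior_n``.  Effects are tested with likelihood-ratio chi-square tests of
nested designs, and the three effect gene lists (genotype, treatment,
interaction) are assembled with the inclusive p <= alpha threshold, the
chromosome exclusion for the genotype list, and removal of
interaction-significant genes from both main-effect lists.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from deeptag.containers import CountMatrix

logger = logging.getLogger(__name__)

LOG2 = np.log(2.0)
_ETA_MIN, _ETA_MAX = -15.0, 30.0
_POISSON_PHI = 1e-12


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: CountMatrix | pd.DataFrame,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions.  For each sample, per-gene
    log2-ratios M and average log2-abundances A are computed over genes
    expressed in both the sample and the reference, the most extreme
    ``trim_M`` of M values and ``trim_A`` of A values are trimmed on each
    side, and the factor is 2 to the precision-weighted mean of the
    retained M values.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    y = counts.to_numpy(dtype=float)
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample must have a positive library size")
    f75 = np.quantile(y, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = y[:, ref_idx]
    factors = np.ones(y.shape[1])
    for s in range(y.shape[1]):
        if s == ref_idx:
            continue
        obs = y[:, s]
        both = (obs > 0) & (ref > 0)
        if not both.any():
            raise ValueError(
                f"sample {counts.columns[s]!r} shares no expressed gene with the reference"
            )
        p_obs = obs[both] / lib[s]
        p_ref = ref[both] / lib[ref_idx]
        M = np.log2(p_obs / p_ref)
        A = 0.5 * np.log2(p_obs * p_ref)
        finite = np.isfinite(M) & np.isfinite(A)
        M, A = M[finite], A[finite]
        yo, yr = obs[both][finite], ref[both][finite]
        n = len(M)
        # double trim: rank-based, keeping the central part of each scale
        loM, hiM = np.floor(n * trim_M) + 1, n + 1 - (np.floor(n * trim_M) + 1)
        loA, hiA = np.floor(n * trim_A) + 1, n + 1 - (np.floor(n * trim_A) + 1)
        rM = stats.rankdata(M, method="average")
        rA = stats.rankdata(A, method="average")
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if not keep.any():
            factors[s] = 1.0
            continue
        # asymptotic variance of M (delta method) -> precision weights
        var = (lib[s] - yo) / (lib[s] * yo) + (lib[ref_idx] - yr) / (lib[ref_idx] * yr)
        w = 1.0 / var[keep]
        factors[s] = 2.0 ** (np.sum(w * M[keep]) / np.sum(w))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def build_design(samples: pd.DataFrame, model: str = "interaction") -> pd.DataFrame:
    """Design matrix for the 2x2 factorial (treatment coding, log link).

    ``model="additive"`` gives intercept + genotype + treatment (the
    main-effects model); ``model="interaction"`` adds the product column.
    """
    g = (samples["genotype"].astype(str) == "MUT").astype(float)
    t = (samples["treatment"].astype(str) == "CSD").astype(float)
    cols = {"intercept": np.ones(len(samples)), "genotype": g, "treatment": t}
    if model == "interaction":
        cols["genotype:treatment"] = g * t
    elif model != "additive":
        raise ValueError("model must be 'additive' or 'interaction'")
    return pd.DataFrame(cols, index=samples.index)


# ---------------------------------------------------------------------------
# NB GLM fitting (vectorized IRLS)
# ---------------------------------------------------------------------------

@dataclass
class GLMFit:
    """Per-gene NB GLM fit for one shared design matrix."""

    coef: np.ndarray  # (G, p), natural-log scale
    mu: np.ndarray  # (G, n) fitted means
    loglik: np.ndarray  # (G,)
    converged: np.ndarray  # (G,) bool
    cr_logdet: np.ndarray  # (G,) log det of X' W X at the fit
    design: pd.DataFrame


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row sums of the NB log-likelihood (Poisson branch for phi ~ 0)."""
    phi = np.broadcast_to(np.atleast_1d(phi).astype(float)[:, None], y.shape)
    mu = np.maximum(mu, 1e-300)
    pois = phi[:, 0] < _POISSON_PHI
    out = np.empty(y.shape[0])
    if pois.any():
        yp, mp = y[pois], mu[pois]
        out[pois] = (yp * np.log(mp) - mp - gammaln(yp + 1)).sum(axis=1)
    if (~pois).any():
        yn, mn, pn = y[~pois], mu[~pois], phi[~pois]
        r = 1.0 / pn
        ll = (
            gammaln(yn + r)
            - gammaln(r)
            - gammaln(yn + 1)
            + yn * np.log(pn * mn / (1 + pn * mn))
            - r * np.log1p(pn * mn)
        )
        out[~pois] = ll.sum(axis=1)
    return out


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    phi = np.broadcast_to(np.atleast_1d(phi).astype(float)[:, None], y.shape)
    mu = np.maximum(mu, 1e-300)
    phi_safe = np.maximum(phi, _POISSON_PHI)
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
        nb_tail = (y + 1.0 / phi_safe) * (np.log1p(phi_safe * y) - np.log1p(phi_safe * mu))
        tail = np.where(phi < _POISSON_PHI, y - mu, nb_tail)
    return 2.0 * (ylogy - tail).sum(axis=1)


def fit_nb_glm(
    y: np.ndarray,
    design: pd.DataFrame | np.ndarray,
    dispersion: float | np.ndarray,
    offset: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GLMFit:
    """Fit one NB log-link GLM per gene by IRLS, all genes at once.

    Parameters
    ----------
    y
        (G, n) count matrix.
    design
        (n, p) full-rank design matrix shared by all genes.
    dispersion
        NB dispersion, scalar or per-gene array; 0 selects the Poisson limit.
    offset
        (n,) per-sample offset, normally ``log(library_size * tmm_factor)``.
    """
    if isinstance(design, pd.DataFrame):
        X = design.to_numpy(dtype=float)
        design_df = design
    else:
        X = np.asarray(design, dtype=float)
        design_df = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    G, n = y.shape
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    phi = np.broadcast_to(np.atleast_1d(np.asarray(dispersion, dtype=float)), (G,)).copy()
    offset = np.asarray(offset, dtype=float)

    z0 = np.log(y + 0.5) - offset
    beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T  # (G, p)
    dev = np.full(G, np.inf)
    converged = np.zeros(G, dtype=bool)
    phi_col = phi[:, None]
    for _ in range(max_iter):
        eta = np.clip(offset + beta @ X.T, _ETA_MIN, _ETA_MAX)
        mu = np.exp(eta)
        w = mu / (1.0 + phi_col * mu)
        z = (eta - offset) + (y - mu) / mu
        XtWX = np.einsum("gn,ni,nj->gij", w, X, X, optimize=True)
        XtWz = np.einsum("gn,ni,gn->gi", w, X, z, optimize=True)
        try:
            beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.array(
                [np.linalg.lstsq(XtWX[g], XtWz[g], rcond=None)[0] for g in range(G)]
            )
        beta = beta_new
        dev_new = _nb_deviance(y, np.exp(np.clip(offset + beta @ X.T, _ETA_MIN, _ETA_MAX)), phi)
        converged = np.abs(dev_new - dev) < tol * (np.abs(dev_new) + 1.0)
        dev = dev_new
        if converged.all():
            break
    eta = np.clip(offset + beta @ X.T, _ETA_MIN, _ETA_MAX)
    mu = np.exp(eta)
    w = mu / (1.0 + phi_col * mu)
    XtWX = np.einsum("gn,ni,nj->gij", w, X, X, optimize=True)
    sign, logdet = np.linalg.slogdet(XtWX)
    logdet = np.where(sign > 0, logdet, -np.inf)
    return GLMFit(beta, mu, nb_loglik(y, mu, phi), converged, logdet, design_df)


def adjusted_profile_loglik(
    y: np.ndarray, design: pd.DataFrame | np.ndarray, phi: float, offset: np.ndarray
) -> np.ndarray:
    """Per-gene Cox-Reid APL at dispersion ``phi``: loglik - 0.5 logdet(X'WX)."""
    fit = fit_nb_glm(y, design, phi, offset)
    return fit.loglik - 0.5 * fit.cr_logdet


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionModel:
    """Common / trended / tagwise NB dispersions with APL shrinkage."""

    common: float
    trended: pd.Series
    tagwise: pd.Series
    prior_n: float
    abundance: pd.Series = field(repr=False)  # average log2 CPM per gene

    def __post_init__(self) -> None:
        if self.common < 0 or (self.trended < 0).any() or (self.tagwise < 0).any():
            raise ValueError("dispersions must be nonnegative")


def average_log_cpm(y: np.ndarray, effective_lib: np.ndarray) -> np.ndarray:
    cpm = (y + 0.5) / (effective_lib + 1.0) * 1e6
    return np.log2(cpm.mean(axis=1))


def _golden_max(f, lo: float, hi: float, iters: int = 30) -> float:
    """Golden-section maximum of f on [lo, hi] (deterministic)."""
    invphi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2


def _quadratic_peak(xs: np.ndarray, ys: np.ndarray) -> float:
    """Vertex of the parabola through the grid max and its neighbours."""
    i = int(np.argmax(ys))
    if i == 0 or i == len(xs) - 1:
        return float(xs[i])
    x0, x1, x2 = xs[i - 1 : i + 2]
    y0, y1, y2 = ys[i - 1 : i + 2]
    denom = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
    if denom == 0:
        return float(x1)
    vertex = x1 - 0.5 * ((x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)) / denom
    return float(np.clip(vertex, x0, x2))


def estimate_dispersions(
    counts: CountMatrix | pd.DataFrame,
    design: pd.DataFrame,
    offset: np.ndarray | None = None,
    prior_n: float = 10.0,
    n_bins: int | None = None,
    grid: np.ndarray | None = None,
) -> DispersionModel:
    """Cox-Reid dispersion estimation with empirical-Bayes shrinkage.

    The common dispersion maximizes the summed APL over a log-spaced grid
    with golden-section refinement.  The trend is estimated within
    average-abundance bins: each gene's local APL curve is the
    abundance-interpolated mean APL of its neighbouring bins, and the
    trended dispersion is that curve's maximizer.  The tagwise dispersion
    maximizes ``APL_g + prior_n * APL_local,g``, so ``prior_n -> inf``
    recovers the trend and ``prior_n = 0`` gives the unshrunk tagwise
    estimate.
    """
    if isinstance(counts, CountMatrix):
        genes = counts.genes
        y = counts.counts.to_numpy(dtype=float)
    else:
        genes = counts.index
        y = counts.to_numpy(dtype=float)
    n_samples, p = design.shape
    if n_samples - p < 1:
        raise ValueError("no residual degrees of freedom: replicates are required")
    if offset is None:
        offset = np.log(y.sum(axis=0))
    if grid is None:
        grid = np.logspace(-4, np.log10(5.0), 19)
    log_grid = np.log(grid)

    apl = np.column_stack([adjusted_profile_loglik(y, design, phi, offset) for phi in grid])

    # common dispersion: grid bracket + golden-section refinement
    total = apl.sum(axis=0)
    i = int(np.argmax(total))
    lo = log_grid[max(i - 1, 0)]
    hi = log_grid[min(i + 1, len(grid) - 1)]
    if i in (0, len(grid) - 1):
        common = float(grid[i])
    else:
        f = lambda lphi: float(adjusted_profile_loglik(y, design, np.exp(lphi), offset).sum())
        common = float(np.exp(_golden_max(f, lo, hi, iters=25)))

    # abundance bins and the local (trend) APL curve per gene
    abundance = average_log_cpm(y, np.exp(offset))
    G = len(abundance)
    if n_bins is None:
        n_bins = int(np.clip(G // 100, 1, 20))
    order = np.argsort(abundance, kind="stable")
    bin_of = np.empty(G, dtype=int)
    bin_of[order] = np.arange(G) * n_bins // G
    centers = np.array([abundance[bin_of == b].mean() for b in range(n_bins)])
    bin_curves = np.vstack([apl[bin_of == b].mean(axis=0) for b in range(n_bins)])

    if n_bins == 1:
        local = np.repeat(bin_curves, G, axis=0)
    else:
        hi_bin = np.clip(np.searchsorted(centers, abundance), 1, n_bins - 1)
        lo_bin = hi_bin - 1
        span = centers[hi_bin] - centers[lo_bin]
        lam = np.where(span > 0, (abundance - centers[lo_bin]) / np.where(span == 0, 1, span), 0.0)
        lam = np.clip(lam, 0.0, 1.0)
        local = (1 - lam)[:, None] * bin_curves[lo_bin] + lam[:, None] * bin_curves[hi_bin]

    trended = np.exp([_quadratic_peak(log_grid, local[g]) for g in range(G)])
    objective = apl + prior_n * local
    tagwise = np.exp([_quadratic_peak(log_grid, objective[g]) for g in range(G)])

    return DispersionModel(
        common=common,
        trended=pd.Series(trended, index=genes, name="trended_dispersion"),
        tagwise=pd.Series(tagwise, index=genes, name="tagwise_dispersion"),
        prior_n=prior_n,
        abundance=pd.Series(abundance, index=genes, name="ave_log_cpm"),
    )


# ---------------------------------------------------------------------------
# Likelihood ratio test and list assembly
# ---------------------------------------------------------------------------

def _is_nested(full: np.ndarray, reduced: np.ndarray) -> bool:
    rank_full = np.linalg.matrix_rank(full)
    return np.linalg.matrix_rank(np.hstack([full, reduced])) == rank_full


def lrt_test(
    counts: CountMatrix | pd.DataFrame,
    full_design: pd.DataFrame,
    reduced_design: pd.DataFrame,
    dispersion: float | np.ndarray | pd.Series,
    offset: np.ndarray,
    coef: str | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio test of nested NB GLMs, per gene.

    Returns a DataFrame with the log2 fold change of ``coef`` (default: the
    column of the full design absent from the reduced design), the LRT
    statistic, its degrees of freedom and the chi-square p-value.  Genes
    whose full-model fit failed to converge get a missing p.
    """
    if isinstance(counts, CountMatrix):
        genes, y = counts.genes, counts.counts.to_numpy(dtype=float)
    else:
        genes, y = counts.index, counts.to_numpy(dtype=float)
    Xf = full_design.to_numpy(dtype=float)
    Xr = reduced_design.to_numpy(dtype=float)
    if not _is_nested(Xf, Xr):
        raise ValueError("reduced design is not nested in the full design")
    df = np.linalg.matrix_rank(Xf) - np.linalg.matrix_rank(Xr)
    if isinstance(dispersion, pd.Series):
        dispersion = dispersion.reindex(genes).to_numpy()
    full = fit_nb_glm(y, full_design, dispersion, offset)
    red = fit_nb_glm(y, reduced_design, dispersion, offset)
    lrt = np.maximum(2.0 * (full.loglik - red.loglik), 0.0)
    # df = 0 (designs of equal rank, e.g. full == reduced): statistic 0, p 1
    p = stats.chi2.sf(lrt, df) if df >= 1 else np.ones_like(lrt)
    if df < 1:
        lrt = np.zeros_like(lrt)
    ok = full.converged & red.converged
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} gene(s) failed to converge; p set missing", stacklevel=2)
        p = np.where(ok, p, np.nan)
    if coef is None:
        extra = [c for c in full_design.columns if c not in reduced_design.columns]
        coef = extra[-1] if extra else full_design.columns[-1]
    j = list(full_design.columns).index(coef)
    return pd.DataFrame(
        {
            "log2FC": full.coef[:, j] / LOG2,
            "LRT": lrt,
            "df": df,
            "p_value": p,
            "converged": ok,
        },
        index=pd.Index(genes, name="gene"),
    )


@dataclass
class EffectLists:
    """The three thresholded gene lists with the assembly rules applied."""

    genotype: set[str]
    csd: set[str]
    interaction: set[str]
    alpha: float
    excluded_chromosomes: tuple[str, ...] = ("8",)


def assemble_effect_lists(
    genotype_result: pd.DataFrame,
    csd_result: pd.DataFrame,
    interaction_result: pd.DataFrame,
    chromosomes: pd.Series,
    alpha: float = 0.005,
    exclude_chromosomes: tuple[str, ...] = ("8",),
    interaction_exclusion: bool = True,
) -> EffectLists:
    """Threshold the three effect tables and apply the exclusion rules.

    Genes with p <= ``alpha`` (inclusive) enter each list; genes on the
    excluded chromosomes are removed from the genotype list only; genes
    passing the interaction threshold are removed from the genotype and
    treatment lists (they may not reflect a pure main effect).
    """
    def hits(res: pd.DataFrame) -> set[str]:
        return set(res.index[res["p_value"] <= alpha])

    geno, csd, inter = hits(genotype_result), hits(csd_result), hits(interaction_result)
    missing = [g for g in geno if g not in chromosomes.index or pd.isna(chromosomes.loc[g])]
    if missing:
        raise ValueError(f"genotype-list genes without chromosome annotation: {sorted(missing)[:10]}")
    excluded = set(str(c) for c in exclude_chromosomes)
    geno = {g for g in geno if str(chromosomes.loc[g]) not in excluded}
    if interaction_exclusion:
        geno -= inter
        csd -= inter
    return EffectLists(geno, csd, inter, alpha, tuple(exclude_chromosomes))
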