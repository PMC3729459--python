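"""Pooled moderated linear modelling of PE and gestational-age effects.

Per probe pair g the pooled, transformed transcription values are fitted to

    y_g = X b_g + eps_g,   X columns: intercept, study dummies (reference
    study 1), PE indicator, gestational age in weeks, optionally PE x GA,

by ordinary least squares.  Residual variances are then moderated with the
empirical-Bayes hierarchical model

    s_g^2 | sigma_g^2 ~ sigma_g^2 chi2_{d_g} / d_g,
    1 / sigma_g^2 ~ chi2_{d0} / (d0 s0^2),

whose posterior variance is the precision-weighted blend
s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g).  The moderated t-statistic
beta / (s~_g * u_j) (u_j the unscaled coefficient standard error) follows a
t-distribution with d0 + d_g degrees of freedom under the null.  The prior
(d0, s0^2) is estimated by moment matching on log s_g^2 via digamma /
trigamma identities (Newton inversion of the trigamma function).

Multiplicity control is Bonferroni at alpha / m with m the number of probe
pairs in the family (not transcripts), with Benjamini-Hochberg step-up
q-values alongside.  "Fold change" is reported as sign(beta) * 2^|beta| on
the transformed scale — a reporting convention, since the inverse-normal
scale is not literally log2 of abundance.

The proportion pi0 of non-differentially-expressed features is estimated as
f(1) of the maximum-likelihood convex decreasing density f fitted to the
p-value distribution (mixture of triangular densities and the uniform).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .exceptions import (
    DegeneratePriorError,
    InsufficientDFError,
    InvalidArgumentError,
    InvalidInputError,
    ConsistencyError,
    RankDeficiencyError,
)
from .probe_mapping import ProbePairTable

logger = logging.getLogger(__name__)

DESIGN_COLUMN_ORDER = ["intercept", "study2", "study3", "pe", "ga_weeks", "pe_x_ga"]


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(metadata: pd.DataFrame, include_interaction: bool = False) -> pd.DataFrame:
    """Design matrix with fixed column order from a sample metadata table.

    Study dummies use the lowest study label as reference and are dropped for
    single-study input; a PE column with no variation (e.g. a control-only
    study) is dropped, as is its interaction.  Collinear designs raise
    :class:`RankDeficiencyError` naming the offending columns.
    """
    required = {"sample_id", "study", "pe", "ga_weeks"}
    missing = required - set(metadata.columns)
    if missing:
        raise InvalidInputError(f"metadata missing columns {sorted(missing)}")
    if metadata[list(required)].isna().to_numpy().any():
        raise InvalidInputError("metadata contains missing covariate values")

    n = len(metadata)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    studies = sorted(metadata["study"].unique())
    for s in studies[1:]:
        # dummies are named by position: the 2nd and 3rd represented study
        name = f"study{studies.index(s) + 1}"
        cols[name] = (metadata["study"] == s).to_numpy(float)
    pe = metadata["pe"].to_numpy(float)
    if not set(np.unique(pe)) <= {0.0, 1.0}:
        raise InvalidInputError("pe must be coded 0/1")
    if pe.min() != pe.max():
        cols["pe"] = pe
    else:
        logger.info("build_design: PE constant (=%g); column dropped", pe[0])
    ga = metadata["ga_weeks"].to_numpy(float)
    if ga.min() != ga.max():
        cols["ga_weeks"] = ga
    else:
        logger.info("build_design: GA constant; column dropped")
    if include_interaction:
        if "pe" in cols and "ga_weeks" in cols:
            cols["pe_x_ga"] = pe * ga
        else:
            logger.info("build_design: interaction dropped with its main effect")

    order = [c for c in DESIGN_COLUMN_ORDER if c in cols] + [
        c for c in cols if c not in DESIGN_COLUMN_ORDER
    ]
    design = pd.DataFrame({c: cols[c] for c in order}, index=metadata["sample_id"])
    X = design.to_numpy(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, design.columns)
        raise RankDeficiencyError(bad)
    return design


def _collinear_columns(X: np.ndarray, names) -> list[str]:
    full_rank = np.linalg.matrix_rank(X)
    bad = []
    for j in range(X.shape[1]):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            bad.append(names[j])
    return bad or list(names)


# ---------------------------------------------------------------------------
# per-feature OLS
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    """Per-feature OLS results for a common design."""

    feature_ids: pd.Index
    coef_names: list[str]
    beta: np.ndarray            # features x coefficients
    sigma: np.ndarray           # residual SD s_g per feature
    df_resid: int               # d_g = n - p, shared (common design)
    stdev_unscaled: np.ndarray  # sqrt(diag((X'X)^-1)), per coefficient


def fit_linear(pooled: pd.DataFrame, design: pd.DataFrame) -> LinearFit:
    """Ordinary least squares of every pooled row on the shared design."""
    if list(pooled.columns) != list(design.index):
        if set(pooled.columns) != set(design.index):
            raise InvalidInputError("pooled samples and design rows disagree")
        design = design.loc[pooled.columns]
    Y = pooled.to_numpy(float).T          # samples x features
    X = design.to_numpy(float)
    n, p = X.shape
    if n <= p:
        raise InsufficientDFError(f"n={n} samples <= p={p} parameters")
    if np.linalg.matrix_rank(X) < p:
        raise RankDeficiencyError(_collinear_columns(X, list(design.columns)))

    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ Y)    # p x features
    resid = Y - X @ beta
    df = n - p
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma = np.sqrt(np.maximum(rss, 0.0) / df)
    xtx_inv = np.linalg.inv(R.T @ R)
    return LinearFit(
        feature_ids=pooled.index,
        coef_names=list(design.columns),
        beta=beta.T,
        sigma=sigma,
        df_resid=df,
        stdev_unscaled=np.sqrt(np.diag(xtx_inv)),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def estimate_variance_prior(sigma2: np.ndarray, df_resid: int) -> tuple[float, float]:
    """Moment-matching fit of the scaled-F model s^2 ~ s0^2 F(d_g, d0).

    Works on z = log s^2, whose mean and variance involve digamma/trigamma of
    the degrees of freedom; the excess dispersion of z beyond trigamma(d_g/2)
    identifies d0 through the trigamma inverse.  Returns (d0, s0_sq); d0 is
    ``inf`` when the observed dispersion does not exceed the sampling floor,
    in which case all variances are shrunk to s0_sq.
    """
    sigma2 = np.asarray(sigma2, float)
    positive = sigma2 > 0
    if not positive.any():
        raise DegeneratePriorError("all residual variances are zero")
    if not positive.all():
        logger.info(
            "variance prior estimated from %d/%d features with s_g > 0",
            int(positive.sum()), sigma2.size,
        )
        sigma2 = sigma2[positive]
    if sigma2.size < 2:
        raise DegeneratePriorError("need >= 2 positive variances to fit the prior")

    z = np.log(sigma2)
    half_d = df_resid / 2.0
    e = z - float(special.digamma(half_d)) + np.log(half_d)
    n = z.size
    e_mean = float(e.mean())
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1))
    excess = e_var - float(special.polygamma(1, half_d))
    if excess <= 0:
        # no excess dispersion: point-mass prior at the (geometric) mean
        # observed variance, so identical s_g^2 shrink to themselves
        return np.inf, float(np.exp(np.mean(z)))
    half_d0 = trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


@dataclass
class ModeratedFitResult:
    """Moderated statistics per feature and coefficient."""

    feature_ids: pd.Index
    coef_names: list[str]
    beta: np.ndarray        # features x coefficients
    t: np.ndarray
    p: np.ndarray
    d0: float
    s0_sq: float
    df_resid: int
    df_total: float
    post_var: np.ndarray    # s~_g^2 per feature
    sigma: np.ndarray = field(default=None)

    def coefficient_frame(
        self, coefficient: str, m: int | None = None, alpha: float = 0.05
    ) -> pd.DataFrame:
        """Per-feature results table for one coefficient, with adjusted
        p-values over a family of size ``m`` (default: features tested)."""
        j = self.coef_names.index(coefficient)
        p = self.p[:, j]
        m_eff = len(p) if m is None else m
        bonf, _ = adjust_pvalues(p, m=m_eff, method="bonferroni", alpha=alpha)
        bh, _ = adjust_pvalues(p, m=m_eff, method="bh", alpha=alpha)
        return pd.DataFrame(
            {
                "beta": self.beta[:, j],
                "fold_change": signed_fold_change(self.beta[:, j]),
                "t": self.t[:, j],
                "p": p,
                "bonferroni_p": bonf,
                "bh_q": bh,
            },
            index=self.feature_ids,
        )


def ebayes_moderate(fit: LinearFit, d0_override: float | None = None) -> ModeratedFitResult:
    """Apply empirical-Bayes variance moderation to per-feature OLS fits.

    ``d0_override`` forces the prior df (0 reproduces ordinary t-statistics;
    ``inf`` gives the z-like limit); by default (d0, s0^2) are estimated from
    the observed residual variances.  Features with zero residual variance
    (interpolating fits) receive the prior variance, avoiding infinite
    statistics.
    """
    sigma2 = fit.sigma**2
    if d0_override is None:
        d0, s0_sq = estimate_variance_prior(sigma2, fit.df_resid)
    else:
        d0 = float(d0_override)
        if d0 < 0:
            raise InvalidArgumentError("d0 must be >= 0")
        _, s0_sq = estimate_variance_prior(sigma2, fit.df_resid)

    if np.isinf(d0):
        post_var = np.full_like(sigma2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        post_var = sigma2.copy()
        zero = post_var == 0
        post_var[zero] = s0_sq  # interpolating fits: fall back to the prior
        df_total = float(fit.df_resid)
    else:
        post_var = (d0 * s0_sq + fit.df_resid * sigma2) / (d0 + fit.df_resid)
        df_total = d0 + fit.df_resid

    se = np.sqrt(post_var)[:, None] * fit.stdev_unscaled[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.beta / se
    t = np.where(se == 0, 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    return ModeratedFitResult(
        feature_ids=fit.feature_ids,
        coef_names=fit.coef_names,
        beta=fit.beta,
        t=t,
        p=p,
        d0=d0,
        s0_sq=s0_sq,
        df_resid=fit.df_resid,
        df_total=df_total,
        post_var=post_var,
        sigma=fit.sigma,
    )


# ---------------------------------------------------------------------------
# multiplicity adjustment and reporting conventions
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, m: int) -> tuple[float, str]:
    """The family-wise threshold alpha/m, exact and formatted to 3 s.f."""
    if not 0 < alpha < 1:
        raise InvalidArgumentError("alpha must lie in (0, 1)")
    if m < 1:
        raise InvalidArgumentError("family size m must be >= 1")
    exact = alpha / m
    return exact, f"{exact:.3g}"


def adjust_pvalues(
    p, m: int | None = None, method: str = "bonferroni", alpha: float = 0.05
) -> tuple[np.ndarray, float]:
    """Adjust p-values over a family of size m (m >= len(p) allowed).

    Bonferroni returns min(1, m p) with the significance threshold alpha/m;
    ``bh`` returns Benjamini-Hochberg step-up adjusted values, monotone
    non-decreasing in p.  Supporting m larger than the tested vector lets a
    subset analysis stay calibrated against the full probe-pair family.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise InvalidArgumentError("empty p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InvalidInputError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise InvalidArgumentError("family size m cannot be smaller than len(p)")

    if method == "bonferroni":
        return np.minimum(1.0, m * p), alpha / m
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order]
        scaled = m * ranked / np.arange(1, p.size + 1)
        q = np.minimum.accumulate(scaled[::-1])[::-1]
        out = np.empty_like(q)
        out[order] = np.minimum(q, 1.0)
        return out, alpha / m
    raise InvalidArgumentError(f"unknown adjustment method {method!r}")


def signed_fold_change(beta) -> np.ndarray:
    """Report a coefficient as a signed fold change: 2^beta for beta >= 0,
    -2^(-beta) for beta < 0, so |FC| >= 1 and the sign gives direction."""
    beta = np.asarray(beta, dtype=float)
    if not np.isfinite(beta).all():
        raise InvalidArgumentError("beta must be finite")
    return np.where(beta >= 0, np.exp2(beta), -np.exp2(-beta))


# ---------------------------------------------------------------------------
# proportion of non-differentially-expressed features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pi0Estimate:
    pi0: float
    coefficient: str = ""
    method: str = "convex-decreasing-mle"


def _tent_density_matrix(p: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Columns: uniform density then triangular densities
    f_theta(x) = 2 (theta - x)_+ / theta^2 for a grid of theta in (0, 1]."""
    F = np.empty((p.size, theta.size + 1))
    F[:, 0] = 1.0
    diff = theta[None, :] - p[:, None]
    F[:, 1:] = np.where(diff > 0, 2.0 * diff / theta[None, :] ** 2, 0.0)
    return F


def estimate_pi0(
    p,
    coefficient: str = "",
    grid_size: int = 100,
    n_bins: int = 512,
    tol: float = 1e-12,
    max_iter: int = 30000,
) -> Pi0Estimate:
    """Estimate the non-DE fraction as f(1) of the convex decreasing density
    MLE of the p-value distribution.

    Any convex decreasing density on [0, 1] is a mixture of the uniform and
    triangular densities 2(theta - x)_+ / theta^2, theta in (0, 1]; only the
    uniform has positive mass at 1, so pi0 = f(1) is the fitted uniform
    weight.  Mixture weights are driven to the maximum-likelihood solution by
    EM over a theta grid; the p-values are binned first (the mixture
    densities are smooth, so fine histogram cells lose nothing of note while
    making each EM sweep O(bins x grid)).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise InvalidArgumentError("empty p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InvalidInputError("p-values must lie in [0, 1]")

    counts, edges = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    mids = 0.5 * (edges[:-1] + edges[1:])
    occupied = counts > 0
    mids, bin_w = mids[occupied], counts[occupied] / p.size

    theta = np.linspace(1.0 / grid_size, 1.0, grid_size)
    F = _tent_density_matrix(mids, theta)
    k = F.shape[1]
    w = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    for _ in range(max_iter):
        mix = np.maximum(F @ w, 1e-300)
        ll = float(bin_w @ np.log(mix))
        w = w * (F.T @ (bin_w / mix))
        w /= w.sum()
        if ll - prev_ll < tol * max(1.0, abs(ll)):
            break
        prev_ll = ll
    pi0 = float(np.clip(w[0], 0.0, 1.0))
    return Pi0Estimate(pi0=pi0, coefficient=coefficient)


# ---------------------------------------------------------------------------
# transcript-level summaries
# ---------------------------------------------------------------------------

def summarize_transcript_level(
    results: pd.DataFrame,
    pairs: ProbePairTable,
    alpha: float = 0.05,
) -> dict:
    """Count Bonferroni-significant pairs and the distinct transcripts and
    genes they represent.

    ``results`` is a coefficient frame indexed by pair id (as produced by
    :meth:`ModeratedFitResult.coefficient_frame` on pooled fits) carrying a
    ``bonferroni_p`` column.
    """
    if "bonferroni_p" not in results.columns:
        raise InvalidInputError("results must carry a bonferroni_p column")
    lookup = pairs.table.copy()
    lookup.index = pairs.pair_ids
    unknown = results.index.difference(lookup.index)
    if len(unknown):
        raise ConsistencyError(f"pair ids absent from pair table: {list(unknown[:5])}")
    sig = results.index[results["bonferroni_p"] < alpha]
    rows = lookup.loc[lookup.index.isin(sig)]
    return {
        "n_significant_pairs": int(len(sig)),
        "n_transcripts": int(rows["transcript_id"].nunique()),
        "n_genes": int(rows["gene_symbol"].nunique()),
    }
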