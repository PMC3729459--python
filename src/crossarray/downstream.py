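"""Model-comparison and concordance analyses.

Two questions about the pooled analysis are examined here:

* **Linear vs dichotomized gestational age.**  Earlier work categorised
  gestational age as mid-gestation vs term, while the pooled model treats it
  as a continuous per-week covariate.  ``compare_ga_models`` refits the same
  (control-only) study both ways and correlates the per-feature log2FC
  vectors; agreement (Pearson r near 1) justifies the linear treatment,
  which interpolates across the full gestational range.

* **Cross-study concordance.**  ``per_study_fit`` reruns the moderated
  analysis on a single study; ``concordance`` compares two result sets by
  the Pearson correlation of their log2FC vectors, the overlap of their
  top-K most significant features, and how many of one analysis's top K are
  nominally significant (p < 0.05) in the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import diffexpr
from .diffexpr import ModeratedFitResult
from .exceptions import InvalidArgumentError, InvalidInputError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gestational-age dichotomization
# ---------------------------------------------------------------------------

def dichotomize_ga(
    metadata: pd.DataFrame,
    mid_max: float = 24.0,
    term_min: float = 37.0,
) -> pd.Series:
    """Binary GA covariate: 0 for mid-gestation (GA <= mid_max), 1 for term
    (GA >= term_min); samples in the gap are excluded (logged).

    Returns a 0/1 series indexed by the retained sample ids.
    """
    if not mid_max < term_min:
        raise InvalidArgumentError("mid_max must be below term_min")
    ga = metadata.set_index("sample_id")["ga_weeks"].astype(float)
    mid = ga.index[ga <= mid_max]
    term = ga.index[ga >= term_min]
    excluded = ga.index.difference(mid.union(term))
    if len(excluded):
        logger.info(
            "dichotomize_ga: %d samples between %g and %g weeks excluded: %s",
            len(excluded), mid_max, term_min, list(excluded),
        )
    if len(mid) == 0 or len(term) == 0:
        raise InvalidArgumentError("dichotomization leaves an empty GA group")
    kept = ga.index[(ga <= mid_max) | (ga >= term_min)]
    return pd.Series((ga.loc[kept] >= term_min).astype(int), index=kept)


@dataclass
class GAComparisonReport:
    """Per-feature linear (per-week) vs dichotomized (term-vs-mid contrast)
    GA coefficients and their Pearson correlation."""

    table: pd.DataFrame  # columns: beta_linear, beta_dichot
    r: float
    n_features: int
    n_excluded_samples: int


def compare_ga_models(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    mid_max: float = 24.0,
    term_min: float = 37.0,
) -> GAComparisonReport:
    """Fit GA continuously and dichotomized on the same matrix and correlate
    the per-feature log2FC vectors.

    Intended for control-only input (the matrix's samples must match the
    metadata); the continuous model uses all samples, the dichotomized model
    only those at or below ``mid_max`` / at or above ``term_min`` weeks.
    """
    meta = metadata[metadata["sample_id"].isin(matrix.columns)].copy()
    if len(meta) != matrix.shape[1]:
        raise InvalidInputError("matrix columns missing from metadata")

    # the comparison is between coefficient vectors; moderation rescales
    # t-statistics but leaves the coefficients untouched, so plain OLS
    # suffices (and keeps the noise-free case, where every residual variance
    # is zero, well defined)
    design_lin = diffexpr.build_design(meta)
    fit_lin = diffexpr.fit_linear(matrix, design_lin)

    dichot = dichotomize_ga(meta, mid_max=mid_max, term_min=term_min)
    meta_d = meta[meta["sample_id"].isin(dichot.index)].copy()
    meta_d["ga_weeks"] = dichot.loc[meta_d["sample_id"]].to_numpy()
    design_d = diffexpr.build_design(meta_d)
    fit_d = diffexpr.fit_linear(matrix[list(meta_d["sample_id"])], design_d)

    j_lin = fit_lin.coef_names.index("ga_weeks")
    j_d = fit_d.coef_names.index("ga_weeks")
    table = pd.DataFrame(
        {"beta_linear": fit_lin.beta[:, j_lin], "beta_dichot": fit_d.beta[:, j_d]},
        index=matrix.index,
    )
    r = float(stats.pearsonr(table["beta_dichot"], table["beta_linear"])[0])
    return GAComparisonReport(
        table=table,
        r=r,
        n_features=len(table),
        n_excluded_samples=len(meta) - len(meta_d),
    )


# ---------------------------------------------------------------------------
# per-study refits and concordance
# ---------------------------------------------------------------------------

def per_study_fit(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    include_interaction: bool = False,
) -> ModeratedFitResult:
    """Moderated fit restricted to one study: same machinery as the pooled
    fit, with the design adapting to the covariates the study supports (no
    study dummies; PE dropped for a control-only study)."""
    meta = metadata[metadata["sample_id"].isin(matrix.columns)]
    if len(meta) != matrix.shape[1]:
        raise InvalidInputError("matrix columns missing from metadata")
    if meta["study"].nunique() != 1:
        raise InvalidArgumentError("per_study_fit expects samples from one study")
    design = diffexpr.build_design(meta, include_interaction=include_interaction)
    return diffexpr.ebayes_moderate(
        diffexpr.fit_linear(matrix[list(design.index)], design)
    )


@dataclass
class ConcordanceReport:
    r: float
    n_features: int
    K: int
    shared_top_k: int
    a_top_nominal_in_b: int
    b_top_nominal_in_a: int
    top_k_a: list
    top_k_b: list


def _top_k(frame: pd.DataFrame, K: int) -> list:
    # deterministic: ascending p, ties broken by feature id
    ranked = frame.assign(_fid=frame.index).sort_values(
        ["p", "_fid"], kind="mergesort"
    )
    return list(ranked.index[:K])


def concordance(
    result_a: ModeratedFitResult | pd.DataFrame,
    result_b: ModeratedFitResult | pd.DataFrame,
    coefficient: str = "pe",
    K: int = 100,
    nominal_alpha: float = 0.05,
) -> ConcordanceReport:
    """Compare two analyses of the same coefficient.

    Accepts moderated fit results (or coefficient frames with ``beta`` and
    ``p`` columns); computes Pearson r of the log2FC vectors over the
    feature intersection, the number of features shared between the two
    top-K lists (ranked by ascending p, ties broken by feature id), and the
    count of each side's top K that are nominally significant on the other.
    """
    if K < 1:
        raise InvalidArgumentError("K must be >= 1")
    fa = _as_frame(result_a, coefficient)
    fb = _as_frame(result_b, coefficient)
    common = fa.index.intersection(fb.index)
    if len(common) == 0:
        raise InvalidInputError("no shared features between the two analyses")
    fa, fb = fa.loc[common], fb.loc[common]

    r = float(stats.pearsonr(fa["beta"], fb["beta"])[0])
    top_a = _top_k(fa, K)
    top_b = _top_k(fb, K)
    shared = len(set(top_a) & set(top_b))
    a_nom = int((fb.loc[top_a, "p"] < nominal_alpha).sum())
    b_nom = int((fa.loc[top_b, "p"] < nominal_alpha).sum())
    return ConcordanceReport(
        r=r,
        n_features=len(common),
        K=K,
        shared_top_k=shared,
        a_top_nominal_in_b=a_nom,
        b_top_nominal_in_a=b_nom,
        top_k_a=top_a,
        top_k_b=top_b,
    )


def _as_frame(result, coefficient: str) -> pd.DataFrame:
    if isinstance(result, ModeratedFitResult):
        return result.coefficient_frame(coefficient)[["beta", "p"]]
    if not {"beta", "p"} <= set(result.columns):
        raise InvalidInputError("result frame must carry beta and p columns")
    return result[["beta", "p"]]
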