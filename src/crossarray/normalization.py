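"""Quantile normalization, the two-pass inverse normal transform, and pooling.

Cross-platform pooling requires transcription values that are comparable
across samples and probes regardless of platform, RNA quantity or probe
specificity.  The procedure is:

1. quantile normalization within each study (every sample column receives
   the across-sample mean of order statistics at its ranks);
2. a first inverse normal transform (INT) applied to each sample separately,
   across probes, removing sample-level distributional differences;
3. a second INT applied to each probe separately, across the samples of the
   study, so every probe ends up with the same mean-0, SD-1 marginal.

After the second pass each feature row of a study is exactly a permutation
of the fixed quantile vector Phi^{-1}((r - c) / (n - 2c + 1)), r = 1..n.
The rank offset ``c`` defaults to 0 (probability r/(n+1)); Blom's c = 3/8 is
available via the parameter.  In the standalone transform ties receive
average ranks, so tied inputs map to identical z-values deterministically;
in the second pass of ``double_int`` ties (which pass 1 manufactures
whenever a feature holds the same rank in two samples) are broken by sample
order so that every row is an exact permutation of the quantile vector.

Studies are transformed separately and then pooled onto the probe-pair
feature space; pooling performs no further transformation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidArgumentError, InvalidInputError
from .probe_mapping import ProbePairTable
from .synthetic_data import AFFY25, ILMN50

logger = logging.getLogger(__name__)


def _check_complete(matrix: pd.DataFrame) -> None:
    if matrix.isna().to_numpy().any():
        raise InvalidInputError("matrix contains missing values")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column to the across-column mean of order statistics.

    Within-column ranks are preserved; tied values receive the mean of the
    reference values at the tied ranks.  Idempotent to machine precision.
    """
    if matrix.shape[1] < 2:
        raise InvalidArgumentError("quantile normalization requires >= 2 samples")
    _check_complete(matrix)
    values = matrix.to_numpy(float)
    reference = np.sort(values, axis=0).mean(axis=1)  # mean of order statistics
    n = values.shape[0]
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        # average ranks -> linear interpolation between reference entries
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), reference)
    result = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    result.attrs["scale"] = "quantile_normalized"
    return result


def _int_1d(values: np.ndarray, c: float) -> np.ndarray:
    n = values.shape[0]
    ranks = stats.rankdata(values, method="average")
    p = (ranks - c) / (n - 2.0 * c + 1.0)
    return stats.norm.ppf(p)


def inverse_normal_transform(values, c: float = 0.0) -> np.ndarray:
    """Rank-based inverse normal transform of a vector.

    Maps value of rank r (average ranks on ties) to
    Phi^{-1}((r - c)/(n - 2c + 1)); with the default c = 0 this is
    Phi^{-1}(r/(n+1)).  Strictly monotone in the input and invariant under
    any strictly increasing transformation of it.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InvalidArgumentError("expected a 1-D vector")
    if arr.shape[0] < 2:
        raise InvalidArgumentError("inverse normal transform requires n >= 2")
    if np.isnan(arr).any():
        raise InvalidInputError("input contains missing values")
    if not (0.0 <= c < 0.5):
        raise InvalidArgumentError("rank offset c must lie in [0, 0.5)")
    return _int_1d(arr, c)


def _int_along_axis(values: np.ndarray, axis: int, c: float) -> np.ndarray:
    n = values.shape[axis]
    ranks = stats.rankdata(values, method="average", axis=axis)
    p = (ranks - c) / (n - 2.0 * c + 1.0)
    return stats.norm.ppf(p)


def canonical_quantiles(n: int, c: float = 0.0) -> np.ndarray:
    """The fixed vector {Phi^{-1}((r - c)/(n - 2c + 1))}, r = 1..n, of which
    every feature row is a permutation after the second INT pass."""
    r = np.arange(1, n + 1, dtype=float)
    return stats.norm.ppf((r - c) / (n - 2.0 * c + 1.0))


def double_int(matrix: pd.DataFrame, c: float = 0.0) -> pd.DataFrame:
    """Two-pass inverse normal transform of one study's matrix.

    Pass 1 transforms each sample column across features (adjusting for
    sample-level variation such as RNA quantity); pass 2 transforms each
    feature row across the study's samples (adjusting for probe-level
    variation such as probe specificity).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise InvalidArgumentError("double INT requires >= 2 features and samples")
    _check_complete(matrix)
    values = matrix.to_numpy(float)
    pass1 = _int_along_axis(values, axis=0, c=c)
    # Pass 1 maps every column onto the same quantile grid, so a feature with
    # equal ranks in two samples produces tied pass-1 values even for
    # continuous data.  Pass 2 breaks such ties by sample order (stable
    # ordinal ranks): the result depends only on within-column ranks, stays
    # deterministic, and makes every row an exact permutation of the
    # canonical quantile vector.
    quant = canonical_quantiles(values.shape[1], c)
    order = np.argsort(pass1, axis=1, kind="stable")
    pass2 = np.empty_like(pass1)
    np.put_along_axis(pass2, order, quant[None, :], axis=1)
    result = pd.DataFrame(pass2, index=matrix.index, columns=matrix.columns)
    result.attrs["scale"] = "int_transformed"
    return result


def align_to_pairs(
    study_matrices: list[pd.DataFrame],
    pairs: ProbePairTable,
    platform_of_study: list[str],
) -> pd.DataFrame:
    """Pool per-study matrices onto the probe-pair feature space.

    Each probe pair becomes one pooled row, keyed ``probeset::probe``: studies
    on the 25-mer platform contribute the probeset's values, the 50-mer study
    contributes the probe's values.  Pairs missing a feature in any study are
    dropped (logged).  Columns are the concatenation of the studies' samples.
    """
    if len(study_matrices) != len(platform_of_study):
        raise InvalidArgumentError("one platform tag required per study matrix")
    for s, mat in enumerate(study_matrices):
        if mat.index.duplicated().any():
            raise InvalidInputError(f"duplicated feature ids in study {s + 1}")
    all_samples = np.concatenate([m.columns for m in study_matrices])
    if len(set(all_samples)) != len(all_samples):
        raise InvalidInputError("sample ids collide across studies")

    keep = np.ones(pairs.m, dtype=bool)
    for mat, platform in zip(study_matrices, platform_of_study):
        if platform == AFFY25:
            feature_col = pairs.table["affy_probeset_id"]
        elif platform == ILMN50:
            feature_col = pairs.table["ilmn_probe_id"]
        else:
            raise InvalidArgumentError(f"unknown platform {platform!r}")
        keep &= feature_col.isin(mat.index).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("align_to_pairs: dropped %d pairs missing in >=1 study", n_dropped)

    kept = pairs.table.loc[keep]
    # one (probeset, probe) couple can be assigned to several transcripts;
    # it is still a single tested pair, so keep one pooled row per couple
    dup = kept.duplicated(subset=["affy_probeset_id", "ilmn_probe_id"])
    if dup.any():
        logger.info("align_to_pairs: %d multi-transcript pair rows collapsed", int(dup.sum()))
        kept = kept.loc[~dup]
    pair_ids = (kept["affy_probeset_id"] + "::" + kept["ilmn_probe_id"]).to_numpy()

    blocks = []
    for mat, platform in zip(study_matrices, platform_of_study):
        col = "affy_probeset_id" if platform == AFFY25 else "ilmn_probe_id"
        block = mat.loc[kept[col].to_numpy()]
        block.index = pair_ids
        blocks.append(block)
    pooled = pd.concat(blocks, axis=1)
    pooled.index.name = "pair_id"
    pooled.attrs["scale"] = study_matrices[0].attrs.get("scale", "unknown")
    pooled.attrs["n_dropped_pairs"] = n_dropped
    pooled.attrs["study_of_sample"] = {
        s: list(m.columns) for s, m in enumerate(study_matrices, start=1)
    }
    return pooled
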