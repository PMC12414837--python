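"""Expression preprocessing: filtering, logCPM, covariate residualization,
isoform ratios and PCA-based sample outlier detection.

All matrices are pandas DataFrames with features as rows and samples as
columns. The pipeline order is fixed: filter -> logCPM -> residualize ->
drop negative features -> isoform ratios -> outlier removal.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "filter_features", "logcpm", "residualize", "drop_negative_features",
    "compute_isoform_ratios", "detect_outlier_samples",
]


def filter_features(counts: pd.DataFrame, min_count: int = 10,
                    min_frac: float = 0.95) -> pd.DataFrame:
    """Keep features with ``count >= min_count`` in at least
    ``ceil(min_frac * n_samples)`` samples.

    The boundary is inclusive on both the count and the sample fraction;
    all-zero features never pass. Row order is preserved.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    if not (0.0 < min_frac <= 1.0):
        raise ValueError("min_frac must lie in (0, 1]")
    need = math.ceil(min_frac * counts.shape[1])
    ok = (counts.to_numpy() >= min_count).sum(axis=1) >= need
    ok &= counts.to_numpy().sum(axis=1) > 0
    return counts.loc[ok]


def logcpm(counts: pd.DataFrame, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million: ``log2((count + prior) / (libsize + 1) * 1e6)``.

    Library size is the column sum of the matrix passed in.
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    vals = np.log2((counts.to_numpy(dtype=float) + prior_count)
                   / (lib[None, :] + 1.0) * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def _design_matrix(samples: pd.DataFrame, covariate_names: list[str]) -> np.ndarray:
    cols = []
    names = []
    for c in covariate_names:
        if c not in samples.columns:
            raise KeyError(f"covariate {c!r} missing from sample table")
        v = samples[c]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype) or v.dtype == bool:
            dummies = pd.get_dummies(v, prefix=c, drop_first=True, dtype=float)
            cols.append(dummies.to_numpy())
            names.extend(dummies.columns)
        else:
            cols.append(v.to_numpy(dtype=float)[:, None])
            names.append(c)
    if not cols:
        return np.empty((len(samples), 0)), []
    return np.hstack(cols), names


def residualize(expr: pd.DataFrame, samples: pd.DataFrame,
                covariate_names: list[str]) -> pd.DataFrame:
    """Remove covariate-explained variation per feature by joint OLS.

    Each feature is regressed on intercept + covariates (categoricals
    one-hot with the reference level dropped) and the fitted covariate
    contribution is subtracted, keeping the intercept, so group-associated
    signal is untouched as long as ``group`` is not listed as a covariate.
    """
    if "group" in covariate_names:
        raise ValueError("'group' must not be residualized out")
    if not covariate_names:
        return expr.copy()
    samples = samples.loc[expr.columns]
    C, names = _design_matrix(samples, covariate_names)
    X = np.hstack([np.ones((C.shape[0], 1)), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that do not increase rank when added incrementally
        bad = []
        r = 1
        for j in range(C.shape[1]):
            rj = np.linalg.matrix_rank(np.hstack([np.ones((C.shape[0], 1)), C[:, : j + 1]]))
            if rj == r:
                bad.append(names[j])
            r = rj
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    Y = expr.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted_cov = C @ beta[1:]          # covariate contribution only
    return pd.DataFrame(Y - fitted_cov.T, index=expr.index, columns=expr.columns)


def drop_negative_features(expr: pd.DataFrame) -> pd.DataFrame:
    """Drop every feature with at least one negative entry."""
    keep = (expr.to_numpy() >= 0).all(axis=1)
    return expr.loc[keep]


def compute_isoform_ratios(tx: pd.DataFrame, genes: pd.DataFrame,
                           feature_map: pd.DataFrame
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample isoform ratios: transcript value over parent-gene value.

    ``feature_map`` must have ``transcript_id`` and ``gene_id`` columns and
    map every transcript in ``tx`` to a gene present in ``genes``
    (transcripts of filtered genes are expected to have been removed
    beforehand). 0/0 entries are imputed with the transcript's mean ratio
    over the samples where it is defined; a zero denominator with a
    non-zero numerator is an error. Transcripts undefined in every sample
    are dropped with a warning.

    Returns ``(ir, gene_of)`` where ``gene_of`` maps each retained
    transcript to its parent gene.
    """
    gmap = feature_map.set_index("transcript_id")["gene_id"]
    if gmap.index.duplicated().any():
        raise ValueError("transcript mapped to more than one gene")
    missing = tx.index.difference(gmap.index)
    if len(missing):
        raise KeyError(f"unmapped transcripts: {list(missing[:5])}")
    gene_of = gmap.loc[tx.index]
    absent = set(gene_of) - set(genes.index)
    if absent:
        raise KeyError(f"transcripts map to genes absent from the gene matrix: "
                       f"{sorted(absent)[:5]}")

    num = tx.to_numpy(dtype=float)
    den = genes.loc[gene_of].to_numpy(dtype=float)
    bad = (den == 0) & (num != 0)
    if bad.any():
        t_i, s_i = np.argwhere(bad)[0]
        raise ValueError(
            f"zero gene value with non-zero transcript value at "
            f"({tx.index[t_i]}, {tx.columns[s_i]})")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((den == 0) & (num == 0), np.nan, num / np.where(den == 0, 1, den))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows handled below
        row_mean = np.nanmean(ratio, axis=1)
    all_nan = np.isnan(row_mean)
    if all_nan.any():
        logger.warning("dropping %d transcripts undefined in every sample",
                       int(all_nan.sum()))
    fill = np.where(np.isnan(ratio), row_mean[:, None], ratio)
    ir = pd.DataFrame(fill, index=tx.index, columns=tx.columns).loc[~all_nan]
    return ir, gene_of.loc[~all_nan]


def _pc_scores(values: np.ndarray, n_components: int = 2) -> np.ndarray:
    # samples as observations (rows); features centred
    X = values.T - values.T.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    return X @ vt[:n_components].T


def detect_outlier_samples(gene_expr: pd.DataFrame, ir: pd.DataFrame,
                           sd_mult: float = 2.0) -> set[str]:
    """Samples deviating more than ``sd_mult`` standard deviations from the
    mean on PC1 or PC2 of either the gene matrix or the IR matrix.

    PCA is run on each matrix separately; the union of flags is returned.
    """
    if sd_mult <= 0:
        raise ValueError("sd_mult must be positive")
    if gene_expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    flagged: set[str] = set()
    for mat in (gene_expr, ir):
        scores = _pc_scores(mat.to_numpy(dtype=float))
        for pc in range(min(2, scores.shape[1])):
            col = scores[:, pc]
            sd = col.std()
            if sd == 0:
                continue
            out = np.abs(col - col.mean()) > sd_mult * sd
            flagged.update(np.asarray(mat.columns)[out])
    return flagged
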