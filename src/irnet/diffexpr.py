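"""Two-group moderated differential expression with empirical Bayes
variance shrinkage (limma-trend style), Benjamini-Hochberg FDR control and
isoform-specific DE classification.

The moderated t-statistic shrinks per-feature residual variances toward a
prior estimated by method of moments on the log variances; with
``trend=True`` the prior variance is a smooth (lowess) function of mean
expression. The resulting statistic follows a t distribution with the
residual degrees of freedom augmented by the prior degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = ["moderated_de", "bh_adjust", "isoform_specific_de", "squeeze_var"]

_MAX_DF = 1e10  # stand-in for an infinite prior df


def _trigamma(x: np.ndarray) -> np.ndarray:
    return special.polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(_trigamma(np.array(x)))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return x


def squeeze_var(s2: np.ndarray, df: float, amean: np.ndarray | None = None,
                trend: bool = True, lowess_frac: float = 0.4
                ) -> tuple[float, np.ndarray, np.ndarray]:
    """Empirical Bayes shrinkage of sample variances.

    Hyperparameters (prior df ``d0`` and prior variance ``s0^2``) are fitted
    by method of moments on ``log(s2)``, using the known mean and variance
    of the log of a scaled chi-square. Returns
    ``(df_prior, s2_prior, s2_post)``; ``df_prior`` is ``inf`` when the
    observed log variances are no more dispersed than sampling alone
    explains.
    """
    s2 = np.clip(np.asarray(s2, dtype=float), 1e-12, None)
    z = np.log(s2)
    # E[log s2] = log s0^2 + digamma(df/2) - log(df/2); Var = trigamma(df/2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    if trend and amean is not None and len(s2) >= 10:
        order = np.argsort(amean, kind="stable")
        sm = lowess(e[order], amean[order], frac=lowess_frac, return_sorted=False)
        e_mean = np.empty_like(sm)
        e_mean[order] = sm
    else:
        e_mean = np.full_like(e, e.mean())
    resid = e - e_mean
    evar = resid.var(ddof=1) - float(_trigamma(np.array(df / 2.0)))
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
    else:
        df_prior = np.inf
    if np.isfinite(df_prior):
        s2_prior = np.exp(e_mean + special.digamma(df_prior / 2.0)
                          - np.log(df_prior / 2.0))
        s2_post = (df_prior * s2_prior + df * s2) / (df_prior + df)
    else:
        s2_prior = np.exp(e_mean)
        s2_post = s2_prior.copy()
    return df_prior, s2_prior, s2_post


def moderated_de(expr: pd.DataFrame, samples: pd.DataFrame,
                 trend: bool = True, q_thresh: float = 0.05) -> pd.DataFrame:
    """Moderated two-group differential expression (affected - unaffected).

    ``samples`` needs a ``group`` column with values ``affected`` /
    ``unaffected`` covering the columns of ``expr``. Returns a DataFrame
    indexed by feature with logFC, average expression, moderated t,
    p-value, BH q-value, significance flag at ``q_thresh`` and direction.
    """
    groups = samples.loc[expr.columns, "group"]
    a = (groups == "affected").to_numpy()
    b = (groups == "unaffected").to_numpy()
    n1, n2 = int(a.sum()), int(b.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    Y = expr.to_numpy(dtype=float)
    mean_a = Y[:, a].mean(axis=1)
    mean_b = Y[:, b].mean(axis=1)
    logfc = mean_a - mean_b
    amean = Y.mean(axis=1)
    rss = ((Y[:, a] - mean_a[:, None]) ** 2).sum(axis=1) \
        + ((Y[:, b] - mean_b[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = rss / df
    df_prior, _, s2_post = squeeze_var(s2, df, amean=amean, trend=trend)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(logfc == 0.0, 0.0, logfc / se)
    df_total = df + min(df_prior, _MAX_DF)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    out = pd.DataFrame({
        "logFC": logfc, "AveExpr": amean, "t_stat": t,
        "p_value": p, "q_value": q,
    }, index=expr.index.rename("feature_id"))
    out["significant"] = out["q_value"] <= q_thresh
    out["direction"] = np.where(logfc >= 0, "up", "down")
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Order-preserving with respect to the input; values lie in [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


@dataclass
class DEOverlap:
    """Direction-resolved overlap between gene- and transcript-level calls."""

    transcript_only_up: set
    transcript_only_down: set
    both_up: set
    both_down: set
    gene_only_up: set
    gene_only_down: set

    def counts(self) -> dict[str, int]:
        return {k: len(getattr(self, k)) for k in (
            "transcript_only_up", "transcript_only_down", "both_up",
            "both_down", "gene_only_up", "gene_only_down")}


def isoform_specific_de(gene_de: pd.DataFrame, tx_de: pd.DataFrame,
                        feature_map: pd.DataFrame, q_thresh: float = 0.05
                        ) -> tuple[set, DEOverlap]:
    """Transcripts significant at ``q <= q_thresh`` whose parent gene is not.

    A parent gene absent from ``gene_de`` (filtered out upstream) counts as
    not significant. Also returns the direction-resolved overlap partition
    of gene-only / both / transcript-only calls.
    """
    gmap = feature_map.set_index("transcript_id")["gene_id"]
    missing = tx_de.index.difference(gmap.index)
    if len(missing):
        raise KeyError(f"unmapped transcripts: {list(missing[:5])}")
    sig_tx = tx_de[tx_de["q_value"] <= q_thresh]
    sig_genes = set(gene_de.index[gene_de["q_value"] <= q_thresh])

    iso_specific = {t for t in sig_tx.index if gmap[t] not in sig_genes}
    # direction-resolved Venn: within each direction, compare the significant
    # transcripts (via their parent gene) against the significant genes
    tx_up = set(sig_tx.index[sig_tx["direction"] == "up"])
    tx_down = set(sig_tx.index) - tx_up
    g_up = {g for g in sig_genes if gene_de.at[g, "direction"] == "up"}
    g_down = sig_genes - g_up
    overlap = DEOverlap(
        transcript_only_up={t for t in tx_up if gmap[t] not in g_up},
        transcript_only_down={t for t in tx_down if gmap[t] not in g_down},
        both_up={t for t in tx_up if gmap[t] in g_up},
        both_down={t for t in tx_down if gmap[t] in g_down},
        gene_only_up=g_up - {gmap[t] for t in tx_up},
        gene_only_down=g_down - {gmap[t] for t in tx_down},
    )
    return iso_specific, overlap
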