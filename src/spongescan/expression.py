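"""Differential expression for two-condition count matrices.

The model is the standard bulk RNA-seq negative-binomial setup: counts
``K_gj ~ NB(s_j * mu_gc, alpha_g)`` with sample size factors ``s_j``
(median-of-ratios), condition means ``mu_gc`` and per-gene dispersion
``alpha_g`` (variance ``mu + alpha * mu^2``).  Dispersions are estimated by
method of moments and shrunk toward a fitted mean-dispersion trend; the
test on the log2 fold change is a Wald test with a delta-method standard
error referred to the standard normal, the usual convention for NB Wald
tests in this field.  Multiplicity is handled by Benjamini-Hochberg.
Exact replication of any specific DE package is not attempted.

"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONDITIONS = ("control", "stimulated")


class ExpressionError(ValueError):
    """Raised on malformed count matrices or invalid test input."""


@dataclass
class CountMatrix:
    """Integer counts, genes x samples, with condition labels and lengths.

    Parameters
    ----------
    counts:
        DataFrame indexed by gene id with one column per sample;
        non-negative integers.
    conditions:
        Series mapping sample id -> ``control`` | ``stimulated``.
    gene_lengths:
        Series mapping gene id -> transcript length in nucleotides (> 0).
    """

    counts: pd.DataFrame
    conditions: pd.Series
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ExpressionError("duplicate gene or sample ids in count matrix")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ExpressionError("counts must be integers")
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ExpressionError("counts must be non-negative")
        if set(self.conditions.index) != set(c.columns):
            raise ExpressionError("condition labels do not match sample ids")
        bad = set(self.conditions.unique()) - set(CONDITIONS)
        if bad:
            raise ExpressionError(f"unknown condition labels {sorted(bad)}; expected {CONDITIONS}")
        self.conditions = self.conditions.reindex(c.columns)
        if set(self.gene_lengths.index) != set(c.index):
            raise ExpressionError("gene_lengths do not match gene ids")
        self.gene_lengths = self.gene_lengths.reindex(c.index).astype(float)
        if (self.gene_lengths <= 0).any():
            raise ExpressionError("gene lengths must be positive")

    def samples_of(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])


def read_counts(counts_path: str | Path, conditions_path: str | Path) -> CountMatrix:
    """Read a tab-delimited count matrix plus a two-column condition file.

    The count file's first column is the gene id, the second column
    (``length``) the transcript length, remaining columns are samples.
    The condition file has two columns: sample id, condition.
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if "length" not in df.columns:
        raise ExpressionError(f"{counts_path}: expected a 'length' column")
    lengths = df["length"]
    counts = df.drop(columns="length")
    cond = pd.read_csv(conditions_path, sep="\t", index_col=0).iloc[:, 0]
    return CountMatrix(counts=counts, conditions=cond, gene_lengths=lengths)


def write_counts(cm: CountMatrix, counts_path: str | Path, conditions_path: str | Path) -> None:
    out = cm.counts.copy()
    out.insert(0, "length", cm.gene_lengths.astype(int))
    out.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.conditions.rename("condition").to_csv(conditions_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def compute_tpm(cm: CountMatrix) -> pd.DataFrame:
    """Transcripts-per-million per gene and sample.

    ``TPM_gj = 1e6 * (c_gj / L_g) / sum_h (c_hj / L_h)``.  Columns of an
    expressed sample sum to 1e6; an all-zero sample yields all-zero TPM
    with a warning.
    """
    rate = cm.counts.div(cm.gene_lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        warnings.warn(
            f"samples with no counts at all: {list(denom.index[zero])}; their TPM is set to 0",
            stacklevel=2,
        )
        denom = denom.replace(0, np.nan)
    tpm = rate.div(denom, axis=1) * 1e6
    return tpm.fillna(0.0)


def size_factors(cm: CountMatrix | pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios sample scale factors.

    Each sample's factor is the median, over genes expressed in every
    sample, of its count divided by that gene's geometric mean across
    samples.  ``pseudocount`` (added to every count) rescues matrices with
    no gene expressed everywhere.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    arr = counts.to_numpy(dtype=float) + pseudocount
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise ExpressionError(
            "no gene has nonzero counts in all samples; pass pseudocount=0.5 "
            "(or larger) to compute size factors on shifted counts"
        )
    sub = arr[all_pos]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------

def _dispersion_estimates(
    norm: np.ndarray, ctrl: np.ndarray, stim: np.ndarray, sf: np.ndarray,
    floor: float = 1e-8, ceiling: float = 10.0, trend_weight: float = 0.5,
) -> np.ndarray:
    """Per-gene NB dispersions: floored method of moments, shrunk to trend.

    The method-of-moments estimate uses the pooled within-condition variance
    of normalized counts; the trend ``alpha(mu) = a0 + a1/mu`` is fit by
    least squares over genes and the final estimate is the ``trend_weight``
    arithmetic blend of the two.
    """
    mu = norm.mean(axis=1)
    n_c, n_t = ctrl.sum(), stim.sum()
    var_c = norm[:, ctrl].var(axis=1, ddof=1)
    var_t = norm[:, stim].var(axis=1, ddof=1)
    var_pooled = ((n_c - 1) * var_c + (n_t - 1) * var_t) / (n_c + n_t - 2)
    # normalized counts have variance mu/s + alpha*mu^2; use the mean 1/s
    inv_s = (1.0 / sf).mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (var_pooled - mu * inv_s) / mu**2
    alpha_mom = np.clip(np.nan_to_num(alpha_mom, nan=floor), floor, ceiling)

    ok = (mu > 0) & (alpha_mom > floor)
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(X, alpha_mom[ok], rcond=None)
        a0, a1 = max(coef[0], floor), max(coef[1], 0.0)
    else:  # too few informative genes for a trend; fall back to the mean
        a0, a1 = max(alpha_mom.mean(), floor), 0.0
    with np.errstate(divide="ignore"):
        alpha_trend = np.clip(a0 + a1 / np.where(mu > 0, mu, np.inf), floor, ceiling)
    alpha = (1 - trend_weight) * alpha_mom + trend_weight * alpha_trend
    return np.clip(alpha, floor, ceiling)


def nb_differential_test(
    cm: CountMatrix,
    lfc_pseudocount: float = 0.5,
    trend_weight: float = 0.5,
    sample_size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of stimulated vs control.

    Returns a DataFrame indexed by gene id with columns ``base_mean``,
    ``log2fc``, ``pvalue``, ``fdr``, ``mean_tpm_control`` and
    ``mean_tpm_stimulated``.  ``log2fc = log2((m_stim + eps) / (m_ctrl +
    eps))`` on normalized condition means with ``eps = lfc_pseudocount``
    normalized counts; the Wald statistic is referred to the standard
    normal.  ``sample_size_factors`` overrides the median-of-ratios
    normalization (e.g. all ones when spike-in-calibrated counts are
    supplied).  Deterministic given the input.
    """
    ctrl = (cm.conditions == "control").to_numpy()
    stim = (cm.conditions == "stimulated").to_numpy()
    if ctrl.sum() < 2 or stim.sum() < 2:
        raise ExpressionError(
            f"need >= 2 replicates per condition (got {int(ctrl.sum())} control, "
            f"{int(stim.sum())} stimulated)"
        )
    if sample_size_factors is not None:
        sf = sample_size_factors.reindex(cm.counts.columns).to_numpy(dtype=float)
    else:
        try:
            sf = size_factors(cm).to_numpy()
        except ExpressionError:
            sf = size_factors(cm, pseudocount=0.5).to_numpy()
    norm = cm.counts.to_numpy(dtype=float) / sf[None, :]
    alpha = _dispersion_estimates(norm, ctrl, stim, sf, trend_weight=trend_weight)

    eps = lfc_pseudocount
    m_c = norm[:, ctrl].mean(axis=1)
    m_t = norm[:, stim].mean(axis=1)
    lfc = np.log2(m_t + eps) - np.log2(m_c + eps)

    ln2 = np.log(2.0)

    def var_log2_mean(m: np.ndarray, cond: np.ndarray) -> np.ndarray:
        n = cond.sum()
        mu = np.maximum(m, eps)
        var_m = (mu[:, None] / sf[None, cond] + alpha[:, None] * mu[:, None] ** 2).sum(axis=1) / n**2
        return var_m / ((m + eps) ** 2 * ln2**2)

    se = np.sqrt(var_log2_mean(m_c, ctrl) + var_log2_mean(m_t, stim))
    z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))

    tpm = compute_tpm(cm)
    out = pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2fc": lfc,
            "pvalue": pvalue,
            "fdr": bh_adjust(pvalue),
            "mean_tpm_control": tpm.loc[:, ctrl].mean(axis=1),
            "mean_tpm_stimulated": tpm.loc[:, stim].mean(axis=1),
        },
        index=cm.counts.index.rename("gene_id"),
    )
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ExpressionError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_and_rank_de(
    results: pd.DataFrame,
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
    tpm_threshold: float = 1.0,
) -> pd.DataFrame:
    """The differential-expression call, ranked by mean expression.

    Keeps genes with ``|log2fc|`` strictly above ``lfc_threshold``, ``fdr``
    strictly below ``fdr_threshold`` and maximum per-condition mean TPM
    strictly above ``tpm_threshold``; the strict inequalities mirror the
    stated cutoffs (|log2FC| > 0.5, FDR < 0.05, TPM > 1).  Output is
    ordered by ``base_mean`` descending, ties by |log2fc| descending then
    gene id ascending.
    """
    df = results.copy()
    tpm_max = df[["mean_tpm_control", "mean_tpm_stimulated"]].max(axis=1)
    keep = (
        (df["log2fc"].abs() > lfc_threshold)
        & (df["fdr"] < fdr_threshold)
        & (tpm_max > tpm_threshold)
    )
    df = df[keep]
    order = df.assign(_abs_lfc=df["log2fc"].abs(), _id=df.index).sort_values(
        ["base_mean", "_abs_lfc", "_id"], ascending=[False, False, True]
    )
    return order.drop(columns=["_abs_lfc", "_id"])


def ddct_fold_change(
    ct_target_treated: float,
    ct_reference_treated: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """Comparative-CT (2^-ddCt) fold change from qPCR threshold cycles."""
    ddct = (ct_target_treated - ct_reference_treated) - (
        ct_target_control - ct_reference_control
    )
    return float(2.0 ** (-ddct))
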