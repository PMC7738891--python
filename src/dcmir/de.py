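"""Paired differential expression with independent filtering and BH.

The stage works on integer count matrices (features x samples) with a paired
sample sheet: each donor contributes one control and one treated sample.
Counts are prefiltered (any sample below a minimum count drops the feature),
normalized by median-of-ratios size factors, log2-transformed with a
pseudocount, and tested feature-wise with a paired t statistic on the
within-donor treated-minus-control differences. Multiple testing uses
independent filtering on the mean of normalized counts — the filter
threshold is chosen to maximize the number of adjusted p-values at or below
alpha — followed by Benjamini-Hochberg on the surviving features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import io

DE_COLUMNS = [
    "feature_id", "log2fc", "se_log2fc", "p_raw", "p_adj",
    "base_mean", "filtered", "zero_var",
]


def aggregate_and_prefilter(
    counts: pd.DataFrame,
    id_map: pd.Series | dict | None = None,
    min_count: int = 5,
) -> pd.DataFrame:
    """Sum rows mapping to the same canonical id, then drop features whose
    count falls below ``min_count`` in any sample.

    ``id_map`` maps raw feature ids to canonical ids; identity by default.
    Raises if nothing survives.
    """
    if id_map is not None:
        id_map = pd.Series(id_map)
        canon = counts.index.to_series().map(id_map).fillna(
            counts.index.to_series()
        )
        counts = counts.groupby(canon.values).sum()
        counts.index.name = "feature_id"
    keep = (counts >= min_count).all(axis=1)
    out = counts.loc[keep]
    if out.empty:
        raise ValueError("all features filtered")
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each feature with nonzero counts in every sample, compute the ratio
    of each sample's count to the feature's geometric mean; the factor for a
    sample is the median ratio.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no feature with nonzero counts in all samples")
    sub = mat[all_pos]
    log_geo = np.log(sub).mean(axis=1)
    ratios = sub / np.exp(log_geo)[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_log(
    counts: pd.DataFrame, factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount).

    The pseudocount moderates low-count variance, standing in for
    model-based shrinkage transforms.
    """
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return np.log2(counts.div(factors, axis=1) + pseudocount)


def normalized_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    return counts.div(factors, axis=1)


def test_paired(norm: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Paired t-test per feature on within-donor differences.

    delta_d = treated - control on the normalized-log scale; log2fc is the
    mean delta, its standard error sd(delta)/sqrt(n_donors), and the raw
    p-value two-sided t with n_donors - 1 df. Zero-variance features are
    flagged: p = 1 when the effect is exactly zero, otherwise the smallest
    positive float (never silently significant without the flag).
    """
    io.validate_sample_sheet(sheet)
    donors = sorted(sheet["donor"].unique())
    n = len(donors)

    by = sheet.set_index(["donor", "condition"])["sample_id"]
    treated_cols = [by.loc[(d, "treated")] for d in donors]
    control_cols = [by.loc[(d, "control")] for d in donors]
    delta = norm[treated_cols].to_numpy() - norm[control_cols].to_numpy()

    log2fc = delta.mean(axis=1)
    sd = delta.std(axis=1, ddof=1)
    se = sd / np.sqrt(n)

    zero_var = se == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / se
    p_raw = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p_raw = np.where(
        zero_var, np.where(log2fc == 0.0, 1.0, np.finfo(float).tiny), p_raw
    )

    return pd.DataFrame(
        {
            "feature_id": norm.index,
            "log2fc": log2fc,
            "se_log2fc": se,
            "p_raw": p_raw,
            "zero_var": zero_var,
        }
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def independent_filter_bh(
    de: pd.DataFrame, alpha: float = 0.05,
    quantile_step: float = 0.01, quantile_max: float = 0.95,
) -> pd.DataFrame:
    """Independent filtering on base_mean followed by BH.

    Candidate thresholds are the base_mean quantiles from 0 to
    ``quantile_max`` in ``quantile_step`` increments. For each, BH is applied
    to features at or above the threshold and the number of adjusted
    p-values <= alpha counted; the threshold maximizing that count wins
    (ties go to the smallest threshold, i.e. the least filtering).
    Features below the chosen threshold get ``filtered=True`` and a missing
    adjusted p-value.

    The chosen threshold and its quantile are stored in
    ``result.attrs['filter_threshold']`` / ``['filter_quantile']``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if "base_mean" not in de.columns:
        raise ValueError("de table must carry base_mean")
    base_mean = de["base_mean"].to_numpy(dtype=float)
    p_raw = de["p_raw"].to_numpy(dtype=float)

    quantiles = np.arange(0.0, quantile_max + 1e-9, quantile_step)
    thresholds = np.quantile(base_mean, quantiles)

    best_q = 0
    best_rej = -1
    for qi, thr in enumerate(thresholds):
        mask = base_mean >= thr
        if not mask.any():
            continue
        adj = bh_adjust(p_raw[mask])
        rej = int((adj <= alpha).sum())
        if rej > best_rej:
            best_rej = rej
            best_q = qi

    thr = thresholds[best_q]
    mask = base_mean >= thr
    p_adj = np.full(len(de), np.nan)
    p_adj[mask] = bh_adjust(p_raw[mask])

    out = de.copy()
    out["p_adj"] = p_adj
    out["filtered"] = ~mask
    out.attrs["filter_threshold"] = float(thr)
    out.attrs["filter_quantile"] = float(quantiles[best_q])
    out.attrs["n_rejected"] = int(best_rej)
    return out


def run_de(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    min_count: int = 5,
    id_map: pd.Series | dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full DE stage: prefilter, normalize, paired test, filter + BH.

    Returns ``(de_table, norm_log)`` — the per-feature results and the
    normalized-log expression matrix used downstream for correlations.
    """
    counts = aggregate_and_prefilter(counts, id_map=id_map,
                                     min_count=min_count)
    factors = size_factors(counts)
    norm_log = normalize_log(counts, factors, pseudocount=pseudocount)
    de = test_paired(norm_log, sheet)
    de["base_mean"] = normalized_counts(counts, factors).mean(axis=1).values
    attrs_src = independent_filter_bh(de, alpha=alpha)
    de = attrs_src[DE_COLUMNS]
    de.attrs.update(attrs_src.attrs)
    return de, norm_log


def significant(de: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows with adjusted p-value at or below alpha."""
    return de[de["p_adj"].notna() & (de["p_adj"] <= alpha)]
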