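"""Interaction-candidate calling.

Each protein's log2 relative intensities are compared, per cell line,
against the blank channels by a one-tailed pooled-variance two-sample
t-test (alternative: line > blanks; df = n1 + n2 - 2, i.e. 3 for two
replicates against three blanks).  The per-line p-values are combined
across the L cell lines by Fisher's method,

    X^2 = -2 * sum_l ln(p_l)  ~  chi-square with 2L df under the null,

and the combined p-values are converted to q-values by Benjamini-Hochberg
step-up adjustment.  A second, orthogonal gate measures effect size in
units of measurement noise: the null SD sigma0 is the SD of a Gaussian fit
to the pooled log2 replicate-to-replicate ratios across all proteins, and

    z = (max_l log2FC_l - mu0) / sigma0.

A protein is an interaction candidate iff q < 0.01 and z > 3 (defaults).
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import (CandidateTable, ChannelLayout, ContractError,
                 DegeneracyError, NullModel, ProteinQuantTable)

logger = logging.getLogger("ppbscreen")

__all__ = ["per_line_test", "fisher_combine", "bh_adjust",
           "estimate_null_model", "call_candidates"]

#: floor applied to p-values before taking logs in Fisher's method
P_FLOOR = 1e-300


def _log2_groups(profile: pd.Series, layout: ChannelLayout, line: str
                 ) -> tuple[np.ndarray, np.ndarray]:
    samp = profile[layout.sample_channels(line)].to_numpy(dtype=float)
    blank = profile[layout.blank_channels()].to_numpy(dtype=float)
    if (samp <= 0).any() or (blank <= 0).any():
        raise ContractError("relative intensities must be positive for log2")
    return np.log2(samp), np.log2(blank)


def _pooled_t(x: np.ndarray, y: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized one-tailed pooled-variance t-test of rows of x vs y.

    Returns (p, fc, degenerate).  One-tailed alternative x > y.  With zero
    pooled variance: p = 0.5 at equal means, else floored at P_FLOOR and
    flagged degenerate.
    """
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ContractError("t-test needs >= 2 replicates and >= 2 blanks")
    mx, my = x.mean(axis=1), y.mean(axis=1)
    fc = mx - my
    df = n1 + n2 - 2
    ss = ((x - mx[:, None]) ** 2).sum(axis=1) + \
         ((y - my[:, None]) ** 2).sum(axis=1)
    sp = np.sqrt(ss / df)
    se = sp * np.sqrt(1.0 / n1 + 1.0 / n2)
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / se
    p = np.empty_like(fc)
    ok = ~degenerate
    p[ok] = scipy.stats.t.sf(t[ok], df)
    p[degenerate & (fc == 0)] = 0.5
    zero_var_shift = degenerate & (fc != 0)
    p[zero_var_shift & (fc > 0)] = P_FLOOR
    p[zero_var_shift & (fc < 0)] = 1.0
    if zero_var_shift.any():
        logger.warning("%d proteins had zero pooled variance with unequal "
                       "means; p floored", int(zero_var_shift.sum()))
    return p, fc, degenerate


def per_line_test(profile: pd.Series, layout: ChannelLayout, line: str
                  ) -> tuple[float, float]:
    """One-tailed pooled-t comparison of one protein's line replicates
    against the blanks, on log2 relative intensities.

    Returns ``(p, log2FC)`` with log2FC = mean(line) - mean(blanks).
    """
    lx, ly = _log2_groups(profile, layout, line)
    p, fc, _ = _pooled_t(lx[None, :], ly[None, :])
    return float(p[0]), float(fc[0])


def fisher_combine(p_values: Sequence[float]
                   ) -> tuple[float, float]:
    """Fisher's method: combine independent p-values into one.

    Returns ``(X2, combined_p)`` where X2 = -2 sum(ln p) and combined_p is
    the chi-square(2L) upper-tail probability.  Zero p-values are floored
    at 1e-300 to keep the log finite.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ContractError("fisher_combine needs at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ContractError("p-values must lie in [0, 1]")
    p = np.maximum(p, P_FLOOR)
    x2 = float(-2.0 * np.log(p).sum())
    return x2, float(scipy.stats.chi2.sf(x2, df=2 * p.size))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min_{j: p_j >= p_i} (p_(j) * n / rank_j), capped at 1; monotone in
    p-rank with ties preserved.  Delegates to statsmodels' fdr_bh.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ContractError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=0.05, method="fdr_bh")[1]


def estimate_null_model(table: ProteinQuantTable, layout: ChannelLayout,
                        estimator: str = "mle") -> NullModel:
    """Fit the null distribution of log2 replicate ratios.

    For every protein and cell line, log2(rep_i / rep_j) of relative
    intensities over all replicate pairs is pooled across proteins and
    lines; ``mle`` fits a Gaussian (mean, SD), ``mad`` uses the median and
    1.4826 * MAD for robustness to true binders in the pool.
    """
    rel = table.relative
    ratios = []
    for line in layout.cell_lines:
        chans = layout.sample_channels(line)
        for a, b in combinations(chans, 2):
            x = rel[a].to_numpy(dtype=float)
            y = rel[b].to_numpy(dtype=float)
            if (x <= 0).any() or (y <= 0).any():
                raise ContractError(
                    "relative intensities must be positive for log2 ratios")
            ratios.append(np.log2(x / y))
    pooled = np.concatenate(ratios)
    if np.ptp(pooled) == 0:
        raise DegeneracyError(
            "all replicate log2 ratios are identical; null SD undefined")
    if estimator == "mle":
        mu0 = float(pooled.mean())
        sigma0 = float(pooled.std(ddof=0))
    elif estimator == "mad":
        mu0 = float(np.median(pooled))
        sigma0 = float(1.4826 * np.median(np.abs(pooled - mu0)))
        if sigma0 == 0:
            raise DegeneracyError("MAD of replicate ratios is zero")
    else:
        raise ContractError(f"unknown null estimator {estimator!r}")
    return NullModel(mu0, sigma0, n_ratios=pooled.size, estimator=estimator)


def call_candidates(table: ProteinQuantTable, layout: ChannelLayout,
                    null: NullModel, fdr_threshold: float = 0.01,
                    z_threshold: float = 3.0,
                    fc_rule: str = "max") -> CandidateTable:
    """Score every protein and flag interaction candidates.

    Runs the per-line tests, Fisher combination, BH adjustment and the
    null-SD z-gate; a candidate needs q < ``fdr_threshold`` and
    z > ``z_threshold``.  ``fc_rule`` picks the fold change entering the
    z-score: ``max`` over lines (default: a strong line-specific binder can
    pass), ``mean``, or ``all`` (the weakest line must pass).
    """
    rel = table.relative
    lines = layout.cell_lines
    vals = rel.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ContractError("relative intensities must be positive")
    log2rel = pd.DataFrame(np.log2(vals), index=rel.index, columns=rel.columns)

    blank_cols = layout.blank_channels()
    y = log2rel[blank_cols].to_numpy()
    p_mat = np.empty((len(rel), len(lines)))
    fc_mat = np.empty_like(p_mat)
    for j, line in enumerate(lines):
        x = log2rel[layout.sample_channels(line)].to_numpy()
        p_mat[:, j], fc_mat[:, j], _ = _pooled_t(x, y)

    logp = np.log(np.maximum(p_mat, P_FLOOR))
    x2 = -2.0 * logp.sum(axis=1)
    combined_p = scipy.stats.chi2.sf(x2, df=2 * len(lines))
    q = bh_adjust(combined_p)

    if fc_rule == "max":
        fc_stat = fc_mat.max(axis=1)
    elif fc_rule == "mean":
        fc_stat = fc_mat.mean(axis=1)
    elif fc_rule == "all":
        fc_stat = fc_mat.min(axis=1)
    else:
        raise ContractError(f"unknown fc_rule {fc_rule!r}")
    z = (fc_stat - null.mu0) / null.sigma0
    called = (q < fdr_threshold) & (z > z_threshold)

    out = pd.DataFrame({"protein": rel.index.to_numpy()})
    for j, line in enumerate(lines):
        out[f"p_{line}"] = p_mat[:, j]
        out[f"log2fc_{line}"] = fc_mat[:, j]
    out["fisher_x2"] = x2
    out["combined_p"] = combined_p
    out["q_value"] = q
    out["z_score"] = z
    out["is_candidate"] = called
    logger.info("called %d candidates among %d proteins "
                "(FDR < %g, z > %g)", int(called.sum()), len(out),
                fdr_threshold, z_threshold)
    return CandidateTable(out, null, tuple(lines), fdr_threshold, z_threshold)
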