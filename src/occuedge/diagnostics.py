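"""Posterior diagnostics: Gelman-Rubin Rhat, sign-consistency f, summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["gelman_rubin", "f_statistic", "posterior_summary"]


def gelman_rubin(chain_draws) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    ``chain_draws`` is an (m, n) array of m >= 2 chains with n retained
    draws each.  Computes the classic PSRF from the between-chain (B) and
    within-chain (W) variances,

        Rhat = sqrt( ((n-1)/n * W + B/n) / W ).

    A parameter on which every chain is constant at the same value has no
    scale to reduce and returns 1 by convention.
    """
    x = np.asarray(chain_draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D array with at least two chains")
    m, n = x.shape
    if n < 10:
        raise ValueError("need at least 10 draws per chain")
    chain_means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    if W == 0.0:
        return 1.0
    B_over_n = chain_means.var(ddof=1)
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def f_statistic(draws) -> float:
    """Sign-consistency confidence f of a posterior sample.

    f is the proportion of draws lying on the posterior mean's side of
    zero — the confidence that the parameter is either positive or
    negative — and lies in [0.5, 1].  Draws exactly at zero count toward
    the mean's side (a measure-zero event, resolved deterministically).
    For a skewed sample whose mean falls on the minority side of zero the
    majority side is reported, keeping f a two-sided sign confidence and
    preserving the lower bound of 0.5.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty sample")
    mean_sign = 1.0 if x.mean() >= 0 else -1.0
    same = np.count_nonzero((x * mean_sign > 0) | (x == 0)) / x.size
    return float(max(same, 1.0 - same))


def posterior_summary(draws_by_name: dict, round_to: int | None = None) -> pd.DataFrame:
    """Summary table: mean, SD, 2.5%/97.5% quantiles, Rhat and f per row.

    ``draws_by_name`` maps parameter names to (chains, draws) arrays.
    """
    rows = []
    for name, x in draws_by_name.items():
        x = np.asarray(x, dtype=float)
        flat = x.ravel()
        rows.append(
            {
                "parameter": name,
                "mean": flat.mean(),
                "sd": flat.std(ddof=1) if flat.size > 1 else 0.0,
                "q2.5": np.quantile(flat, 0.025),
                "q97.5": np.quantile(flat, 0.975),
                "rhat": gelman_rubin(x) if x.ndim == 2 and x.shape[0] >= 2 else np.nan,
                "f": f_statistic(flat),
            }
        )
    df = pd.DataFrame(rows).set_index("parameter")
    if round_to is not None:
        df = df.round(round_to)
    return df
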