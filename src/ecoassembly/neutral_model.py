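"""Sloan neutral community model: fit, goodness of fit, prediction bounds.

The model predicts a taxon's occurrence frequency across a metacommunity
from its mean relative abundance:

    freq_pred_i = 1 - BetaCDF(1/N; N m p_i, N m (1 - p_i))

with N the (common) number of individuals per community and m the
immigration rate. m is fitted by bounded least squares on the observed
occupancy-abundance cloud; R^2 = 1 - SS_err/SS_total may be negative when
the data deviate strongly from neutrality (no clamp is applied).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ecoassembly.core_data import CommunityTable, ValidationError

M_BOUNDS = (1e-6, 1.0)


@dataclass
class NCMFit:
    m: float
    N: int
    r_squared: float
    taxa: pd.DataFrame  # p_i, freq_obs, freq_pred, pred_lwr, pred_upr, class
    n_samples: int


def freq_predicted(p: np.ndarray, m: float, N: int) -> np.ndarray:
    """Neutral-model occurrence frequency for mean relative abundance p."""
    p = np.asarray(p, dtype=float)
    a = N * m * p
    b = N * m * (1.0 - p)
    return stats.beta.sf(1.0 / N, a, b)


def ncm_fit(table: CommunityTable, min_taxa: int = 10) -> NCMFit:
    """Fit the neutral model to a rarefied count table.

    All samples must share a common depth N (rarefy first); taxa with zero
    total are dropped. Returns the fitted immigration rate m, R^2, and the
    per-taxon observed/predicted frequencies with 95% Wilson bounds and an
    above/within/below classification.
    """
    totals = table.sample_totals
    if len(set(totals.tolist())) != 1:
        raise ValidationError(
            "ncm_fit requires equal sample depths; rarefy the table first "
            f"(totals range {totals.min()}..{totals.max()})"
        )
    N = int(totals[0])
    if N <= 1:
        raise ValidationError("sample depth must exceed 1")
    sub = table.drop_zero_taxa() if (table.taxon_totals == 0).any() else table
    if sub.n_taxa < min_taxa:
        raise ValidationError(
            f"ncm_fit needs >= {min_taxa} taxa with nonzero totals, got {sub.n_taxa}"
        )
    rel = sub.counts / N
    p = rel.mean(axis=1)
    freq_obs = (sub.counts > 0).mean(axis=1)

    def sse(m: float) -> float:
        resid = freq_obs - freq_predicted(p, m, N)
        return float((resid**2).sum())

    res = optimize.minimize_scalar(sse, bounds=M_BOUNDS, method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise ValidationError(f"NCM fit did not converge: {res.message}")
    m_hat = float(res.x)
    pred = freq_predicted(p, m_hat, N)
    ss_err = float(((freq_obs - pred) ** 2).sum())
    ss_tot = float(((freq_obs - freq_obs.mean()) ** 2).sum())
    r2 = 1.0 - ss_err / ss_tot if ss_tot > 0 else (1.0 if ss_err == 0 else -np.inf)
    taxa = pd.DataFrame(
        {
            "p_i": p,
            "freq_obs": freq_obs,
            "freq_pred": pred,
            "pred_lwr": np.nan,
            "pred_upr": np.nan,
            "class": "",
        },
        index=pd.Index(sub.taxon_ids, name="taxon_id"),
    )
    fit = NCMFit(m=m_hat, N=N, r_squared=float(r2), taxa=taxa,
                 n_samples=sub.n_samples)
    return ncm_bounds(fit, sub.n_samples)


def wilson_interval(p: np.ndarray, n: int, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Wilson score interval for a binomial proportion (vectorized)."""
    if not 0 < level < 1:
        raise ValidationError(f"confidence level {level} outside (0, 1)")
    p = np.asarray(p, dtype=float)
    z = stats.norm.ppf(0.5 + level / 2.0)
    denom = 1.0 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    return np.clip(center - half, 0.0, 1.0), np.clip(center + half, 0.0, 1.0)


def ncm_bounds(fit: NCMFit, n_samples: int, level: float = 0.95) -> NCMFit:
    """Attach Wilson prediction bounds and above/within/below classes."""
    pred = fit.taxa["freq_pred"].to_numpy()
    lwr, upr = wilson_interval(pred, n_samples, level)
    obs = fit.taxa["freq_obs"].to_numpy()
    cls = np.where(obs > upr, "above", np.where(obs < lwr, "below", "within"))
    fit.taxa["pred_lwr"] = lwr
    fit.taxa["pred_upr"] = upr
    fit.taxa["class"] = cls
    return fit
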