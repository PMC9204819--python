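"""Empirical-Bayes moderated t-testing with an intensity-dependent variance trend.

For a log2 feature matrix with channels assigned to groups, each feature's
residual variance ``s^2`` (df ``d = n_channels - n_groups``) is shrunk toward
a trend value ``s0^2(intensity)`` obtained by local regression of
``log s^2`` on mean log2 intensity. The prior degrees of freedom ``d0`` are
estimated by moment-matching the spread of ``log(s^2 / s0^2)`` against the
theoretical log-F distribution, using trigamma inversion. The posterior
variance

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

yields moderated t statistics ``log2FC / (s~ * sqrt(1/n1 + 1/n2))`` with
``d0 + d`` degrees of freedom. Multiple testing is corrected per contrast by
the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .exceptions import DesignError, ParameterError
from .synthetic import parse_contrast

_TINY = 1e-300
#: Local-regression span for the variance trend, with one robustifying pass.
TREND_SPAN = 0.4


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    ``q_i = min_{j >= rank(i)} (m * p_(j) / j)``, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ParameterError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return y


def _fit_variance_prior(
    s2: np.ndarray, df: float, amean: np.ndarray, trend: bool
) -> tuple[float, np.ndarray]:
    """Estimate prior df ``d0`` and trend variance ``s0^2`` per feature.

    Moment-matching on ``e = log(s^2) - digamma(d/2) + log(d/2)``: under the
    scaled-F model, E[e] = log(s0^2) - digamma(d0/2) + log(d0/2) and
    Var[e - trend] = trigamma(d/2) + trigamma(d0/2).
    """
    ok = np.isfinite(s2) & (s2 > _TINY)
    if not ok.any():
        # degenerate (e.g. noise-free) input: every residual variance is zero
        return np.inf, np.full_like(s2, _TINY)
    z = np.log(np.clip(s2, _TINY, None))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)

    if trend and ok.sum() >= 10:
        fitted = lowess(e[ok], amean[ok], frac=TREND_SPAN, it=1, return_sorted=False)
        etrend = np.empty_like(e)
        etrend[ok] = fitted
        if (~ok).any():
            srt = np.argsort(amean[ok])
            etrend[~ok] = np.interp(amean[~ok], amean[ok][srt], fitted[srt])
    else:
        etrend = np.full_like(e, e[ok].mean() if ok.any() else 0.0)

    resid = e[ok] - etrend[ok]
    evar = float(np.var(resid, ddof=1)) if resid.size > 1 else 0.0
    evar -= float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = np.exp(etrend + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(etrend)
    return d0, s0_sq


@dataclass
class ModeratedFit:
    """Fitted moderated test: tidy per-contrast results plus hyperparameters."""

    results: pd.DataFrame  # feature_id, contrast, log2fc, t, df_resid, df_prior, p, q
    d0: float
    s0_sq: np.ndarray
    s2: np.ndarray
    amean: np.ndarray

    def for_contrast(self, contrast: str) -> pd.DataFrame:
        out = self.results[self.results["contrast"] == contrast]
        if out.empty:
            raise ParameterError(f"contrast {contrast!r} not fitted")
        return out.reset_index(drop=True)


def fit_moderated_test(
    values: pd.DataFrame,
    groups: Mapping[str, str],
    contrasts: Sequence[str],
    trend: bool = True,
    prior_df: float | None = None,
) -> ModeratedFit:
    """Moderated differential testing of a log2 feature matrix.

    Parameters
    ----------
    values
        Features x channels, log2 scale, indexed by feature id.
    groups
        Channel label -> group label; every group needs >= 2 channels.
    contrasts
        Contrast strings ``"num_vs_den"``; log2FC = mean(num) - mean(den).
    trend
        Fit the intensity-dependent prior variance; with ``False`` the prior
        variance is constant (classic no-trend moderation).
    prior_df
        Override the estimated prior df (0 recovers the ordinary pooled t).
    """
    labels = list(values.columns)
    unknown = [c for c in labels if c not in groups]
    if unknown:
        raise DesignError(f"channels without a group assignment: {unknown}")
    group_names = list(dict.fromkeys(groups[c] for c in labels))
    members = {g: [c for c in labels if groups[c] == g] for g in group_names}
    for g, chans in members.items():
        if len(chans) < 2:
            raise DesignError(f"group {g!r} has fewer than 2 channels")

    X = values.to_numpy(dtype=float)
    n, k = X.shape[1], len(group_names)
    df_resid = n - k
    if df_resid < 1:
        raise DesignError("residual degrees of freedom must be >= 1")

    col_idx = {c: i for i, c in enumerate(labels)}
    means = {g: X[:, [col_idx[c] for c in members[g]]].mean(axis=1) for g in group_names}
    rss = np.zeros(X.shape[0])
    for g in group_names:
        block = X[:, [col_idx[c] for c in members[g]]]
        rss += ((block - means[g][:, None]) ** 2).sum(axis=1)
    s2 = rss / df_resid
    amean = X.mean(axis=1)

    d0_est, s0_sq = _fit_variance_prior(s2, df_resid, amean, trend)
    d0 = d0_est if prior_df is None else float(prior_df)

    if np.isinf(d0):
        s2_post = s0_sq
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    frames = []
    for contrast in contrasts:
        num, den = parse_contrast(contrast)
        if num not in members or den not in members:
            raise DesignError(f"contrast {contrast!r} references unknown groups")
        log2fc = means[num] - means[den]
        se = np.sqrt(s2_post * (1.0 / len(members[num]) + 1.0 / len(members[den])))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, log2fc / se, np.sign(log2fc) * np.inf)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": values.index.astype(str),
                    "contrast": contrast,
                    "log2fc": log2fc,
                    "t": t,
                    "df_resid": float(df_resid),
                    "df_prior": d0,
                    "p": p,
                    "q": bh_fdr(p),
                }
            )
        )
    results = pd.concat(frames, ignore_index=True)
    return ModeratedFit(results=results, d0=d0, s0_sq=s0_sq, s2=s2, amean=amean)
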