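"""Survival curves and the species x elevation proportional-hazards test.

Mortality of transplanted clones is the fitness evidence for adaptive
divergence: each species should survive best at its native elevation, and
that pattern is a species x site interaction on the hazard scale.  The
module provides

* Kaplan-Meier product-limit curves (Greenwood variance, log-log
  confidence bands) per group,
* a Cox proportional-hazards fit of ``species + site + species:site`` by
  direct Newton maximisation of the partial likelihood with Breslow tie
  handling (Efron available), optionally with a shared gamma frailty per
  genotype estimated by EM,
* the likelihood-ratio test comparing the full model against the
  interaction-free reduction, and
* a transplant-shock pre-filter removing plants that died within a short
  window after transplanting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from lifelines import KaplanMeierFitter

__all__ = [
    "remove_transplant_shock",
    "km_curve",
    "CoxFit",
    "cox_fit",
    "interaction_lrt",
]

logger = logging.getLogger(__name__)


def remove_transplant_shock(records: pd.DataFrame, shock_window_days: float = 3.0) -> pd.DataFrame:
    """Drop plants that died within the transplant-shock window.

    Deaths within the first few days reflect failed establishment of the
    cutting rather than the site environment, so they are excluded before
    any survival modelling.  Censored records are never removed.
    """
    mask = (records["event"] == 1) & (records["time"] <= shock_window_days)
    removed = int(mask.sum())
    if removed:
        logger.info("removed %d transplant-shock deaths (time <= %g d)", removed, shock_window_days)
    return records.loc[~mask].reset_index(drop=True)


def km_curve(records: pd.DataFrame, group_cols: list[str] | None = None) -> pd.DataFrame:
    """Kaplan-Meier survival estimates per group.

    Returns a long table with one row per event time per group: the
    product-limit estimate and its 95% log-log (exponential Greenwood)
    confidence band.  A group with no events yields a flat curve at one.
    """
    if group_cols is None:
        group_cols = ["species", "site"]
    out = []
    for key, sub in records.groupby(group_cols):
        if not isinstance(key, tuple):
            key = (key,)
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_
        ci = kmf.confidence_interval_
        tbl = pd.DataFrame(
            {
                "time": sf.index.to_numpy(),
                "survival": sf.iloc[:, 0].to_numpy(),
                "ci_lower": ci.iloc[:, 0].to_numpy(),
                "ci_upper": ci.iloc[:, 1].to_numpy(),
            }
        )
        for col, val in zip(group_cols, key):
            tbl[col] = val
        out.append(tbl)
    return pd.concat(out, ignore_index=True)[group_cols + ["time", "survival", "ci_lower", "ci_upper"]]


# ---------------------------------------------------------------------------
# Cox partial likelihood


def _design_matrix(records: pd.DataFrame, interaction: bool) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design for species + site (+ species:site), no intercept
    column (the Cox model has no baseline parameter)."""
    sp = pd.Categorical(records["species"])
    site = pd.Categorical(records["site"])
    cols, names = [], []
    for lev in sp.categories[1:]:
        cols.append((records["species"] == lev).to_numpy(dtype=float))
        names.append(f"species[{lev}]")
    for lev in site.categories[1:]:
        cols.append((records["site"] == lev).to_numpy(dtype=float))
        names.append(f"site[{lev}]")
    if interaction:
        for s_lev in sp.categories[1:]:
            for e_lev in site.categories[1:]:
                cols.append(
                    (
                        (records["species"] == s_lev) & (records["site"] == e_lev)
                    ).to_numpy(dtype=float)
                )
                names.append(f"species[{s_lev}]:site[{e_lev}]")
    x = np.column_stack(cols) if cols else np.empty((len(records), 0))
    return x, names


def _cox_loglik(
    beta: np.ndarray,
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    offset: np.ndarray,
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient and Hessian (Breslow or Efron ties).

    Observations must be sorted by ascending time.  Cumulative risk-set
    sums are built from the bottom of the sort order.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method {ties!r}")
    eta = x @ beta + offset
    w = np.exp(eta)
    n, p = x.shape
    # suffix sums over the risk set {j : t_j >= t}
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * x)[::-1], axis=0)[::-1]
    s2 = np.cumsum((w[:, None, None] * (x[:, :, None] * x[:, None, :]))[::-1], axis=0)[::-1]

    starts = np.flatnonzero(np.r_[True, time[1:] != time[:-1]])
    d_g = np.add.reduceat(event.astype(float), starts)
    keep = d_g > 0
    starts_e = starts[keep]
    d_e = d_g[keep]

    ev = event == 1
    ll = float(eta[ev].sum())
    grad = x[ev].sum(axis=0).astype(float)
    hess = np.zeros((p, p))
    if ties == "breslow":
        s0g = s0[starts_e]
        m1 = s1[starts_e] / s0g[:, None]
        ll -= float(d_e @ np.log(s0g))
        grad -= d_e @ m1
        m2 = s2[starts_e] / s0g[:, None, None]
        hess -= np.einsum("g,gij->ij", d_e, m2 - m1[:, :, None] * m1[:, None, :])
    else:  # efron
        bounds = np.r_[starts, n]
        for gi, s in enumerate(starts_e):
            g_idx = np.searchsorted(starts, s)
            sl = slice(bounds[g_idx], bounds[g_idx + 1])
            dead = ev[sl]
            d = int(d_e[gi])
            wd = w[sl][dead]
            xd = x[sl][dead]
            sd0 = wd.sum()
            sd1 = wd @ xd
            sd2 = (wd[:, None, None] * (xd[:, :, None] * xd[:, None, :])).sum(axis=0)
            f = np.arange(d) / d
            denom = s0[s] - f * sd0  # (d,)
            ll -= float(np.log(denom).sum())
            num1 = s1[s][None, :] - f[:, None] * sd1[None, :]
            gt = num1 / denom[:, None]
            grad -= gt.sum(axis=0)
            num2 = s2[s][None, :, :] - f[:, None, None] * sd2[None, :, :]
            hess -= (num2 / denom[:, None, None]).sum(axis=0)
            hess += np.einsum("gi,gj->ij", gt, gt)
    return ll, grad, hess


def _newton_cox(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    offset: np.ndarray,
    ties: str,
    max_iter: int = 50,
    tol: float = 1e-9,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, bool, float]:
    p = x.shape[1]
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    ll_old = -np.inf
    converged = False
    gnorm = np.inf
    for _ in range(max_iter):
        ll, grad, hess = _cox_loglik(beta, x, time, event, offset, ties)
        gnorm = float(np.linalg.norm(grad))
        try:
            step = np.linalg.solve(hess - 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step-halving on the Newton direction
        new = beta - step
        for _ in range(30):
            ll_new, _, _ = _cox_loglik(new, x, time, event, offset, ties)
            if ll_new >= ll - 1e-12:
                break
            new = (beta + new) / 2
        beta = new
        if abs(ll_new - ll_old) < tol and gnorm < 1e-5:
            converged = True
            ll = ll_new
            break
        ll_old = ll_new
        ll = ll_new
    if np.abs(beta).max() > 15:
        logger.warning(
            "cox_fit: very large coefficient (|beta|>15) — possible monotone "
            "likelihood / complete separation; estimates unreliable"
        )
    _, _, hess = _cox_loglik(beta, x, time, event, offset, ties)
    return beta, hess, float(ll), converged, gnorm


def _breslow_cumhaz(
    x: np.ndarray, time: np.ndarray, event: np.ndarray, offset: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """Breslow cumulative baseline hazard evaluated at each subject's time,
    multiplied by the subject's own risk score (i.e. subject-level expected
    event count under the fit)."""
    w = np.exp(x @ beta + offset)
    s0 = np.cumsum(w[::-1])[::-1]
    n = len(time)
    h0 = np.zeros(n)  # baseline hazard increments at each (sorted) time
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d = sum(event[i:j])
        if d:
            h0[i] = d / s0[i]
        i = j
    cum_h0 = np.cumsum(h0)
    # subject's cumulative baseline hazard is at its own (sorted) position
    return cum_h0 * w


@dataclass
class CoxFit:
    """Cox proportional-hazards fit with optional genotype frailty."""

    coef: pd.Series
    se: pd.Series
    loglik: float
    ties: str
    converged: bool
    gradient_norm: float
    n: int
    n_events: int
    has_interaction: bool
    frailty_variance: float | None = None
    frailty: pd.Series | None = field(default=None, repr=False)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coef)


def cox_fit(
    records: pd.DataFrame,
    interaction: bool = True,
    ties: str = "breslow",
    frailty: bool = False,
    frailty_col: str = "genotype",
    max_em_iter: int = 30,
) -> CoxFit:
    """Fit the species x site proportional-hazards model.

    ``interaction=False`` drops the species:site terms (the reduced model
    for the likelihood-ratio test).  With ``frailty=True`` a shared gamma
    frailty per level of ``frailty_col`` multiplies the hazard; it is
    estimated by EM (posterior-mean frailties entering as offsets, the
    frailty variance by profile likelihood).  If the EM fails the fit
    falls back to the fixed-effects model with a logged note.
    """
    if records["event"].sum() < 2:
        raise ValueError("need at least two events to fit a Cox model")
    rec = records.sort_values("time", kind="mergesort").reset_index(drop=True)
    x, names = _design_matrix(rec, interaction)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("collinear design: check species/site factor levels")
    time = rec["time"].to_numpy(dtype=float)
    event = rec["event"].to_numpy(dtype=int)
    offset = np.zeros(len(rec))

    beta, hess, ll, converged, gnorm = _newton_cox(x, time, event, offset, ties)
    theta = None
    frail_series = None
    if frailty:
        try:
            beta, hess, ll, converged, gnorm, theta, frail_series = _gamma_frailty_em(
                rec, x, time, event, beta, ties, frailty_col, max_em_iter
            )
        except Exception as exc:  # pragma: no cover - defensive fallback
            logger.warning("frailty EM failed (%s); falling back to fixed-effects Cox", exc)
            beta, hess, ll, converged, gnorm = _newton_cox(x, time, event, offset, ties)
            theta = None
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return CoxFit(
        coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        loglik=ll,
        ties=ties,
        converged=converged,
        gradient_norm=gnorm,
        n=len(rec),
        n_events=int(event.sum()),
        has_interaction=interaction,
        frailty_variance=theta,
        frailty=frail_series,
    )


def _gamma_frailty_em(
    rec: pd.DataFrame,
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    beta0: np.ndarray,
    ties: str,
    frailty_col: str,
    max_em_iter: int,
):
    """Shared gamma frailty per group, EM with posterior-mean offsets.

    E-step: with frailty variance theta, the posterior mean frailty of
    group g is (1/theta + D_g) / (1/theta + H_g), D_g the group's event
    count and H_g its accumulated expected events.  M-step refits beta
    with log-frailty offsets; theta maximises the gamma-frailty profile
    marginal likelihood.
    """
    groups = pd.Categorical(rec[frailty_col])
    g_idx = groups.codes
    n_g = len(groups.categories)
    theta = 0.1
    beta = beta0.copy()
    w_g = np.ones(n_g)
    ll = -np.inf
    for _ in range(max_em_iter):
        offset = np.log(w_g)[g_idx]
        beta, hess, ll, conv, gnorm = _newton_cox(x, time, event, offset, ties, beta0=beta)
        h_subj = _breslow_cumhaz(x, time, event, np.zeros(len(rec)), beta)
        d_g = np.bincount(g_idx, weights=event, minlength=n_g)
        h_g = np.bincount(g_idx, weights=h_subj, minlength=n_g)

        def _neg_marg(log_theta: float) -> float:
            th = np.exp(log_theta)
            nu = 1.0 / th
            # gamma-frailty marginal contribution per group
            term = (
                gammaln(nu + d_g) - gammaln(nu)
                + nu * np.log(nu)
                - (nu + d_g) * np.log(nu + h_g)
            )
            return -float(term.sum())

        opt = minimize_scalar(_neg_marg, bounds=(np.log(1e-4), np.log(10.0)), method="bounded")
        theta_new = float(np.exp(opt.x))
        nu = 1.0 / theta_new
        w_new = (nu + d_g) / (nu + h_g)
        if np.max(np.abs(w_new - w_g)) < 1e-6 and abs(theta_new - theta) < 1e-6:
            w_g = w_new
            theta = theta_new
            break
        w_g, theta = w_new, theta_new
    frail = pd.Series(w_g, index=list(groups.categories), name="frailty")
    return beta, hess, ll, conv, gnorm, theta, frail


def interaction_lrt(full: CoxFit, reduced: CoxFit) -> dict[str, float]:
    """Likelihood-ratio test of the species x site interaction.

    ``chi2 = 2 (logPL_full - logPL_reduced)`` on degrees of freedom equal
    to the number of interaction parameters dropped.  Both fits must use
    the same tie handling and frailty setting.
    """
    if not full.has_interaction or reduced.has_interaction:
        raise ValueError("pass (full with interaction, reduced without)")
    if full.ties != reduced.ties:
        raise ValueError("fits use different tie handling; not comparable")
    if not set(reduced.coef.index) <= set(full.coef.index):
        raise ValueError("reduced model is not nested in the full model")
    df = len(full.coef) - len(reduced.coef)
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return {
        "chi2": chi2,
        "df": df,
        "p_value": float(stats.chi2.sf(chi2, df)),
    }
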