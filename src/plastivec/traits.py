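"""Trait derivation and univariate reaction-norm analysis.

Derived quantities
------------------
* leaf complexity = perimeter^2 / area (dimensionless; higher values mean
  more dissected leaf margins),
* indent density = number of margin indentations / perimeter,
* SLA (specific leaf area) = area / dry mass (mm^2 / mg),
* intrinsic water-use efficiency WUE = photosynthesis A / stomatal
  conductance gs,
* saturation-pulse quantum yields Y(II), Y(NPQ), Y(NO) partitioning
  absorbed light into photochemistry, regulated and non-regulated heat
  dissipation (they sum to one by construction),
* PI_total, the JIP-test total performance index of photosystems I and II.

Statistical layer
-----------------
The reaction-norm model for one trait is a linear mixed model with
species, transplant site and their interaction as fixed effects, and
genotype-by-site and block-within-site random intercepts:

    y = species + site + species:site + (1|genotype:site) + (1|block) + e

The species x site interaction is tested with a likelihood-ratio test on
full-maximum-likelihood refits (REML likelihoods are not comparable across
fixed structures); p-values are corrected for multiple traits by
multiplying by the number of tests and capping at one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "derive_leaf_traits",
    "water_use_efficiency",
    "quantum_yields",
    "pi_total",
    "clone_means",
    "genotype_means",
    "MixedModelFit",
    "fit_trait_model",
    "pairwise_site_tests",
    "welch_t",
    "species_comparison_test",
    "soil_mds",
]

logger = logging.getLogger(__name__)

TRAIT_COLUMNS = ["species", "genotype", "site", "block", "clone", "trait", "value"]


def _require_positive(df: pd.DataFrame, col: str) -> None:
    bad = ~(df[col] > 0)
    if bad.any():
        idx = df.index[bad][0]
        raise ValueError(
            f"{col} must be strictly positive; first offending row index {idx!r}"
        )


def derive_leaf_traits(measurements: pd.DataFrame) -> pd.DataFrame:
    """Compute leaf complexity, indent density and SLA per leaf.

    Parameters
    ----------
    measurements
        One row per scanned leaf with columns ``area`` (mm^2),
        ``perimeter`` (mm), ``n_indents`` (count) and ``dry_weight`` (mg).
        Any identifier columns (clone, leaf id, ...) are carried through.

    Returns
    -------
    The input frame with ``leaf_complexity``, ``indent_density`` and
    ``sla`` columns appended.
    """
    for col in ("area", "perimeter", "dry_weight"):
        if col not in measurements:
            raise KeyError(f"missing required column {col!r}")
        _require_positive(measurements, col)
    if (measurements["n_indents"] < 0).any():
        raise ValueError("n_indents must be non-negative")
    out = measurements.copy()
    out["leaf_complexity"] = out["perimeter"] ** 2 / out["area"]
    out["indent_density"] = out["n_indents"] / out["perimeter"]
    out["sla"] = out["area"] / out["dry_weight"]
    return out


def water_use_efficiency(a: float | np.ndarray, gs: float | np.ndarray) -> float | np.ndarray:
    """Intrinsic water-use efficiency: photosynthesis per unit conductance."""
    gs = np.asarray(gs, dtype=float)
    if np.any(gs <= 0):
        raise ValueError("stomatal conductance gs must be positive")
    return np.asarray(a, dtype=float) / gs


def quantum_yields(f: float, fm_prime: float, fm: float) -> dict[str, float]:
    """Partition absorbed light energy from saturation-pulse fluorometry.

    Uses the standard lake-model partition: Y(II) = (Fm' - F)/Fm' is the
    photochemical yield, Y(NO) = F/Fm the non-regulated loss relative to
    the dark-adapted maximum Fm, and Y(NPQ) = F/Fm' - F/Fm the regulated
    thermal dissipation.  The three always sum to one.
    """
    if not (0 < f <= fm_prime <= fm):
        raise ValueError(
            "invalid fluorescence: need 0 < F <= Fm' <= Fm "
            f"(got F={f}, Fm'={fm_prime}, Fm={fm})"
        )
    y_ii = (fm_prime - f) / fm_prime
    y_no = f / fm
    y_npq = f / fm_prime - f / fm
    return {"Y_II": y_ii, "Y_NPQ": y_npq, "Y_NO": y_no}


def pi_total(rc_per_abs: float, phi_p0: float, psi_e0: float, delta_r0: float) -> float:
    """JIP-test total performance index of photosystem I and II.

    Product of four flux-ratio factors from the fast (OJIP) fluorescence
    induction curve::

        PI_total = (RC/ABS) * phi_P0/(1-phi_P0) * psi_E0/(1-psi_E0)
                   * delta_R0/(1-delta_R0)

    ``RC/ABS`` is the density of active reaction centres per absorbed
    photon flux; ``phi_P0`` the maximum quantum yield of primary
    photochemistry (Fv/Fm); ``psi_E0`` the probability that a trapped
    exciton moves an electron past QA; and ``delta_R0`` the efficiency of
    electron transfer to the PSI end acceptors.
    """
    if rc_per_abs <= 0:
        raise ValueError("RC/ABS must be positive")
    for name, v in [("phi_p0", phi_p0), ("psi_e0", psi_e0), ("delta_r0", delta_r0)]:
        if not 0 < v < 1:
            raise ValueError(f"{name} must lie strictly between 0 and 1, got {v}")
    return (
        rc_per_abs
        * phi_p0 / (1 - phi_p0)
        * psi_e0 / (1 - psi_e0)
        * delta_r0 / (1 - delta_r0)
    )


# ---------------------------------------------------------------------------
# aggregation


def clone_means(table: pd.DataFrame) -> pd.DataFrame:
    """Average repeated leaf measurements to one value per clone per trait."""
    keys = ["species", "genotype", "site", "block", "clone", "trait"]
    out = table.groupby(keys, as_index=False, sort=False)["value"].mean()
    return out


def remove_block_effects(table: pd.DataFrame) -> pd.DataFrame:
    """Subtract estimated block deviations within each site and trait.

    Each observation is adjusted by its (site, block) mean's deviation
    from the site mean, pooled over species and genotypes.  Blocks are
    shared by both species within a site, so unremoved block noise does
    not average out with genotype count and would otherwise put a floor
    on the precision of multivariate cell means; with a balanced design
    this adjustment is unbiased for the species x site cell means.
    """
    t = table.copy()
    site_mean = t.groupby(["trait", "site"])["value"].transform("mean")
    block_mean = t.groupby(["trait", "site", "block"])["value"].transform("mean")
    t["value"] = t["value"] - (block_mean - site_mean)
    return t


def genotype_means(table: pd.DataFrame) -> pd.DataFrame:
    """Average clone values to one value per genotype per site per trait.

    Groups with no finite observation are dropped with a logged warning.
    """
    t = table.dropna(subset=["value"])
    dropped = len(table) - len(t)
    if dropped:
        logger.warning("genotype_means: dropped %d missing observations", dropped)
    keys = ["species", "genotype", "site", "trait"]
    out = t.groupby(keys, as_index=False, sort=False).agg(
        value=("value", "mean"), n_clones=("value", "size")
    )
    return out


# ---------------------------------------------------------------------------
# mixed model


@dataclass
class MixedModelFit:
    """Result of the univariate reaction-norm mixed model for one trait."""

    trait: str
    fixed_effects: pd.Series
    var_genotype_by_site: float
    var_block: float
    var_residual: float
    lrt_chi2: float
    lrt_df: int
    p_raw: float
    p_adjusted: float
    n_tests: int
    converged: bool
    cell_means: pd.DataFrame = field(repr=False)
    data: pd.DataFrame = field(repr=False)


def _balanced_design_stats(df: pd.DataFrame) -> dict | None:
    """Sufficient statistics for the exact balanced-design likelihood.

    For a perfectly balanced two-species layout (equal genotypes per
    species, equal blocks per site, equal clones per genotype x block)
    the mixed model's covariance is block-diagonal by site and its
    strata (genotype contrasts, block contrasts, cell interaction and
    within-cell residual) are eigenspaces with variances

        lambda_E  = sigma_e^2                      (residual strata)
        lambda_B  = sigma_e^2 + P*G*C * sigma_b^2  (block contrasts)
        lambda_G  = sigma_e^2 + B*C   * sigma_g^2  (genotype contrasts)
        lambda_0  = lambda_G + P*G*C * sigma_b^2 - ...  (site grand mean)

    so the profile ML likelihood of both fixed structures reduces to a
    three-parameter optimisation over precomputed sums of squares.
    Returns None when the layout is not balanced.
    """
    species = df["species"].unique()
    if len(species) != 2:
        return None
    counts = df.groupby(["site", "species", "genotype", "block"], observed=True).size()
    if counts.nunique() != 1:
        return None
    nc = int(counts.iloc[0])
    g_per_sp = df.groupby("species")["genotype"].nunique()
    if g_per_sp.nunique() != 1:
        return None
    g = int(g_per_sp.iloc[0])
    b_per_site = df.groupby("site")["block"].nunique()
    if b_per_site.nunique() != 1:
        return None
    nb = int(b_per_site.iloc[0])
    sites = df["site"].unique()
    s = len(sites)
    # every genotype in every block at every site?
    if len(df) != 2 * g * s * nb * nc:
        return None
    per_cell = df.groupby(["site", "genotype"], observed=True).size()
    if per_cell.nunique() != 1 or int(per_cell.iloc[0]) != nb * nc:
        return None

    p = 2
    ss_e = 0.0
    ss_b = 0.0
    ss_gc = 0.0
    u = []
    sp0 = species[0]
    for site in sites:
        sub = df[df["site"] == site]
        y = sub["value"].to_numpy()
        cell = sub.groupby(["genotype", "block"], observed=True)["value"].transform("mean")
        gbar = sub.groupby("genotype", observed=True)["value"].transform("mean")
        bbar = sub.groupby("block", observed=True)["value"].transform("mean")
        sbar = y.mean()
        spbar = sub.groupby("species", observed=True)["value"].transform("mean")
        # row sums equal the stratum sums of squares (each cell/block/
        # genotype mean is repeated over its members)
        ss_e += float(((y - cell) ** 2).sum())
        ss_e += float(((cell - gbar - bbar + sbar) ** 2).sum())
        ss_b += float(((bbar - sbar) ** 2).sum())
        ss_gc += float(((gbar - spbar) ** 2).sum())
        m_sp = sub.groupby("species", observed=True)["value"].mean()
        u.append(np.sqrt(g * nb * nc / 2.0) * (m_sp[sp0] - m_sp[species[1]]))
    u = np.asarray(u)
    d_e = s * (p * g * nb * (nc - 1) + (p * g - 1) * (nb - 1))
    return {
        "S": s, "P": p, "G": g, "B": nb, "C": nc,
        "ss_e": ss_e, "d_e": d_e,
        "ss_b": ss_b, "d_b": s * (nb - 1),
        "ss_gc": ss_gc, "d_gc": s * p * (g - 1),
        "u": u,
    }


def _balanced_ml_lrt(stats_d: dict) -> tuple[float, dict]:
    """Exact full-ML likelihood-ratio test of the species x site
    interaction from balanced-design sufficient statistics.

    Both fixed structures are profiled analytically except for the three
    variance parameters, which are optimised numerically on the log
    scale.  Returns (chi2, full-model ML variance estimates).
    """
    from scipy.optimize import minimize

    s = stats_d["S"]
    p, g, nb, nc = stats_d["P"], stats_d["G"], stats_d["B"], stats_d["C"]
    ss_e, d_e = stats_d["ss_e"], stats_d["d_e"]
    ss_b, d_b = stats_d["ss_b"], stats_d["d_b"]
    ss_gc, d_gc = stats_d["ss_gc"], stats_d["d_gc"]
    u = stats_d["u"]
    ss_u = float(((u - u.mean()) ** 2).sum())
    log2pi = np.log(2 * np.pi)

    def neg2ll(logv, reduced: bool) -> float:
        ve, vg, vb = np.exp(logv)
        lam_e = ve
        lam_b = ve + p * g * nc * vb
        lam_g = ve + nb * nc * vg
        lam_0 = ve + nb * nc * vg + p * g * nc * vb
        val = (
            d_e * (log2pi + np.log(lam_e)) + ss_e / lam_e
            + d_b * (log2pi + np.log(lam_b)) + ss_b / lam_b
            + d_gc * (log2pi + np.log(lam_g)) + ss_gc / lam_g
            + s * (log2pi + np.log(lam_g))  # species-contrast directions
            + s * (log2pi + np.log(lam_0))  # site grand-mean directions
        )
        if reduced:
            val += ss_u / lam_g
        return float(val)

    res_full = res_red = None
    for x0 in ([0.0, -1.0, -1.0], [0.0, -6.0, -6.0]):
        rf = minimize(neg2ll, x0, args=(False,), method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000})
        rr = minimize(neg2ll, x0, args=(True,), method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000})
        if res_full is None or rf.fun < res_full.fun:
            res_full = rf
        if res_red is None or rr.fun < res_red.fun:
            res_red = rr
    chi2 = max(0.0, res_red.fun - res_full.fun)
    ve, vg, vb = np.exp(res_full.x)
    return chi2, {"var_residual": ve, "var_genotype_by_site": vg, "var_block": vb}


def _check_model_inputs(df: pd.DataFrame) -> None:
    if df["species"].nunique() < 2:
        raise ValueError("reaction-norm model needs at least two species")
    if df["site"].nunique() < 2:
        raise ValueError("reaction-norm model needs at least two sites")
    per_sp = df.groupby("species")["genotype"].nunique()
    if (per_sp < 2).any():
        raise ValueError("need at least two genotypes per species")


def fit_trait_model(
    table: pd.DataFrame, trait: str, n_tests: int = 1, lrt_only: bool = False
) -> MixedModelFit:
    """Fit the reaction-norm mixed model for one trait and test the
    species x site interaction.

    Variance components are estimated by REML; the interaction LRT refits
    the full and interaction-free fixed structures under full maximum
    likelihood.  The adjusted p-value multiplies the raw LRT p by
    ``n_tests`` (capped at one).  ``lrt_only`` skips the REML fit and
    reports the full-ML variance components instead (used by simulation
    studies that only consume the LRT).
    """
    df = table.loc[table["trait"] == trait].copy()
    if df.empty:
        raise ValueError(f"trait {trait!r} not present in table")
    _check_model_inputs(df)
    df["site_f"] = df["site"].astype(str)
    df["gxs"] = df["genotype"].astype(str) + ":" + df["site_f"]
    df["blk"] = df["site_f"] + ":" + df["block"].astype(str)
    vc = {"gxs": "0 + C(gxs)", "blk": "0 + C(blk)"}
    ones = np.ones(len(df))

    def _fit(formula: str, reml: bool):
        # bfgs first; on non-convergence (variance components at the zero
        # boundary) retry with powell and keep the higher-likelihood fit
        md = smf.mixedlm(formula, df, groups=ones, vc_formula=vc, re_formula="0")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = md.fit(reml=reml, method="bfgs")
            if not res.converged:
                alt = md.fit(reml=reml, method="powell")
                if alt.converged and (not res.converged or alt.llf >= res.llf):
                    res = alt
            return res

    full_formula = "value ~ C(species) * C(site_f)"
    dfree = (df["species"].nunique() - 1) * (df["site_f"].nunique() - 1)

    bal = _balanced_design_stats(df)
    if bal is not None:
        # exact profile-ML likelihood ratio via the stratum decomposition
        chi2, ml_vars = _balanced_ml_lrt(bal)
        converged = True
    else:
        res_full = _fit(full_formula, reml=False)
        res_red = _fit("value ~ C(species) + C(site_f)", reml=False)
        chi2 = max(0.0, 2.0 * (res_full.llf - res_red.llf))
        ml_vars = None
        converged = bool(res_full.converged and res_red.converged)

    if lrt_only and bal is not None:
        res_reml = None
        vcomp = {"gxs": ml_vars["var_genotype_by_site"], "blk": ml_vars["var_block"]}
        scale = ml_vars["var_residual"]
        fe = pd.Series(dtype=float)
    else:
        res_reml = _fit(full_formula, reml=True)
        converged = converged and bool(res_reml.converged)
        vcomp = dict(zip(res_reml.model.exog_vc.names, np.atleast_1d(res_reml.vcomp)))
        scale = float(res_reml.scale)
        fe = res_reml.fe_params

    p_raw = float(stats.chi2.sf(chi2, dfree))
    if not converged:
        logger.warning("fit_trait_model(%s): optimiser did not fully converge", trait)
    cells = (
        df.groupby(["species", "site"], as_index=False)["value"]
        .mean()
        .rename(columns={"value": "mean"})
    )
    return MixedModelFit(
        trait=trait,
        fixed_effects=fe,
        var_genotype_by_site=float(vcomp.get("gxs", np.nan)),
        var_block=float(vcomp.get("blk", np.nan)),
        var_residual=float(scale),
        lrt_chi2=float(chi2),
        lrt_df=int(dfree),
        p_raw=p_raw,
        p_adjusted=min(1.0, p_raw * n_tests),
        n_tests=n_tests,
        converged=converged,
        cell_means=cells,
        data=df,
    )


def _letters_from_pmatrix(levels: list, pmat: pd.DataFrame, alpha: float) -> dict:
    """Greedy compact letter display: sites sharing a letter do not differ."""
    groups: list[set] = []
    for lev in levels:
        placed = False
        for g in groups:
            if all(pmat.loc[lev, other] >= alpha for other in g):
                g.add(lev)
                placed = True
        if not placed:
            groups.append({lev})
    letters = {lev: "" for lev in levels}
    for i, g in enumerate(groups):
        ch = chr(ord("a") + i)
        for lev in sorted(g, key=levels.index):
            letters[lev] += ch
    return letters


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of
    freedom; used both for the common-garden species comparisons and the
    within-species pairwise site contrasts.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return 0.0, float(nx + ny - 2), 1.0
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def pairwise_site_tests(
    fit: MixedModelFit, alpha: float = 0.05, on_genotype_means: bool = True
) -> pd.DataFrame:
    """All within-species pairwise site contrasts with letter groupings.

    Contrasts are Welch t-tests on genotype means (one mean per genotype
    per site) by default, with the p-value multiplied by the number of
    pairs per species and capped at one.  Sites sharing a letter within a
    species are not significantly different at ``alpha``.
    """
    data = fit.data
    if on_genotype_means:
        data = (
            data.groupby(["species", "genotype", "site"], as_index=False)["value"].mean()
        )
    rows = []
    letter_rows = []
    for sp, sub in data.groupby("species"):
        sites = sorted(sub["site"].unique())
        pairs = list(combinations(sites, 2))
        pmat = pd.DataFrame(1.0, index=sites, columns=sites)
        for s1, s2 in pairs:
            x = sub.loc[sub["site"] == s1, "value"].to_numpy()
            y = sub.loc[sub["site"] == s2, "value"].to_numpy()
            t, dfree, p = welch_t(x, y)
            p_adj = min(1.0, p * len(pairs))
            pmat.loc[s1, s2] = pmat.loc[s2, s1] = p_adj
            rows.append(
                {
                    "trait": fit.trait,
                    "species": sp,
                    "site_1": s1,
                    "site_2": s2,
                    "mean_1": x.mean(),
                    "mean_2": y.mean(),
                    "t": t,
                    "df": dfree,
                    "p_raw": p,
                    "p_adjusted": p_adj,
                    "significant": p_adj < alpha,
                }
            )
        letters = _letters_from_pmatrix(sites, pmat, alpha)
        for s in sites:
            letter_rows.append(
                {"trait": fit.trait, "species": sp, "site": s, "letters": letters[s]}
            )
    contrasts = pd.DataFrame(rows)
    contrasts.attrs["letters"] = pd.DataFrame(letter_rows)
    return contrasts


def species_comparison_test(
    table: pd.DataFrame, trait: str, n_tests: int = 1
) -> dict[str, float]:
    """Two-species Welch t-test for one common-garden trait.

    Returns t, the Welch degrees of freedom, the raw p and the
    multiplicity-adjusted p (raw p times ``n_tests``, capped at one).
    """
    df = table.loc[table["trait"] == trait]
    species = sorted(df["species"].unique())
    if len(species) != 2:
        raise ValueError("species comparison requires exactly two species present")
    x = df.loc[df["species"] == species[0], "value"].to_numpy()
    y = df.loc[df["species"] == species[1], "value"].to_numpy()
    t, dfree, p = welch_t(x, y)
    return {
        "trait": trait,
        "t": t,
        "df": dfree,
        "p_raw": p,
        "p_adjusted": min(1.0, p * n_tests),
    }


# ---------------------------------------------------------------------------
# soil ordination


def soil_mds(
    data: pd.DataFrame | np.ndarray, n_axes: int = 2, is_distance: bool = False
) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling of soil profiles.

    If ``is_distance`` is false, rows are samples and columns variables;
    variables are z-standardised and Euclidean distances computed.  The
    double-centred Gram matrix is eigen-decomposed, axes ordered by
    eigenvalue, and signs fixed so each axis' largest-magnitude coordinate
    is positive.
    """
    if is_distance:
        d = np.asarray(data, dtype=float)
        if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be square and symmetric")
        if (d < 0).any():
            raise ValueError("distances must be non-negative")
        index = data.index if isinstance(data, pd.DataFrame) else pd.RangeIndex(len(d))
    else:
        x = np.asarray(data, dtype=float)
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xz = (x - x.mean(axis=0)) / sd
        d = np.sqrt(((xz[:, None, :] - xz[None, :, :]) ** 2).sum(axis=2))
        index = data.index if isinstance(data, pd.DataFrame) else pd.RangeIndex(len(d))
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, n_axes))
    for k in range(min(n_axes, n)):
        lam = max(evals[k], 0.0)
        axis = evecs[:, k] * np.sqrt(lam)
        if np.abs(axis).max() > 0 and axis[np.argmax(np.abs(axis))] < 0:
            axis = -axis
        coords[:, k] = axis
    out = pd.DataFrame(
        coords, index=index, columns=[f"MDS{k + 1}" for k in range(n_axes)]
    )
    out.attrs["eigenvalues"] = evals
    return out
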