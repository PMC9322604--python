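"""Simulation-based calibration studies of the pipeline's tests.

Each function simulates data from a known design with the generator,
runs the corresponding estimator, and reports an operating
characteristic: type-I error and power of the reaction-norm interaction
LRT, type-I error of the survival interaction LRT, null p-value
uniformity and planted fold-change recovery of the expression tests,
eigengene recovery of a planted elevation-linked module, and end-to-end
recovery of a planted between-species plasticity angle.

These are the package's own verification experiments; every replicate is
seeded from the caller's seed, so results are reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import expression, multivar, survival, synthdata, traits

__all__ = [
    "trait_lrt_type1_error",
    "trait_lrt_power",
    "cox_lrt_type1_error",
    "de_null_pvalues",
    "de_lfc_recovery",
    "eigengene_elevation_recovery",
    "planted_angle_design",
    "planted_angle_recovery",
]

# Replicate design for the Monte-Carlo studies at the emulated field
# experiment's own scale: 2 species x 4 sites x 40 genotypes x 3 blocks
# x 3 clones (2880 plants).  The chi-square approximation of the
# full-ML fixed-effect LRT is accurate at this size (it is mildly
# liberal on much smaller designs); the exact balanced-design likelihood
# keeps each replicate fast.
_MC_SIZES = dict(
    n_genotypes_per_species=40, n_blocks_per_site=3, n_clones_per_genotype_block=3
)


def _null_trait_design(seed: int) -> synthdata.SimulationDesign:
    """Additive species and site effects, no interaction."""
    site_eff = np.array([0.0, 0.5, 1.0, 1.5])
    means = {"t1": np.vstack([5.0 + site_eff, 6.0 + site_eff])}
    return synthdata.SimulationDesign(
        trait_fixed_effects=means,
        var_genotype_by_site=0.25,
        var_block=0.1,
        var_residual=1.0,
        seed=seed,
        **_MC_SIZES,
    )


def trait_lrt_type1_error(n_reps: int = 500, seed: int = 0, alpha: float = 0.05) -> dict:
    """Rejection rate of the species x site LRT under a true null."""
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=n_reps)
    rej = 0
    for rep in range(n_reps):
        t = synthdata.simulate_traits(_null_trait_design(int(sub[rep])))
        fit = traits.fit_trait_model(t, "t1", lrt_only=True)
        rej += fit.p_raw < alpha
    return {"rate": rej / n_reps, "n": n_reps}


def trait_lrt_power(n_reps: int = 150, seed: int = 0, alpha: float = 0.05) -> dict:
    """Rejection rate under a strong crossing interaction (effect >> SD)."""
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=n_reps)
    means = {"t1": np.vstack([[0.0, 1.0, 2.0, 3.0], [3.0, 2.0, 1.0, 0.0]])}
    rej = 0
    for rep in range(n_reps):
        d = synthdata.SimulationDesign(
            trait_fixed_effects=means,
            var_genotype_by_site=0.25,
            var_block=0.1,
            var_residual=1.0,
            seed=int(sub[rep]),
            **_MC_SIZES,
        )
        fit = traits.fit_trait_model(synthdata.simulate_traits(d), "t1", lrt_only=True)
        rej += fit.p_raw < alpha
    return {"rate": rej / n_reps, "n": n_reps}


def cox_lrt_type1_error(n_reps: int = 500, seed: int = 0, alpha: float = 0.05) -> dict:
    """Rejection rate of the survival interaction LRT when both species
    share the same site-dependent hazards."""
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=n_reps)
    site_trend = np.array([0.0, 0.3, 0.6, 0.9])
    rates = np.vstack([np.log(0.004) + site_trend] * 2)
    rej = 0
    for rep in range(n_reps):
        d = synthdata.SimulationDesign(
            trait_fixed_effects={"t1": np.full((2, 4), 1.0)},
            hazard_log_rates=rates,
            frailty_variance=0.0,
            seed=int(sub[rep]),
            **_MC_SIZES,
        )
        s = synthdata.simulate_survival(d, follow_up_days=180.0)
        full = survival.cox_fit(s, interaction=True)
        red = survival.cox_fit(s, interaction=False)
        rej += survival.interaction_lrt(full, red)["p_value"] < alpha
    return {"rate": rej / n_reps, "n": n_reps}


def de_null_pvalues(seed: int = 0, n_genes: int = 1000) -> np.ndarray:
    """Raw Wald p-values for a within-species site contrast with no
    planted effects (should be approximately uniform)."""
    d = synthdata.SimulationDesign(
        n_genes=n_genes,
        dispersion=0.1,
        genotype_expression_sd=0.1,
        module_factor_loadings=np.zeros(n_genes),
        n_genotypes_expression=6,
        n_clones_expression=3,
        seed=seed,
    )
    counts, meta = synthdata.simulate_counts(d)
    sp = d.species
    de = expression.de_test(
        counts, meta, contrasts={"null": ((sp[0], 2000), (sp[0], 500))}
    )
    return de["null"].table["p_raw"].dropna().to_numpy()


def de_lfc_recovery(
    seed: int = 0, n_genes: int = 1000, n_planted: int = 200, lfc: float = 2.0
) -> dict:
    """Signed mean of estimated log2 fold changes for genes planted at
    +/-``lfc`` (balanced directions) in a null background."""
    sign = np.where(np.arange(n_planted) % 2 == 0, 1.0, -1.0)
    lfc_site = np.zeros(n_genes)
    lfc_site[:n_planted] = lfc * sign
    d = synthdata.SimulationDesign(
        n_genes=n_genes,
        lfc_site=lfc_site,
        dispersion=0.1,
        n_genotypes_expression=6,
        n_clones_expression=3,
        seed=seed,
    )
    counts, meta = synthdata.simulate_counts(d)
    sp = d.species
    de = expression.de_test(
        counts, meta, contrasts={"site": ((sp[0], 2000), (sp[0], 500))}
    )
    est = de["site"].table["log2fc"][:n_planted].to_numpy()
    return {"signed_mean": float(np.mean(est * sign)), "planted": lfc, "n": n_planted}


def eigengene_elevation_recovery(seed: int = 0) -> dict:
    """Per-species |r| between the eigengene of a planted elevation-linked
    module (loading 1) and transplant elevation."""
    g = 200
    modules = np.zeros(g, dtype=int)
    modules[:60] = 1
    loadings = np.where(modules == 1, 1.0, 0.0)
    d = synthdata.SimulationDesign(
        n_genes=g,
        module_assignments=modules,
        module_factor_loadings=loadings,
        dispersion=0.05,
        n_genotypes_expression=6,
        n_clones_expression=2,
        seed=seed,
    )
    counts, meta = synthdata.simulate_counts(d)
    _, norm = expression.normalize_counts(counts)
    res = expression.module_eigengene(list(counts.index[:60]), norm, meta)
    corr = res.elevation_correlation.set_index("species")["r"].abs()
    return {sp: float(r) for sp, r in corr.items()}


def planted_angle_design(
    angle_deg: float = 60.0, n_genotypes: int = 150, seed: int = 0
) -> synthdata.SimulationDesign:
    """Fixture design planting an exact between-species plasticity angle.

    Block variance is zero because block-average deviations are
    confounded with site effects and would put an irreducible floor on
    the angle estimate; genotype count is chosen so the remaining
    sampling error is well under a degree.
    """
    u = np.array([1.0, 0, 0, 0])
    v = np.array([0, 1.0, 0, 0])
    theta = np.radians(angle_deg)
    a_low = 0.8 * u
    a_high = 0.8 * (np.cos(theta) * u + np.sin(theta) * v)
    div = np.array([0.2, -0.6, -0.6, 0.0])
    means = synthdata.trait_means_from_geometry(div, a_low, a_high)
    return synthdata.SimulationDesign(
        n_genotypes_per_species=n_genotypes,
        trait_fixed_effects=means,
        var_block=0.0,
        seed=seed,
    )


def planted_angle_recovery(angle_deg: float = 60.0, seed: int = 0) -> dict:
    """Estimate the between-species plasticity angle on the planted-angle
    fixture through the full genotype-mean / standardisation path."""
    design = planted_angle_design(angle_deg=angle_deg, seed=seed)
    t = synthdata.simulate_traits(design)
    gm = traits.genotype_means(traits.clone_means(t))
    std, _ = multivar.mean_standardize(gm)
    groups = multivar.group_means(std)
    rep = multivar.adaptive_alignment(
        groups, {design.species[0]: 500, design.species[1]: 2000}
    )
    est = float(
        rep.loc[rep.comparison == "plasticity_between_species", "angle_deg"].iloc[0]
    )
    return {"planted": angle_deg, "estimated": est, "abs_error": abs(est - angle_deg)}
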