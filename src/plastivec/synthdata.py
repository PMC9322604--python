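"""Synthetic reciprocal-transplant data generator.

Emulates a two-species clonal transplant experiment along an elevational
gradient: each genotype (a field-sampled individual propagated as cuttings)
is replicated as several clones in several blocks at each transplant site.
Three data layers are generated with a shared experimental design:

* quantitative leaf/physiology traits following a linear mixed model
  (species x site fixed cell means, genotype-by-site and block random
  effects, Gaussian residual),
* per-plant survival times from exponential hazards with a species x site
  rate matrix and a log-normal genotype frailty,
* a gene x sample negative-binomial count matrix with species, site and
  species x site log-fold-effects, genotype effects and latent coexpression
  modules driven by an elevation-linked factor.

All randomness flows from a single master seed; substreams per data layer
are spawned deterministically, so a design plus a seed fully determines
every output table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationDesign",
    "default_trait_means",
    "simulate_traits",
    "simulate_survival",
    "simulate_counts",
]

#: Transplant-site elevations (m a.s.l.) of the emulated gradient.
DEFAULT_ELEVATIONS = (500, 1000, 1500, 2000)

#: Species labels: a lowland taxon native to 500 m and an upland taxon
#: native to 2000 m.
DEFAULT_SPECIES = ("S_chrysanthemifolius", "S_aethnensis")


#: Trait scales (grand means on the raw measurement scale): leaf area
#: (mm^2), leaf complexity (perimeter^2/area), indent density (1/mm) and
#: specific leaf area (mm^2/mg).
DEFAULT_TRAIT_SCALES = {
    "leaf_area": 20.0,
    "leaf_complexity": 40.0,
    "indent_density": 0.9,
    "sla": 17.0,
}


def trait_means_from_geometry(
    divergence: np.ndarray,
    plasticity_low: np.ndarray,
    plasticity_high: np.ndarray,
    scales: dict[str, float] = DEFAULT_TRAIT_SCALES,
    elevations: tuple[int, ...] = DEFAULT_ELEVATIONS,
) -> dict[str, np.ndarray]:
    """Build species x site cell means planting an exact vector geometry.

    All three arguments live on the mean-standardised trait scale (one
    unit = the trait's grand mean): ``divergence`` is the native
    phenotype of the upland species minus that of the lowland species,
    ``plasticity_low``/``plasticity_high`` are each species' change from
    its native toward the opposite elevational extreme.  Intermediate
    sites interpolate linearly in elevation.  Cell means are constructed
    so every trait's average over all (species, site) cells is exactly
    one, hence empirical mean standardisation asymptotically reproduces
    the planted geometry (angles are exact, not approximate).
    """
    d = np.asarray(divergence, dtype=float)
    a_low = np.asarray(plasticity_low, dtype=float)
    a_high = np.asarray(plasticity_high, dtype=float)
    traits = list(scales)
    p = len(traits)
    if not (d.shape == a_low.shape == a_high.shape == (p,)):
        raise ValueError(f"geometry vectors must have length {p} (one per trait)")
    # natives chosen so that the 4 extreme cells average to 1 per trait;
    # with linear interpolation the site average equals the extreme midpoint,
    # so the full cell average is 1 as well.
    native_low = (2.0 - (a_low + a_high) / 2.0 - d) / 2.0
    native_high = native_low + d
    low_novel = native_low + a_low  # lowland species at the high extreme
    high_novel = native_high + a_high  # upland species at the low extreme
    elev = np.asarray(elevations, dtype=float)
    w = (elev - elev.min()) / (elev.max() - elev.min())  # 0 at low, 1 at high
    means: dict[str, np.ndarray] = {}
    for t_i, trait in enumerate(traits):
        low_row = native_low[t_i] + w * (low_novel[t_i] - native_low[t_i])
        high_row = high_novel[t_i] + w * (native_high[t_i] - high_novel[t_i])
        cell = np.vstack([low_row, high_row]) * scales[trait]
        if (cell <= 0).any():
            raise ValueError(
                f"planted geometry makes trait {trait!r} non-positive; "
                "reduce vector magnitudes"
            )
        means[trait] = cell
    return means


def _default_geometry() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted vectors for the default design.

    The emulated conditions: the species' plasticity directions differ by
    about 66 degrees; plasticity of the lowland species points about 33
    degrees from the divergence vector toward the upland native phenotype
    (adaptive), while the upland species' plasticity points about 95
    degrees from the divergence toward the lowland phenotype
    (nonadaptive).  Divergence is dominated by leaf complexity and indent
    density (dissected vs. entire leaves); the shared component of
    plasticity is a reduction of leaf area and SLA at high elevation.
    """
    d = np.array([0.10, -0.70, -0.80, -0.10])
    u = d / np.linalg.norm(d)
    # common elevational response direction, orthogonalised against u
    v0 = np.array([-0.60, -0.20, 0.00, -0.75])
    v = v0 - (v0 @ u) * u
    v /= np.linalg.norm(v)
    w0 = np.array([0.00, 0.50, -0.50, 0.00])
    w = w0 - (w0 @ u) * u - (w0 @ v) * v
    w /= np.linalg.norm(w)
    ang_low = np.radians(33.0)  # lowland plasticity vs divergence
    ang_high = np.radians(95.0)  # upland plasticity vs reverse divergence
    phi = np.radians(52.0)  # sets the between-species angle near 66 degrees
    a_low = 0.55 * (np.cos(ang_low) * u + np.sin(ang_low) * v)
    a_high = 0.45 * (
        np.cos(ang_high) * (-u)
        + np.sin(ang_high) * (np.cos(phi) * v + np.sin(phi) * w)
    )
    return d, a_low, a_high


def default_trait_means(
    species: tuple[str, ...] = DEFAULT_SPECIES,
    elevations: tuple[int, ...] = DEFAULT_ELEVATIONS,
) -> dict[str, np.ndarray]:
    """Species x site cell means for the four default leaf traits.

    Plants the emulated system's structure: strong species divergence in
    leaf complexity and indent density, a shared reduction of leaf area
    and SLA at high elevation, and species-specific reaction-norm
    directions giving a between-species plasticity angle near 66 degrees
    with the lowland species' plasticity aligned (about 33 degrees) with
    the divergence toward the upland phenotype and the upland species'
    plasticity nearly orthogonal (about 95 degrees) to the reverse
    divergence.
    """
    del species  # labels do not affect the cell means
    d, a_low, a_high = _default_geometry()
    return trait_means_from_geometry(d, a_low, a_high, elevations=elevations)


@dataclass
class SimulationDesign:
    """Parameters of one synthetic transplant experiment.

    Counts mirror the emulated field design (2 species x 4 elevations x
    ~40 genotypes/species x 3 blocks x 3 clones); variance components are
    chosen for testability since realistic magnitudes are not published.
    """

    n_species: int = 2
    species: tuple[str, ...] = DEFAULT_SPECIES
    elevations: tuple[int, ...] = DEFAULT_ELEVATIONS
    n_genotypes_per_species: int = 40
    n_blocks_per_site: int = 3
    n_clones_per_genotype_block: int = 3
    trait_fixed_effects: dict[str, np.ndarray] = field(default_factory=default_trait_means)
    # variances in trait units^2; a scalar applies to every trait, a dict
    # maps trait -> variance.  Defaults scale with each trait's grand mean
    # (coefficients of variation: 5% genotype-by-site, 3% block, 10%
    # residual), since absolute magnitudes are not published.
    var_genotype_by_site: float | dict[str, float] = field(
        default_factory=lambda: {t: (0.05 * s) ** 2 for t, s in DEFAULT_TRAIT_SCALES.items()}
    )
    var_block: float | dict[str, float] = field(
        default_factory=lambda: {t: (0.03 * s) ** 2 for t, s in DEFAULT_TRAIT_SCALES.items()}
    )
    var_residual: float | dict[str, float] = field(
        default_factory=lambda: {t: (0.10 * s) ** 2 for t, s in DEFAULT_TRAIT_SCALES.items()}
    )
    # survival layer: log baseline hazard per day, species x site
    hazard_log_rates: np.ndarray | None = None
    frailty_variance: float = 0.04
    # expression layer
    n_genes: int = 2000
    n_genotypes_expression: int = 12
    n_clones_expression: int = 3
    baseline_log2_expression: float = 6.0
    lfc_species: np.ndarray | None = None
    lfc_site: np.ndarray | None = None
    lfc_interaction: np.ndarray | None = None
    dispersion: np.ndarray | float = 0.1
    genotype_expression_sd: float = 0.1
    module_assignments: np.ndarray | None = None
    module_factor_loadings: np.ndarray | None = None
    # each module's latent factor is elevation_weight * z + N(0, noise_sd)
    # per sample; weight 0 gives an elevation-independent module
    module_elevation_weight: float | dict[int, float] = 1.0
    module_factor_noise_sd: float = 0.1
    library_size_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species != len(self.species):
            raise ValueError("n_species must match the species label tuple")
        if len(set(self.elevations)) != len(self.elevations):
            raise ValueError("site elevations must be unique")
        for name, val in [
            ("n_genotypes_per_species", self.n_genotypes_per_species),
            ("n_blocks_per_site", self.n_blocks_per_site),
            ("n_clones_per_genotype_block", self.n_clones_per_genotype_block),
        ]:
            if val <= 0:
                raise ValueError(f"{name} must be a positive count, got {val}")
        for name, val in [
            ("var_genotype_by_site", self.var_genotype_by_site),
            ("var_block", self.var_block),
            ("var_residual", self.var_residual),
            ("frailty_variance", self.frailty_variance),
        ]:
            vals = val.values() if isinstance(val, dict) else [val]
            if any(v < 0 for v in vals):
                raise ValueError(f"{name} must be non-negative, got {val}")
        disp = np.asarray(self.dispersion, dtype=float)
        if np.any(disp <= 0):
            raise ValueError("dispersion must be strictly positive")
        shape = (self.n_species, len(self.elevations))
        for trait, m in self.trait_fixed_effects.items():
            m = np.asarray(m, dtype=float)
            if m.shape != shape:
                raise ValueError(
                    f"trait_fixed_effects[{trait!r}] has shape {m.shape}, expected {shape}"
                )
            self.trait_fixed_effects[trait] = m
        if self.hazard_log_rates is None:
            self.hazard_log_rates = self._default_hazards()
        self.hazard_log_rates = np.asarray(self.hazard_log_rates, dtype=float)
        if self.hazard_log_rates.shape != shape:
            raise ValueError(f"hazard_log_rates must have shape {shape}")

    def _default_hazards(self) -> np.ndarray:
        # Crossing mortality pattern: the lowland species dies faster at
        # high elevation, the upland species faster at low elevation.
        z = np.linspace(-0.5, 0.5, len(self.elevations))
        low = np.log(0.004) + 2.2 * z
        high = np.log(0.004) - 2.2 * z
        return np.vstack([low, high])

    def replace(self, **kwargs) -> "SimulationDesign":
        """Return a copy of the design with some fields changed."""
        return dataclasses.replace(self, **kwargs)

    # --- deterministic substreams -------------------------------------
    def _rng(self, stream: int) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed)
        return np.random.default_rng(ss.spawn(stream + 1)[stream])

    def plant_frame(self) -> pd.DataFrame:
        """One row per transplanted clone (the experimental plant)."""
        rows = []
        for si, sp in enumerate(self.species):
            for g in range(self.n_genotypes_per_species):
                geno = f"{sp}_g{g + 1:02d}"
                for elev in self.elevations:
                    for b in range(1, self.n_blocks_per_site + 1):
                        for c in range(1, self.n_clones_per_genotype_block + 1):
                            rows.append((sp, geno, elev, f"{elev}_b{b}", c))
        df = pd.DataFrame(
            rows, columns=["species", "genotype", "site", "block", "clone_rep"]
        )
        df["clone"] = (
            df["genotype"]
            + "_s"
            + df["site"].astype(str)
            + "_"
            + df["block"]
            + "_c"
            + df["clone_rep"].astype(str)
        )
        return df.drop(columns="clone_rep")


def simulate_traits(design: SimulationDesign) -> pd.DataFrame:
    """Simulate a long-format trait table, one row per clone per trait.

    Each observation is the species x site fixed cell mean plus a Gaussian
    genotype-by-site deviation, a block deviation, and a residual; all
    three effects are drawn independently per trait.
    """
    rng = design._rng(0)
    plants = design.plant_frame()
    n = len(plants)
    elev_idx = {e: j for j, e in enumerate(design.elevations)}
    sp_idx = {s: i for i, s in enumerate(design.species)}
    i_sp = plants["species"].map(sp_idx).to_numpy()
    j_site = plants["site"].map(elev_idx).to_numpy()

    genos = plants["genotype"].unique()
    blocks = plants["block"].unique()
    g_idx = plants["genotype"].map({g: k for k, g in enumerate(genos)}).to_numpy()
    b_idx = plants["block"].map({b: k for k, b in enumerate(blocks)}).to_numpy()

    def _sd(var: float | dict, trait: str) -> float:
        v = var.get(trait, 0.0) if isinstance(var, dict) else var
        return float(np.sqrt(v))

    out = []
    for trait, cell_means in design.trait_fixed_effects.items():
        gs_dev = rng.normal(0.0, _sd(design.var_genotype_by_site, trait),
                            size=(len(genos), len(design.elevations)))
        b_dev = rng.normal(0.0, _sd(design.var_block, trait), size=len(blocks))
        resid = rng.normal(0.0, _sd(design.var_residual, trait), size=n)
        value = (
            cell_means[i_sp, j_site]
            + gs_dev[g_idx, j_site]
            + b_dev[b_idx]
            + resid
        )
        t = plants.copy()
        t["trait"] = trait
        t["value"] = value
        out.append(t)
    table = pd.concat(out, ignore_index=True)
    return table[["species", "genotype", "site", "block", "clone", "trait", "value"]]


def simulate_survival(design: SimulationDesign, follow_up_days: float = 180.0) -> pd.DataFrame:
    """Simulate per-plant time-to-death records.

    Event times are exponential with rate ``exp(log_rate[species, site] +
    frailty[genotype])`` where genotype frailty is log-normal; times past
    the follow-up horizon are censored at the horizon.  A log rate of
    ``-inf`` is a sentinel for a zero hazard (every record censored).
    """
    if follow_up_days <= 0:
        raise ValueError("follow_up_days must be positive")
    if np.any(np.isnan(design.hazard_log_rates)):
        raise ValueError("hazard_log_rates must not contain NaN")
    rng = design._rng(1)
    plants = design.plant_frame()
    elev_idx = {e: j for j, e in enumerate(design.elevations)}
    sp_idx = {s: i for i, s in enumerate(design.species)}
    i_sp = plants["species"].map(sp_idx).to_numpy()
    j_site = plants["site"].map(elev_idx).to_numpy()

    genos = plants["genotype"].unique()
    frailty = rng.normal(0.0, np.sqrt(design.frailty_variance), size=len(genos))
    g_idx = plants["genotype"].map({g: k for k, g in enumerate(genos)}).to_numpy()

    log_rate = design.hazard_log_rates[i_sp, j_site] + frailty[g_idx]
    rate = np.exp(log_rate)
    with np.errstate(divide="ignore"):
        raw = np.where(rate > 0, rng.exponential(1.0, size=len(plants)) / np.where(rate > 0, rate, 1.0), np.inf)
    event = (raw <= follow_up_days).astype(int)
    time = np.minimum(raw, follow_up_days)
    out = plants.copy()
    out["time"] = time
    out["event"] = event
    return out[["species", "genotype", "site", "block", "clone", "time", "event"]]


def _expression_sample_frame(design: SimulationDesign) -> pd.DataFrame:
    rows = []
    for sp in design.species:
        for g in range(design.n_genotypes_expression):
            geno = f"{sp}_g{g + 1:02d}"
            for elev in design.elevations:
                for c in range(1, design.n_clones_expression + 1):
                    rows.append((f"{geno}_s{elev}_c{c}", sp, geno, elev, c))
    return pd.DataFrame(rows, columns=["sample", "species", "genotype", "site", "clone"])


def simulate_counts(design: SimulationDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a gene x sample NB count matrix plus sample metadata.

    The per-gene log2 mean is ``baseline + lfc_species * x_sp + lfc_site *
    z + lfc_interaction * x_sp * z + genotype effect + loading * factor``
    where ``x_sp`` is +/-0.5 for the two species and ``z`` is elevation
    scaled to [-0.5, 0.5]; each module has its own latent factor
    (``elevation_weight * z`` plus per-sample noise, independent across
    modules), so genes with non-zero loadings form coexpression modules
    that are elevation-linked when the weight is non-zero.  Counts are
    gamma-Poisson with variance
    ``mu + dispersion * mu**2`` and log-normal library size factors.

    Returns ``(counts, metadata)``: counts indexed by gene with one column
    per sample, metadata one row per sample.
    """
    if design.n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng = design._rng(2)
    meta = _expression_sample_frame(design)
    n_samp = len(meta)
    G = design.n_genes

    def _pergene(arr, default):
        if arr is None:
            return np.full(G, default, dtype=float)
        a = np.asarray(arr, dtype=float)
        if a.ndim == 0:
            return np.full(G, float(a))
        if a.shape != (G,):
            raise ValueError(f"per-gene array must have length {G}")
        return a

    lfc_sp = _pergene(design.lfc_species, 0.0)
    lfc_site = _pergene(design.lfc_site, 0.0)
    lfc_int = _pergene(design.lfc_interaction, 0.0)
    disp = _pergene(design.dispersion, 0.1)
    loadings = _pergene(design.module_factor_loadings, 0.0)
    if design.module_assignments is None:
        modules = np.zeros(G, dtype=int)
    else:
        modules = np.asarray(design.module_assignments)
        if modules.shape != (G,):
            raise ValueError("module_assignments must have one label per gene")

    x_sp = np.where(meta["species"] == design.species[0], -0.5, 0.5)
    elev = meta["site"].to_numpy(dtype=float)
    z = (elev - np.mean(design.elevations)) / (
        max(design.elevations) - min(design.elevations)
    )
    # one latent factor per module: elevation signal (weighted) plus
    # per-sample noise, independent across modules
    module_ids = np.unique(modules)
    factors = {}
    for m in module_ids:
        w_m = (
            design.module_elevation_weight.get(int(m), 1.0)
            if isinstance(design.module_elevation_weight, dict)
            else design.module_elevation_weight
        )
        factors[m] = w_m * z + rng.normal(
            0.0, design.module_factor_noise_sd, size=n_samp
        )
    factor_per_gene = np.vstack([factors[m] for m in modules])  # genes x samples

    genos = meta["genotype"].unique()
    g_eff = rng.normal(0.0, design.genotype_expression_sd, size=(G, len(genos)))
    g_idx = meta["genotype"].map({g: k for k, g in enumerate(genos)}).to_numpy()

    lib = np.exp(rng.normal(0.0, design.library_size_sd, size=n_samp))
    log2_mu = (
        design.baseline_log2_expression
        + lfc_sp[:, None] * x_sp[None, :]
        + lfc_site[:, None] * z[None, :]
        + lfc_int[:, None] * (x_sp * z)[None, :]
        + g_eff[:, g_idx]
        + loadings[:, None] * factor_per_gene
    )
    mu = lib[None, :] * np.exp2(log2_mu)
    # gamma-Poisson mixture: var = mu + disp * mu^2
    shape = 1.0 / disp[:, None]
    lam = rng.gamma(np.broadcast_to(shape, mu.shape), mu / shape)
    counts = rng.poisson(lam)
    genes = [f"gene{i + 1:05d}" for i in range(G)]
    cdf = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=meta["sample"])
    meta = meta.set_index("sample")
    for m in module_ids:
        meta[f"module_truth_factor_{m}"] = factors[m]
    return cdf, meta
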