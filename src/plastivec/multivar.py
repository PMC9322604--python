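"""Multivariate plasticity and divergence geometry.

The multivariate layer works on genotype means of mean-standardised
traits.  Mean standardisation (dividing each trait by its grand mean over
all species, sites and genotypes of one experiment) makes traits
dimensionless and comparable, so that vector lengths and angles are not
dominated by units.

Three quantities carry the analysis:

* a MANOVA of the genotype x site means with the genotype-within-cell
  scatter as the error stratum — Wilks' lambda = det(E) / det(H + E) with
  Rao's F approximation — tests whether species and sites differ in
  multivariate mean more than genotypes do;
* the D-matrix, the covariance of the (species x site) cell mean vectors,
  whose leading eigenvectors (d_max, d_2, ...) are the main axes of
  among-group divergence;
* plasticity and divergence vectors: the unit-length multivariate change
  of each species from its native to a novel site, and the unit-length
  difference between the two species' native phenotypes.  The angle
  between plasticity vectors measures how much the species' responses to
  the same gradient differ in direction; the angle between a species'
  plasticity (pointing away from home) and the divergence vector toward
  the other species' native phenotype measures whether that plasticity is
  adaptive (small angle) or not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mean_standardize",
    "GroupMeanSet",
    "group_means",
    "ManovaResult",
    "manova_wilks",
    "DMatrixResult",
    "compute_D",
    "PlasticityVector",
    "plasticity_vector",
    "divergence_vector",
    "vector_angle",
    "adaptive_alignment",
]


def mean_standardize(
    table: pd.DataFrame, traits: list[str] | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each trait by its grand mean across all observations.

    Returns the standardised long table (every trait then has grand mean
    exactly one) and the per-trait grand means used.
    """
    t = table.copy()
    if traits is not None:
        t = t[t["trait"].isin(traits)]
    grand = t.groupby("trait")["value"].mean()
    zero = grand[np.isclose(grand, 0.0)]
    if len(zero):
        raise ValueError(
            f"cannot mean-standardise trait(s) with zero grand mean: {list(zero.index)}"
        )
    t["value"] = t["value"] / t["trait"].map(grand)
    return t, grand


@dataclass
class GroupMeanSet:
    """Multivariate cell means per (species, site), one shared trait order."""

    means: pd.DataFrame  # index (species, site), columns = traits
    n_per_cell: pd.Series
    traits: list[str]

    def cell(self, species: str, site) -> np.ndarray:
        try:
            return self.means.loc[(species, site)].to_numpy(dtype=float)
        except KeyError:
            raise KeyError(f"no cell for species={species!r}, site={site!r}") from None


def group_means(table: pd.DataFrame, traits: list[str] | None = None) -> GroupMeanSet:
    """Cell (species x site) multivariate means from a long genotype-mean table."""
    wide = table.pivot_table(
        index=["species", "genotype", "site"], columns="trait", values="value"
    )
    if traits is None:
        traits = list(wide.columns)
    wide = wide[traits]
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"missing trait values in some cells: {missing}")
    cells = wide.groupby(level=["species", "site"]).mean()
    n = wide.groupby(level=["species", "site"]).size()
    return GroupMeanSet(means=cells, n_per_cell=n, traits=traits)


# ---------------------------------------------------------------------------
# MANOVA


@dataclass
class ManovaResult:
    effect: str
    wilks_lambda: float
    f_value: float
    df_num: float
    df_den: float
    p_value: float
    error_stratum: str = "genotype:site"


def _sscp(mat: np.ndarray) -> np.ndarray:
    return mat.T @ mat


def _rao_f(lam: float, p: int, q: int, v: float) -> tuple[float, float, float, float]:
    """Rao's F approximation for Wilks' lambda.

    p = number of traits, q = hypothesis degrees of freedom, v = error
    degrees of freedom.  Exact for min(p, q) <= 2.
    """
    t = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)) if p**2 + q**2 - 5 > 0 else 1.0
    w = v - (p - q + 1) / 2.0
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    f = (1 - lam_t) / lam_t * df2 / df1
    pval = float(stats.f.sf(f, df1, df2))
    return float(f), float(df1), float(df2), pval


def manova_wilks(
    table: pd.DataFrame,
    effect: str = "species:site",
    traits: list[str] | None = None,
) -> ManovaResult:
    """MANOVA on genotype x site means with the genotype-within-cell
    scatter as the error stratum.

    ``effect`` is one of ``"species"``, ``"site"`` or ``"species:site"``.
    The hypothesis SSCP uses the classical balanced two-way decomposition
    of the cell-structure means; the error SSCP pools the scatter of
    genotype means around their (species, site) cell mean, which asks
    whether species/site differences exceed differences among genotypes.
    """
    wide = table.pivot_table(
        index=["species", "genotype", "site"], columns="trait", values="value"
    )
    if traits is None:
        traits = list(wide.columns)
    wide = wide[traits].dropna()
    p = len(traits)
    meta = wide.index.to_frame(index=False)
    x = wide.to_numpy(dtype=float)
    n = len(x)
    species = meta["species"].to_numpy()
    site = meta["site"].to_numpy()
    sp_levels = np.unique(species)
    site_levels = np.unique(site)
    a, b = len(sp_levels), len(site_levels)
    if a < 2 or b < 2:
        raise ValueError("MANOVA needs at least two species and two sites")

    grand = x.mean(axis=0)
    cell_mean = {}
    for s in sp_levels:
        for e in site_levels:
            mask = (species == s) & (site == e)
            if mask.sum() == 0:
                raise ValueError(f"empty cell species={s!r} site={e!r}")
            cell_mean[(s, e)] = x[mask].mean(axis=0)
    sp_mean = {s: x[species == s].mean(axis=0) for s in sp_levels}
    site_mean = {e: x[site == e].mean(axis=0) for e in site_levels}

    # error: genotype means about their cell mean
    resid = np.empty_like(x)
    for i in range(n):
        resid[i] = x[i] - cell_mean[(species[i], site[i])]
    e_sscp = _sscp(resid)
    v = n - a * b  # error df: genotype-site units minus fitted cells

    dev = np.empty_like(x)
    if effect == "species":
        for i in range(n):
            dev[i] = sp_mean[species[i]] - grand
        q = a - 1
    elif effect == "site":
        for i in range(n):
            dev[i] = site_mean[site[i]] - grand
        q = b - 1
    elif effect in ("species:site", "site:species"):
        for i in range(n):
            dev[i] = (
                cell_mean[(species[i], site[i])]
                - sp_mean[species[i]]
                - site_mean[site[i]]
                + grand
            )
        q = (a - 1) * (b - 1)
    else:
        raise ValueError(f"unknown effect {effect!r}")
    h_sscp = _sscp(dev)

    if v <= p:
        raise ValueError(
            "error stratum too small: need more genotype x site units than traits; "
            "reduce the trait set"
        )
    sign_e, logdet_e = np.linalg.slogdet(e_sscp)
    sign_he, logdet_he = np.linalg.slogdet(h_sscp + e_sscp)
    if sign_e <= 0 or sign_he <= 0:
        raise ValueError(
            "singular error SSCP; reduce the number of traits or add genotypes"
        )
    lam = float(np.exp(logdet_e - logdet_he))
    f, df1, df2, pval = _rao_f(lam, p, q, v)
    return ManovaResult(
        effect=effect,
        wilks_lambda=lam,
        f_value=f,
        df_num=df1,
        df_den=df2,
        p_value=pval,
    )


# ---------------------------------------------------------------------------
# D-matrix


@dataclass
class DMatrixResult:
    d: pd.DataFrame  # trait x trait divergence matrix
    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # traits x axes (d_max, d_2, ...)
    proportion: np.ndarray
    scores: pd.DataFrame  # cell means projected on the axes
    weighted: bool = False


def compute_D(groups: GroupMeanSet, weighted: bool = False) -> DMatrixResult:
    """Among-group divergence matrix and its eigen-axes.

    D is the covariance of the (species x site) cell mean vectors, cells
    equally weighted by default; with ``weighted=True`` cells are weighted
    by their genotype counts (the SSCP divided by total n minus one).
    Eigenvalues are returned in descending order, each eigenvector scaled
    to unit norm with its largest-magnitude loading positive, and the
    proportion of divergence per axis is eigenvalue / trace.
    """
    cells = groups.means.to_numpy(dtype=float)
    c = cells.shape[0]
    if c < 2:
        raise ValueError("divergence undefined with fewer than two cells")
    if weighted:
        w = groups.n_per_cell.to_numpy(dtype=float)
        mean = (w[:, None] * cells).sum(axis=0) / w.sum()
        dev = cells - mean
        d = (w[:, None] * dev).T @ dev / (w.sum() - 1)
    else:
        mean = cells.mean(axis=0)
        dev = cells - mean
        d = dev.T @ dev / (c - 1)
    trace = np.trace(d)
    evals, evecs = np.linalg.eigh(d)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    for k in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, k])), k] < 0:
            evecs[:, k] = -evecs[:, k]
    if trace <= 0:
        proportion = np.array([])
    else:
        proportion = evals / evals.sum()
    axes = [f"d_{i + 1}" for i in range(evecs.shape[1])]
    axes[0] = "d_max"
    if len(axes) > 1:
        axes[1] = "d_2"
    loadings = pd.DataFrame(evecs, index=groups.traits, columns=axes)
    scores = pd.DataFrame(
        dev @ evecs, index=groups.means.index, columns=axes
    )
    return DMatrixResult(
        d=pd.DataFrame(d, index=groups.traits, columns=groups.traits),
        eigenvalues=evals,
        loadings=loadings,
        proportion=proportion,
        scores=scores,
        weighted=weighted,
    )


# ---------------------------------------------------------------------------
# vectors and angles


@dataclass
class PlasticityVector:
    """Unit-length multivariate change between two cell means."""

    label: str
    from_cell: tuple
    to_cell: tuple
    raw: np.ndarray
    unit: np.ndarray = field(init=False)
    magnitude: float = field(init=False)

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.raw))
        if norm == 0:
            raise ValueError(
                f"{self.label}: cell means are identical, direction undefined"
            )
        self.magnitude = norm
        self.unit = self.raw / norm


def plasticity_vector(
    groups: GroupMeanSet, species: str, native_site, novel_site
) -> PlasticityVector:
    """Phenotypic change of one species between its native and a novel site.

    The raw vector is x_native - x_novel; swapping native and novel
    negates it exactly.
    """
    raw = groups.cell(species, native_site) - groups.cell(species, novel_site)
    return PlasticityVector(
        label=f"plasticity[{species}]",
        from_cell=(species, novel_site),
        to_cell=(species, native_site),
        raw=raw,
    )


def divergence_vector(
    groups: GroupMeanSet,
    species_a: str,
    native_a,
    species_b: str,
    native_b,
) -> PlasticityVector:
    """Between-species difference of native phenotypes: x_A(native_A) - x_B(native_B)."""
    raw = groups.cell(species_a, native_a) - groups.cell(species_b, native_b)
    return PlasticityVector(
        label=f"divergence[{species_a}-{species_b}]",
        from_cell=(species_b, native_b),
        to_cell=(species_a, native_a),
        raw=raw,
    )


def vector_angle(a: np.ndarray | PlasticityVector, b: np.ndarray | PlasticityVector) -> float:
    """Angle in degrees, in [0, 180], between two multivariate vectors."""
    va = a.unit if isinstance(a, PlasticityVector) else np.asarray(a, dtype=float)
    vb = b.unit if isinstance(b, PlasticityVector) else np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("angle undefined for a zero vector")
    cosang = np.clip(np.dot(va / na, vb / nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def adaptive_alignment(
    groups: GroupMeanSet,
    native_sites: dict[str, object],
    aligned_threshold: float = 45.0,
) -> pd.DataFrame:
    """Angle report for the adaptive-plasticity assessment.

    ``native_sites`` maps each of the two species to its native site; the
    novel site of each species is the other species' native site (the
    elevational extremes).  Three angles are reported:

    * the angle between the two species' plasticity vectors (how much the
      direction of plasticity differs between species), each taken from
      native toward novel phenotype;
    * for each species, the angle between its plasticity (pointing from
      its home phenotype toward the novel site) and the divergence vector
      pointing from its home phenotype toward the other species' native
      phenotype.  Plasticity is flagged "aligned" (adaptive direction)
      when this angle is below ``aligned_threshold``.
    """
    species = list(native_sites)
    if len(species) != 2:
        raise ValueError("adaptive_alignment requires exactly two species")
    (sp_a, home_a), (sp_b, home_b) = native_sites.items()
    # plasticity pointing away from home, toward the novel (other extreme) site
    away_a = groups.cell(sp_a, home_b) - groups.cell(sp_a, home_a)
    away_b = groups.cell(sp_b, home_a) - groups.cell(sp_b, home_b)
    # divergence pointing from each species' home phenotype toward the other's
    div_ab = groups.cell(sp_b, home_b) - groups.cell(sp_a, home_a)
    rows = []
    ang_sp = vector_angle(away_a, away_b)
    rows.append(
        {
            "comparison": "plasticity_between_species",
            "species": f"{sp_a} vs {sp_b}",
            "angle_deg": ang_sp,
            "aligned": np.nan,
        }
    )
    for sp, away, div in [(sp_a, away_a, div_ab), (sp_b, away_b, -div_ab)]:
        ang = vector_angle(away, div)
        rows.append(
            {
                "comparison": "plasticity_vs_divergence",
                "species": sp,
                "angle_deg": ang,
                "aligned": bool(ang < aligned_threshold),
            }
        )
    return pd.DataFrame(rows)
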