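"""Readers, writers, configuration and the end-to-end pipeline driver.

File schemas
------------
Trait table CSV: ``species, genotype, site, block, clone, trait, value``
with ``site`` as numeric elevation in metres.  Survival CSV: ``species,
genotype, site, block, clone, time, event`` with time in days and event
1 = died / 0 = censored.  Count matrix: genes x samples TSV (first column
gene ids) or a MatrixMarket triplet with separate gene/sample list files;
sample metadata CSV indexed by sample with ``species, site, genotype``
columns.  Gene-to-term map: two-column TSV (gene, term).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression, multivar, survival as surv, synthdata, traits

__all__ = [
    "read_trait_table",
    "write_trait_table",
    "read_survival",
    "read_counts",
    "read_term_map",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

TRAIT_SCHEMA = ["species", "genotype", "site", "block", "clone", "trait", "value"]
SURVIVAL_SCHEMA = ["species", "genotype", "site", "block", "clone", "time", "event"]


def _check_schema(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{what}: missing required column(s) {missing}; expected columns {required}"
        )


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format trait table CSV."""
    df = pd.read_csv(path)
    _check_schema(df, TRAIT_SCHEMA, f"trait table {path}")
    bad = df["value"].isna() & df["trait"].notna()
    if bad.any():
        logger.warning("%s: %d rows with missing values", path, int(bad.sum()))
    df["site"] = pd.to_numeric(df["site"])
    logger.info("read %d trait rows from %s", len(df), path)
    return df[TRAIT_SCHEMA]


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    df[TRAIT_SCHEMA].to_csv(path, index=False, float_format="%.10g")


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-plant survival CSV."""
    df = pd.read_csv(path)
    _check_schema(df, SURVIVAL_SCHEMA, f"survival table {path}")
    if not df["event"].isin([0, 1]).all():
        bad = df.index[~df["event"].isin([0, 1])][0]
        raise ValueError(f"survival table {path}: event must be 0/1 (row {bad})")
    if (df["time"] <= 0).any():
        bad = df.index[df["time"] <= 0][0]
        raise ValueError(f"survival table {path}: non-positive time (row {bad})")
    df["site"] = pd.to_numeric(df["site"])
    return df[SURVIVAL_SCHEMA]


def read_counts(
    path: str | Path,
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
) -> pd.DataFrame:
    """Read a gene x sample count matrix (dense TSV or MatrixMarket triplet).

    A dense TSV has gene ids in the first column and one column per
    sample.  For MatrixMarket, pass the ``.mtx`` path plus gene and
    sample list files (one id per line, genes = rows, samples = columns).
    """
    path = Path(path)
    if path.suffix == ".mtx" or genes_path is not None:
        from scipy.io import mmread

        raw = mmread(str(path))
        mat = np.asarray(raw.todense()) if hasattr(raw, "todense") else np.asarray(raw)
        genes = Path(genes_path).read_text().split()
        samples = Path(samples_path).read_text().split()
        df = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = "gene"
    arr = df.to_numpy()
    if (arr < 0).any():
        gi, si = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"count matrix {path}: negative entry at gene line {gi + 2}, "
            f"sample {df.columns[si]!r}"
        )
    if not np.allclose(arr, np.round(arr)):
        gi, si = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise ValueError(
            f"count matrix {path}: non-integer entry at gene line {gi + 2}, "
            f"sample {df.columns[si]!r}"
        )
    return df.astype(np.int64)


def read_term_map(path: str | Path) -> pd.DataFrame:
    """Read a two-column gene-to-term TSV (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], comment="#")
    return df


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    With no input paths the pipeline simulates its own data from the
    bundled design, making a fully self-contained run possible.
    """

    label: str = "synthetic"
    trait_table: str | None = None
    survival_table: str | None = None
    count_matrix: str | None = None
    sample_metadata: str | None = None
    native_sites: dict[str, float] = field(
        default_factory=lambda: {
            synthdata.DEFAULT_SPECIES[0]: 500,
            synthdata.DEFAULT_SPECIES[1]: 2000,
        }
    )
    traits: list[str] | None = None
    alpha: float = 0.05
    de_alpha: float = 0.01
    magnitude_delta: float = 1.0
    min_count: int = 5
    min_fraction: float = 0.5
    rescue_fraction: float = 0.75
    module_cut_height: float = 0.4
    min_module_size: int = 20
    shock_window_days: float = 3.0
    ties: str = "breslow"
    frailty: bool = False
    seed: int = 0
    # sizes used only when simulating
    sim_genotypes: int = 20
    sim_genes: int = 600
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name, v in [
            ("alpha", self.alpha),
            ("de_alpha", self.de_alpha),
            ("min_fraction", self.min_fraction),
            ("rescue_fraction", self.rescue_fraction),
        ]:
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if len(self.native_sites) != 2:
            raise ValueError("native_sites must map exactly two species")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _default_design(cfg: PipelineConfig) -> synthdata.SimulationDesign:
    return synthdata.SimulationDesign(
        n_genotypes_per_species=cfg.sim_genotypes,
        n_genes=cfg.sim_genes,
        seed=cfg.seed,
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in dependency order and return the result bundle.

    Stages: load-or-simulate -> univariate trait models -> multivariate
    geometry (standardise, MANOVA, D-matrix, plasticity/divergence
    angles) -> survival (shock filter, KM, Cox interaction LRT) ->
    expression (filter, normalise, DE, quadrants, modules).  The bundle
    holds every stage's output plus a JSON-serialisable ``summary`` that
    is identical for identical config + seed.
    """
    bundle: dict = {"config": asdict(cfg)}
    summary: dict = {"label": cfg.label, "seed": cfg.seed}
    design = _default_design(cfg)

    stage = "load"
    try:
        trait_tbl = (
            read_trait_table(cfg.trait_table)
            if cfg.trait_table
            else synthdata.simulate_traits(design)
        )
        surv_tbl = (
            read_survival(cfg.survival_table)
            if cfg.survival_table
            else synthdata.simulate_survival(design)
        )
        if cfg.count_matrix:
            counts = read_counts(cfg.count_matrix)
            meta = pd.read_csv(cfg.sample_metadata, index_col=0)
        else:
            expr_design = _expression_demo_design(design)
            counts, meta = synthdata.simulate_counts(expr_design)

        stage = "traits"
        trait_names = cfg.traits or sorted(trait_tbl["trait"].unique())
        geno_means = traits.genotype_means(
            traits.remove_block_effects(traits.clone_means(trait_tbl))
        )
        fits = {}
        for tr in trait_names:
            fits[tr] = traits.fit_trait_model(trait_tbl, tr, n_tests=len(trait_names))
        bundle["trait_fits"] = fits
        summary["trait_lrt"] = {
            tr: {
                "chi2": f.lrt_chi2,
                "df": f.lrt_df,
                "p_raw": f.p_raw,
                "p_adjusted": f.p_adjusted,
            }
            for tr, f in fits.items()
        }
        bundle["pairwise_site_tests"] = {
            tr: traits.pairwise_site_tests(f, alpha=cfg.alpha) for tr, f in fits.items()
        }

        stage = "multivar"
        std_tbl, grand = multivar.mean_standardize(geno_means, trait_names)
        groups = multivar.group_means(std_tbl, trait_names)
        man = multivar.manova_wilks(std_tbl, effect="species:site", traits=trait_names)
        dres = multivar.compute_D(groups)
        align = multivar.adaptive_alignment(groups, cfg.native_sites)
        bundle.update(group_means=groups, manova=man, d_matrix=dres, alignment=align)
        summary["manova"] = {
            "wilks_lambda": man.wilks_lambda,
            "F": man.f_value,
            "df": [man.df_num, man.df_den],
            "p_value": man.p_value,
        }
        summary["d_matrix"] = {
            "proportion_d_max": float(dres.proportion[0]) if len(dres.proportion) else None,
            "proportion_d_2": float(dres.proportion[1]) if len(dres.proportion) > 1 else None,
        }
        summary["angles"] = {
            row["comparison"] + ":" + str(row["species"]): row["angle_deg"]
            for _, row in align.iterrows()
        }

        stage = "survival"
        recs = surv.remove_transplant_shock(surv_tbl, cfg.shock_window_days)
        km = surv.km_curve(recs)
        full = surv.cox_fit(recs, interaction=True, ties=cfg.ties, frailty=cfg.frailty)
        red = surv.cox_fit(recs, interaction=False, ties=cfg.ties, frailty=cfg.frailty)
        lrt = surv.interaction_lrt(full, red)
        bundle.update(km_curves=km, cox_full=full, cox_reduced=red)
        summary["survival_interaction"] = lrt

        stage = "expression"
        kept, filt_log = expression.filter_counts(
            counts, meta, cfg.min_count, cfg.min_fraction, cfg.rescue_fraction
        )
        sf, norm = expression.normalize_counts(kept)
        sp_a, sp_b = list(cfg.native_sites)
        home_a, home_b = cfg.native_sites[sp_a], cfg.native_sites[sp_b]
        de = expression.de_test(
            kept,
            meta,
            contrasts={
                f"extreme_vs_home[{sp_a}]": ((sp_a, home_b), (sp_a, home_a)),
                f"extreme_vs_home[{sp_b}]": ((sp_b, home_a), (sp_b, home_b)),
            },
            alpha=cfg.de_alpha,
            size_factors=sf,
        )
        ra = de[f"extreme_vs_home[{sp_a}]"].table
        rb = de[f"extreme_vs_home[{sp_b}]"].table
        # orient both fold changes low -> high elevation before classifying
        sign_a = 1.0 if home_b > home_a else -1.0
        quad = expression.quadrant_classify(
            sign_a * ra["log2fc"].fillna(0.0),
            ra["significant"],
            -sign_a * rb["log2fc"].fillna(0.0),
            rb["significant"],
            magnitude_delta=cfg.magnitude_delta,
        )
        assignment, modules = expression.detect_modules(
            norm, cut_height=cfg.module_cut_height, min_module_size=cfg.min_module_size
        )
        mod_results = [
            expression.module_eigengene(m.genes, norm, meta) for m in modules
        ]
        bundle.update(
            counts_filtered=kept,
            filter_log=filt_log,
            de_results=de,
            quadrants=quad,
            modules=mod_results,
        )
        summary["expression"] = {
            "n_genes_input": int(counts.shape[0]),
            "n_genes_kept": int(kept.shape[0]),
            "n_rescued": int((filt_log["decision"] == "rescued").sum()),
            "n_de": {k: int(v.table["significant"].sum()) for k, v in de.items()},
            "quadrant_counts": quad.value_counts().to_dict(),
            "n_modules": len(mod_results),
            "module_sizes": [len(m.genes) for m in mod_results],
        }
        summary["expression"]["quadrant_counts"] = {
            str(k): int(v) for k, v in quad.value_counts().items()
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    bundle["summary"] = summary
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trait_table(trait_tbl, out / "trait_table.csv")
        surv_tbl.to_csv(out / "survival_table.csv", index=False)
        dres.d.to_csv(out / "d_matrix.csv")
        dres.loadings.to_csv(out / "d_loadings.csv")
        align.to_csv(out / "angles.csv", index=False)
        km.to_csv(out / "km_curves.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        logger.info("wrote pipeline outputs to %s", out)
    return bundle


def _expression_demo_design(design: synthdata.SimulationDesign) -> synthdata.SimulationDesign:
    """Expression design with planted DE and module structure for demo runs."""
    rng = np.random.default_rng(design.seed + 1)
    g = design.n_genes
    lfc_sp = np.zeros(g)
    lfc_site = np.zeros(g)
    lfc_int = np.zeros(g)
    loadings = np.zeros(g)
    modules = np.zeros(g, dtype=int)
    n_de = g // 10
    lfc_sp[:n_de] = rng.choice([-2.0, 2.0], n_de)
    lfc_site[n_de : 2 * n_de] = rng.choice([-2.0, 2.0], n_de)
    lfc_int[2 * n_de : 3 * n_de] = rng.choice([-2.5, 2.5], n_de)
    m = g // 12
    modules[3 * n_de : 3 * n_de + m] = 1
    modules[3 * n_de + m : 3 * n_de + 2 * m] = 2
    loadings[modules == 1] = 1.0
    loadings[modules == 2] = -1.0
    return design.replace(
        lfc_species=lfc_sp,
        lfc_site=lfc_site,
        lfc_interaction=lfc_int,
        module_factor_loadings=loadings,
        module_assignments=modules,
        n_genotypes_expression=8,
        n_clones_expression=2,
    )
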