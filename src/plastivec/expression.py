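"""Expression-plasticity layer for a two-species transplant count matrix.

Works from a gene x sample integer count matrix with per-sample metadata
(species, site elevation, genotype).  The stages are:

1. low-count filtering with a within-species rescue rule: a gene whose
   counts are low in at least half the samples is discarded unless those
   low-count samples are concentrated (>75%) in one species, in which
   case it is kept as a candidate species-specific gene;
2. median-of-ratios size-factor normalisation;
3. per-gene negative-binomial log-linear models of
   ``counts ~ species + site + species:site + genotype`` with Wald tests
   on arbitrary cell-mean contrasts (site vs home within species, species
   at site), Benjamini-Hochberg adjustment, significance at adjusted
   p < 0.01;
4. set overlaps of DE gene lists across sites/species and a quadrant
   classification of reaction-norm direction and magnitude across the
   elevational extremes;
5. coexpression modules by average-linkage clustering on correlation
   distance, each summarised by its eigengene (first principal component)
   and tested for a per-species correlation with elevation;
6. Fisher-exact GO-term enrichment of DE gene sets.

Genotype enters the per-gene model as a sum-to-zero-coded fixed factor
within species, so species and species:site cell contrasts remain
identifiable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform
import statsmodels.api as sm

__all__ = [
    "filter_counts",
    "normalize_counts",
    "de_test",
    "bh_adjust",
    "contrast_sets",
    "quadrant_classify",
    "detect_modules",
    "module_eigengene",
    "go_enrichment",
]

logger = logging.getLogger(__name__)

DE_ALPHA = 0.01  # adjusted-p significance threshold for DE calls


def filter_counts(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    min_count: int = 5,
    min_fraction: float = 0.5,
    rescue_fraction: float = 0.75,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Low-count filter with the within-species rescue rule.

    A gene is discarded when at least ``min_fraction`` of all samples have
    counts below ``min_count`` — unless more than ``rescue_fraction`` of
    those low-count samples belong to a single species, in which case the
    gene is retained (it may simply be unexpressed in one species).

    Returns the filtered matrix and a per-gene decision log with the
    low-count fraction, the dominant-species share among low samples and
    the decision ("pass", "rescued" or "discarded").
    """
    for name, val in [("min_fraction", min_fraction), ("rescue_fraction", rescue_fraction)]:
        if not 0 < val <= 1:
            raise ValueError(f"{name} must lie in (0, 1], got {val}")
    species = metadata.loc[counts.columns, "species"]
    if species.nunique() != 2:
        raise ValueError("filter_counts expects exactly two species in the metadata")
    low = counts.to_numpy() < min_count
    n_samples = counts.shape[1]
    n_low = low.sum(axis=1)
    frac_low = n_low / n_samples
    sp_arr = species.to_numpy()
    sp_levels = np.unique(sp_arr)
    low_by_species = np.vstack(
        [low[:, sp_arr == s].sum(axis=1) for s in sp_levels]
    ).T  # genes x 2
    with np.errstate(invalid="ignore", divide="ignore"):
        dominant_share = np.where(
            n_low > 0, low_by_species.max(axis=1) / np.maximum(n_low, 1), 0.0
        )
    flagged = frac_low >= min_fraction
    rescued = flagged & (dominant_share > rescue_fraction)
    decision = np.where(~flagged, "pass", np.where(rescued, "rescued", "discarded"))
    log = pd.DataFrame(
        {
            "n_low": n_low,
            "fraction_low": frac_low,
            "dominant_species_share": dominant_share,
            "decision": decision,
        },
        index=counts.index,
    )
    keep = decision != "discarded"
    return counts.loc[keep], log


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and log2 normalised abundances.

    The reference is the per-gene geometric mean over samples (genes with
    a zero anywhere are excluded from the reference); each sample's size
    factor is the median ratio of its counts to the reference.  If no
    gene is all-positive the factors fall back to relative library sizes
    with a warning.  Normalised abundances are log2(count/sf + 0.5).
    """
    mat = counts.to_numpy(dtype=float)
    if (mat.sum(axis=0) == 0).any():
        raise ValueError("normalize_counts: sample with all-zero counts")
    allpos = (mat > 0).all(axis=1)
    if allpos.sum() == 0:
        logger.warning(
            "no gene expressed in every sample; falling back to library-size factors"
        )
        lib = mat.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(lib)))
    else:
        logref = np.log(mat[allpos]).mean(axis=1)
        ratios = np.log(mat[allpos]) - logref[:, None]
        sf = np.exp(np.median(ratios, axis=0))
    size_factors = pd.Series(sf, index=counts.columns, name="size_factor")
    norm = pd.DataFrame(
        np.log2(mat / sf[None, :] + 0.5), index=counts.index, columns=counts.columns
    )
    return size_factors, norm


# ---------------------------------------------------------------------------
# per-gene NB model


def _expression_design(metadata: pd.DataFrame) -> tuple[np.ndarray, dict]:
    """Cell-mean design: one column per (species, site) cell plus
    sum-to-zero genotype deviations within species."""
    species = metadata["species"].astype(str).to_numpy()
    site = metadata["site"].to_numpy()
    sp_levels = sorted(set(species))
    site_levels = sorted(set(site))
    cells = [(s, e) for s in sp_levels for e in site_levels]
    cell_cols = np.column_stack(
        [((species == s) & (site == e)).astype(float) for s, e in cells]
    )
    geno_cols = []
    geno_names = []
    for s in sp_levels:
        genos = sorted(set(metadata.loc[metadata["species"] == s, "genotype"]))
        if len(genos) < 2:
            continue
        ref = genos[-1]
        for g in genos[:-1]:
            col = (metadata["genotype"] == g).astype(float).to_numpy()
            col = col - (metadata["genotype"] == ref).astype(float).to_numpy()
            geno_cols.append(col)
            geno_names.append(f"geno[{g}]")
    x = np.column_stack([cell_cols] + ([np.column_stack(geno_cols)] if geno_cols else []))
    info = {
        "cells": cells,
        "cell_index": {c: i for i, c in enumerate(cells)},
        "n_cell_cols": len(cells),
        "geno_names": geno_names,
        "sp_levels": sp_levels,
        "site_levels": site_levels,
    }
    return x, info


def _moment_dispersion(counts: np.ndarray, sf: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion by method of moments pooled over cells.

    On normalised counts q = y/sf, within-cell mean m and variance v give
    alpha = (v - m) / m^2; floored at 1e-4, no shrinkage.
    """
    q = counts / sf[None, :]
    uniq = np.unique(groups)
    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    dof = 0
    for g in uniq:
        mask = groups == g
        n = mask.sum()
        if n < 2:
            continue
        m = q[:, mask].mean(axis=1)
        v = q[:, mask].var(axis=1, ddof=1)
        num += (n - 1) * (v - m)
        den += (n - 1) * m**2
        dof += n - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(den > 0, num / den, 1e-4)
    return np.clip(alpha, 1e-4, 100.0)


@dataclass
class DEResult:
    """Per-gene Wald statistics for one contrast."""

    contrast: str
    table: pd.DataFrame  # index gene; log2fc, se, p_raw, p_adjusted, significant
    alpha: float = DE_ALPHA

    @property
    def significant_genes(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    def up(self) -> pd.Index:
        t = self.table
        return t.index[t["significant"] & (t["log2fc"] > 0)]

    def down(self) -> pd.Index:
        t = self.table
        return t.index[t["significant"] & (t["log2fc"] < 0)]


def de_test(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    contrasts: dict[str, tuple[tuple, tuple]],
    alpha: float = DE_ALPHA,
    size_factors: pd.Series | None = None,
) -> dict[str, DEResult]:
    """Per-gene negative-binomial Wald tests for cell-mean contrasts.

    ``contrasts`` maps a label to a pair of (species, site) cells; the
    reported log2 fold change is cell_1 minus cell_2 on the log2 scale
    (e.g. ``{"novel_vs_home": ((sp, 2000), (sp, 500))}``).  Each gene is
    fit once with the full species/site/interaction + genotype design and
    every contrast is evaluated from that fit.  P-values are BH-adjusted
    per contrast; genes with all-zero counts in both cells of a contrast
    are flagged untestable (NaN statistics).
    """
    meta = metadata.loc[counts.columns]
    x, info = _expression_design(meta)
    if size_factors is None:
        size_factors, _ = normalize_counts(counts)
    sf = size_factors.loc[counts.columns].to_numpy(dtype=float)
    offset = np.log(sf)
    cellkey = (meta["species"].astype(str) + "@" + meta["site"].astype(str)).to_numpy()
    alpha_mom = _moment_dispersion(counts.to_numpy(dtype=float), sf, cellkey)

    lvecs = {}
    for label, (cell1, cell2) in contrasts.items():
        l = np.zeros(x.shape[1])
        for cell, sign in ((tuple(cell1), 1.0), (tuple(cell2), -1.0)):
            if cell not in info["cell_index"]:
                raise KeyError(f"contrast {label!r}: unknown cell {cell!r}")
            l[info["cell_index"][cell]] = sign
        lvecs[label] = l

    genes = counts.index
    est = {label: np.full((len(genes), 2), np.nan) for label in lvecs}  # lfc(ln), se(ln)
    pvals = {label: np.full(len(genes), np.nan) for label in lvecs}
    y_all = counts.to_numpy(dtype=float)
    cell_masks = {
        c: (meta["species"].astype(str) == c[0]).to_numpy()
        & (meta["site"] == c[1]).to_numpy()
        for c in info["cells"]
    }
    for gi in range(len(genes)):
        y = y_all[gi]
        try:
            fam = sm.families.NegativeBinomial(alpha=float(alpha_mom[gi]))
            model = sm.GLM(y, x, family=fam, offset=offset)
            res = model.fit(maxiter=100, tol=1e-8)
            beta, cov = res.params, res.cov_params()
        except Exception:
            continue
        for label, l in lvecs.items():
            cells_pair = contrasts[label]
            m1 = cell_masks[tuple(cells_pair[0])]
            m2 = cell_masks[tuple(cells_pair[1])]
            if y[m1].sum() == 0 and y[m2].sum() == 0:
                continue  # untestable
            c = float(l @ beta)
            se = float(np.sqrt(l @ cov @ l))
            if not np.isfinite(se) or se == 0:
                continue
            est[label][gi] = (c, se)
            pvals[label][gi] = 2 * stats.norm.sf(abs(c / se))

    out = {}
    ln2 = np.log(2.0)
    for label in lvecs:
        p = pvals[label]
        padj = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        if ok.any():
            padj[ok] = bh_adjust(p[ok])
        tbl = pd.DataFrame(
            {
                "log2fc": est[label][:, 0] / ln2,
                "se_log2": est[label][:, 1] / ln2,
                "p_raw": p,
                "p_adjusted": padj,
            },
            index=genes,
        )
        tbl["significant"] = (tbl["p_adjusted"] < alpha).fillna(False)
        tbl["untestable"] = ~ok
        out[label] = DEResult(contrast=label, table=tbl, alpha=alpha)
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# set overlaps and quadrant classification


def contrast_sets(gene_sets: dict[str, set | pd.Index]) -> pd.DataFrame:
    """Exact intersection counts for every non-empty combination of sets.

    Returns one row per combination (upset-style): which input sets are
    in the combination, the number of genes exclusive to exactly that
    combination, and the genes themselves.
    """
    from itertools import combinations as _comb

    sets = {k: set(v) for k, v in gene_sets.items()}
    labels = list(sets)
    universe = set().union(*sets.values()) if sets else set()
    rows = []
    for r in range(1, len(labels) + 1):
        for combo in _comb(labels, r):
            inter = set.intersection(*(sets[k] for k in combo))
            exclusive = inter - set().union(
                *(sets[k] for k in labels if k not in combo), set()
            )
            rows.append(
                {
                    "sets": "+".join(combo),
                    "degree": r,
                    "n_intersection": len(inter),
                    "n_exclusive": len(exclusive),
                    "genes_exclusive": sorted(exclusive),
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["universe_size"] = len(universe)
    return df


QUADRANT_CATEGORIES = (
    "shared_same_direction",
    "magnitude_divergent",
    "opposite_direction",
    "A_specific",
    "B_specific",
    "unchanged",
)


def quadrant_classify(
    lfc_a: pd.Series,
    sig_a: pd.Series,
    lfc_b: pd.Series,
    sig_b: pd.Series,
    magnitude_delta: float = 1.0,
) -> pd.Series:
    """Classify each gene's two-species reaction norm across the extremes.

    Categories (exactly one per gene):

    * ``opposite_direction`` — significant in both species with opposite
      fold-change signs (the strongest plasticity divergence),
    * ``A_specific`` / ``B_specific`` — significant in one species only,
    * ``shared_same_direction`` — significant in both, same sign, fold
      changes within ``magnitude_delta`` log2 units of each other,
    * ``magnitude_divergent`` — same sign in both but magnitudes differing
      by more than ``magnitude_delta``,
    * ``unchanged`` — significant in neither.
    """
    idx = lfc_a.index
    for s in (sig_a, lfc_b, sig_b):
        if not s.index.equals(idx):
            raise ValueError("inputs must share one gene index")
    la = lfc_a.to_numpy(dtype=float)
    lb = lfc_b.to_numpy(dtype=float)
    if not (np.isfinite(la).all() and np.isfinite(lb).all()):
        raise ValueError("fold changes must be finite")
    sa = sig_a.to_numpy(dtype=bool)
    sb = sig_b.to_numpy(dtype=bool)
    cat = np.full(len(idx), "unchanged", dtype=object)
    both = sa & sb
    cat[sa & ~sb] = "A_specific"
    cat[~sa & sb] = "B_specific"
    opp = both & (np.sign(la) != np.sign(lb))
    same = both & ~opp
    cat[same & (np.abs(la - lb) > magnitude_delta)] = "magnitude_divergent"
    cat[same & (np.abs(la - lb) <= magnitude_delta)] = "shared_same_direction"
    cat[opp] = "opposite_direction"
    return pd.Series(pd.Categorical(cat, categories=list(QUADRANT_CATEGORIES)), index=idx, name="category")


# ---------------------------------------------------------------------------
# coexpression modules


@dataclass
class ModuleResult:
    module_id: int
    genes: list[str]
    eigengene: pd.Series = field(repr=False)
    explained_variance: float = 0.0
    elevation_correlation: pd.DataFrame | None = None


def detect_modules(
    norm_expr: pd.DataFrame,
    cut_height: float = 0.4,
    min_module_size: int = 20,
) -> tuple[pd.Series, list[ModuleResult]]:
    """Coexpression modules by average-linkage clustering on 1 - |r|.

    Pearson correlations are computed between gene profiles across
    samples; the tree is cut at ``cut_height`` on the correlation
    distance, clusters below ``min_module_size`` are pooled as unassigned
    (module 0).  Constant-expression genes are excluded with a warning.
    Returns a gene -> module-id assignment and the list of modules (each
    with its eigengene; elevation correlations are added by
    :func:`module_eigengene`).
    """
    x = norm_expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    const = sd == 0
    if const.any():
        logger.warning("detect_modules: excluding %d constant genes", int(const.sum()))
    genes = norm_expr.index[~const]
    x = x[~const]
    if len(genes) < 2:
        raise ValueError("need at least two variable genes")
    corr = np.corrcoef(x)
    dist = np.clip(1.0 - np.abs(corr), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    raw_labels = fcluster(z, t=cut_height, criterion="distance")
    assignment = pd.Series(0, index=norm_expr.index, name="module", dtype=int)
    modules: list[ModuleResult] = []
    next_id = 1
    for lab in np.unique(raw_labels):
        members = genes[raw_labels == lab]
        if len(members) < min_module_size:
            continue
        assignment.loc[members] = next_id
        eig, ev = _first_pc(norm_expr.loc[members])
        modules.append(
            ModuleResult(
                module_id=next_id,
                genes=list(members),
                eigengene=eig,
                explained_variance=ev,
            )
        )
        next_id += 1
    # sort by size, largest first, and renumber
    modules.sort(key=lambda m: -len(m.genes))
    remap = {}
    for i, m in enumerate(modules, start=1):
        remap[m.module_id] = i
        m.module_id = i
    assignment = assignment.map(lambda v: remap.get(v, 0))
    return assignment, modules


def _first_pc(expr: pd.DataFrame) -> tuple[pd.Series, float]:
    """First principal component of standardised member-gene expression.

    The eigengene is the per-sample score, variance-normalised, with its
    sign oriented to correlate positively with mean member expression.
    """
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance gene in module")
    xs = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    pc = vt[0]
    mean_profile = xs.mean(axis=0)
    if np.dot(pc, mean_profile) < 0:
        pc = -pc
    pc = pc / pc.std(ddof=1)
    ev = float(s[0] ** 2 / (s**2).sum())
    return pd.Series(pc, index=expr.columns, name="eigengene"), ev


def module_eigengene(
    module_genes: list[str] | pd.Index,
    norm_expr: pd.DataFrame,
    metadata: pd.DataFrame,
) -> ModuleResult:
    """Eigengene of one module plus its per-species elevation correlation.

    The eigengene is the first principal component of the standardised
    member-gene expression; within each species the Pearson correlation
    between the eigengene and sample elevation is reported with its p.
    """
    members = [g for g in module_genes if g in norm_expr.index]
    if len(members) < 2:
        raise ValueError("module needs at least two genes present in the matrix")
    eig, ev = _first_pc(norm_expr.loc[members])
    meta = metadata.loc[eig.index]
    rows = []
    for sp, sub in meta.groupby("species"):
        e = sub["site"].to_numpy(dtype=float)
        v = eig.loc[sub.index].to_numpy()
        if len(sub) < 3 or np.std(e) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(e, v)
        rows.append({"species": sp, "r": r, "p_value": p, "n": len(sub)})
    res = ModuleResult(
        module_id=-1,
        genes=list(members),
        eigengene=eig,
        explained_variance=ev,
        elevation_correlation=pd.DataFrame(rows),
    )
    return res


# ---------------------------------------------------------------------------
# GO enrichment


def go_enrichment(
    de_genes: set | pd.Index,
    universe: set | pd.Index,
    term_map: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher-exact GO-term enrichment of a DE gene set.

    ``term_map`` is a two-column frame (gene, term).  For each term the
    2x2 table (DE-and-term, DE-not-term, term-not-DE, neither) over the
    gene universe is tested with the one-sided (greater) Fisher exact
    test; terms are reported with p < ``alpha`` flagged significant.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    de = set(de_genes)
    if not de <= universe:
        raise ValueError("DE genes must be a subset of the universe")
    tm = term_map[term_map.iloc[:, 0].isin(universe)]
    rows = []
    n_u = len(universe)
    n_de = len(de)
    for term, sub in tm.groupby(tm.columns[1]):
        term_genes = set(sub.iloc[:, 0])
        a = len(de & term_genes)
        b = n_de - a
        c = len(term_genes) - a
        d = n_u - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "term": term,
                "n_term": len(term_genes),
                "n_de_in_term": a,
                "expected": n_de * len(term_genes) / n_u,
                "p_value": float(p),
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows).sort_values("p_value", ignore_index=True)
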