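"""Sexually dimorphic expression statistics for a tissue x sex count design.

Three likelihood-ratio tests on negative-binomial GLMs (log link, effective
library sizes as offsets), each with Benjamini-Hochberg FDR control applied
within the test:

* ``test_sex_within_tissue`` — female vs male within one tissue (the sex
  contrast of a per-tissue-sex parameterised model);
* ``test_ratio_difference`` — does the female:male ratio differ between
  tissues (the tissue x sex interaction, 1 df);
* ``test_tissue_average`` — tissue effect on (male+female)/2 average
  expression, sexes pooled.

Gene-wise dispersions are stabilised toward a common value by an empirical
Bayes step (``estimate_dispersions``); the module also provides TMM-style
library normalisation, FPKM, chromosome-class tallies of significant genes,
Fisher enrichment, and the Z-dosage (male:female) ratio estimator used to
quantify incomplete dosage compensation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from ._nbglm import fit_nb_glm, nb_loglik
from .core import CountExperiment, TISSUES

__all__ = [
    "DispersionEstimates",
    "DimorphismResult",
    "ClassTally",
    "normalize_library_sizes",
    "tmm_factors",
    "estimate_dispersions",
    "test_sex_within_tissue",
    "test_ratio_difference",
    "test_tissue_average",
    "bh_adjust",
    "classify_tallies",
    "enrichment_fisher",
    "compute_fpkm",
    "z_dosage_ratio",
]

_DISP_FLOOR = 1e-6
_DISP_CEIL = 5.0


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------


def tmm_factors(
    experiment: CountExperiment, trim_m: float = 0.3, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-log-ratios scaling factors, geometric mean 1.

    M-values are log2 ratios of raw counts against a reference sample (the
    one whose upper-quartile count fraction is most typical); the factor is
    2^(trimmed mean M) after discarding the top/bottom ``trim_m`` of
    M-values and ``trim_a`` of A-values.  Factors therefore capture relative
    sequencing depth *and* composition bias together.
    """
    counts = experiment.counts.to_numpy(float)
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    colsum = counts.sum(axis=0)
    if (colsum == 0).any():
        bad = experiment.counts.columns[colsum == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")

    # reference: most typical upper-quartile count fraction
    uq = np.array([
        np.quantile(c[c > 0] / s, 0.75) if (c > 0).any() else 0.0
        for c, s in zip(counts.T, colsum)
    ])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    yref = counts[:, ref]

    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        y = counts[:, j]
        ok = (y > 0) & (yref > 0)
        if not ok.any():
            raise ValueError("no genes shared with the reference sample")
        m = np.log2(y[ok] / yref[ok])
        a = 0.5 * np.log2(y[ok] * yref[ok])
        mlo, mhi = np.quantile(m, [trim_m, 1 - trim_m])
        alo, ahi = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= mlo) & (m <= mhi) & (a >= alo) & (a <= ahi)
        if not keep.any():  # tiny gene sets can trim everything away
            keep = np.ones_like(m, dtype=bool)
        factors[j] = 2.0 ** m[keep].mean()
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=experiment.counts.columns, name="tmm_factor")


def normalize_library_sizes(experiment: CountExperiment, **kwargs) -> pd.Series:
    """Effective library sizes: TMM factor x geometric mean of raw sizes."""
    factors = tmm_factors(experiment, **kwargs)
    geo = np.exp(np.mean(np.log(experiment.library_sizes.to_numpy(float))))
    eff = factors * geo
    eff.name = "effective_library_size"
    return eff


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def _design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Full model: intercept, tissue, and a separate female effect per tissue.

    Columns: [intercept, gonad, F:blastoderm, F:gonad].  Spans the same space
    as the classic tissue*sex interaction model but exposes each tissue's
    sex contrast as a single coefficient.
    """
    t = (design["tissue"] == "gonad").to_numpy(float)
    f = (design["sex"] == "F").to_numpy(float)
    X = np.column_stack([np.ones(len(design)), t, f * (1 - t), f * t])
    return X, ["intercept", "gonad", "F_blastoderm", "F_gonad"]


def _check_levels(design: pd.DataFrame) -> None:
    for tissue in TISSUES:
        for sex in ("F", "M"):
            if not ((design["tissue"] == tissue) & (design["sex"] == sex)).any():
                raise ValueError(f"design lacks {sex} samples in {tissue}")


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


@dataclass
class DispersionEstimates:
    """Common + empirically shrunk gene-wise NB dispersions."""

    common_dispersion: float
    tagwise_dispersions: pd.Series
    prior_weight: float = 10.0

    def for_genes(self, gene_ids) -> np.ndarray:
        return self.tagwise_dispersions.reindex(gene_ids).to_numpy(float)


def estimate_dispersions(
    experiment: CountExperiment,
    X: np.ndarray | None = None,
    prior_weight: float = 10.0,
    grid_span: float = 8.0,
    grid_points: int = 33,
) -> DispersionEstimates:
    """Common dispersion by summed profile likelihood; tagwise by shrinkage.

    The tagwise value for gene g maximises
    ``ll_g(phi) + prior_weight * mean_g' ll_g'(phi)`` over a log2 grid around
    the common value — the common likelihood acts as ``prior_weight``
    effective prior observations pulling each gene toward the consensus.
    """
    if X is None:
        X, _ = _design_matrix(experiment.design)
    n, p = X.shape
    if n - np.linalg.matrix_rank(X) < 1:
        raise ValueError(
            f"saturated design ({n} samples, rank {p}): no residual degrees of "
            "freedom to estimate dispersion"
        )
    Y = experiment.counts.to_numpy(float)
    offset = np.log(normalize_library_sizes(experiment).to_numpy(float))

    def neg_total(log_phi: float) -> float:
        return -fit_nb_glm(Y, X, offset, np.exp(log_phi)).adj_loglik.sum()

    res = minimize_scalar(
        neg_total,
        bounds=(np.log(_DISP_FLOOR), np.log(_DISP_CEIL)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    common = float(np.clip(np.exp(res.x), _DISP_FLOOR, _DISP_CEIL))

    # profile likelihood of every gene on a shared grid around the common value
    grid = common * 2.0 ** np.linspace(-grid_span, grid_span, grid_points)
    grid = np.clip(grid, _DISP_FLOOR, _DISP_CEIL)
    ll = np.column_stack(
        [fit_nb_glm(Y, X, offset, phi).adj_loglik for phi in grid]
    )  # genes x K
    shared = ll.mean(axis=0)
    score = ll + prior_weight * shared[None, :]
    best = np.argmax(score, axis=1)

    # parabolic refinement on log2(phi) where the argmax is interior
    log2g = np.log2(grid)
    tag = grid[best].astype(float)
    interior = (best > 0) & (best < len(grid) - 1)
    idx = np.flatnonzero(interior)
    if len(idx):
        b = best[idx]
        y0, y1, y2 = score[idx, b - 1], score[idx, b], score[idx, b + 1]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        step = log2g[1] - log2g[0]
        tag[idx] = 2.0 ** (log2g[b] + shift * step)
    tag = np.clip(tag, _DISP_FLOOR, _DISP_CEIL)
    return DispersionEstimates(
        common_dispersion=common,
        tagwise_dispersions=pd.Series(tag, index=experiment.counts.index,
                                      name="dispersion"),
        prior_weight=prior_weight,
    )


# ---------------------------------------------------------------------------
# likelihood ratio tests
# ---------------------------------------------------------------------------


@dataclass
class DimorphismResult:
    """Per-gene LRT outcome for one named test."""

    test: str
    table: pd.DataFrame  # log2fc, stat, pvalue, qvalue, direction

    def significant(self, fdr: float = 0.05) -> pd.Index:
        return self.table.index[self.table["qvalue"] < fdr]


def _pseudo_cpm(
    experiment: CountExperiment, eff: pd.Series, pseudo: float = 0.125
) -> pd.DataFrame:
    """Counts-per-million after adding an offset-scaled pseudo-fraction.

    The pseudo-count 0.125 is scaled by each sample's relative effective
    library size, so an all-zero gene gets log fold change exactly 0.
    """
    eff_arr = eff.to_numpy(float)
    rel = eff_arr / np.exp(np.mean(np.log(eff_arr)))
    padded = experiment.counts.to_numpy(float) + pseudo * rel[None, :]
    return pd.DataFrame(
        padded / (eff_arr[None, :] / 1e6),
        index=experiment.counts.index,
        columns=experiment.counts.columns,
    )


def _lrt(Y, X_full, X_red, offset, phi) -> tuple[np.ndarray, np.ndarray]:
    full = fit_nb_glm(Y, X_full, offset, phi)
    red = fit_nb_glm(Y, X_red, offset, phi)
    stat = np.clip(2.0 * (full.loglik - red.loglik), 0.0, None)
    p = stats.chi2.sf(stat, df=X_full.shape[1] - X_red.shape[1])
    return stat, p


def _result(experiment, test, log2fc, stat, p, pos_label, neg_label
            ) -> DimorphismResult:
    q = bh_adjust(p)
    direction = np.where(log2fc >= 0, pos_label, neg_label)
    table = pd.DataFrame(
        {"log2fc": log2fc, "stat": stat, "pvalue": p, "qvalue": q,
         "direction": direction},
        index=experiment.counts.index,
    )
    return DimorphismResult(test=test, table=table)


def test_sex_within_tissue(
    experiment: CountExperiment,
    dispersions: DispersionEstimates,
    tissue: str,
    effective_library_sizes: pd.Series | None = None,
) -> DimorphismResult:
    """LRT for the sex effect within one tissue (1 df).

    The model is fitted on all samples with a per-tissue sex effect; the
    tested coefficient is the female effect in ``tissue``.  log2fc is
    female over male (positive = female-biased).
    """
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue {tissue!r}")
    _check_levels(experiment.design)
    X, cols = _design_matrix(experiment.design)
    drop = cols.index(f"F_{tissue}")
    X_red = np.delete(X, drop, axis=1)
    eff = (effective_library_sizes if effective_library_sizes is not None
           else normalize_library_sizes(experiment))
    offset = np.log(eff.to_numpy(float))
    phi = dispersions.for_genes(experiment.counts.index)
    Y = experiment.counts.to_numpy(float)
    stat, p = _lrt(Y, X, X_red, offset, phi)

    cpm = _pseudo_cpm(experiment, eff)
    fs = experiment.samples(tissue=tissue, sex="F")
    ms = experiment.samples(tissue=tissue, sex="M")
    log2fc = np.log2(cpm[fs].mean(axis=1) / cpm[ms].mean(axis=1)).to_numpy()
    return _result(experiment, f"sex_{tissue}", log2fc, stat, p, "F", "M")


def test_ratio_difference(
    experiment: CountExperiment,
    dispersions: DispersionEstimates,
    effective_library_sizes: pd.Series | None = None,
) -> DimorphismResult:
    """LRT on the tissue x sex interaction (1 df).

    Significant means the gene's female:male ratio differs between
    blastoderm and gonad.  log2fc is the interaction on the log2 scale
    (female-bias in gonad minus female-bias in blastoderm); its sign sets
    the direction label.
    """
    _check_levels(experiment.design)
    X, _ = _design_matrix(experiment.design)
    t = (experiment.design["tissue"] == "gonad").to_numpy(float)
    f = (experiment.design["sex"] == "F").to_numpy(float)
    X_red = np.column_stack([np.ones(len(t)), t, f])  # additive model
    eff = (effective_library_sizes if effective_library_sizes is not None
           else normalize_library_sizes(experiment))
    offset = np.log(eff.to_numpy(float))
    phi = dispersions.for_genes(experiment.counts.index)
    Y = experiment.counts.to_numpy(float)
    stat, p = _lrt(Y, X, X_red, offset, phi)

    cpm = _pseudo_cpm(experiment, eff)

    def bias(tissue):
        fsel = experiment.samples(tissue=tissue, sex="F")
        msel = experiment.samples(tissue=tissue, sex="M")
        return np.log2(cpm[fsel].mean(axis=1) / cpm[msel].mean(axis=1))

    log2fc = (bias("gonad") - bias("blastoderm")).to_numpy()
    return _result(
        experiment, "ratio_difference", log2fc, stat, p,
        "more-dimorphic-in-gonad", "more-dimorphic-in-blastoderm",
    )


def test_tissue_average(
    experiment: CountExperiment,
    dispersions: DispersionEstimates,
    effective_library_sizes: pd.Series | None = None,
) -> DimorphismResult:
    """LRT on the tissue main effect with sexes pooled (1 df).

    Tests whether the (male+female)/2 average expression changes between
    tissues; log2fc positive = higher in gonad.
    """
    for tissue in TISSUES:
        if not (experiment.design["tissue"] == tissue).any():
            raise ValueError(f"design lacks {tissue} samples")
    t = (experiment.design["tissue"] == "gonad").to_numpy(float)
    X = np.column_stack([np.ones(len(t)), t])
    X_red = np.ones((len(t), 1))
    eff = (effective_library_sizes if effective_library_sizes is not None
           else normalize_library_sizes(experiment))
    offset = np.log(eff.to_numpy(float))
    phi = dispersions.for_genes(experiment.counts.index)
    Y = experiment.counts.to_numpy(float)
    stat, p = _lrt(Y, X, X_red, offset, phi)

    cpm = _pseudo_cpm(experiment, eff)
    g = experiment.samples(tissue="gonad")
    b = experiment.samples(tissue="blastoderm")
    log2fc = np.log2(cpm[g].mean(axis=1) / cpm[b].mean(axis=1)).to_numpy()
    return _result(
        experiment, "tissue_average", log2fc, stat, p,
        "higher-in-gonad", "higher-in-blastoderm",
    )


# ---------------------------------------------------------------------------
# multiple testing, tallies, enrichment
# ---------------------------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values with monotonicity enforcement."""
    p = np.asarray(p_values, float)
    if p.ndim != 1:
        p = p.reshape(-1)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


@dataclass
class ClassTally:
    """Chromosome-class breakdown of significant genes.

    ``sex_counts``: (test, chrom_class) x direction counts for the two
    within-tissue sex tests.  ``ratio_patterns`` / ``tissue_patterns``:
    per-dimorphic-gene inter-tissue categories.  ``missing_annotation``:
    gene ids excluded for lack of annotation.
    """

    sex_counts: pd.DataFrame
    ratio_patterns: pd.Series
    tissue_patterns: pd.Series
    missing_annotation: list = field(default_factory=list)

    def total_significant(self, test: str) -> int:
        return int(self.sex_counts.loc[test].to_numpy().sum())


def classify_tallies(
    results: dict[str, DimorphismResult],
    annotation: pd.DataFrame,
    fdr: float = 0.05,
) -> ClassTally:
    """Tally significant genes by chromosome class and inter-tissue pattern.

    ``results`` must contain the two sex tests; the ratio-difference and
    tissue-average results, when present, provide the inter-tissue pattern
    of every gene dimorphic in at least one tissue.
    """
    sex_tests = [k for k in ("sex_blastoderm", "sex_gonad") if k in results]
    if not sex_tests:
        raise ValueError("need at least one sex test result")
    missing: set = set()
    rows = {}
    for name in sex_tests:
        table = results[name].table
        unknown = table.index.difference(annotation.index)
        missing.update(unknown)
        sig = table[(table["qvalue"] < fdr)].drop(index=unknown, errors="ignore")
        cls = annotation.loc[sig.index, "chrom_class"]
        for direction in ("F", "M"):
            counted = cls[sig["direction"] == direction].value_counts()
            rows[(name, direction)] = counted
    sex_counts = (
        pd.DataFrame(rows).T.fillna(0).astype(int)
        .rename_axis(index=["test", "direction"])
    )

    dimorphic = pd.Index(sorted(set().union(
        *[set(results[n].significant(fdr)) for n in sex_tests]
    )))
    dimorphic = dimorphic.difference(pd.Index(sorted(missing)))

    def patterns(result_name: str, null_label: str) -> pd.Series:
        if result_name not in results:
            return pd.Series(dtype=object)
        t = results[result_name].table.reindex(dimorphic)
        return pd.Series(
            np.where(t["qvalue"] < fdr, t["direction"], null_label),
            index=dimorphic, name=result_name,
        )

    return ClassTally(
        sex_counts=sex_counts,
        ratio_patterns=patterns("ratio_difference", "no-difference"),
        tissue_patterns=patterns("tissue_average", "no-change"),
        missing_annotation=sorted(missing),
    )


def enrichment_fisher(
    significant_genes, annotated_list, universe
) -> tuple[float, float]:
    """Two-sided Fisher's exact test for over-representation of a gene list.

    Returns (odds ratio, p).  The 2x2 table crosses membership of the
    significant set with membership of the annotated list over ``universe``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    listed = set(annotated_list)
    if not listed <= universe:
        raise ValueError("annotated list is not a subset of the universe")
    sig = set(significant_genes) & universe
    a = len(sig & listed)
    b = len(sig - listed)
    c = len(listed - sig)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


# ---------------------------------------------------------------------------
# FPKM and Z dosage
# ---------------------------------------------------------------------------


def compute_fpkm(
    counts: pd.DataFrame, gene_lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """FPKM_gs = count_gs / (length_g/1e3 x libsize_s/1e6)."""
    lengths = gene_lengths.reindex(counts.index).to_numpy(float)
    if np.any(~np.isfinite(lengths)) or np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive for all genes")
    libs = library_sizes.reindex(counts.columns).to_numpy(float)
    if np.any(libs <= 0):
        raise ValueError("library sizes must be positive")
    return counts / np.outer(lengths / 1e3, libs / 1e6)


def z_dosage_ratio(
    fpkm: pd.DataFrame,
    design: pd.DataFrame,
    annotation: pd.DataFrame,
    expressed_floor: float = 1.0,
    trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean male:female expression ratio over expressed Z genes.

    Per tissue: each Z gene contributes (mean male FPKM)/(mean female FPKM);
    genes below ``expressed_floor`` mean FPKM in both sexes are excluded;
    the per-gene ratios are summarised by a ``trim``-trimmed mean taken on
    the log scale (so the estimate inverts exactly when the sex labels are
    swapped, and single-sex outliers such as the female-only MHM locus fall
    into the trimmed tails).
    """
    z_genes = annotation.index[annotation["chrom_class"] == "Z"]
    z_genes = z_genes.intersection(fpkm.index)
    if len(z_genes) == 0:
        raise ValueError("no Z genes present")
    out = {}
    for tissue in sorted(design["tissue"].unique()):
        fs = design.index[(design["tissue"] == tissue) & (design["sex"] == "F")]
        ms = design.index[(design["tissue"] == tissue) & (design["sex"] == "M")]
        fmean = fpkm.loc[z_genes, fs].mean(axis=1)
        mmean = fpkm.loc[z_genes, ms].mean(axis=1)
        expressed = (fmean >= expressed_floor) | (mmean >= expressed_floor)
        if not expressed.any():
            raise ValueError(f"no expressed Z genes in {tissue}")
        with np.errstate(divide="ignore"):
            log_ratio = np.log(mmean[expressed].to_numpy()) - np.log(
                fmean[expressed].to_numpy()
            )
        trimmed = stats.trim_mean(log_ratio, proportiontocut=trim)
        if not np.isfinite(trimmed):
            raise ValueError(
                f"too many single-sex Z genes in {tissue} for a stable ratio"
            )
        out[tissue] = float(np.exp(trimmed))
    return pd.Series(out, name="z_male_female_ratio")
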