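"""Statistical layer: transform, impute, t-tests, ANOVA + LSD, PCA, clustering.

All tests operate on the imputed log2 matrix. Differential results are
long-format DataFrames with one row per protein per contrast; the ANOVA
additionally carries a study-level least-significant-difference cutoff on
the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats as sps

from .matrix import IntensityMatrix

RESULT_COLUMNS = ["protein", "contrast", "estimate", "p_value", "significant"]


@dataclass
class AnalysisConfig:
    alpha: float = 0.05
    imputation_offset: float = 1.0
    lsd_alpha: float = 0.05
    linkage: str = "average"
    welch: bool = False
    bh_adjust: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.imputation_offset < 0:
            raise ValueError(f"imputation_offset must be >= 0, got {self.imputation_offset}")
        if not 0.0 < self.lsd_alpha < 1.0:
            raise ValueError(f"lsd_alpha must be in (0, 1), got {self.lsd_alpha}")


def log2_transform(m: IntensityMatrix) -> IntensityMatrix:
    """log2 of present values; missing stays missing."""
    if m.log2:
        return m
    vals = m.intensities.to_numpy(dtype=float)
    if np.nanmin(vals, initial=np.inf) < 0:
        raise ValueError("intensities must be >= 0 before log2 transform")
    with np.errstate(divide="ignore"):
        logged = np.log2(vals)
    logged[np.isneginf(logged)] = np.nan  # zero intensity = missing
    return m.with_intensities(
        pd.DataFrame(logged, index=m.proteins, columns=m.samples), log2=True
    )


def impute_constant(m: IntensityMatrix, cfg: AnalysisConfig | None = None) -> IntensityMatrix:
    """Replace every missing cell by (global min observed log2 − offset).

    Keeps a presence/absence mask on the returned matrix so downstream
    stages can distinguish measured from imputed cells.
    """
    cfg = cfg or AnalysisConfig()
    if not m.log2:
        raise ValueError("impute_constant expects a log2-transformed matrix")
    vals = m.intensities
    if vals.isna().all().all():
        raise ValueError("matrix is fully missing; no imputation constant defined")
    constant = float(np.nanmin(vals.to_numpy())) - cfg.imputation_offset
    presence = vals.notna()
    return m.with_intensities(vals.fillna(constant), presence=presence)


def _ttest_arrays(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided t-test per row. Zero pooled variance: p=1 if means equal else 0."""
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    diff = mean_a - mean_b
    if equal_var:
        sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = np.full(len(diff), na + nb - 2, dtype=float)
    else:
        se2 = var_a / na + var_b / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        p = 2.0 * sps.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    if degenerate.any():
        p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
        with np.errstate(invalid="ignore"):
            t = np.where(degenerate, np.sign(diff) * np.inf, t)
        t = np.where(degenerate & (diff == 0), 0.0, t)
    return t, p


def ttest_contrast(
    m: IntensityMatrix,
    group_a: list[str],
    group_b: list[str],
    cfg: AnalysisConfig | None = None,
    contrast: str = "A-vs-B",
) -> pd.DataFrame:
    """Per-protein two-sided Student's t-test; estimate = mean(A) − mean(B)."""
    cfg = cfg or AnalysisConfig()
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    a = m.intensities[group_a].to_numpy(dtype=float)
    b = m.intensities[group_b].to_numpy(dtype=float)
    _, p = _ttest_arrays(a, b, equal_var=not cfg.welch)
    out = pd.DataFrame(
        {
            "protein": m.proteins,
            "contrast": contrast,
            "estimate": a.mean(axis=1) - b.mean(axis=1),
            "p_value": p,
        }
    )
    if cfg.bh_adjust:
        out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["p_value"] <= cfg.alpha
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class AnovaResult:
    table: pd.DataFrame  # protein, contrast, estimate, p_value, significant
    critical_difference: float
    df_within: int
    median_ms_within: float


def anova_all_groups(
    m: IntensityMatrix,
    groups: dict[str, list[str]],
    cfg: AnalysisConfig | None = None,
    contrast: str = "ANOVA",
) -> AnovaResult:
    """One-way fixed-effects ANOVA per protein plus a Fisher LSD cutoff.

    The study-level critical difference is
    ``t(1 − lsd_alpha/2, df_within) * sqrt(2 * MSw / n_h)`` with MSw the
    median within-group mean square across proteins and n_h the harmonic
    mean of group sizes. The per-protein estimate is the largest absolute
    difference between group means (signed).
    """
    cfg = cfg or AnalysisConfig()
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    sizes = {k: len(v) for k, v in groups.items()}
    if min(sizes.values()) < 2:
        small = [k for k, n in sizes.items() if n < 2]
        raise ValueError(f"groups with < 2 samples: {small}")
    seen: set[str] = set()
    for k, v in groups.items():
        dup = seen & set(v)
        if dup:
            raise ValueError(f"samples assigned to multiple groups: {sorted(dup)}")
        seen |= set(v)

    arrays = {k: m.intensities[v].to_numpy(dtype=float) for k, v in groups.items()}
    n_total = sum(sizes.values())
    k = len(groups)
    grand = np.hstack(list(arrays.values())).mean(axis=1)

    ss_between = np.zeros(len(m.proteins))
    ss_within = np.zeros(len(m.proteins))
    means = {}
    for name, arr in arrays.items():
        mu = arr.mean(axis=1)
        means[name] = mu
        ss_between += sizes[name] * (mu - grand) ** 2
        ss_within += ((arr - mu[:, None]) ** 2).sum(axis=1)

    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
        p = sps.f.sf(f, df_between, df_within)
    # degenerate rows: no within-variance
    zero_within = ms_within == 0
    p = np.where(zero_within, np.where(ms_between == 0, 1.0, 0.0), p)

    mean_mat = np.column_stack(list(means.values()))
    hi = mean_mat.max(axis=1)
    lo = mean_mat.min(axis=1)
    estimate = np.where(hi - grand >= grand - lo, hi - lo, lo - hi)

    n_h = len(sizes) / sum(1.0 / n for n in sizes.values())
    median_msw = float(np.median(ms_within))
    crit = float(sps.t.ppf(1.0 - cfg.lsd_alpha / 2.0, df_within) * np.sqrt(2.0 * median_msw / n_h))

    table = pd.DataFrame(
        {
            "protein": m.proteins,
            "contrast": contrast,
            "estimate": estimate,
            "p_value": p,
        }
    )
    if cfg.bh_adjust:
        table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    table["significant"] = table["p_value"] <= cfg.alpha
    table["critical_difference"] = crit
    return AnovaResult(
        table=table,
        critical_difference=crit,
        df_within=df_within,
        median_ms_within=median_msw,
    )


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # proteins x components
    explained_variance_ratio: np.ndarray


def pca(m: IntensityMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of samples on the protein-wise mean-centered log2 matrix.

    Centering only — no variance scaling.
    """
    x = m.intensities.to_numpy(dtype=float).T  # samples x proteins
    if np.isnan(x).any():
        raise ValueError("PCA requires a complete (imputed) matrix")
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    max_comp = min(x.shape)
    n_components = min(n_components or max_comp, max_comp)
    scores = u[:, :n_components] * s[:n_components]
    var = s**2 / max(x.shape[0] - 1, 1)
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    comps = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=m.samples, columns=comps),
        loadings=pd.DataFrame(vt[:n_components].T, index=m.proteins, columns=comps),
        explained_variance_ratio=ratio[:n_components],
    )


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    newick: str


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0  # constant profile -> all-zero z-scores
    return (values - mean) / sd


def _to_newick(node: sch.ClusterNode, labels: list[str], parent_dist: float) -> str:
    length = parent_dist - node.dist
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.6g}"
    left = _to_newick(node.left, labels, node.dist)
    right = _to_newick(node.right, labels, node.dist)
    return f"({left},{right}):{length:.6g}"


def cluster_significant(
    m: IntensityMatrix,
    significant: list[str],
    cfg: AnalysisConfig | None = None,
) -> ClusterResult:
    """Z-score significant protein profiles, cluster them, export Newick."""
    cfg = cfg or AnalysisConfig()
    if len(significant) < 2:
        raise ValueError("need >= 2 significant proteins to cluster")
    sub = m.intensities.loc[significant]
    if sub.isna().any().any():
        raise ValueError("clustering requires a complete (imputed) matrix")
    z = _zscore_rows(sub.to_numpy(dtype=float))
    link = sch.linkage(z, method=cfg.linkage, metric="euclidean")
    tree = sch.to_tree(link)
    newick = _to_newick(tree, list(significant), tree.dist) + ";"
    return ClusterResult(linkage=link, labels=list(significant), newick=newick)
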