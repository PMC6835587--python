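"""Feature-wise statistics battery: PCA, repeated-measures ANOVA,
Kruskal-Wallis and Bonferroni adjustment.

The RM-ANOVA is the one-way within-subjects form with pools as subjects:
F = MS_condition / MS_(condition x subject), df = (k-1) and (k-1)(n-1).
It is implemented as a vectorized sums-of-squares decomposition so that
thousands of features can be tested at once.  The Kruskal-Wallis test
(scipy, mid-rank tie correction, chi-squared reference with k-1 df)
compares the most extreme condition of a series against the reference.
With three pools per group its permutation distribution has only 20 atoms,
so the smallest attainable two-group p is about 0.0495 and a Bonferroni
correction at family sizes in the hundreds or thousands can never reject;
see docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA as _SKPCA

from .annotation import AnnotatedMatrix
from .synthetic import REFERENCE_SERIES, StudyDesign

log = logging.getLogger(__name__)


@dataclass
class TestResult:
    """One feature-wise test outcome."""

    metabolite: str
    test: str  # "rm_anova" | "kruskal_wallis"
    statistic: float
    df1: float
    df2: float | None
    p_raw: float
    p_bonferroni: float
    family_m: int
    degenerate: bool = False


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


def pca(
    matrix: AnnotatedMatrix | pd.DataFrame,
    centering: str = "center_only",
    n_components: int | None = None,
) -> PCAResult:
    """PCA over samples (rows) with mean-centering only by default.

    No intensity normalisation or unit-variance scaling is applied unless
    ``centering='center_scale'`` (features with zero variance are left
    unscaled).  Input is an annotated matrix (features x samples, transposed
    internally) or a samples x features DataFrame.
    """
    if isinstance(matrix, AnnotatedMatrix):
        X = matrix.values.T  # samples x features
    else:
        X = matrix
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    data = X.to_numpy(float)
    if centering not in ("center_only", "center_scale"):
        raise ValueError(f"unknown centering {centering!r}")
    if centering == "center_scale":
        sd = data.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        data = (data - data.mean(axis=0)) / sd
    k = n_components or min(data.shape)
    model = _SKPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(data)
    comps = [f"PC{i + 1}" for i in range(model.n_components_)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comps),
        loadings=pd.DataFrame(model.components_.T, index=X.columns, columns=comps),
        explained_variance=model.explained_variance_,
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def rm_anova_matrix(x: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized one-way within-subjects ANOVA.

    ``x`` has shape (n_features, n_subjects, n_levels) and must be complete
    (drop incomplete subjects beforehand).  Returns arrays ``F, df1, df2, p,
    degenerate``.  A zero error term with zero condition effect (constant
    feature) yields F = 0, p = 1, flagged degenerate; a zero error term with
    a non-zero condition effect yields F = inf, p = 0, flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected features x subjects x levels array")
    n_feat, n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("RM-ANOVA needs >= 2 subjects and >= 2 levels")
    grand = x.mean(axis=(1, 2), keepdims=True)
    subj = x.mean(axis=2, keepdims=True)
    cond = x.mean(axis=1, keepdims=True)
    ss_cond = (n * (cond - grand) ** 2).sum(axis=(1, 2))
    resid = x - subj - cond + grand
    ss_err = (resid**2).sum(axis=(1, 2))
    df1, df2 = float(k - 1), float((k - 1) * (n - 1))
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    degenerate = ms_err == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ms_cond / ms_err
    F = np.where(degenerate & (ss_cond == 0), 0.0, F)
    F = np.where(degenerate & (ss_cond > 0), np.inf, F)
    p = np.where(
        np.isinf(F), 0.0, np.where(F == 0, 1.0, sps.f.sf(np.where(np.isfinite(F), F, 1.0), df1, df2))
    )
    return {
        "F": F,
        "df1": np.full(n_feat, df1),
        "df2": np.full(n_feat, df2),
        "p": p,
        "degenerate": degenerate,
    }


def rm_anova(feature_values: np.ndarray | pd.DataFrame) -> TestResult:
    """One-way RM-ANOVA for a single feature given a pools x levels grid."""
    grid = (
        feature_values.to_numpy(float)
        if isinstance(feature_values, pd.DataFrame)
        else np.asarray(feature_values, dtype=float)
    )
    res = rm_anova_matrix(grid[None, :, :])
    return TestResult(
        metabolite="",
        test="rm_anova",
        statistic=float(res["F"][0]),
        df1=float(res["df1"][0]),
        df2=float(res["df2"][0]),
        p_raw=float(res["p"][0]),
        p_bonferroni=float(min(1.0, res["p"][0])),
        family_m=1,
        degenerate=bool(res["degenerate"][0]),
    )


def kruskal_wallis(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-group Kruskal-Wallis (H with mid-rank tie correction, chi2 df=1)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    try:
        with np.errstate(invalid="ignore"):
            H, p = sps.kruskal(a, b)
    except ValueError:
        H, p = 0.0, 1.0
    if not np.isfinite(H):
        # all observations tied across both groups: no evidence, H = 0
        H, p = 0.0, 1.0
    return TestResult(
        metabolite="",
        test="kruskal_wallis",
        statistic=float(H),
        df1=1.0,
        df2=None,
        p_raw=float(p),
        p_bonferroni=float(min(1.0, p)),
        family_m=1,
    )


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p -> min(1, m * p), order preserved.

    ``m`` is the family size (defaults to the list length) and may exceed the
    number of p-values supplied, e.g. when a subset of a larger tested family
    is being adjusted.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m must be >= number of p-values")
    return np.minimum(1.0, m * p)


def feature_tests(
    annotated: AnnotatedMatrix,
    design: StudyDesign,
    series: str,
    family_m: int | None = None,
    include_reference_level: bool = True,
) -> pd.DataFrame:
    """RM-ANOVA across all levels of ``series`` and Kruskal-Wallis comparing
    the most extreme level to the reference, for every feature, with
    Bonferroni adjustment at family size ``family_m`` (default: number of
    features tested).

    The reference sample enters the RM-ANOVA as the baseline level.  Pools
    with a missing (excluded) cell in the grid are dropped for all features
    of that series; if that would leave fewer than two pools, the levels
    with missing cells are dropped instead so all pools are retained
    (both fallbacks logged).
    """
    meta = annotated.sample_meta.reset_index()
    levels = sorted(meta.loc[meta["series"] == series, "level"].unique())
    if not levels:
        raise KeyError(f"series {series!r} not present")
    grid_levels = ([("reference", 0.0)] if include_reference_level else []) + [
        (series, lv) for lv in levels
    ]
    pools = sorted(meta["pool"].unique())

    def sample_of(p, s, lv):
        s_eff = REFERENCE_SERIES if s == "reference" else s
        sel = meta[(meta["pool"] == p) & (meta["series"] == s_eff) & (meta["level"] == lv)]
        return sel["sample_id"].iloc[0] if len(sel) else None

    def complete_pools(levels_used):
        out = {}
        for p in pools:
            ids = [sample_of(p, s, lv) for s, lv in levels_used]
            if all(i is not None for i in ids):
                out[p] = ids
        return out

    cells = complete_pools(grid_levels)
    if len(cells) < len(pools):
        log.info(
            "rm_anova(%s): %d incomplete pool(s)", series, len(pools) - len(cells)
        )
    if len(cells) < 2:
        # keep every pool by restricting to levels measured in all pools
        kept = [
            (s, lv)
            for s, lv in grid_levels
            if all(sample_of(p, s, lv) is not None for p in pools)
        ]
        log.info(
            "rm_anova(%s): dropping %d level(s) with missing cells instead of pools",
            series, len(grid_levels) - len(kept),
        )
        grid_levels = kept
        cells = complete_pools(grid_levels)
    if len(cells) < 2 or len(grid_levels) < 2:
        raise ValueError(f"series {series!r}: not enough complete pools/levels")

    values = annotated.values
    feats = list(values.index)
    x = np.stack(
        [values[ids].to_numpy(float) for ids in cells.values()], axis=1
    )  # features x subjects x levels
    anova = rm_anova_matrix(x)

    # KW uses every pool with both the extreme and the reference measured,
    # independently of the ANOVA's completion strategy
    extreme = levels[-1]
    ext_ids, ref_ids = [], []
    for p in pools:
        e = sample_of(p, series, extreme)
        r = sample_of(p, "reference", 0.0)
        if e is not None and r is not None:
            ext_ids.append(e)
            ref_ids.append(r)
    if not ext_ids:
        raise ValueError(f"series {series!r}: extreme condition not measured")
    kw_stat = np.empty(len(feats))
    kw_p = np.empty(len(feats))
    ext_vals = values[ext_ids].to_numpy(float)
    ref_vals = values[ref_ids].to_numpy(float)
    for i in range(len(feats)):
        r = kruskal_wallis(ext_vals[i], ref_vals[i])
        kw_stat[i], kw_p[i] = r.statistic, r.p_raw

    m = family_m or len(feats)
    out = pd.DataFrame(
        {
            "metabolite": feats * 2,
            "test": ["rm_anova"] * len(feats) + ["kruskal_wallis"] * len(feats),
            "statistic": np.concatenate([anova["F"], kw_stat]),
            "df1": np.concatenate([anova["df1"], np.ones(len(feats))]),
            "df2": np.concatenate([anova["df2"], np.full(len(feats), np.nan)]),
            "p_raw": np.concatenate([anova["p"], kw_p]),
            "degenerate": np.concatenate(
                [anova["degenerate"], np.zeros(len(feats), dtype=bool)]
            ),
        }
    )
    out["family_m"] = m
    out["p_bonferroni"] = np.minimum(1.0, m * out["p_raw"].to_numpy())
    return out
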