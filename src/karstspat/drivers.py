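"""Environmental drivers of the karst / non-karst split: balanced
sampling, raster extraction, correlation filtering, and PCA.

The workflow mirrors a standard ordination protocol: (1) balance the
two landscape classes by subsampling the larger (non-karst) class down
to the karst count; (2) extract environmental values at each point
from single-band rasters; (3) drop predictors that are nearly
uncorrelated with the landscape response (|point-biserial r| < 0.1)
and prune collinear pairs (|pairwise r| > 0.70), keeping the member
better correlated with the response; (4) z-score the survivors and run
a PCA, reporting per-component variance explained and labelled scores.
A descriptive separation diagnostic (between-class centroid distance
in PC1-PC2, in pooled within-class SD units) summarises whether the
two classes actually segregate in environmental space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .occurrences import KL
from .rasters import Raster

RESPONSE_COL = "karst"

BIOCLIM_VARS = ("BIO1", "BIO4", "BIO7", "BIO12", "BIO15", "BIO17", "BIO19")
SOIL_VARS = ("BDTICM", "elevation", "ORC", "clay")

WEAK_RESPONSE_R = 0.1
COLLINEARITY_R = 0.70


def balance_sample(records: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Subsample NKL records without replacement to the KL count.

    All KL records are kept. When NKL is already the smaller class no
    subsampling happens. Deterministic for a given seed.
    """
    if "landscape" not in records.columns:
        raise ValueError("records must be landscape-tagged")
    kl = records[records["landscape"] == KL]
    nkl = records[records["landscape"] != KL]
    if kl.empty or nkl.empty:
        raise ValueError("both landscape classes must be non-empty")
    if len(nkl) <= len(kl):
        return records.copy()
    rng = np.random.default_rng(seed)
    take = rng.choice(len(nkl), size=len(kl), replace=False)
    take.sort()
    out = pd.concat([kl, nkl.iloc[take]])
    return out.sort_index().reset_index(drop=True)


def extract_env(
    records: pd.DataFrame, rasters: Mapping[str, Raster]
) -> tuple[pd.DataFrame, int]:
    """Environment matrix: one row per point, one column per raster,
    plus the binary landscape response (karst = 1, non-karst = 0).

    Values are read with the nearest-cell rule. Points over no-data in
    any layer are dropped; the count of dropped points is returned.
    """
    lons = records["decimalLongitude"].to_numpy(dtype=float)
    lats = records["decimalLatitude"].to_numpy(dtype=float)
    cols = {name: r.sample(lons, lats) for name, r in rasters.items()}
    env = pd.DataFrame(cols)
    env[RESPONSE_COL] = (records["landscape"].to_numpy() == KL).astype(int)
    keep = ~env.drop(columns=RESPONSE_COL).isna().any(axis=1)
    n_dropped = int((~keep).sum())
    return env[keep].reset_index(drop=True), n_dropped


@dataclass
class FilterLog:
    """Record of every predictor dropped and why."""

    zero_variance: list[str] = field(default_factory=list)
    weak_response: list[tuple[str, float]] = field(default_factory=list)
    collinear: list[tuple[str, str, float, float, float]] = field(default_factory=list)
    # collinear entries: (dropped, kept, pairwise_r, dropped_resp_r, kept_resp_r)

    @property
    def n_dropped(self) -> int:
        return len(self.zero_variance) + len(self.weak_response) + len(self.collinear)


def filter_predictors(
    env: pd.DataFrame, response_col: str = RESPONSE_COL
) -> tuple[pd.DataFrame, FilterLog]:
    """Two-step predictor screening.

    Step 1 drops predictors with |point-biserial r| < 0.1 against the
    binary response (zero-variance columns are dropped first, their
    correlation being undefined). Step 2 walks collinear pairs
    (|pairwise Pearson r| > 0.70) from the strongest pair down and
    drops the member with the weaker |response correlation|.
    """
    if response_col not in env.columns:
        raise ValueError(f"missing response column {response_col!r}")
    y = env[response_col].to_numpy(dtype=float)
    if len(np.unique(y)) < 2 or min(np.bincount(y.astype(int))) < 2:
        raise ValueError("need at least 2 points in each class")
    log = FilterLog()
    predictors = [c for c in env.columns if c != response_col]

    resp_r: dict[str, float] = {}
    for c in predictors:
        x = env[c].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            log.zero_variance.append(c)
            continue
        resp_r[c] = float(stats.pearsonr(x, y).statistic)
    survivors = []
    for c, r in resp_r.items():
        if abs(r) < WEAK_RESPONSE_R:
            log.weak_response.append((c, r))
        else:
            survivors.append(c)

    # greedy collinearity pruning, strongest pairs first
    while len(survivors) >= 2:
        sub = env[survivors].to_numpy(dtype=float)
        corr = np.corrcoef(sub, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        r_pair = float(corr[i, j])
        if abs(r_pair) <= COLLINEARITY_R:
            break
        a, b = survivors[i], survivors[j]
        # drop the weaker response correlate; tie -> keep earlier column
        drop, keep = (a, b) if abs(resp_r[a]) < abs(resp_r[b]) else (b, a)
        log.collinear.append((drop, keep, r_pair, resp_r[drop], resp_r[keep]))
        survivors.remove(drop)

    reduced = env[survivors + [response_col]].copy()
    return reduced, log


@dataclass
class PcaResult:
    """Loadings, variance explained (percent) and labelled scores."""

    loadings: pd.DataFrame          # variables x components
    explained_pct: np.ndarray       # per component, sums to 100
    scores: pd.DataFrame            # PC columns + landscape label
    mode: str

    @property
    def cumulative_pct(self) -> np.ndarray:
        return np.cumsum(self.explained_pct)


def run_pca(env: pd.DataFrame, mode: str = "all") -> PcaResult:
    """PCA of the z-scored environment matrix.

    ``mode`` selects the variable set: ``all``, ``bioclim_only``
    (BIO* columns) or ``soil_only`` (soil plus elevation). Columns are
    standardized to zero mean / unit variance, so the decomposition is
    of the correlation matrix; variance explained per component is
    eigenvalue / sum(eigenvalues) * 100.
    """
    if mode not in ("all", "bioclim_only", "soil_only"):
        raise ValueError(f"unknown mode {mode!r}")
    predictors = [c for c in env.columns if c != RESPONSE_COL]
    if mode == "bioclim_only":
        predictors = [c for c in predictors if c in BIOCLIM_VARS]
    elif mode == "soil_only":
        predictors = [c for c in predictors if c in SOIL_VARS]
    if len(predictors) < 2:
        raise ValueError(f"need >= 2 variables for PCA, have {len(predictors)}")
    if len(env) < 3:
        raise ValueError("need >= 3 points for PCA")

    X = env[predictors].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [p for p, s in zip(predictors, sd) if s == 0]
        raise ValueError(f"zero-variance predictor(s): {bad}")
    Z = (X - mu) / sd

    pca = PCA(n_components=len(predictors), svd_solver="full")
    scores = pca.fit_transform(Z)
    explained = pca.explained_variance_ratio_ * 100.0

    comp_names = [f"PC{i + 1}" for i in range(len(predictors))]
    loadings = pd.DataFrame(pca.components_.T, index=predictors, columns=comp_names)
    score_df = pd.DataFrame(scores, columns=comp_names)
    if RESPONSE_COL in env.columns:
        score_df["landscape"] = np.where(
            env[RESPONSE_COL].to_numpy() == 1, "KL", "NKL"
        )
    return PcaResult(
        loadings=loadings, explained_pct=explained, scores=score_df, mode=mode
    )


@dataclass
class SeparationSummary:
    """Descriptive class separation in the PC1-PC2 plane."""

    centroid_distance: float  # pooled within-class SD units
    nested: bool              # True when distance < 1


def separation_diagnostic(result: PcaResult) -> SeparationSummary:
    """Distance between KL and NKL score centroids in PC1-PC2,
    standardized by the pooled within-class SD; classes closer than one
    pooled SD are flagged "nested" (no discernible clustering)."""
    if "landscape" not in result.scores.columns:
        raise ValueError("scores carry no landscape labels")
    pcs = result.scores[["PC1", "PC2"]].to_numpy(dtype=float)
    labels = result.scores["landscape"].to_numpy()
    groups = [pcs[labels == g] for g in ("KL", "NKL")]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each class needs >= 2 points")
    centroids = [g.mean(axis=0) for g in groups]
    dist = float(np.linalg.norm(centroids[0] - centroids[1]))
    pooled_var = np.mean([g.var(axis=0, ddof=1).mean() for g in groups])
    d = dist / np.sqrt(pooled_var)
    return SeparationSummary(centroid_distance=float(d), nested=bool(d < 1.0))


def plot_scores(result: PcaResult, path) -> None:
    """PC1-PC2 scatter coloured by landscape, written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, color in (("KL", "tab:blue"), ("NKL", "tab:red")):
        sub = result.scores[result.scores["landscape"] == label]
        ax.scatter(sub["PC1"], sub["PC2"], s=8, alpha=0.6, label=label, color=color)
    ax.set_xlabel(f"PC1 ({result.explained_pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({result.explained_pct[1]:.1f}%)")
    ax.legend(frameon=False)
    ax.set_title(f"PCA scores ({result.mode})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
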