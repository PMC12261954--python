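"""Multi-area regression of VEP topographies on forward predictions.

Observed topography sets are regressed against the predicted sets of
V1, V2 and V3 (and optionally further areas such as MT loaded from
file), stacking all wedges so each model sees
``n_wedges x n_electrodes`` observations.  All variables are z-scored,
models are fit without intercept for every non-empty area subset, and
subsets are compared by R^2 and BIC.  A sliding-window variant traces
area beta coefficients across the epoch with bootstrap standard
errors, and a beta-dominance summary contrasts |beta_V1| with the
other areas over time.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .geometry_forward import ElectrodeLayout, TopographySet
from .vep_derivation import EvokedSet

__all__ = [
    "Design",
    "RegressionResult",
    "TimecourseFit",
    "stack_and_zscore",
    "fit_model",
    "enumerate_models",
    "time_resolved_fit",
    "beta_dominance",
    "results_table",
]


@dataclass
class Design:
    """Stacked, z-scored regression design with row bookkeeping."""

    y: np.ndarray
    X: np.ndarray
    areas: list[str]
    wedge_of_row: np.ndarray
    electrode_of_row: np.ndarray
    y_mean: float
    y_sd: float
    x_mean: np.ndarray
    x_sd: np.ndarray


@dataclass
class RegressionResult:
    areas: tuple[str, ...]
    beta: np.ndarray
    r2: float
    bic: float
    n: int
    k: int
    best_bic: bool = False

    def beta_of(self, area: str) -> float:
        return float(self.beta[self.areas.index(area)])


@dataclass
class TimecourseFit:
    centers_ms: np.ndarray
    results: list[dict[tuple[str, ...], RegressionResult]]
    boot_se: list[dict[tuple[str, ...], np.ndarray]]

    def beta_timecourse(
        self, model: tuple[str, ...], area: str
    ) -> np.ndarray:
        return np.array([r[model].beta_of(area) for r in self.results])

    def se_timecourse(self, model: tuple[str, ...], area: str) -> np.ndarray:
        idx = list(model).index(area)
        return np.array([b[model][idx] for b in self.boot_se])


def _zscore_cols(a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = a.mean(axis=0)
    sd = a.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"zero-variance column {bad} cannot be z-scored")
    return (a - mean) / sd, mean, sd


def stack_and_zscore(
    obs: TopographySet, preds: list[TopographySet]
) -> Design:
    """Stack wedges and z-score outcome and regressors.

    Rows are ordered wedge-major (wedge 0's electrodes first); the
    returned bookkeeping arrays allow any row to be traced back to its
    wedge and electrode.
    """
    n_w, n_e = obs.values.shape
    for p in preds:
        if p.values.shape != (n_w, n_e):
            raise ValueError("prediction sets must match the observed shape")
    yz, y_mean, y_sd = _zscore_cols(obs.stacked()[:, None])
    X = np.column_stack([p.stacked() for p in preds])
    Xz, x_mean, x_sd = _zscore_cols(X)
    return Design(
        y=yz.ravel(),
        X=Xz,
        areas=[p.label for p in preds],
        wedge_of_row=np.repeat(np.arange(n_w), n_e),
        electrode_of_row=np.tile(np.arange(n_e), n_w),
        y_mean=float(y_mean[0]),
        y_sd=float(y_sd[0]),
        x_mean=x_mean,
        x_sd=x_sd,
    )


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    gram = X.T @ X
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("collinear regressors: design is rank deficient")
    beta = np.linalg.solve(gram, X.T @ y)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def fit_model(design: Design, areas: tuple[str, ...] | list[str]) -> RegressionResult:
    """OLS fit (no intercept; all variables z-scored) of an area subset.

    ``R^2 = 1 - RSS/TSS`` and the Gaussian-likelihood BIC
    ``n*ln(RSS/n) + k*ln(n)`` with ``k`` counting the included areas.
    """
    areas = tuple(areas)
    if not areas:
        raise ValueError("area subset must be non-empty")
    idx = [design.areas.index(a) for a in areas]
    X = design.X[:, idx]
    beta, rss = _ols(design.y, X)
    n = len(design.y)
    tss = float(design.y @ design.y)
    r2 = 1.0 - rss / tss
    k = len(areas)
    bic = n * np.log(max(rss, 1e-300) / n) + k * np.log(n)
    return RegressionResult(
        areas=areas, beta=beta, r2=r2, bic=float(bic), n=n, k=k
    )


def enumerate_models(
    design: Design, areas: list[str] | None = None
) -> list[RegressionResult]:
    """Fit every non-empty subset of areas; flag the lowest BIC."""
    if areas is None:
        areas = list(design.areas)
    if not areas:
        raise ValueError("need at least one area")
    results = []
    for r in range(1, len(areas) + 1):
        for subset in combinations(areas, r):
            results.append(fit_model(design, subset))
    best = int(np.argmin([m.bic for m in results]))
    results[best].best_bic = True
    return results


def results_table(results: list[RegressionResult]) -> pd.DataFrame:
    """Wide summary of enumerated models (one row per subset)."""
    areas = sorted({a for m in results for a in m.areas})
    rows = []
    for m in results:
        row = {"model": "&".join(m.areas), "R2": m.r2, "BIC": m.bic,
               "best": m.best_bic}
        for a in areas:
            row[f"beta_{a}"] = m.beta_of(a) if a in m.areas else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Time-resolved fits
# ---------------------------------------------------------------------------

def _window_topographies(
    evoked: EvokedSet,
    layout: ElectrodeLayout,
    center_ms: float,
    win_ms: float,
) -> np.ndarray:
    lo = (center_ms - win_ms / 2.0) / 1000.0
    hi = (center_ms + win_ms / 2.0) / 1000.0
    sel = (evoked.times >= lo - 1e-9) & (evoked.times <= hi + 1e-9)
    if not np.any(sel):
        raise ValueError("measurement window outside the epoch")
    return evoked.data[:, :, sel].mean(axis=2)


def time_resolved_fit(
    evoked: EvokedSet,
    preds: list[TopographySet],
    layout: ElectrodeLayout,
    win_ms: float = 10.0,
    step_ms: float = 5.0,
    time_range_ms: tuple[float, float] = (-100.0, 400.0),
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = 0,
    models: list[tuple[str, ...]] | None = None,
) -> TimecourseFit:
    """Sliding-window area regressions with bootstrap standard errors.

    Every ``step_ms`` a ``win_ms`` window of the evoked response is
    collapsed to a topography set, stacked and regressed on the
    predictions (single-area models and the full model by default).
    The outcome is z-scored with the mean/SD pooled over all windows,
    so beta amplitudes are comparable across time.  Bootstrap SEs
    resample the stacked observations with replacement (implemented as
    multinomial row weights).
    """
    if step_ms > win_ms:
        import warnings

        warnings.warn("step larger than window: time courses have gaps")
    rng = np.random.default_rng(seed)
    labels = [p.label for p in preds]
    if models is None:
        models = [(a,) for a in labels] + [tuple(labels)]
    centers = np.arange(
        time_range_ms[0], time_range_ms[1] + 1e-9, step_ms
    )
    # pool outcome scaling over the whole epoch
    all_topos = [
        _window_topographies(evoked, layout, c, win_ms) for c in centers
    ]
    pooled = np.concatenate([t.ravel() for t in all_topos])
    y_mean, y_sd = pooled.mean(), pooled.std()
    if y_sd == 0:
        y_sd = 1.0
    Xz, _, _ = _zscore_cols(np.column_stack([p.stacked() for p in preds]))
    n = Xz.shape[0]
    results, boots = [], []
    for topo in all_topos:
        y = (topo.ravel() - y_mean) / y_sd
        res_here: dict[tuple[str, ...], RegressionResult] = {}
        se_here: dict[tuple[str, ...], np.ndarray] = {}
        for model in models:
            idx = [labels.index(a) for a in model]
            X = Xz[:, idx]
            beta, rss = _ols(y, X)
            tss = float(y @ y)
            r2 = 1.0 - rss / tss if tss > 0 else 0.0
            bic = n * np.log(max(rss, 1e-300) / n) + len(model) * np.log(n)
            res_here[model] = RegressionResult(
                areas=model, beta=beta, r2=r2, bic=float(bic), n=n,
                k=len(model),
            )
            if n_boot > 0:
                w = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)
                xtx = np.einsum("bn,nj,nk->bjk", w, X, X, optimize=True)
                xty = np.einsum("bn,nj,n->bj", w, X, y, optimize=True)
                betas = np.linalg.solve(xtx, xty[..., None])[..., 0]
                se_here[model] = betas.std(axis=0)
            else:
                se_here[model] = np.full(len(model), np.nan)
        results.append(res_here)
        boots.append(se_here)
    return TimecourseFit(centers_ms=centers, results=results, boot_se=boots)


def beta_dominance(
    tc: TimecourseFit,
    model: tuple[str, ...],
    ref: str = "V1",
) -> dict[str, np.ndarray]:
    """|beta_ref| - |beta_other| time courses (plus beta_ref itself).

    Positive values mean the reference area's coefficient dominates in
    magnitude at that window.
    """
    if ref not in model:
        raise ValueError(f"reference area {ref!r} not in model {model}")
    b_ref = tc.beta_timecourse(model, ref)
    out: dict[str, np.ndarray] = {f"beta_{ref}": b_ref}
    for a in model:
        if a == ref:
            continue
        out[a] = np.abs(b_ref) - np.abs(tc.beta_timecourse(model, a))
    return out
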