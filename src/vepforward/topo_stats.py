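"""Topographic correlation statistics and permutation inference.

Empirical and predicted topography sets are compared with Pearson
correlations treating electrodes as observations -- per stimulus wedge
and "stacked" over all wedges into one long vector (16 x 128 = 2048
pairs for the canonical design).  Significance is assessed by shuffling
the wedge labels of the predicted set, either freely over all wedges or
only within visual-field quadrants; the within-quadrant null retains
between-quadrant structure (such as the upper/lower polarity inversion
all three areas share) and therefore isolates the within-quadrant
topography shifts that distinguish V1 from V2/V3.  A centre-of-gravity
laterality index summarises whether a topography's dominant focus sits
ipsilateral (+) or contralateral (-) to the stimulated hemifield.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .geometry_forward import ElectrodeLayout, TopographySet

__all__ = [
    "CorrelationProfile",
    "PermutationNull",
    "LateralityProfile",
    "correlate_sets",
    "permutation_null",
    "null_mean_difference_ci",
    "laterality_index",
]


@dataclass
class CorrelationProfile:
    r_per_wedge: np.ndarray
    r_stacked: float
    n_per_wedge: int
    n_stacked: int


@dataclass
class PermutationNull:
    scheme: str
    n_perm: int
    null: np.ndarray
    observed: float
    p: float


@dataclass
class LateralityProfile:
    values: np.ndarray
    upper_field_polarity: int
    """Sign of the dominant focus for upper-field wedges (-1 means the
    C1-aligned mapping: negative foci dominate the upper field)."""


def _check_compatible(obs: TopographySet, pred: TopographySet) -> None:
    if obs.values.shape != pred.values.shape:
        raise ValueError("topography sets differ in shape")
    if obs.layout is not pred.layout and obs.layout.ids != pred.layout.ids:
        raise ValueError("topography sets use different layouts")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("zero-variance input to correlation")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def correlate_sets(obs: TopographySet, pred: TopographySet) -> CorrelationProfile:
    """Per-wedge and stacked Pearson correlations over electrodes.

    Raises a ``ValueError`` naming the wedge if either set has a
    zero-variance topography there (the correlation is undefined).
    """
    _check_compatible(obs, pred)
    n_w, n_e = obs.values.shape
    r = np.empty(n_w)
    for w in range(n_w):
        try:
            r[w] = _pearson(obs.values[w], pred.values[w])
        except ValueError:
            raise ValueError(f"zero-variance topography at wedge {w}") from None
    r_stacked = _pearson(obs.stacked(), pred.stacked())
    return CorrelationProfile(
        r_per_wedge=r, r_stacked=r_stacked, n_per_wedge=n_e, n_stacked=n_w * n_e
    )


def _quadrant_groups(tset: TopographySet) -> list[np.ndarray]:
    quads = np.array([w.quadrant for w in tset.wedges])
    return [np.flatnonzero(quads == q) for q in np.unique(quads)]


def _stacked_r_for_perms(
    obs: TopographySet, pred: TopographySet, perms: np.ndarray
) -> np.ndarray:
    """Stacked r for many wedge permutations of ``pred`` at once.

    Permuting wedge labels only reorders blocks of the stacked vector,
    leaving its mean and SD unchanged, so the stacked correlation
    reduces to a sum of per-block cross-products: precomputing the
    (wedge x wedge) block cross-product matrix makes each permutation
    O(n_wedges).
    """
    n_w, n_e = obs.values.shape
    n = n_w * n_e
    zo = (obs.stacked() - obs.stacked().mean()) / obs.stacked().std()
    zp = (pred.stacked() - pred.stacked().mean()) / pred.stacked().std()
    zo = zo.reshape(n_w, n_e)
    zp = zp.reshape(n_w, n_e)
    block = zo @ zp.T / n  # block[i, j] = contribution of pred block j at slot i
    rows = np.arange(n_w)
    return block[rows[None, :], perms].sum(axis=1)


def permutation_null(
    obs: TopographySet,
    pred: TopographySet,
    scheme: str = "full",
    n_perm: int = 1_000_000,
    seed: int | np.random.Generator | None = 0,
    exhaustive: bool = False,
) -> PermutationNull:
    """Permutation null distribution of the stacked correlation.

    ``scheme='full'`` shuffles the predicted set's wedge labels freely;
    ``scheme='within_quadrant'`` shuffles independently within each
    quadrant's wedges, preserving between-quadrant structure.  Draws
    are sampled with replacement from the permutation group;
    ``exhaustive=True`` enumerates all within-quadrant permutations
    instead (the group is small: (n/4)!^4).  The two-sided p-value uses
    the add-one correction ``(1 + #{|null| >= |observed|}) / (n + 1)``.
    """
    _check_compatible(obs, pred)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n_w = obs.n_wedges
    if scheme == "full":
        if exhaustive:
            raise ValueError("exhaustive enumeration supported only within quadrants")
        perms = np.argsort(rng.random((n_perm, n_w)), axis=1)
    elif scheme == "within_quadrant":
        groups = _quadrant_groups(pred)
        if exhaustive:
            per_group = [
                np.array(list(itertools.permutations(range(len(g)))))
                for g in groups
            ]
            sizes = [len(p) for p in per_group]
            total = int(np.prod(sizes))
            perms = np.empty((total, n_w), dtype=int)
            grid = np.indices(sizes).reshape(len(groups), -1).T
            for gi, (g, pg) in enumerate(zip(groups, per_group)):
                perms[:, g] = g[pg[grid[:, gi]]]
            n_perm = total
        else:
            perms = np.empty((n_perm, n_w), dtype=int)
            for g in groups:
                local = np.argsort(rng.random((n_perm, len(g))), axis=1)
                perms[:, g] = g[local]
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    null = _stacked_r_for_perms(obs, pred, perms)
    observed = correlate_sets(obs, pred).r_stacked
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(observed))) / (len(null) + 1.0)
    return PermutationNull(
        scheme=scheme, n_perm=len(null), null=null, observed=observed, p=float(p)
    )


def null_mean_difference_ci(
    null_a: np.ndarray,
    null_b: np.ndarray,
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = 0,
) -> tuple[tuple[float, float], float]:
    """Bootstrap CI and p-value for the difference of two null means.

    Nulls centred on negative correlations are sign-flipped first, so
    the difference is taken on the absolute-correlation scale.  The CI
    is the percentile interval of mean differences over paired
    bootstrap resamples of the two null samples; the p-value is the
    two-sided bootstrap tail probability of the difference crossing 0.
    """
    a = np.asarray(null_a, float)
    b = np.asarray(null_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty null distribution")
    if a.mean() < 0:
        a = -a
    if b.mean() < 0:
        b = -b
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, a.size, size=(n_boot, min(a.size, 10_000)))
    ib = rng.integers(0, b.size, size=(n_boot, min(b.size, 10_000)))
    diffs = a[ia].mean(axis=1) - b[ib].mean(axis=1)
    alpha = 1.0 - level
    lo, hi = np.quantile(diffs, [alpha / 2.0, 1.0 - alpha / 2.0])
    p_lo = (1.0 + np.count_nonzero(diffs <= 0)) / (n_boot + 1.0)
    p_hi = (1.0 + np.count_nonzero(diffs >= 0)) / (n_boot + 1.0)
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    return (float(lo), float(hi)), float(p)


def laterality_index(
    tset: TopographySet, layout: ElectrodeLayout | None = None
) -> LateralityProfile:
    """Centre-of-gravity laterality of the dominant topographic focus.

    The field-to-polarity mapping is determined from the data: the sign
    of the largest-|value| electrode of the mean upper-field topography
    gives the dominant polarity of upper-field wedges (lower-field
    wedges take the opposite).  Per wedge, the index is the amplitude-
    weighted mean lateral coordinate of all electrodes carrying the
    dominant polarity, sign-flipped per hemifield so that +1 means all
    dominant amplitude on the most lateral ipsilateral electrode and
    -1 the contralateral mirror.  The index is scale invariant.
    """
    if layout is None:
        layout = tset.layout
    upper = np.array([w.upper_field for w in tset.wedges])
    mean_upper = tset.values[upper].mean(axis=0)
    dom = int(np.sign(mean_upper[np.argmax(np.abs(mean_upper))]))
    if dom == 0:
        raise ValueError("cannot determine dominant polarity (flat topography)")
    values = np.empty(tset.n_wedges)
    for i, w in enumerate(tset.wedges):
        polarity = dom if w.upper_field else -dom
        v = tset.values[i]
        mask = np.sign(v) == polarity
        if not np.any(mask):
            raise ValueError(
                f"no electrode of dominant polarity for wedge {w.index}"
            )
        weights = np.abs(v[mask])
        cog = float(np.sum(weights * layout.lateral_coord[mask]) / weights.sum())
        ipsi_sign = 1.0 if w.hemifield == "right" else -1.0
        values[i] = ipsi_sign * cog
    return LateralityProfile(values=values, upper_field_polarity=dom)
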