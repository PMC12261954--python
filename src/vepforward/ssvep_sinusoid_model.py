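"""Phasor arithmetic and the shared-lag sinusoidal SSVEP model.

Oscillations reaching one electrode from cortical areas of opposing
surface orientation sum as phasors.  For equal amplitudes the sum obeys

    cos(w t + pi) + cos(w t - w d) = 2 cos((pi + w d)/2) cos(w t + (pi - w d)/2)

so a small cortical delay ``d`` between polarity-opposed sources
produces a near-orthogonal (about 90 degree) phase shift of the scalp
signal.  With unequal amplitudes the resultant phase slides between
the constituent phases, and it does so more abruptly (as a function of
the amplitude ratio) the closer the phase delay is to 180 degrees --
hence more abruptly at low flicker frequencies for a fixed time delay.

The regression model makes this quantitative: each observed SSVEP
coefficient is expanded into a single-cycle cosine snippet, snippets
of both flicker frequencies are stacked into one outcome vector, and
each visual area contributes one regressor per frequency built from
its predicted topography amplitudes and a cosine time course at an
assumed baseline phase (per frequency) and time lag (per area, shared
across frequencies, V1 fixed at lag 0).  A grid over the two baseline
phases and the V2/V3 lags (within half a slow cycle, +/-66 ms) is
scanned by OLS; only parameterisations where all fitted area
magnitudes are positive are admissible (phase flips make the sign
redundant), and the best admissible R^2 wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry_forward import TopographySet
from .vep_derivation import ComplexSpectrumSet

__all__ = [
    "PhasorSum",
    "SinusoidDesign",
    "LagGridResult",
    "sum_opposed_sinusoids",
    "phase_shift_sweep",
    "build_sinusoid_design",
    "fit_lag_grid",
    "wedge_axial_phase",
]


@dataclass
class PhasorSum:
    """Sum of two opposed sinusoids ``w1*cos(wt+pi) + w2*cos(wt-w*d)``."""

    w1: float
    w2: float
    delay: float
    omega: float
    amplitude: float
    phase: float


def sum_opposed_sinusoids(
    w1: float,
    w2: float,
    delay: float,
    omega: float,
    t_grid: np.ndarray | None = None,
) -> tuple[PhasorSum, np.ndarray | None]:
    """Phasor sum of two polarity-opposed, time-lagged oscillations.

    The first oscillation is polarity-inverted (phase pi), the second
    delayed by ``delay`` seconds.  Returns the resultant amplitude and
    phase from complex addition, plus the summed waveform on
    ``t_grid`` when given.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    z = w1 * np.exp(1j * np.pi) + w2 * np.exp(-1j * omega * delay)
    amp, ph = float(np.abs(z)), float(np.angle(z))
    wave = None
    if t_grid is not None:
        t = np.asarray(t_grid, float)
        wave = w1 * np.cos(omega * t + np.pi) + w2 * np.cos(
            omega * (t - delay)
        )
    return PhasorSum(w1, w2, delay, omega, amp, ph), wave


def phase_shift_sweep(
    weight_ratios: np.ndarray,
    delays: np.ndarray,
    frequencies: np.ndarray,
) -> np.ndarray:
    """Resultant phase across relative weights, delays and frequencies.

    Returns an array of shape ``(n_ratios, n_delays, n_freqs)`` with
    the phase (radians) of ``rho*cos(wt+pi) + cos(wt - w*d)`` where
    ``rho`` is the weight of the polarity-inverted constituent.  As
    ``rho`` runs from 0 to infinity the phase moves monotonically from
    the delayed constituent's phase to pi.
    """
    ratios = np.asarray(weight_ratios, float)
    if np.any(ratios <= 0):
        raise ValueError("weight ratios must be positive")
    d = np.asarray(delays, float)
    f = np.asarray(frequencies, float)
    omega = 2.0 * np.pi * f
    z = (
        ratios[:, None, None] * np.exp(1j * np.pi)
        + np.exp(-1j * omega[None, None, :] * d[None, :, None])
    )
    return np.angle(z)


# ---------------------------------------------------------------------------
# Sinusoidal regression design
# ---------------------------------------------------------------------------

@dataclass
class SinusoidDesign:
    """Stacked single-cycle design for both SSVEP frequencies.

    ``y`` and ``X`` are z-scored; ``columns`` names each regressor as
    ``(area, frequency)``.  Rows for one frequency carry zeros in the
    other frequency's raw regressors (before z-scoring).
    """

    y: np.ndarray
    X: np.ndarray
    columns: list[tuple[str, float]]
    freq_of_row: np.ndarray
    wedge_of_row: np.ndarray
    electrode_of_row: np.ndarray
    sample_of_row: np.ndarray
    row_fraction: dict[float, float]


def _cycle_samples(fs: float, f: float) -> int:
    return int(round(fs / f))


def _single_cycle_outcome(
    spec: ComplexSpectrumSet, fs: float
) -> tuple[np.ndarray, int]:
    """Reconstruct |z|cos(2*pi*f*t + arg z) over one cycle per
    wedge/electrode; returns (n_wedges*n_electrodes*n_t,) and n_t."""
    n_t = _cycle_samples(fs, spec.frequency)
    t = np.arange(n_t) / fs
    phase = 2.0 * np.pi * spec.frequency * t
    # (w, e, t)
    out = np.abs(spec.values)[:, :, None] * np.cos(
        phase[None, None, :] + np.angle(spec.values)[:, :, None]
    )
    return out.ravel(), n_t


def build_sinusoid_design(
    spectra: dict[float, ComplexSpectrumSet],
    preds: list[TopographySet],
    fs: float = 512.0,
    baseline_phases: dict[float, float] | None = None,
    lags_s: dict[str, float] | None = None,
) -> SinusoidDesign:
    """Materialise the stacked design for one parameter instantiation.

    Mostly a reference implementation: :func:`fit_lag_grid` evaluates
    the same model over whole parameter grids without rebuilding the
    matrix.  ``lags_s`` maps area labels to lags in seconds (missing
    areas, canonically V1, lag 0).
    """
    baseline_phases = baseline_phases or {f: 0.0 for f in spectra}
    lags_s = lags_s or {}
    freqs = sorted(spectra)
    for p in preds[1:]:
        if p.values.shape != preds[0].values.shape:
            raise ValueError("prediction sets differ in shape")
    if any(
        s.values.shape != preds[0].values.shape for s in spectra.values()
    ):
        raise ValueError("spectra and predictions differ in layout/wedges")
    y_parts, rows_f, rows_w, rows_e, rows_t = [], [], [], [], []
    for f in freqs:
        spec = spectra[f]
        y_f, n_t = _single_cycle_outcome(spec, fs)
        n_w, n_e = spec.values.shape
        y_parts.append(y_f)
        rows_f.append(np.full(y_f.size, f))
        rows_w.append(np.repeat(np.arange(n_w), n_e * n_t))
        rows_e.append(np.tile(np.repeat(np.arange(n_e), n_t), n_w))
        rows_t.append(np.tile(np.arange(n_t), n_w * n_e))
    y = np.concatenate(y_parts)
    freq_of_row = np.concatenate(rows_f)
    columns, X_cols = [], []
    for area_set in preds:
        for f in freqs:
            lag = lags_s.get(area_set.label, 0.0)
            phi = baseline_phases[f]
            col = np.zeros(y.size)
            sel = freq_of_row == f
            n_t = _cycle_samples(fs, f)
            t = np.arange(n_t) / fs
            snippet = np.cos(2.0 * np.pi * f * (t - lag) + phi)
            amp = area_set.values  # (n_w, n_e)
            col[sel] = (amp[:, :, None] * snippet[None, None, :]).ravel()
            columns.append((area_set.label, f))
            X_cols.append(col)
    X = np.column_stack(X_cols)
    sd_y = y.std()
    if sd_y == 0:
        raise ValueError("all-zero outcome")
    yz = (y - y.mean()) / sd_y
    mx, sx = X.mean(axis=0), X.std(axis=0)
    if np.any(sx == 0):
        raise ValueError("zero-variance regressor column")
    Xz = (X - mx) / sx
    counts = {f: float(np.mean(freq_of_row == f)) for f in freqs}
    return SinusoidDesign(
        y=yz,
        X=Xz,
        columns=columns,
        freq_of_row=freq_of_row,
        wedge_of_row=np.concatenate(rows_w),
        electrode_of_row=np.concatenate(rows_e),
        sample_of_row=np.concatenate(rows_t),
        row_fraction=counts,
    )


# ---------------------------------------------------------------------------
# Lag-grid fitting
# ---------------------------------------------------------------------------

@dataclass
class LagGridResult:
    """Scanned grid of shared-lag sinusoidal models.

    ``entries`` holds one row per grid point: phases (rad) per
    frequency, lags (s) for the non-reference areas, overall and
    per-frequency R^2, fitted magnitudes, and the admissibility flag
    (all magnitudes positive).  ``best`` indexes the admissible
    maximum-R^2 entry.
    """

    phases: np.ndarray      # (n_points, n_freqs)
    lags: np.ndarray        # (n_points, n_lagged_areas)
    r2: np.ndarray          # (n_points,)
    r2_per_freq: np.ndarray  # (n_points, n_freqs)
    magnitudes: np.ndarray  # (n_points, n_areas * n_freqs)
    admissible: np.ndarray  # bool
    best: int
    freqs: list[float]
    lagged_areas: list[str]
    columns: list[tuple[str, float]]

    @property
    def best_lags_ms(self) -> dict[str, float]:
        return {
            a: 1000.0 * float(self.lags[self.best, i])
            for i, a in enumerate(self.lagged_areas)
        }

    def top_fraction(self, frac: float = 0.01) -> np.ndarray:
        """Indices of the best ``frac`` admissible grid points."""
        adm = np.flatnonzero(self.admissible)
        k = max(int(np.ceil(frac * adm.size)), 1)
        order = adm[np.argsort(self.r2[adm])[::-1]]
        return order[:k]


class _GridEngine:
    """Precomputed cosine/sine basis moments for fast grid scanning.

    Every regressor column is a linear combination of 2 fixed basis
    columns (cosine and sine snippets scaled by the area topography),
    so each grid point's z-scored normal equations follow from one
    12x12 Gram matrix by trigonometric reparameterisation -- no design
    matrix is ever rebuilt.
    """

    def __init__(self, spectra, preds, fs):
        self.freqs = sorted(spectra)
        self.areas = [p.label for p in preds]
        self.fs = fs
        y_parts, freq_rows = [], []
        for f in self.freqs:
            y_f, _ = _single_cycle_outcome(spectra[f], fs)
            y_parts.append(y_f)
            freq_rows.append(np.full(y_f.size, f))
        y = np.concatenate(y_parts)
        self.freq_of_row = np.concatenate(freq_rows)
        self.n = y.size
        sd = y.std()
        if sd == 0:
            raise ValueError("all-zero outcome")
        self.yz = (y - y.mean()) / sd
        # basis: for each (area, freq): cos column and sin column
        self.pairs = [(a, f) for a in self.areas for f in self.freqs]
        B = np.zeros((self.n, 2 * len(self.pairs)))
        for i, (a, f) in enumerate(self.pairs):
            sel = self.freq_of_row == f
            n_t = _cycle_samples(fs, f)
            t = np.arange(n_t) / fs
            amp = preds[self.areas.index(a)].values
            c = (amp[:, :, None] * np.cos(2 * np.pi * f * t)[None, None, :]).ravel()
            s = (amp[:, :, None] * np.sin(2 * np.pi * f * t)[None, None, :]).ravel()
            B[sel, 2 * i] = c
            B[sel, 2 * i + 1] = s
        self.G = B.T @ B
        self.gy = B.T @ self.yz
        self.colsum = B.sum(axis=0)
        # per-frequency restrictions
        self.block = {}
        for f in self.freqs:
            sel = self.freq_of_row == f
            self.block[f] = dict(
                n=int(sel.sum()),
                yy=float(self.yz[sel] @ self.yz[sel]),
                sy=float(self.yz[sel].sum()),
                in_block=np.array([pf == f for (_, pf) in self.pairs]),
            )

    def _transforms(self, psis: np.ndarray) -> np.ndarray:
        """(n_points, n_cols, n_basis) transform matrices from the
        per-column phase offsets ``psis`` (n_points, n_cols)."""
        npnt, ncol = psis.shape
        T = np.zeros((npnt, ncol, 2 * ncol))
        idx = np.arange(ncol)
        T[:, idx, 2 * idx] = np.cos(psis)
        T[:, idx, 2 * idx + 1] = -np.sin(psis)
        return T

    def fit(self, psis: np.ndarray):
        """Batch OLS over phase-offset matrices.

        ``psis[p, j]`` is the total phase offset of column ``j`` (pair
        ``self.pairs[j]``) at grid point ``p``.  Returns betas (z
        units), overall R^2 and per-frequency R^2.
        """
        n = self.n
        T = self._transforms(psis)
        raw_gram = np.einsum("pij,jk,plk->pil", T, self.G, T, optimize=True)
        sums = np.einsum("pij,j->pi", T, self.colsum)
        means = sums / n
        gram_c = raw_gram - n * means[:, :, None] * means[:, None, :]
        sd = np.sqrt(np.clip(np.einsum("pii->pi", gram_c) / n, 1e-300, None))
        gram_z = gram_c / (n * sd[:, :, None] * sd[:, None, :])
        xty_raw = np.einsum("pij,j->pi", T, self.gy)
        xty_z = xty_raw / (n * sd)
        beta = np.linalg.solve(gram_z, xty_z[..., None])[..., 0]
        explained = np.einsum("pi,pi->p", beta, xty_z)
        r2 = explained  # yz'yz/n = 1
        # per-frequency decomposition
        r2_f = np.zeros((len(psis), len(self.freqs)))
        for fi, f in enumerate(self.freqs):
            blk = self.block[f]
            nb, yy, sy = blk["n"], blk["yy"], blk["sy"]
            inb = blk["in_block"]
            mask = np.zeros((len(self.pairs), len(self.pairs)))
            mask[np.ix_(inb, inb)] = 1.0
            raw_gram_f = np.einsum(
                "pij,jk,plk->pil", T, self.G * np.kron(mask, np.ones((2, 2))),
                T, optimize=True,
            )
            sums_f = np.where(inb[None, :], sums, 0.0)
            gram_b = (
                raw_gram_f
                - sums_f[:, :, None] * means[:, None, :]
                - means[:, :, None] * sums_f[:, None, :]
                + nb * means[:, :, None] * means[:, None, :]
            ) / (sd[:, :, None] * sd[:, None, :])
            xty_b = (
                np.where(inb[None, :], xty_raw, 0.0) - means * sy
            ) / sd
            rss_f = (
                yy
                - 2.0 * np.einsum("pi,pi->p", beta, xty_b)
                + np.einsum("pi,pij,pj->p", beta, gram_b, beta)
            )
            r2_f[:, fi] = 1.0 - rss_f / yy
        return beta, r2, r2_f

    def psis_for(self, phases: np.ndarray, lags: np.ndarray,
                 lagged_areas: list[str]) -> np.ndarray:
        """Column phase offsets from grid parameters.

        ``phases``: (n_points, n_freqs) baseline phase per frequency;
        ``lags``: (n_points, n_lagged) lag (s) per non-reference area.
        The offset of column (a, f) is ``phi_f - 2*pi*f*lag_a``.
        """
        npnt = phases.shape[0]
        psis = np.zeros((npnt, len(self.pairs)))
        for j, (a, f) in enumerate(self.pairs):
            fi = self.freqs.index(f)
            lag = (
                lags[:, lagged_areas.index(a)]
                if a in lagged_areas
                else np.zeros(npnt)
            )
            psis[:, j] = phases[:, fi] - 2.0 * np.pi * f * lag
        return psis


def fit_lag_grid(
    spectra: dict[float, ComplexSpectrumSet],
    preds: list[TopographySet],
    fs: float = 512.0,
    reference_area: str = "V1",
    lag_range_s: float = 0.066,
    coarse_lag_step_s: float = 0.004,
    coarse_phases_per_cycle: int = 8,
    refine: bool = True,
    n_refine_basins: int = 8,
    exhaustive: bool = False,
) -> LagGridResult:
    """Grid search of the shared-lag sinusoidal model.

    Scans baseline phases (one per flicker frequency, spanning a full
    cycle) and time lags for the non-reference areas (V2, V3) in
    ``+/-lag_range_s``, fitting the stacked two-frequency regression
    at every point.  The default is a coarse scan (4 ms lags, 8 phases
    per cycle) followed by local refinement at the sample period and
    one phase sample; ``exhaustive=True`` scans the full-resolution
    grid directly (slow).  Grid points where any fitted magnitude is
    non-positive are inadmissible; the best admissible R^2 wins.
    """
    engine = _GridEngine(spectra, preds, fs)
    freqs = engine.freqs
    lagged = [a for a in engine.areas if a != reference_area]
    if not lagged and len(engine.areas) < 1:
        raise ValueError("need at least one area")

    def scan(phase_axes, lag_axes):
        mesh = np.meshgrid(*phase_axes, *lag_axes, indexing="ij")
        flat = [m.ravel() for m in mesh]
        phases = np.column_stack(flat[: len(freqs)])
        lags = (
            np.column_stack(flat[len(freqs):])
            if lagged
            else np.zeros((len(flat[0]), 0))
        )
        psis = engine.psis_for(phases, lags, lagged)
        # batch in chunks to bound memory
        betas, r2s, r2fs = [], [], []
        for i in range(0, len(psis), 4096):
            b, r, rf = engine.fit(psis[i : i + 4096])
            betas.append(b)
            r2s.append(r)
            r2fs.append(rf)
        return (
            phases,
            lags,
            np.concatenate(betas),
            np.concatenate(r2s),
            np.concatenate(r2fs),
        )

    def phase_axis(f, step=None, center=None, span=None):
        full_step = 2.0 * np.pi / _cycle_samples(fs, f)
        step = step if step is not None else full_step
        if center is None:
            return np.arange(0.0, 2.0 * np.pi, step)
        return center + np.arange(-span, span + step / 2, step)

    lag_step_fine = 1.0 / fs
    if exhaustive:
        phase_axes = [phase_axis(f) for f in freqs]
        lag_axis = np.arange(-lag_range_s, lag_range_s + 1e-12, lag_step_fine)
        lag_axes = [lag_axis] * len(lagged)
        phases, lags, beta, r2, r2f = scan(phase_axes, lag_axes)
    else:
        phase_axes = [
            phase_axis(f, step=2.0 * np.pi / coarse_phases_per_cycle)
            for f in freqs
        ]
        lag_axis = np.arange(
            -lag_range_s, lag_range_s + 1e-12, coarse_lag_step_s
        )
        lag_axes = [lag_axis] * len(lagged)
        phases, lags, beta, r2, r2f = scan(phase_axes, lag_axes)
        if refine:
            adm = np.all(beta > 0, axis=1)
            cand = np.flatnonzero(adm) if np.any(adm) else np.arange(len(r2))
            # refine the best few distinct lag basins, not just the single
            # best point: at low SNR a half-period alias of the faster
            # frequency can top the coarse scan while the true basin wins
            # at full resolution
            order = cand[np.argsort(r2[cand])[::-1]]
            basins: list[int] = []
            seen: set[tuple] = set()
            for i in order:
                key = tuple(np.round(lags[i] / coarse_lag_step_s).astype(int))
                if key in seen:
                    continue
                seen.add(key)
                basins.append(int(i))
                if len(basins) >= n_refine_basins:
                    break
            for i0 in basins:
                phase_axes = [
                    phase_axis(
                        f,
                        center=phases[i0, fi],
                        span=2.0 * np.pi / coarse_phases_per_cycle,
                    )
                    for fi, f in enumerate(freqs)
                ]
                lag_axes = [
                    np.unique(
                        np.clip(
                            lags[i0, li]
                            + np.arange(
                                -coarse_lag_step_s * 1.5,
                                coarse_lag_step_s * 1.5 + 1e-12,
                                lag_step_fine,
                            ),
                            -lag_range_s,
                            lag_range_s,
                        )
                    )
                    for li in range(len(lagged))
                ]
                ph2, lg2, b2, r2_2, r2f2 = scan(phase_axes, lag_axes)
                phases = np.vstack([phases, ph2])
                lags = np.vstack([lags, lg2])
                beta = np.vstack([beta, b2])
                r2 = np.concatenate([r2, r2_2])
                r2f = np.vstack([r2f, r2f2])

    admissible = np.all(beta > 0, axis=1)
    if not np.any(admissible):
        raise ValueError("no admissible model (all grids have non-positive magnitudes)")
    cand = np.flatnonzero(admissible)
    best = int(cand[np.argmax(r2[cand])])
    return LagGridResult(
        phases=phases,
        lags=lags,
        r2=r2,
        r2_per_freq=r2f,
        magnitudes=beta,
        admissible=admissible,
        best=best,
        freqs=freqs,
        lagged_areas=lagged,
        columns=engine.pairs,
    )


# ---------------------------------------------------------------------------
# Phase summaries
# ---------------------------------------------------------------------------

def wedge_axial_phase(spec: ComplexSpectrumSet) -> np.ndarray:
    """Magnitude-weighted axial mean phase per wedge, in [0, pi).

    Topographies contain antiphase foci (the two poles of a dipolar
    pattern), so ordinary circular means cancel; doubling the angles
    first treats opposite phases as identical (axial statistics).
    """
    z = spec.values
    doubled = np.sum(np.abs(z) ** 2 * np.exp(2j * np.angle(z)), axis=1)
    return (np.angle(doubled) / 2.0) % np.pi
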