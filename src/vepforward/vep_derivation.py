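"""Deriving the four VEP signals from conditioned recordings.

* Transient and multifocal evoked responses: stimulus-locked epochs
  (-100 to 400 ms) averaged per wedge; C1 topographies as the 70-80 ms
  window mean.  Multifocal waveforms can equivalently be estimated by
  regressing the continuous data against the lagged stimulus pulse
  design (the two methods agree almost perfectly on overlapping pulse
  streams with realistic noise).
* Steady-state responses: per-trial 4-s epochs (after discarding the
  first 500 ms of each flicker train) are Fourier-transformed and the
  complex coefficient at the flicker frequency is retained and
  averaged *as a complex number* across epochs, preserving phase so
  that polarity-opposed oscillations cancel rather than add.

Because steady-state topographies live in the complex plane, a signed
scalar amplitude per electrode is obtained by projecting every
coefficient onto the "principal phase axis" -- the line through the
origin that the coefficients of all electrodes and wedges best align
to -- with the sign convention anchored to the C1: upper-field wedges
near the horizontal meridian get negative dominant foci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix

from .geometry_forward import ElectrodeLayout, TopographySet, WedgeSpec
from .preprocessing import ContinuousRecording
from .stimulus_protocols import PulseStreamSet

__all__ = [
    "EvokedSet",
    "ComplexSpectrumSet",
    "PhaseAxis",
    "epoch_average",
    "c1_topography",
    "mfvep_deconvolve",
    "ssvep_spectrum",
    "spectrum_from_epochs",
    "principal_phase_axis",
    "project_phase",
]


@dataclass
class EvokedSet:
    """Per-wedge evoked waveforms on a common time axis.

    ``data`` is (n_wedges, n_channels, n_times) in microvolts; ``times``
    in seconds relative to stimulus onset.
    """

    data: np.ndarray
    times: np.ndarray
    sample_rate: float
    n_trials: np.ndarray
    wedges: list[WedgeSpec] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.times = np.asarray(self.times, float)
        if self.data.shape[2] != len(self.times):
            raise ValueError("data/time axis mismatch")

    @property
    def n_wedges(self) -> int:
        return self.data.shape[0]


@dataclass
class ComplexSpectrumSet:
    """Complex Fourier coefficient per wedge and electrode at one
    flicker frequency.

    The convention is amplitude-calibrated: an input
    ``A*cos(2*pi*f*t + phi)`` yields the coefficient ``A*exp(i*phi)``.
    """

    frequency: float
    values: np.ndarray  # (n_wedges, n_electrodes) complex
    layout: ElectrodeLayout | None = None
    wedges: list[WedgeSpec] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, complex)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")


@dataclass(frozen=True)
class PhaseAxis:
    """Orientation of the principal phase axis in the complex plane.

    ``theta`` is in [0, pi); ``polarity_sign`` fixes which end of the
    axis is treated as negative (C1-anchored convention).
    """

    theta: float
    polarity_sign: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta < np.pi:
            raise ValueError("theta must lie in [0, pi)")
        if self.polarity_sign not in (-1, 1):
            raise ValueError("polarity_sign must be +/-1")


# ---------------------------------------------------------------------------
# Epoch averaging
# ---------------------------------------------------------------------------

def epoch_average(
    rec: ContinuousRecording,
    events: list[tuple[str, int, int]] | None = None,
    window_ms: tuple[float, float] = (-100.0, 400.0),
    n_wedges: int = 16,
    wedges: list[WedgeSpec] | None = None,
) -> EvokedSet:
    """Stimulus-locked epoch average per wedge.

    Epochs extending past the recording edges are dropped.  Raises if
    any wedge retains zero trials.
    """
    if events is None:
        events = rec.events
    fs = rec.sample_rate
    lo = int(round(window_ms[0] / 1000.0 * fs))
    hi = int(round(window_ms[1] / 1000.0 * fs))
    n_t = hi - lo + 1
    times = (np.arange(lo, hi + 1)) / fs
    sums = np.zeros((n_wedges, rec.n_channels, n_t))
    counts = np.zeros(n_wedges, dtype=int)
    for _, s, w in events:
        a, b = s + lo, s + hi + 1
        if a < 0 or b > rec.n_samples:
            continue
        sums[w] += rec.data[:, a:b]
        counts[w] += 1
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"no surviving trials for wedge {int(empty[0])}")
    data = sums / counts[:, None, None]
    return EvokedSet(
        data=data, times=times, sample_rate=fs, n_trials=counts, wedges=wedges
    )


def grand_average(evoked_sets: list[EvokedSet]) -> EvokedSet:
    """Unweighted mean of subject-level evoked sets."""
    first = evoked_sets[0]
    data = np.mean([e.data for e in evoked_sets], axis=0)
    return EvokedSet(
        data=data,
        times=first.times,
        sample_rate=first.sample_rate,
        n_trials=np.sum([e.n_trials for e in evoked_sets], axis=0),
        wedges=first.wedges,
    )


def c1_topography(
    evoked: EvokedSet,
    layout: ElectrodeLayout,
    window_ms: tuple[float, float] = (70.0, 80.0),
    label: str = "C1",
) -> TopographySet:
    """Mean topography over the C1 time window per wedge."""
    lo, hi = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    if lo < evoked.times[0] or hi > evoked.times[-1]:
        raise ValueError("C1 window outside the epoch")
    sel = (evoked.times >= lo - 1e-9) & (evoked.times <= hi + 1e-9)
    values = evoked.data[:, :, sel].mean(axis=2)
    wedges = evoked.wedges
    if wedges is None:
        from .geometry_forward import build_wedge_set

        wedges = build_wedge_set(evoked.n_wedges)
    return TopographySet(label=label, values=values, layout=layout, wedges=wedges)


# ---------------------------------------------------------------------------
# Multifocal deconvolution
# ---------------------------------------------------------------------------

def _stream_onset_samples(
    rec: ContinuousRecording, streams: PulseStreamSet
) -> list[np.ndarray]:
    """Pulse onset samples per stream.

    Prefers the recording's embedded ``'pulse'`` events (which carry
    the true alignment of the pulse trains within the recording);
    falls back to converting frame indices at the recording's sample
    rate, assuming the first frame is sample 0.
    """
    pulses = [
        (s, w) for (t, s, w) in rec.events if t == "pulse"
    ]
    if pulses:
        out = []
        for k in range(streams.n_streams):
            out.append(np.sort([s for s, w in pulses if w == k]).astype(int))
        if all(len(o) for o in out):
            return out
    return [
        np.round(o / streams.frame_rate * rec.sample_rate).astype(int)
        for o in streams.onsets
    ]


def mfvep_deconvolve(
    rec: ContinuousRecording,
    streams: PulseStreamSet,
    window_ms: tuple[float, float] = (-100.0, 400.0),
    method: str = "average",
    lag_step_samples: float = 1.0,
) -> EvokedSet:
    """Multifocal waveforms by epoch averaging or pulse-matrix regression.

    ``method='average'`` epoch-averages at each stream's pulse onsets
    (overlap from concurrent streams remains in the average as noise).
    ``method='regression'`` solves the full least-squares deconvolution
    of the continuous data against the lagged pulse design -- one
    indicator column per stream and lag -- which unmixes overlapping
    responses exactly when the design has full rank.  The lag grid
    defaults to every sample; ``lag_step_samples`` can coarsen it (the
    natural choice is the stimulus frame period, since pulse timing
    carries no sub-frame information), in which case waveforms are
    interpolated back onto the sample grid.
    """
    fs = rec.sample_rate
    onset_samples = _stream_onset_samples(rec, streams)
    if method == "average":
        events = [
            ("pulse", int(s), k)
            for k, ons in enumerate(onset_samples)
            for s in ons
        ]
        return epoch_average(
            rec, events, window_ms=window_ms, n_wedges=streams.n_streams
        )
    if method != "regression":
        raise ValueError(f"unknown method {method!r}")
    lo = int(round(window_ms[0] / 1000.0 * fs))
    hi = int(round(window_ms[1] / 1000.0 * fs))
    step = float(lag_step_samples)
    if step < 1.0:
        raise ValueError("lag_step_samples must be >= 1")
    m_lo = int(np.floor(lo / step))
    m_hi = int(np.ceil(hi / step))
    lags = np.unique(np.round(np.arange(m_lo, m_hi + 1) * step).astype(int))
    n_lag = len(lags)
    n_streams = streams.n_streams
    n_cols = n_streams * n_lag
    rows, cols = [], []
    for k, ons in enumerate(onset_samples):
        for li, lag in enumerate(lags):
            r = ons + lag
            valid = r[(r >= 0) & (r < rec.n_samples)]
            rows.append(valid)
            cols.append(np.full(len(valid), k * n_lag + li))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    X = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(rec.n_samples, n_cols)
    )
    gram = (X.T @ X).toarray()
    xty = X.T @ rec.data.T  # (n_cols, n_channels)
    try:
        from scipy.linalg import cho_factor, cho_solve

        c = cho_factor(gram)
        beta = cho_solve(c, xty)
    except np.linalg.LinAlgError:
        raise ValueError("singular pulse design: streams are degenerate")
    except Exception as err:  # scipy raises its own LinAlgError subclass
        if "positive definite" in str(err) or "singular" in str(err).lower():
            raise ValueError(
                "singular pulse design: streams are degenerate"
            ) from None
        raise
    kern = beta.T.reshape(rec.n_channels, n_streams, n_lag).transpose(1, 0, 2)
    sample_lags = np.arange(lo, hi + 1)
    if n_lag == len(sample_lags) and np.array_equal(lags, sample_lags):
        data = kern
    else:
        data = np.empty((n_streams, rec.n_channels, len(sample_lags)))
        for w in range(n_streams):
            for ch in range(rec.n_channels):
                data[w, ch] = np.interp(sample_lags, lags, kern[w, ch])
    times = sample_lags / fs
    counts = np.array([len(o) for o in onset_samples])
    return EvokedSet(
        data=data, times=times, sample_rate=fs, n_trials=counts
    )


# ---------------------------------------------------------------------------
# Steady-state spectra
# ---------------------------------------------------------------------------

def spectrum_from_epochs(
    epochs: np.ndarray, sample_rate: float, frequency: float
) -> np.ndarray:
    """Amplitude-calibrated DFT coefficient at ``frequency``.

    ``epochs`` is (..., n_samples); the frequency must fall on an
    exact DFT bin (integer number of cycles in the epoch), making the
    estimate leakage-free without tapering.  Returns complex values of
    shape ``epochs.shape[:-1]`` where a pure ``A*cos(2*pi*f*t + phi)``
    maps to ``A*exp(i*phi)``.
    """
    n = epochs.shape[-1]
    k = frequency * n / sample_rate
    if abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"{frequency} Hz is not an integer number of cycles in the epoch"
        )
    k = int(round(k))
    t = np.arange(n)
    kernel = np.exp(-2j * np.pi * k * t / n)
    return (epochs @ kernel) * (2.0 / n)


def ssvep_spectrum(
    rec: ContinuousRecording,
    frequency: float,
    epoch_s: float = 4.0,
    discard_s: float = 0.5,
    layout: ElectrodeLayout | None = None,
    wedges: list[WedgeSpec] | None = None,
    n_wedges: int = 16,
) -> ComplexSpectrumSet:
    """Complex SSVEP spectrum per wedge.

    Events of type ``'flicker'`` mark train onsets (sample, wedge).
    The first ``discard_s`` seconds after each onset are discarded to
    exclude the onset-evoked transient, then one ``epoch_s`` epoch is
    extracted and its DFT coefficient at ``frequency`` retained.
    Coefficients are averaged across epochs as complex numbers.
    """
    fs = rec.sample_rate
    n_ep = int(round(epoch_s * fs))
    skip = int(round(discard_s * fs))
    acc = np.zeros((n_wedges, rec.n_channels), dtype=complex)
    counts = np.zeros(n_wedges, dtype=int)
    accepted = {"flicker", f"flicker@{frequency:g}"}
    for typ, s, w in rec.events:
        if typ not in accepted:
            continue
        a = s + skip
        b = a + n_ep
        if b > rec.n_samples:
            raise ValueError("flicker trial shorter than discard + epoch")
        coefs = spectrum_from_epochs(rec.data[:, a:b], fs, frequency)
        # reference phase to the flicker-train onset, not the epoch start
        coefs *= np.exp(-2j * np.pi * frequency * skip / fs)
        acc[w] += coefs
        counts[w] += 1
    if np.any(counts == 0):
        w0 = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"no flicker epochs for wedge {w0}")
    return ComplexSpectrumSet(
        frequency=frequency,
        values=acc / counts[:, None],
        layout=layout,
        wedges=wedges,
    )


# ---------------------------------------------------------------------------
# Principal phase axis
# ---------------------------------------------------------------------------

def principal_phase_axis(
    spec: ComplexSpectrumSet,
    reference_wedges: list[int] | None = None,
) -> PhaseAxis:
    """Dominant phase orientation of a complex spectrum set.

    The axis is the first eigenvector of the 2x2 second-moment matrix
    of the (Re, Im) pairs stacked over electrodes and wedges -- the
    line through the origin (no centering) best aligned with all
    coefficients.  The polarity sign is chosen so the dominant focus
    of the reference wedges (by default the upper-field wedges nearest
    the horizontal meridian) projects negative, matching the C1.
    """
    z = spec.values.ravel()
    if np.count_nonzero(z) < 2:
        raise ValueError("need at least two non-zero coefficients")
    pts = np.column_stack([z.real, z.imag])
    m = pts.T @ pts
    if not np.any(m):
        raise ValueError("all-zero spectrum")
    evals, evecs = np.linalg.eigh(m)
    v = evecs[:, np.argmax(evals)]
    theta = float(np.arctan2(v[1], v[0])) % np.pi
    axis = PhaseAxis(theta=theta, polarity_sign=1)
    if reference_wedges is None:
        if spec.wedges is None:
            from .geometry_forward import build_wedge_set

            wedges = build_wedge_set(spec.values.shape[0])
        else:
            wedges = spec.wedges
        per_q = len(wedges) // 4
        reference_wedges = [
            w.index for w in wedges if w.upper_field and w.vm_rank == per_q
        ]
    proj = _project_values(spec.values, axis)
    ref_mean = proj[reference_wedges].mean(axis=0)
    dominant = ref_mean[np.argmax(np.abs(ref_mean))]
    sign = -1 if dominant > 0 else 1
    return PhaseAxis(theta=theta, polarity_sign=sign)


def _project_values(values: np.ndarray, axis: PhaseAxis) -> np.ndarray:
    u = np.exp(1j * axis.theta)
    return axis.polarity_sign * (
        values.real * u.real + values.imag * u.imag
    )


def project_phase(
    spec: ComplexSpectrumSet,
    axis: PhaseAxis,
    component: str = "principal",
    label: str | None = None,
) -> TopographySet:
    """Signed scalar projection of each coefficient onto the axis.

    ``component='principal'`` projects along the axis,
    ``'orthogonal'`` along the perpendicular; the two projections
    decompose each coefficient's energy (p^2 + o^2 = |z|^2).
    Flipping ``axis.polarity_sign`` flips both projections jointly and
    therefore cannot alter any downstream correlation magnitude.
    """
    if component == "principal":
        theta = axis.theta
    elif component == "orthogonal":
        theta = axis.theta + np.pi / 2.0
    else:
        raise ValueError(f"unknown component {component!r}")
    rot = PhaseAxis(theta=theta % np.pi, polarity_sign=axis.polarity_sign)
    # keep the relative sign of the two components consistent when the
    # orthogonal angle wraps past pi
    wrap_sign = 1 if theta < np.pi else -1
    values = wrap_sign * _project_values(spec.values, rot)
    if spec.layout is None:
        raise ValueError("spectrum has no layout attached")
    wedges = spec.wedges
    if wedges is None:
        from .geometry_forward import build_wedge_set

        wedges = build_wedge_set(spec.values.shape[0])
    return TopographySet(
        label=label or f"{spec.frequency:g}Hz-{component}",
        values=values,
        layout=spec.layout,
        wedges=wedges,
    )
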