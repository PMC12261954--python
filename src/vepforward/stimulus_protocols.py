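"""Stimulation protocol event structures.

Three protocols drive the four VEP signals:

* **Transient**: isolated 50 ms flashes per wedge, one location at a
  time, separated by 500 ms blank.
* **Multifocal** (mfVEP): all 16 wedges pulse concurrently, each
  following a time-lagged copy of a maximal-length (m-)sequence.
  Pulses occur at off-to-on (-1 -> +1) transitions; to limit the pulse
  rate, three of every four pulses are discarded, leaving 256 pulses
  per location from a 4095-frame order-12 sequence.
* **Steady state** (SSVEP): wedges flicker as square on/off frame
  trains at 18.75 Hz (2 on / 2 off at 75 frames/s) and 7.5 Hz
  (5 on / 5 off).

A raster-scan timing correction accounts for CRT presentation delays
proportional to the stimulus' vertical position on the monitor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PulseStreamSet",
    "FrameTrain",
    "generate_msequence",
    "pulse_streams_from_msequence",
    "ssvep_frame_train",
    "raster_correction",
    "max_pairwise_stream_correlation",
    "write_pulse_streams",
    "read_pulse_streams",
    "DEFAULT_MSEQ_TAPS",
]

#: Feedback taps of the default primitive polynomial for order 12:
#: x^12 + x^6 + x^4 + x + 1.
DEFAULT_MSEQ_TAPS = {12: (12, 6, 4, 1)}


@dataclass
class PulseStreamSet:
    """Frame-indexed stimulus onset trains for multifocal stimulation."""

    frame_rate: float
    n_frames: int
    onsets: list[np.ndarray]  # sorted onset frame indices per stream

    def __post_init__(self) -> None:
        counts = {len(o) for o in self.onsets}
        if len(counts) != 1:
            raise ValueError("all streams must have equal onset counts")
        for o in self.onsets:
            if np.any(np.diff(o) <= 0):
                raise ValueError("onsets must be strictly increasing")
            if len(o) and (o[0] < 0 or o[-1] >= self.n_frames):
                raise ValueError("onsets out of frame range")

    @property
    def n_streams(self) -> int:
        return len(self.onsets)

    @property
    def onsets_per_stream(self) -> int:
        return len(self.onsets[0])

    def onset_times(self, stream: int) -> np.ndarray:
        """Onset times in seconds."""
        return self.onsets[stream] / self.frame_rate


@dataclass
class FrameTrain:
    """Periodic on/off frame pattern for one flicker frequency."""

    frequency: float
    frame_rate: float
    pattern: np.ndarray  # bool, one full duration
    period_frames: int

    @property
    def duration(self) -> float:
        return len(self.pattern) / self.frame_rate


def generate_msequence(
    order: int,
    taps: tuple[int, ...] | None = None,
    init: int = 1,
) -> np.ndarray:
    """Maximal-length +/-1 sequence from a linear-feedback shift register.

    Parameters
    ----------
    order
        Register length; the sequence has length ``2**order - 1``.
    taps
        Feedback positions (1-based, e.g. ``(12, 6, 4, 1)``) forming a
        primitive polynomial.  Defaults to a standard primitive choice
        when one is known for ``order``.
    init
        Nonzero initial register state (an ``order``-bit integer).

    The resulting sequence visits every nonzero register state once, so
    its circular autocorrelation is exactly ``-1/(2**order - 1)`` at
    all nonzero lags.  Raises if ``init`` is zero or the taps are not
    primitive (the register cycles early).
    """
    if init == 0:
        raise ValueError("initial state must be nonzero")
    if taps is None:
        if order not in DEFAULT_MSEQ_TAPS:
            raise ValueError(f"no default taps for order {order}; pass taps")
        taps = DEFAULT_MSEQ_TAPS[order]
    if max(taps) != order:
        raise ValueError("highest tap must equal the order")
    length = 2**order - 1
    state = init & (2**order - 1)
    if state == 0:
        raise ValueError("initial state must be nonzero within the register")
    # taps list the nonzero polynomial exponents (besides the constant
    # term); the Fibonacci register realises x_{m+n} = XOR_e x_{m+e}
    exponents = sorted({t for t in taps if t != order} | {0})
    out = np.empty(length, dtype=np.int8)
    start = state
    for i in range(length):
        out[i] = 1 if (state & 1) else -1
        fb = 0
        for e in exponents:
            fb ^= (state >> e) & 1
        state = (state >> 1) | (fb << (order - 1))
        if state == start and i != length - 1:
            raise ValueError("taps are not primitive: register cycled early")
    if state != start:
        raise ValueError("taps are not primitive: register did not close")
    return out.astype(int)


def pulse_streams_from_msequence(
    seq: np.ndarray,
    n_streams: int = 16,
    stream_lag: int = 255,
    keep_every: int = 4,
    frame_rate: float = 75.0,
    keep_offset: int = 0,
) -> PulseStreamSet:
    """Decimated off-to-on pulse streams from time-lagged sequence copies.

    Stream ``k`` is the input sequence cyclically shifted by
    ``k * stream_lag`` frames; its pulses are the frames where the
    value flips from -1 to +1 (counting the wrap-around transition), of
    which every ``keep_every``-th in temporal order is kept (phase
    ``keep_offset``).  Because every stream is a cyclic shift, all
    streams carry identical pulse counts.
    """
    seq = np.asarray(seq, int)
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    if n_streams * stream_lag > len(seq):
        raise ValueError("n_streams * stream_lag exceeds sequence length")
    onsets = []
    for k in range(n_streams):
        s = np.roll(seq, -k * stream_lag)
        prev = np.roll(s, 1)
        trans = np.flatnonzero((prev == -1) & (s == 1))
        onsets.append(trans[keep_offset % keep_every :: keep_every])
    return PulseStreamSet(
        frame_rate=frame_rate, n_frames=len(seq), onsets=onsets
    )


def ssvep_frame_train(
    frequency: float, frame_rate: float, duration: float
) -> FrameTrain:
    """Square on/off frame train at a flicker frequency.

    The frame period ``frame_rate / frequency`` must be an even integer
    so the pattern splits into equal on and off halves (e.g. 2 on /
    2 off for 18.75 Hz at 75 frames/s; 5 on / 5 off for 7.5 Hz).
    """
    period = frame_rate / frequency
    if abs(period - round(period)) > 1e-9 or round(period) % 2 != 0:
        raise ValueError(
            f"frame_rate/frequency = {period} must be an even integer"
        )
    period = int(round(period))
    n_frames = int(round(duration * frame_rate))
    one = np.concatenate(
        [np.ones(period // 2, bool), np.zeros(period // 2, bool)]
    )
    reps = int(np.ceil(n_frames / period))
    pattern = np.tile(one, reps)[:n_frames]
    return FrameTrain(
        frequency=frequency,
        frame_rate=frame_rate,
        pattern=pattern,
        period_frames=period,
    )


def raster_correction(
    stim_vertical_fraction: float, full_delay_ms: float = 11.5
) -> float:
    """CRT raster-scan presentation delay for a stimulus position.

    The electron beam paints the screen top to bottom at constant
    speed, so a stimulus centred a fraction ``f`` of the way down the
    monitor appears ``f * full_delay_ms`` after the nominal frame
    onset (11.5 ms top-to-bottom for the reference monitor).
    """
    if not 0.0 <= stim_vertical_fraction <= 1.0:
        raise ValueError("vertical fraction must be in [0, 1]")
    return stim_vertical_fraction * full_delay_ms


def max_pairwise_stream_correlation(streams: PulseStreamSet) -> float:
    """Diagnostic: maximum |Pearson r| between stream indicator trains.

    Decimation breaks the exact orthogonality of the underlying
    m-sequence copies; this reports how much cross-stream correlation
    the kept pulse trains retain (at zero lag, over frames).
    """
    ind = np.zeros((streams.n_streams, streams.n_frames))
    for k, o in enumerate(streams.onsets):
        ind[k, o] = 1.0
    c = np.corrcoef(ind)
    off = c[~np.eye(len(c), dtype=bool)]
    return float(np.max(np.abs(off)))


def write_pulse_streams(streams: PulseStreamSet, path) -> None:
    """TSV export with columns ``stream<TAB>onset_frame``."""
    rows = [
        (k, int(f)) for k, o in enumerate(streams.onsets) for f in o
    ]
    pd.DataFrame(rows, columns=["stream", "onset_frame"]).to_csv(
        path, sep="\t", index=False
    )


def read_pulse_streams(
    path, frame_rate: float = 75.0, n_frames: int | None = None
) -> PulseStreamSet:
    df = pd.read_csv(path, sep="\t")
    onsets = [
        np.sort(df.loc[df["stream"] == k, "onset_frame"].to_numpy(int))
        for k in sorted(df["stream"].unique())
    ]
    if n_frames is None:
        n_frames = int(max(o[-1] for o in onsets)) + 1
    return PulseStreamSet(frame_rate=frame_rate, n_frames=n_frames, onsets=onsets)
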