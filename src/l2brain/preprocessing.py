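"""Continuous-EEG preprocessing: filtering, threshold artifact masking,
bad-channel interpolation, re-referencing and epoching.

The chain mirrors standard resting-state practice: a zero-phase band-pass
(0.1 Hz high-pass at 12 dB/oct, 30 Hz low-pass at 48 dB/oct), ocular
correction, per-channel rejection of samples violating any of three
threshold criteria (voltage step > 50 µV between samples, peak-to-peak
> 200 µV within any 200 ms window, peak-to-peak < 0.5 µV within any 100 ms
window), expansion of flagged samples by 200 ms on each side, topographic
interpolation of channels that would lose more than 10% of their data,
average re-referencing, and segmentation into 2-s epochs with 50% overlap
(resting) or stimulus-locked -100..1000 ms epochs (ERP).

Sample indexing is 0-based and all intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.ndimage import maximum_filter1d, minimum_filter1d


class PreprocessingError(ValueError):
    pass


@dataclass
class Event:
    sample: int
    kind: str
    payload: dict | None = None


@dataclass
class Recording:
    """Continuous multichannel signal in µV.

    ``data`` is (channels x samples); ``positions`` are 3-D electrode
    coordinates aligned with ``labels``; ``events`` are typed markers in
    sample coordinates.
    """

    data: np.ndarray = field(repr=False)
    fs: float
    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise PreprocessingError("data must be (channels x samples)")
        if len(self.labels) != len(set(self.labels)):
            raise PreprocessingError("labels must be unique")
        if len(self.labels) != self.data.shape[0]:
            raise PreprocessingError("one label per data channel required")
        if self.positions.shape != (self.data.shape[0], 3):
            raise PreprocessingError("positions must be (n_channels, 3)")
        for ev in self.events:
            if not 0 <= ev.sample < self.n_samples:
                raise PreprocessingError(f"event at sample {ev.sample} out of bounds")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(), events=list(self.events))

    def slice(self, start: int, end: int) -> "Recording":
        """Sub-recording over ``[start, end)`` (events re-anchored)."""
        if not 0 <= start < end <= self.n_samples:
            raise PreprocessingError("invalid slice bounds")
        evs = [
            Event(ev.sample - start, ev.kind, ev.payload)
            for ev in self.events
            if start <= ev.sample < end
        ]
        return Recording(self.data[:, start:end].copy(), self.fs, self.labels,
                         self.positions, evs)


@dataclass
class ArtifactMask:
    """Per-channel bad intervals (half-open, sorted, merged, pad applied)."""

    intervals: list[np.ndarray]  # per channel: (k, 2) int arrays
    n_samples: int
    pad_ms: float

    def to_bool(self) -> np.ndarray:
        out = np.zeros((len(self.intervals), self.n_samples), bool)
        for ch, iv in enumerate(self.intervals):
            for s, e in iv:
                out[ch, s:e] = True
        return out

    def flagged_fraction(self) -> np.ndarray:
        return np.array(
            [iv[:, 1].sum() - iv[:, 0].sum() if len(iv) else 0 for iv in self.intervals],
            float,
        ) / self.n_samples

    def any_channel(self) -> np.ndarray:
        """Boolean vector: sample flagged on at least one channel."""
        return self.to_bool().any(axis=0)

    def clear_channels(self, indices) -> "ArtifactMask":
        ivs = [iv.copy() for iv in self.intervals]
        for ch in indices:
            ivs[ch] = np.empty((0, 2), int)
        return ArtifactMask(ivs, self.n_samples, self.pad_ms)


@dataclass
class EpochSet:
    """Equal-length epochs: (trials x channels x samples) in µV."""

    data: np.ndarray = field(repr=False)
    fs: float
    window_ms: tuple[float, float]
    labels: tuple[str, ...]
    tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise PreprocessingError("epochs must be (trials x channels x samples)")
        if self.tags and len(self.tags) != self.data.shape[0]:
            raise PreprocessingError("one condition tag per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.window_ms[0] + np.arange(n) / self.fs * 1000.0


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


# ---------------------------------------------------------------------------
# filtering

def bandpass_filter(
    rec: Recording,
    low_hz: float = 0.1,
    high_hz: float = 30.0,
    low_rolloff_db_oct: float = 12.0,
    high_rolloff_db_oct: float = 48.0,
) -> Recording:
    """Zero-phase Butterworth band-pass.

    Roll-offs are mapped to Butterworth orders at 6 dB/octave/order; the
    forward-backward application preserves phase and steepens the effective
    slope beyond the nominal figure.
    """
    nyq = rec.fs / 2.0
    if not 0 < low_hz < high_hz:
        raise PreprocessingError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise PreprocessingError(f"high cutoff {high_hz} Hz >= Nyquist {nyq} Hz")
    n_hp = max(1, _round_half_even(low_rolloff_db_oct / 6.0))
    n_lp = max(1, _round_half_even(high_rolloff_db_oct / 6.0))
    sos = np.vstack(
        [
            signal.butter(n_hp, low_hz, "highpass", fs=rec.fs, output="sos"),
            signal.butter(n_lp, high_hz, "lowpass", fs=rec.fs, output="sos"),
        ]
    )
    data = signal.sosfiltfilt(sos, rec.data, axis=1).astype(rec.data.dtype)
    return replace(rec, data=data, events=list(rec.events))


# ---------------------------------------------------------------------------
# artifact detection

def _window_len(ms: float, fs: float) -> int:
    return max(1, int(round(ms * fs / 1000.0)))


def _sliding_range_violations(x: np.ndarray, w: int, thr: float, below: bool) -> np.ndarray:
    """Boolean per-sample flags from a sliding peak-to-peak criterion.

    ``x`` is (channels x samples).  Every length-``w`` window is checked; a
    violating window flags all of its samples.  ``below=False`` flags range
    > thr, ``below=True`` flags range < thr (flatline).
    """
    n = x.shape[1]
    if w > n:
        raise PreprocessingError(f"window of {w} samples longer than trace of {n}")
    # max/min over windows *starting* at i: centred filter evaluated at i + w//2
    cmax = maximum_filter1d(x, w, axis=1, mode="nearest")
    cmin = minimum_filter1d(x, w, axis=1, mode="nearest")
    sl = slice(w // 2, w // 2 + n - w + 1)
    # subtraction in float64 so the peak-to-peak value is exact
    rng = cmax[:, sl].astype(np.float64) - cmin[:, sl].astype(np.float64)
    viol = rng < thr if below else rng > thr
    # dilate via a difference array: window start i covers samples [i, i + w)
    nw = n - w + 1
    d = np.zeros((x.shape[0], n + 1), np.int32)
    d[:, :nw][viol] = 1
    d[:, w : w + nw][viol] -= 1
    return np.cumsum(d[:, :n], axis=1) > 0


def _block_range_violations(x: np.ndarray, w: int, thr: float, below: bool) -> np.ndarray:
    n = x.shape[1]
    if w > n:
        raise PreprocessingError(f"window of {w} samples longer than trace of {n}")
    flags = np.zeros(x.shape, bool)
    for i in range(0, n - w + 1, w):
        seg = x[:, i : i + w].astype(np.float64)
        rng = seg.max(axis=1) - seg.min(axis=1)
        hit = rng < thr if below else rng > thr
        flags[hit, i : i + w] = True
    return flags


def detect_artifacts(
    rec: Recording,
    gradient_uv: float = 50.0,
    maxdiff_uv: float = 200.0,
    maxdiff_window_ms: float = 200.0,
    lowact_uv: float = 0.5,
    lowact_window_ms: float = 100.0,
    pad_ms: float = 200.0,
    windows: str = "sliding",
) -> ArtifactMask:
    """Threshold-based per-channel artifact masking.

    A sample is flagged when (a) the voltage step from the previous sample
    exceeds ``gradient_uv``, (b) any enclosing ``maxdiff_window_ms`` window
    has peak-to-peak above ``maxdiff_uv``, or (c) any enclosing
    ``lowact_window_ms`` window has peak-to-peak below ``lowact_uv`` (the
    flatline criterion).  Flags are then expanded by ``pad_ms`` on each side
    and merged into intervals.  ``windows="block"`` checks disjoint windows
    only (the less conservative mode of the commercial tooling).
    """
    for name, v in (("gradient_uv", gradient_uv), ("maxdiff_uv", maxdiff_uv),
                    ("lowact_uv", lowact_uv)):
        if v <= 0:
            raise PreprocessingError(f"{name} must be positive")
    if windows not in ("sliding", "block"):
        raise PreprocessingError(f"unknown window mode {windows!r}")
    range_viol = _sliding_range_violations if windows == "sliding" else _block_range_violations
    w_b = _window_len(maxdiff_window_ms, rec.fs)
    w_c = _window_len(lowact_window_ms, rec.fs)
    pad = int(round(pad_ms * rec.fs / 1000.0))
    n = rec.n_samples
    x = np.ascontiguousarray(rec.data, np.float32)
    flags = np.zeros(x.shape, bool)
    xd = x.astype(np.float64)
    flags[:, 1:] = np.abs(np.diff(xd, axis=1)) > gradient_uv
    flags |= range_viol(x, w_b, maxdiff_uv, below=False)
    flags |= range_viol(x, w_c, lowact_uv, below=True)
    intervals = [_flags_to_intervals(flags[ch], pad, n) for ch in range(rec.n_channels)]
    return ArtifactMask(intervals, n, pad_ms)


def _flags_to_intervals(flags: np.ndarray, pad: int, n: int) -> np.ndarray:
    if not flags.any():
        return np.empty((0, 2), int)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], flags.view(np.int8), [0]])))
    starts, ends = edges[::2] - pad, edges[1::2] + pad
    starts = np.clip(starts, 0, n)
    ends = np.clip(ends, 0, n)
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, int)


# ---------------------------------------------------------------------------
# interpolation and referencing

def interpolate_bad_channels(
    rec: Recording,
    mask: ArtifactMask,
    reject_fraction: float = 0.10,
    max_interp: int = 5,
    k_neighbors: int = 4,
) -> tuple[Recording, dict]:
    """Replace channels that would reject > ``reject_fraction`` of the data.

    Replacement is the unweighted mean of the ``k_neighbors`` nearest good
    channels (Euclidean distance on montage positions), emulating
    topographic interpolation by adjacent electrodes.  More than
    ``max_interp`` qualifying channels is a hard error: recordings that bad
    are outside the regime the pipeline is meant for.
    """
    frac = mask.flagged_fraction()
    bad = np.flatnonzero(frac > reject_fraction)
    report = {
        "replaced": [rec.labels[i] for i in bad],
        "replaced_idx": bad.tolist(),
        "flagged_fraction": frac.tolist(),
    }
    if bad.size > max_interp:
        raise PreprocessingError(
            f"{bad.size} channels exceed reject fraction {reject_fraction} "
            f"(limit {max_interp}): {report['replaced']}"
        )
    if bad.size == 0:
        return rec, report
    out = replace_channels(rec, bad, k_neighbors)
    report["k_neighbors"] = min(k_neighbors, rec.n_channels - bad.size)
    return out, report


def replace_channels(rec: Recording, bad: np.ndarray, k_neighbors: int = 4) -> Recording:
    """k-nearest-good-neighbour topographic replacement of ``bad`` channels."""
    bad = np.asarray(bad, int)
    good = np.setdiff1d(np.arange(rec.n_channels), bad)
    if good.size == 0:
        raise PreprocessingError("no good channels left to interpolate from")
    k = min(k_neighbors, good.size)
    data = rec.data.copy()
    for ch in bad:
        d = np.linalg.norm(rec.positions[good] - rec.positions[ch], axis=1)
        nbr = good[np.argsort(d)[:k]]
        data[ch] = rec.data[nbr].mean(axis=0)
    return replace(rec, data=data, events=list(rec.events))


def rereference_average(rec: Recording) -> Recording:
    """Subtract the instantaneous mean over all channels (average reference)."""
    if rec.n_channels < 2:
        raise PreprocessingError("average reference needs >= 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data, events=list(rec.events))


# ---------------------------------------------------------------------------
# segment extraction and epoching

def extract_ec_segments(
    rec: Recording, trim_s: float = 5.0, kind: str = "eyes-closed"
) -> list[tuple[int, int]]:
    """Eyes-closed intervals in sample coordinates, trimmed at both ends.

    Segments run from each ``kind`` event to the next event of any kind (or
    the end of the recording); segments shorter than ``2 * trim_s`` are
    dropped with a warning.
    """
    evs = sorted(rec.events, key=lambda e: e.sample)
    onsets = [i for i, e in enumerate(evs) if e.kind == kind]
    if not onsets:
        raise PreprocessingError(f"no {kind!r} events in recording")
    trim = int(round(trim_s * rec.fs))
    out = []
    for i in onsets:
        start = evs[i].sample
        end = evs[i + 1].sample if i + 1 < len(evs) else rec.n_samples
        if end - start <= 2 * trim:
            warnings.warn(
                f"{kind} segment [{start}, {end}) shorter than twice the "
                f"{trim_s} s trim; dropped"
            )
            continue
        out.append((start + trim, end - trim))
    return out


def epoch_fixed_overlap(
    rec: Recording,
    segments: list[tuple[int, int]],
    mask: ArtifactMask | None = None,
    epoch_s: float = 2.0,
    overlap: float = 0.5,
) -> EpochSet:
    """Tile segments with fixed-length epochs at stride ``epoch_s*(1-overlap)``.

    Epochs overlapping a masked interval on any channel are skipped.
    Epoch length in samples is ``round(epoch_s * fs)`` (round half to even).
    """
    if not 0 <= overlap < 1:
        raise PreprocessingError("overlap must lie in [0, 1)")
    n_len = _round_half_even(epoch_s * rec.fs)
    stride = max(1, _round_half_even(epoch_s * (1 - overlap) * rec.fs))
    bad = mask.any_channel() if mask is not None else np.zeros(rec.n_samples, bool)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    chunks = []
    for seg_start, seg_end in segments:
        if not 0 <= seg_start <= seg_end <= rec.n_samples:
            raise PreprocessingError("segment outside recording bounds")
        starts = np.arange(seg_start, seg_end - n_len + 1, stride)
        if starts.size == 0:
            continue
        keep = cbad[starts + n_len] - cbad[starts] == 0
        for s in starts[keep]:
            chunks.append(rec.data[:, s : s + n_len])
    data = (
        np.stack(chunks) if chunks else np.empty((0, rec.n_channels, n_len), rec.data.dtype)
    )
    return EpochSet(data, rec.fs, (0.0, epoch_s * 1000.0), rec.labels)


def baseline_correct(epochs: EpochSet, baseline_ms: tuple[float, float]) -> EpochSet:
    """Subtract the per-channel mean over ``baseline_ms`` from every epoch."""
    t = epochs.times_ms
    sel = (t >= baseline_ms[0]) & (t < baseline_ms[1])
    if not sel.any():
        raise PreprocessingError("baseline window contains no samples")
    base = epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base, tags=list(epochs.tags))


def epoch_events(
    rec: Recording,
    mask: ArtifactMask | None,
    anchor_kind: str,
    window_ms: tuple[float, float] = (-100.0, 1000.0),
    baseline_ms: tuple[float, float] | None = (-100.0, 0.0),
) -> EpochSet:
    """Stimulus-locked epochs around events of ``anchor_kind``.

    Epochs extending past the recording bounds or overlapping the mask are
    dropped (counted in the returned set's length); condition tags are taken
    from the event payload key ``"condition"``.
    """
    anchors = [e for e in rec.events if e.kind == anchor_kind]
    if not anchors:
        raise PreprocessingError(f"no {anchor_kind!r} events in recording")
    n_pre = _round_half_even(-window_ms[0] / 1000.0 * rec.fs)
    n_len = _round_half_even((window_ms[1] - window_ms[0]) / 1000.0 * rec.fs)
    bad = mask.any_channel() if mask is not None else np.zeros(rec.n_samples, bool)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    chunks, tags = [], []
    for ev in anchors:
        s = ev.sample - n_pre
        e = s + n_len
        if s < 0 or e > rec.n_samples or cbad[e] - cbad[s] > 0:
            continue
        chunks.append(rec.data[:, s:e])
        tags.append((ev.payload or {}).get("condition", ""))
    data = (
        np.stack(chunks) if chunks else np.empty((0, rec.n_channels, n_len), rec.data.dtype)
    )
    out = EpochSet(data, rec.fs, window_ms, rec.labels, tags)
    return baseline_correct(out, baseline_ms) if baseline_ms and len(chunks) else out


# ---------------------------------------------------------------------------
# ocular correction

def correct_ocular(
    rec: Recording,
    method: str = "regression",
    frontal: tuple[str, ...] | None = None,
    blink_uv: float = 50.0,
    proxy_lowpass_hz: float = 5.0,
    pad_s: float = 0.15,
) -> tuple[Recording, dict]:
    """Remove blink/saccade activity; pluggable backend.

    ``regression`` (default, deterministic): a low-frequency ocular proxy is
    built as the mean of the frontal channels low-passed at
    ``proxy_lowpass_hz``; windows where the proxy deviates from its median
    by more than ``blink_uv`` are treated as blinks, and within each window
    every channel has its least-squares projection on the (demeaned) proxy
    subtracted.  Samples outside detected windows are untouched.

    ``ica``: FastICA blind source separation; components correlating with
    the proxy above 0.6 are removed.  Falls back to a pass-through with a
    warning flag if the backend is unavailable.
    """
    if frontal is None:
        from .montage import Montage, frontal_channels

        frontal = frontal_channels(Montage(rec.labels, rec.positions))
    fidx = [rec.labels.index(lab) for lab in frontal]
    if not fidx:
        raise PreprocessingError("no frontal channels identified")
    sos = signal.butter(4, proxy_lowpass_hz, "lowpass", fs=rec.fs, output="sos")
    proxy = signal.sosfiltfilt(sos, np.asarray(rec.data[fidx], np.float64).mean(axis=0))
    dev = np.abs(proxy - np.median(proxy))
    flags = dev > blink_uv
    pad = int(round(pad_s * rec.fs))
    intervals = _flags_to_intervals(flags, pad, rec.n_samples)
    report: dict = {"method": method, "intervals": intervals.tolist(), "warning": None}

    if method == "regression":
        data = rec.data.copy()
        for s, e in intervals:
            p = proxy[s:e] - proxy[s:e].mean()
            denom = float(p @ p)
            if denom == 0:
                continue
            seg = np.asarray(data[:, s:e], np.float64)
            beta = (seg @ p) / denom
            data[:, s:e] = (seg - np.outer(beta, p)).astype(data.dtype)
        return replace(rec, data=data, events=list(rec.events)), report
    if method == "ica":
        try:
            from sklearn.decomposition import FastICA
        except ImportError:  # pragma: no cover
            report["warning"] = "ICA backend unavailable; data passed through"
            return rec.copy(), report
        x = np.asarray(rec.data, np.float64).T
        ica = FastICA(n_components=min(rec.n_channels, 20), random_state=0,
                      whiten="unit-variance", max_iter=500, tol=1e-3)
        sources = ica.fit_transform(x)
        r = np.array(
            [abs(np.corrcoef(sources[:, k], proxy)[0, 1]) for k in range(sources.shape[1])]
        )
        drop = r > 0.6
        sources[:, drop] = 0.0
        clean = ica.inverse_transform(sources) + 0.0
        data = clean.T.astype(rec.data.dtype)
        report["components_removed"] = int(drop.sum())
        return replace(rec, data=data, events=list(rec.events)), report
    raise PreprocessingError(f"unknown ocular-correction method {method!r}")
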