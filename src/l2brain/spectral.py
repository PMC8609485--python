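"""Band power extraction from epoched resting-state EEG.

Per-epoch periodograms (FFT, one-sided, optionally Hann-tapered with
amplitude-loss compensation) are averaged across epochs, then reduced to
mean power in µV² per frequency band and electrode pool.  Normalization is
fixed so that a sinusoid of amplitude A contributes A²/2 at its frequency
bin and, taper-free, the bins sum to the signal's mean square (Parseval).
Band statistics are the *mean* over the bins whose centre frequency falls
in the half-open band ``(low, high]`` (so 12.5 Hz is alpha, not beta1), and
are log10-transformed for all downstream analyses.

Standard band edges: theta 4–7.5, alpha 8–12.5, beta1 13–14.5, beta2
15–17.5, beta3 18–29.5, optional gamma 30–40 Hz.  Gamma sits above the
30 Hz low-pass of the standard filter chain and is therefore off by
default; enabling it only makes sense with a wider filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .preprocessing import EpochSet

BAND_EDGES: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.5),
    "alpha": (8.0, 12.5),
    "beta1": (13.0, 14.5),
    "beta2": (15.0, 17.5),
    "beta3": (18.0, 29.5),
}
GAMMA_EDGES: tuple[float, float] = (30.0, 40.0)
BAND_ORDER = ("theta", "alpha", "beta1", "beta2", "beta3", "gamma")


@dataclass(frozen=True)
class BandScheme:
    """Named, non-overlapping frequency bands with ``(low, high]`` edges."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BAND_EDGES)
    )

    def __post_init__(self) -> None:
        items = sorted(self.bands.items(), key=lambda kv: kv[1][0])
        for name, (lo, hi) in items:
            if not lo < hi:
                raise ValueError(f"band {name}: need low < high")
        for (n1, (_, h1)), (n2, (l2, _)) in zip(items, items[1:]):
            if h1 > l2:
                raise ValueError(f"bands {n1} and {n2} overlap")

    @classmethod
    def with_gamma(cls) -> "BandScheme":
        return cls({**BAND_EDGES, "gamma": GAMMA_EDGES})

    def names(self) -> tuple[str, ...]:
        return tuple(sorted(self.bands, key=lambda n: self.bands[n][0]))


@dataclass
class Spectra:
    """Epoch-averaged one-sided power spectra, µV² per bin."""

    freqs: np.ndarray
    power: np.ndarray  # (channels x freq bins)
    labels: tuple[str, ...]
    n_epochs: int


def epoch_psd(epochs: EpochSet, taper: str = "hann") -> Spectra:
    """Per-channel power spectra averaged over epochs.

    ``taper`` is ``"hann"`` or ``"none"``.  Scaling is scipy's
    ``"spectrum"`` convention: amplitude-correct at a sinusoid's bin (A²/2)
    with the taper's coherent gain compensated.  Bin width is
    ``fs / n_samples``.
    """
    if epochs.n_epochs == 0:
        raise ValueError("empty epoch set")
    if taper not in ("hann", "none"):
        raise ValueError(f"unknown taper {taper!r}")
    from scipy import fft as sfft

    data = epochs.data
    dtype = np.float64 if data.dtype == np.float64 else np.float32
    data = np.ascontiguousarray(data, dtype)
    n = data.shape[-1]
    if taper == "hann":
        win = _signal.windows.hann(n, sym=False).astype(dtype)
        data = data * win
        norm = 1.0 / win.sum() ** 2
    else:
        norm = 1.0 / float(n) ** 2
    spec = sfft.rfft(data, axis=-1)
    pxx = (spec.real**2 + spec.imag**2).mean(axis=0).astype(np.float64) * norm
    # one-sided doubling (DC and, for even n, the Nyquist bin are unique)
    if n % 2 == 0:
        pxx[..., 1:-1] *= 2.0
    else:
        pxx[..., 1:] *= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / epochs.fs)
    return Spectra(freqs, pxx, epochs.labels, epochs.n_epochs)


def band_pool_means(
    spectra: Spectra,
    bands: BandScheme | None = None,
    pools: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Mean power per electrode pool and frequency band (long format).

    For each pool x band cell the spectral values are averaged over member
    channels and over the bins with centre frequency in ``(low, high]``;
    both the raw µV² mean and its log10 are returned.  A band that captures
    no bins at the current resolution is an error (it would silently alias
    into its neighbours otherwise).
    """
    bands = bands or BandScheme()
    if pools is None:
        raise ValueError("pool membership required")
    label_idx = {lab: i for i, lab in enumerate(spectra.labels)}
    rows = []
    for pool_name, members in pools.items():
        missing = [m for m in members if m not in label_idx]
        if missing:
            raise KeyError(f"pool {pool_name!r}: channels {missing} not in montage")
        ch = [label_idx[m] for m in members]
        for band_name in bands.names():
            lo, hi = bands.bands[band_name]
            sel = (spectra.freqs > lo) & (spectra.freqs <= hi)
            if not sel.any():
                raise ValueError(
                    f"band {band_name!r} ({lo}-{hi} Hz) has no bins at "
                    f"resolution {np.diff(spectra.freqs).mean():.3g} Hz"
                )
            raw = float(spectra.power[np.ix_(ch, np.flatnonzero(sel))].mean())
            rows.append(
                {
                    "pool": pool_name,
                    "band": band_name,
                    "power_uv2": raw,
                    "log10_power": np.log10(raw) if raw > 0 else -np.inf,
                }
            )
    return pd.DataFrame(rows)


def band_power_change(
    table_t1: pd.DataFrame, table_t2: pd.DataFrame, band: str = "beta1"
) -> pd.Series:
    """Per-subject mean (over pools) log10-power change T2 - T1 for a band.

    Both tables must be long-format band-power tables with ``subject``,
    ``pool``, ``band`` and ``log10_power`` columns covering the same
    subjects.
    """
    out = {}
    t1 = table_t1[table_t1["band"] == band]
    t2 = table_t2[table_t2["band"] == band]
    subjects = sorted(set(t1["subject"]) | set(t2["subject"]))
    for s in subjects:
        a = t1.loc[t1["subject"] == s, "log10_power"]
        b = t2.loc[t2["subject"] == s, "log10_power"]
        if a.empty or b.empty:
            raise ValueError(f"subject {s!r} missing a session for band {band!r}")
        out[s] = float(b.mean() - a.mean())
    return pd.Series(out, name=f"delta_{band}")
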