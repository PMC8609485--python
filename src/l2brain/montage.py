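"""Electrode montages and electrode-pool definitions.

The study montage is the 128-channel BioSemi cap (labels A1..D32); its 3-D
positions come from the standard template shipped with :mod:`mne`.  For
reduced channel counts (used to keep simulations light) a synthetic
upper-hemisphere montage is generated instead, and pools are assigned
geometrically.  Head coordinates follow the usual convention: +x right,
+y anterior, +z superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

RESTING_POOL_NAMES = (
    "medial-frontal",
    "left-frontotemporal",
    "right-frontotemporal",
    "left-posterior",
    "right-posterior",
)

#: ERP pool memberships on the BioSemi-128 cap (Central pool for the N400,
#: Parietal pool for the LPC).  Pools from different schemes may overlap.
ERP_CENTRAL_128 = ("A1", "A2", "A3", "D1", "D14", "D15", "D16")
ERP_PARIETAL_128 = ("A3", "A4", "A5", "A6", "A20", "A21", "D16", "D17")


@dataclass(frozen=True)
class Montage:
    """Channel labels and 3-D positions (one row per channel, metres)."""

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("channel labels must be unique")
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_channels, 3)")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def unit_positions(self) -> np.ndarray:
        """Positions projected onto the unit sphere (direction cosines)."""
        p = np.asarray(self.positions, float)
        r = np.linalg.norm(p, axis=1, keepdims=True)
        r[r == 0] = 1.0
        return p / r


@lru_cache(maxsize=8)
def build_montage(n_channels: int = 128) -> Montage:
    """Return the study montage.

    128 channels map to the standard BioSemi-128 template; any other count
    yields a deterministic synthetic hemisphere montage with generic labels.
    """
    if n_channels == 128:
        import mne

        std = mne.channels.make_standard_montage("biosemi128")
        ch_pos = std.get_positions()["ch_pos"]
        labels = tuple(ch_pos.keys())
        pos = np.array([ch_pos[lab] for lab in labels], float)
        return Montage(labels=labels, positions=pos)
    return _fibonacci_montage(n_channels)


def _fibonacci_montage(n_channels: int, radius: float = 0.095) -> Montage:
    # Fibonacci lattice on the upper hemisphere: even coverage, deterministic.
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    i = np.arange(n_channels)
    golden = (1 + 5**0.5) / 2
    z = (i + 0.5) / n_channels  # (0, 1): hemisphere only
    theta = 2 * np.pi * i / golden
    rho = np.sqrt(1 - z**2)
    pos = radius * np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    labels = tuple(f"CH{k + 1:02d}" for k in i)
    return Montage(labels=labels, positions=pos)


def resting_pools(montage: Montage) -> dict[str, tuple[str, ...]]:
    """Five resting-state pools assigned from scalp geometry.

    The published pool layout is schematic only, so membership is derived
    from channel positions: an anterior midline strip plus lateral
    frontotemporal and posterior quadrants.  Channels in the central band
    belong to no resting pool.
    """
    u = montage.unit_positions()
    pools: dict[str, list[str]] = {name: [] for name in RESTING_POOL_NAMES}
    for lab, (x, y, _z) in zip(montage.labels, u):
        if y > 0.20 and abs(x) <= 0.30:
            pools["medial-frontal"].append(lab)
        elif y > 0.10:
            pools["left-frontotemporal" if x < 0 else "right-frontotemporal"].append(lab)
        elif y < -0.10:
            pools["left-posterior" if x < 0 else "right-posterior"].append(lab)
    empty = [k for k, v in pools.items() if not v]
    if empty:
        raise ValueError(f"montage too sparse: empty resting pools {empty}")
    return {k: tuple(v) for k, v in pools.items()}


def erp_pools(montage: Montage) -> dict[str, tuple[str, ...]]:
    """Central (N400) and Parietal (LPC) pools.

    On the BioSemi-128 cap the published memberships are used verbatim.
    Note the published Parietal list names D16/D17 (frontopolar labels on
    this cap) alongside centro-parietal sites; the listed labels are kept
    as-is and the inconsistency is documented.  Other montages fall back to
    the channels nearest the vertex and the midline parietal direction.
    """
    if set(ERP_CENTRAL_128) <= set(montage.labels):
        return {"central": ERP_CENTRAL_128, "parietal": ERP_PARIETAL_128}
    u = montage.unit_positions()

    def nearest(direction: np.ndarray, k: int) -> tuple[str, ...]:
        d = u @ (direction / np.linalg.norm(direction))
        order = np.argsort(-d)[:k]
        return tuple(montage.labels[j] for j in sorted(order))

    k_c = max(2, round(montage.n_channels * 7 / 128))
    k_p = max(2, round(montage.n_channels * 8 / 128))
    return {
        "central": nearest(np.array([0.0, 0.0, 1.0]), k_c),
        "parietal": nearest(np.array([0.0, -0.6, 0.8]), k_p),
    }


def frontal_channels(montage: Montage, fraction: float = 0.12) -> tuple[str, ...]:
    """Most anterior channels (blink injection / ocular-proxy set)."""
    u = montage.unit_positions()
    k = max(2, int(np.ceil(fraction * montage.n_channels)))
    order = np.argsort(-u[:, 1])[:k]
    return tuple(montage.labels[j] for j in sorted(order))
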