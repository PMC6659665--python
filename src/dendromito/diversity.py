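"""Nucleotide diversity (pi) per region and in sliding windows.

pi is the mean, over all unordered pairs of rows, of the proportion of
differing sites. Columns containing any gap or ambiguous base are removed
before counting (complete deletion within the evaluated range), so the
numerator and denominator always refer to the same clean columns. The
sliding window uses the mitogenome-survey convention of 100 bp windows
moved in 25 bp steps; a trailing stretch shorter than one window is
dropped rather than emitted as a short window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import DendromitoError

_VALID = frozenset(b"ACGT")


def _as_array(rows: Mapping[str, str] | Sequence[str]) -> np.ndarray:
    if isinstance(rows, Mapping):
        rows = list(rows.values())
    rows = [r.upper() for r in rows]
    if len(rows) < 2:
        raise DendromitoError("pi needs at least 2 rows")
    if len({len(r) for r in rows}) != 1:
        raise DendromitoError("ragged alignment rows")
    return np.array(
        [np.frombuffer(r.encode(), dtype=np.uint8) for r in rows]
    )


def _pi_on_columns(arr: np.ndarray) -> Optional[float]:
    """pi over the clean columns of a (rows, sites) byte array; None when
    no column is clean."""
    valid = np.ones(arr.shape[1], dtype=bool)
    for code in np.unique(arr):
        if code not in _VALID:
            valid &= ~(arr == code).any(axis=0)
    clean = arr[:, valid]
    nsites = clean.shape[1]
    if nsites == 0:
        return None
    nrows = clean.shape[0]
    total = 0.0
    for i in range(nrows):
        for j in range(i + 1, nrows):
            total += np.count_nonzero(clean[i] != clean[j]) / nsites
    npairs = nrows * (nrows - 1) // 2
    return total / npairs


def nucleotide_diversity(
    rows: Mapping[str, str] | Sequence[str],
    site_range: Optional[tuple[int, int]] = None,
) -> Optional[float]:
    """pi within an optional 1-based inclusive site range.

    Returns None (the explicit "undefined" flag) when every column in the
    range carries a gap or ambiguous base.
    """
    arr = _as_array(rows)
    if site_range is not None:
        start, end = site_range
        if not (1 <= start <= end <= arr.shape[1]):
            raise DendromitoError(f"site range {site_range} out of bounds")
        arr = arr[:, start - 1 : end]
    return _pi_on_columns(arr)


@dataclass
class SlidingWindowProfile:
    """Windowed pi series for one region.

    ``windows`` holds (1-based window start, pi) pairs; ``mean_pi`` is pi
    over the whole region (the horizontal reference line when plotted).
    Midpoints for plotting are ``start + window_size // 2``.
    """

    region: str
    window_size: int
    step: int
    windows: list[tuple[int, Optional[float]]]
    mean_pi: Optional[float]

    @property
    def midpoints(self) -> list[float]:
        return [s + self.window_size / 2.0 for s, _ in self.windows]


def sliding_pi(
    rows: Mapping[str, str] | Sequence[str],
    window: int = 100,
    step: int = 25,
    region: str = "",
) -> SlidingWindowProfile:
    """pi in sliding windows; window count = floor((L - window)/step) + 1."""
    arr = _as_array(rows)
    length = arr.shape[1]
    if window > length:
        raise DendromitoError(
            f"window {window} exceeds alignment length {length}"
        )
    if step < 1 or window < 1:
        raise DendromitoError("window and step must be >= 1")
    nwin = (length - window) // step + 1
    series: list[tuple[int, Optional[float]]] = []
    for k in range(nwin):
        start = 1 + k * step
        series.append(
            (start, _pi_on_columns(arr[:, start - 1 : start - 1 + window]))
        )
    return SlidingWindowProfile(
        region, window, step, series, _pi_on_columns(arr)
    )


def rank_regions(profiles: Iterable[SlidingWindowProfile]) -> list[str]:
    """Region labels ordered by mean pi, most variable first.

    Regions with undefined mean pi sort last; exact ties are broken
    lexicographically and reported with a warning.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise DendromitoError("ranking needs >= 2 regions")
    keyed = sorted(
        profiles,
        key=lambda p: (
            p.mean_pi is None,
            -(p.mean_pi if p.mean_pi is not None else 0.0),
            p.region,
        ),
    )
    by_value: dict[Optional[float], list[str]] = {}
    for p in profiles:
        by_value.setdefault(p.mean_pi, []).append(p.region)
    for value, names in by_value.items():
        if len(names) > 1:
            warnings.warn(
                f"regions {sorted(names)} tie at pi={value}; "
                "lexicographic order applied",
                stacklevel=2,
            )
    return [p.region for p in keyed]


def write_sliding_tsv(
    profiles: Iterable[SlidingWindowProfile], path: str | Path
) -> None:
    lines = ["region\twindow_start\tpi"]
    for prof in profiles:
        for start, pi in prof.windows:
            val = "NA" if pi is None else f"{pi:.6f}"
            lines.append(f"{prof.region}\t{start}\t{val}")
    Path(path).write_text("\n".join(lines) + "\n")


def plot_sliding(
    profiles: Sequence[SlidingWindowProfile], path: str | Path
) -> None:
    """Multi-panel pi profiles, one panel per region, each with a dotted
    horizontal line at the region's mean pi."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(profiles)
    ncol = 3
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(4 * ncol, 2.2 * nrow), squeeze=False
    )
    for ax in axes.flat[n:]:
        ax.axis("off")
    for ax, prof in zip(axes.flat, profiles):
        xs = prof.midpoints
        ys = [np.nan if pi is None else pi for _, pi in prof.windows]
        ax.plot(xs, ys, lw=0.8)
        if prof.mean_pi is not None:
            ax.axhline(prof.mean_pi, color="red", ls=":", lw=0.8)
        ax.set_title(prof.region, fontsize=8)
        ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
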