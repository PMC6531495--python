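"""Projection onto the Munsell chip array, distribution grids, and peaks.

A Lab point is projected onto the 330-chip array in two steps: first the
lightness row whose constant L* is nearest, then — between that row's
achromatic chip and the chromatic chip whose hue angle atan2(b*, a*) is
nearest (wrap-aware) — the chip whose chroma radius is nearest.  Focal
distributions count, per chip, the languages with a focus projected there,
normalised by how many input stimuli project to the chip.  Peaks of the
8 x 40 chromatic grid are chips strictly exceeding their four block
neighbours (hue adjacency wraps by default; the top and bottom lightness
rows are border chips and never peaks), and two peak sets are compared by
a size-weighted bidirectional minimum-matching distance in grid
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .colour_space import angular_difference
from .focal_analysis import LanguageSet
from .stimuli import ChipArray, StimulusSet


class Peak(NamedTuple):
    """A local maximum of the chromatic grid: hue column, lightness row, value."""

    h: int  # hue column, 0..39
    l: int  # lightness row, 1..8 (chromatic rows of the array)
    value: float


@dataclass
class PeakSet:
    """The top-N peaks of a grid, sorted by value descending."""

    peaks: list[Peak]
    n_requested: int
    truncated: bool = False  # fewer peaks were available than requested

    def __len__(self) -> int:
        return len(self.peaks)

    def coords(self) -> np.ndarray:
        return np.array([(p.h, p.l) for p in self.peaks], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.peaks, columns=["h", "l", "value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ChipGrid:
    """One scalar per chip of a :class:`ChipArray` (counts or normalised)."""

    array: ChipArray
    values: np.ndarray  # (330,)
    normalisation: str = "raw-count"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.array.n,):
            raise ValueError("grid needs one value per chip")
        if np.any(self.values < 0):
            raise ValueError("grid values must be non-negative")

    def chromatic_grid(self) -> np.ndarray:
        """The (8, 40) chromatic block, row 0 = lightness row 1 (lightest)."""
        idx = self.array.chrom_idx[1:9]
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"row": self.array.row, "column": self.array.col, "value": self.values}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def project_to_chip(lab, array: ChipArray) -> int:
    """Project one Lab point to a chip index by the two-step rule."""
    return int(project_many(np.atleast_2d(np.asarray(lab, dtype=float)), array)[0])


def project_many(labs: np.ndarray, array: ChipArray) -> np.ndarray:
    """Vectorised two-step projection of (n, 3) Lab rows to chip indices."""
    labs = np.asarray(labs, dtype=float)
    rows = np.argmin(np.abs(labs[:, 0:1] - array.row_L[None, :]), axis=1)
    radii = np.hypot(labs[:, 1], labs[:, 2])
    angles = np.arctan2(labs[:, 2], labs[:, 1])
    out = np.empty(len(labs), dtype=int)
    for i, r in enumerate(rows):
        ach = array.achromatic_idx[r]
        chips = array.chrom_idx[r]
        if chips[0] < 0:  # achromatic-only row (white / black)
            out[i] = ach
            continue
        dh = angular_difference(array.angles[chips], angles[i])
        cand = chips[int(np.argmin(dh))]
        # radius tie-break between the achromatic chip (radius 0) and the
        # angular nearest chromatic chip
        if abs(array.radii[cand] - radii[i]) <= abs(0.0 - radii[i]):
            out[i] = cand
        else:
            out[i] = ach
    return out


def stimulus_multiplicity(stimuli: StimulusSet, array: ChipArray) -> np.ndarray:
    """How many input stimuli project to each of the 330 chips."""
    counts = np.zeros(array.n)
    np.add.at(counts, project_many(stimuli.labs, array), 1.0)
    return counts


def focal_distribution(
    languages: LanguageSet | None,
    stimuli: StimulusSet,
    array: ChipArray,
    normalise: bool = True,
) -> ChipGrid:
    """Per-chip focal-colour frequency, normalised by stimulus multiplicity.

    The raw count of a chip is the number of languages with at least one
    focus projected onto it.  With ``normalise=True`` each count is divided
    by the number of input stimuli projecting to that chip; chips receiving
    zero stimuli keep value 0 by convention.
    """
    counts = np.zeros(array.n)
    if languages is not None:
        for lang in languages.languages:
            hit = np.unique(project_many(lang.foci, array))
            counts[hit] += 1.0
    if not normalise:
        return ChipGrid(array, counts, normalisation="raw-count")
    mult = stimulus_multiplicity(stimuli, array)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(mult > 0, counts / np.where(mult > 0, mult, 1.0), 0.0)
    return ChipGrid(array, vals, normalisation="per-chip-normalised")


def find_peaks(grid: ChipGrid, hue_wrap: bool = True) -> list[Peak]:
    """Local maxima of the chromatic block under the four-neighbour rule.

    A peak strictly exceeds its up/down/left/right neighbours.  The top and
    bottom lightness rows are border chips and excluded; with
    ``hue_wrap=True`` (Munsell hue is circular) every column is interior,
    otherwise the first and last hue columns are excluded too.
    """
    g = grid.chromatic_grid()
    n_rows, n_cols = g.shape
    peaks: list[Peak] = []
    col_range = range(n_cols) if hue_wrap else range(1, n_cols - 1)
    for r in range(1, n_rows - 1):
        for c in col_range:
            v = g[r, c]
            left = g[r, (c - 1) % n_cols]
            right = g[r, (c + 1) % n_cols]
            if v > left and v > right and v > g[r - 1, c] and v > g[r + 1, c]:
                peaks.append(Peak(h=c, l=r + 1, value=float(v)))
    return peaks


def select_top_peaks(
    peaks: Sequence[Peak],
    source: str = "emergent",
    mean_categories: float | None = None,
) -> PeakSet:
    """Keep the N highest peaks: N=4 for WCS grids, round(mean)-2 for emergent.

    The emergent rule subtracts the two achromatic categories (black and
    white), flooring at 1.  Ties at the cut break by (value desc, row asc,
    column asc).  If fewer peaks exist than requested, all are kept and the
    result is flagged as truncated.
    """
    if not peaks:
        raise ValueError("no peaks to select from")
    if source == "wcs":
        n = 4
    elif source == "emergent":
        if mean_categories is None:
            raise ValueError("emergent selection needs the mean category count")
        n = max(1, round(float(mean_categories)) - 2)
    else:
        raise ValueError(f"unknown grid source {source!r}")
    ordered = sorted(peaks, key=lambda p: (-p.value, p.l, p.h))
    return PeakSet(ordered[:n], n_requested=n, truncated=len(ordered) < n)


def peak_to_peak_distance(P: PeakSet | Sequence[Peak], Q: PeakSet | Sequence[Peak]) -> float:
    """Size-weighted bidirectional minimum-matching distance between peak sets.

    With weights W_P = |P| / (|P| + |Q|) and W_Q likewise, sums each set's
    minimum Euclidean grid distances to the other:

        W_P * sum_p min_q dE(p, q) + W_Q * sum_q min_p dE(p, q)
    """
    pc = P.coords() if isinstance(P, PeakSet) else np.array([(p.h, p.l) for p in P], float)
    qc = Q.coords() if isinstance(Q, PeakSet) else np.array([(q.h, q.l) for q in Q], float)
    if len(pc) == 0 or len(qc) == 0:
        raise ValueError("peak sets must be non-empty")
    d = np.sqrt(
        (pc[:, 0:1] - qc[None, :, 0]) ** 2 + (pc[:, 1:2] - qc[None, :, 1]) ** 2
    )
    wp = len(pc) / (len(pc) + len(qc))
    wq = len(qc) / (len(pc) + len(qc))
    return float(wp * d.min(axis=1).sum() + wq * d.min(axis=0).sum())


__all__ = [
    "Peak",
    "PeakSet",
    "ChipGrid",
    "project_to_chip",
    "project_many",
    "stimulus_multiplicity",
    "focal_distribution",
    "find_peaks",
    "select_top_peaks",
    "peak_to_peak_distance",
]
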