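"""Stimulus sets and the Munsell chip array.

Loads the Munsell renotation table (the "real" colour stimuli, one row per
distinct physical colour as H V C x y Y), builds per-stimulus rotation
randomisations, synthesises clustered download-free stimulus sets, and
constructs the 330-chip WCS stimulus array (8 lightness rows x 40 hue
columns of maximally saturated chips plus 10 achromatic levels).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .colour_space import (
    ILLUMINANT_C,
    XyYPoint,
    chroma_radius,
    euclidean_delta_e,
    lab_to_xyy,
    rotate_about_L,
    xyy_to_lab,
)

#: Lab distance below which two stimuli count as indistinct.
DISTINCT_TOL = 1e-6

#: The 40 WCS hue columns, in chart order starting at 2.5R.
WCS_HUES: tuple[str, ...] = tuple(
    f"{step}{family}"
    for family in ("R", "YR", "Y", "GY", "G", "BG", "B", "PB", "P", "RP")
    for step in ("2.5", "5", "7.5", "10")
)

#: Munsell values of the 8 chromatic rows (top row B = 9 down to row I = 2).
WCS_ROW_VALUES: tuple[float, ...] = (9.0, 8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0)

#: Munsell values of the 10 achromatic chips, white (N9.5) to black (N1.5).
WCS_NEUTRAL_VALUES: tuple[float, ...] = (9.5, 9.0, 8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.5)


def munsell_value_to_Y(v) -> np.ndarray:
    """Luminance factor Y (0-100) for a Munsell value, ASTM D1535 quintic."""
    v = np.asarray(v, dtype=float)
    return (
        1.1914 * v
        - 0.22533 * v**2
        + 0.23352 * v**3
        - 0.020484 * v**4
        + 0.00081939 * v**5
    )


def neutral_lab(v) -> np.ndarray:
    """L*a*b* of the neutral (grey) chip at Munsell value ``v``: (L*, 0, 0)."""
    Y = munsell_value_to_Y(v)
    xyy = np.column_stack(
        [np.full_like(Y, ILLUMINANT_C.x), np.full_like(Y, ILLUMINANT_C.y), Y]
    )
    lab = xyy_to_lab(xyy)
    lab[:, 1:] = 0.0  # exactly achromatic by construction
    return lab


@dataclass
class StimulusSet:
    """An ordered collection of distinct colour stimuli.

    ``labs`` is the (n, 3) array of L*a*b* coordinates; ``xyy`` and
    ``munsell`` are carried when known (renotation input), ``None``
    otherwise (rotated or synthetic sets).
    """

    labs: np.ndarray
    label: str = "real"
    xyy: np.ndarray | None = None
    munsell: list[tuple[str, float, float]] | None = None

    def __post_init__(self) -> None:
        self.labs = np.asarray(self.labs, dtype=float)
        if self.labs.ndim != 2 or self.labs.shape[1] != 3:
            raise ValueError("labs must be an (n, 3) array")
        if not np.all(np.isfinite(self.labs)):
            raise ValueError("non-finite Lab coordinate in stimulus set")

    @property
    def n(self) -> int:
        return len(self.labs)

    def __len__(self) -> int:
        return len(self.labs)

    def assert_distinct(self, tol: float = DISTINCT_TOL) -> None:
        """Raise if any two stimuli are closer than ``tol`` in Lab."""
        from scipy.spatial import cKDTree

        pairs = cKDTree(self.labs).query_pairs(tol)
        if pairs:
            raise ValueError(f"{len(pairs)} indistinct stimulus pairs (tol {tol})")

    def to_frame(self) -> pd.DataFrame:
        """Tabular form with columns id, munsell_h/v/c, x, y, Y, L, a, b."""
        n = self.n
        mh = [m[0] for m in self.munsell] if self.munsell else [""] * n
        mv = [m[1] for m in self.munsell] if self.munsell else [np.nan] * n
        mc = [m[2] for m in self.munsell] if self.munsell else [np.nan] * n
        xyy = self.xyy if self.xyy is not None else np.full((n, 3), np.nan)
        return pd.DataFrame(
            {
                "id": np.arange(n),
                "munsell_h": mh,
                "munsell_v": mv,
                "munsell_c": mc,
                "x": xyy[:, 0],
                "y": xyy[:, 1],
                "Y": xyy[:, 2],
                "L": self.labs[:, 0],
                "a": self.labs[:, 1],
                "b": self.labs[:, 2],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str | None = None) -> "StimulusSet":
        df = pd.read_csv(path)
        labs = df[["L", "a", "b"]].to_numpy(dtype=float)
        xyy = df[["x", "y", "Y"]].to_numpy(dtype=float)
        if np.all(np.isnan(xyy)):
            xyy = None
        munsell = None
        if "munsell_h" in df and df["munsell_h"].notna().any():
            munsell = list(
                zip(
                    df["munsell_h"].fillna("").astype(str),
                    df["munsell_v"].to_numpy(dtype=float),
                    df["munsell_c"].to_numpy(dtype=float),
                )
            )
        return cls(labs=labs, label=label or "real", xyy=xyy, munsell=munsell)


def load_renotation(path) -> StimulusSet:
    """Load a Munsell renotation table (whitespace columns H V C x y Y).

    Each row becomes one stimulus; L*a*b* is computed from xyY under
    illuminant C.  Malformed rows raise with the offending line number;
    rows duplicating an existing Lab coordinate are dropped with a warning.
    """
    path = Path(path)
    rows: list[tuple[str, float, float, float, float, float]] = []
    with open(path) as fh:
        lines = fh.readlines()
    # skip a header line (non-numeric second field)
    start = 0
    if lines:
        parts = lines[0].split()
        if len(parts) >= 2:
            try:
                float(parts[1])
            except ValueError:
                start = 1
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ValueError(f"{path.name}: malformed row at line {ln}: expected 6 fields, got {len(parts)}")
        h = parts[0]
        try:
            v, c, x, y, Y = (float(t) for t in parts[1:])
        except ValueError as exc:
            raise ValueError(f"{path.name}: malformed row at line {ln}: {exc}") from None
        rows.append((h, v, c, x, y, Y))
    if not rows:
        raise ValueError(f"{path.name}: no stimulus rows found")
    xyy = np.array([(r[3], r[4], r[5]) for r in rows], dtype=float)
    labs = xyy_to_lab(xyy)
    munsell = [(r[0], r[1], r[2]) for r in rows]
    # deduplicate identical Lab coordinates (keep first occurrence)
    _, first = np.unique(np.round(labs / DISTINCT_TOL).astype(np.int64), axis=0, return_index=True)
    if len(first) < len(labs):
        dropped = len(labs) - len(first)
        warnings.warn(f"{path.name}: dropped {dropped} duplicate stimuli", stacklevel=2)
        keep = np.sort(first)
        labs, xyy = labs[keep], xyy[keep]
        munsell = [munsell[i] for i in keep]
    return StimulusSet(labs=labs, label="real", xyy=xyy, munsell=munsell)


def write_renotation(stimuli: StimulusSet, path) -> None:
    """Write a stimulus set back out in the renotation dialect (H V C x y Y)."""
    if stimuli.munsell is None or stimuli.xyy is None:
        raise ValueError("renotation output needs Munsell notations and xyY coordinates")
    with open(path, "w") as fh:
        fh.write("h V C x y Y\n")
        for (h, v, c), (x, y, Y) in zip(stimuli.munsell, stimuli.xyy):
            fh.write(f"{h} {v:g} {c:g} {x:.6f} {y:.6f} {Y:.6f}\n")


def randomise_stimuli(stimuli: StimulusSet, seed: int) -> StimulusSet:
    """Rotate every stimulus about L* by its own uniform(0, 360) angle.

    Angles come from a counter-based (Philox) stream keyed by ``seed``, so
    the angle of stimulus i depends only on (seed, i).  L* and per-stimulus
    chroma radii are preserved exactly; the displacement of the set (and
    hence all pairwise perceptual distances) is destroyed.
    """
    rng = np.random.Generator(np.random.Philox(key=seed))
    angles = rng.uniform(0.0, 360.0, size=stimuli.n)
    labs = rotate_about_L(stimuli.labs, angles)
    return StimulusSet(labs=labs, label="randomised")


def synth_stimuli(
    n: int = 300,
    n_clusters: int = 6,
    spread: float = 0.3,
    seed: int = 0,
) -> StimulusSet:
    """Clustered synthetic stimulus set emulating a non-uniform displacement.

    ``n`` points are Gaussian-scattered (sd ``spread``, in Lab units) around
    ``n_clusters`` well-separated centres placed inside the working gamut
    region (L* in [10, 95], chroma radius <= 100).  Points are
    rejection-sampled to pairwise distinctness.
    """
    if not (n >= n_clusters >= 1):
        raise ValueError("need n >= n_clusters >= 1")
    rng = np.random.default_rng(seed)
    centres = np.empty((n_clusters, 3))
    placed = 0
    for _ in range(10000):
        if placed == n_clusters:
            break
        L = rng.uniform(20.0, 85.0)
        theta = rng.uniform(0.0, 2 * np.pi)
        r = rng.uniform(20.0, 70.0)
        cand = np.array([L, r * np.cos(theta), r * np.sin(theta)])
        if placed == 0 or np.min(np.linalg.norm(centres[:placed] - cand, axis=1)) >= 25.0:
            centres[placed] = cand
            placed += 1
    if placed < n_clusters:
        raise ValueError("could not place well-separated cluster centres")
    assign = rng.integers(n_clusters, size=n)
    pts = centres[assign] + rng.normal(0.0, spread, size=(n, 3))
    pts[:, 0] = np.clip(pts[:, 0], 0.5, 100.0)
    # enforce pairwise distinctness by resampling offenders
    from scipy.spatial import cKDTree

    for _ in range(100):
        pairs = cKDTree(pts).query_pairs(DISTINCT_TOL)
        if not pairs:
            break
        bad = sorted({j for _, j in pairs})
        pts[bad] = centres[assign[bad]] + rng.normal(0.0, spread, size=(len(bad), 3))
        pts[bad, 0] = np.clip(pts[bad, 0], 0.5, 100.0)
    else:
        raise ValueError("could not achieve pairwise-distinct stimuli at this density")
    return StimulusSet(labs=pts, label="synthetic")


def synth_renotation_table(seed: int = 0, jitter: float = 0.0) -> pd.DataFrame:
    """A small synthetic table in the renotation dialect (H V C x y Y).

    Covers every WCS hue at every chromatic row value with two chroma levels,
    so :func:`build_wcs_chip_array` accepts it.  Lab coordinates are laid out
    on a Munsell-like lattice (constant L* per value, hue angle per column)
    and converted to xyY, so loading the table reproduces them.  This is a
    synthetic stand-in for the hosted renotation data, not a copy of it.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for v in WCS_ROW_VALUES:
        Y = float(munsell_value_to_Y(v))
        for j, hue in enumerate(WCS_HUES):
            theta = 2 * np.pi * j / len(WCS_HUES)
            # radius 2.5 * chroma keeps even the darkest row inside the gamut
            for c in (4.0, 8.0):
                r = 2.5 * c + (rng.uniform(-jitter, jitter) if jitter else 0.0)
                lab = np.array([[0.0, r * np.cos(theta), r * np.sin(theta)]])
                lab[0, 0] = xyy_to_lab(np.array([[ILLUMINANT_C.x, ILLUMINANT_C.y, Y]]))[0, 0]
                x, y, _Y = lab_to_xyy(lab)[0]
                rows.append((hue, v, c, x, y, Y))
    return pd.DataFrame(rows, columns=["h", "V", "C", "x", "y", "Y"])


def write_synth_renotation(path, seed: int = 0) -> None:
    """Write the synthetic renotation-dialect table of :func:`synth_renotation_table`."""
    df = synth_renotation_table(seed=seed)
    with open(path, "w") as fh:
        fh.write("h V C x y Y\n")
        for h, v, c, x, y, Y in df.itertuples(index=False):
            fh.write(f"{h} {v:g} {c:g} {x:.6f} {y:.6f} {Y:.6f}\n")


# ---------------------------------------------------------------------------
# The 330-chip array


@dataclass
class ChipArray:
    """The WCS Munsell stimulus array: 8 x 40 chromatic chips + 10 greys.

    Rows are lightness levels 0 (white) to 9 (black); rows 1-8 carry the 40
    chromatic hue columns, rows 0 and 9 are achromatic-only.  ``col`` is the
    hue column (0-39) for chromatic chips and -1 for achromatic chips.
    """

    labs: np.ndarray  # (330, 3)
    row: np.ndarray  # (330,) int, 0..9
    col: np.ndarray  # (330,) int, 0..39 chromatic, -1 achromatic
    notation: list[str] = field(default_factory=list)

    N_ROWS = 10
    N_CHROMATIC_ROWS = 8
    N_COLS = 40

    def __post_init__(self) -> None:
        self.labs = np.asarray(self.labs, dtype=float)
        self.row = np.asarray(self.row, dtype=int)
        self.col = np.asarray(self.col, dtype=int)
        if len(self.labs) != 330:
            raise ValueError(f"chip array needs 330 chips, got {len(self.labs)}")
        chrom = self.col >= 0
        if chrom.sum() != 320 or (~chrom).sum() != 10:
            raise ValueError("chip array needs 320 chromatic + 10 achromatic chips")
        # constant L* per chromatic row
        for r in range(1, 9):
            Ls = self.labs[(self.row == r) & chrom, 0]
            if len(Ls) != self.N_COLS:
                raise ValueError(f"row {r} must hold {self.N_COLS} chromatic chips")
            if np.ptp(Ls) > 1e-6:
                raise ValueError(f"row {r} L* not constant (spread {np.ptp(Ls):.3g})")
        # caches for projection
        self.row_L = np.empty(self.N_ROWS)
        self.achromatic_idx = np.empty(self.N_ROWS, dtype=int)
        self.chrom_idx = np.full((self.N_ROWS, self.N_COLS), -1, dtype=int)
        for r in range(self.N_ROWS):
            ach = np.flatnonzero((self.row == r) & ~chrom)
            if len(ach) != 1:
                raise ValueError(f"row {r} must hold exactly one achromatic chip")
            self.achromatic_idx[r] = ach[0]
            self.row_L[r] = self.labs[ach[0], 0]
            for i in np.flatnonzero((self.row == r) & chrom):
                self.chrom_idx[r, self.col[i]] = i
        self.angles = np.arctan2(self.labs[:, 2], self.labs[:, 1])
        self.radii = np.hypot(self.labs[:, 1], self.labs[:, 2])

    @property
    def n(self) -> int:
        return len(self.labs)

    @classmethod
    def synthetic(cls, seed: int = 0) -> "ChipArray":
        """A constructed 8x40+10 chip array for download-free runs and tests."""
        rng = np.random.default_rng(seed)
        labs, rows, cols, notation = [], [], [], []
        neutral_L = neutral_lab(np.asarray(WCS_NEUTRAL_VALUES))[:, 0]
        chrom_L = neutral_L[1:9]  # rows 1..8 share the grey ladder L*
        for r in range(10):
            labs.append([neutral_L[r], 0.0, 0.0])
            rows.append(r)
            cols.append(-1)
            notation.append(f"N{WCS_NEUTRAL_VALUES[r]:g}")
        radii = rng.uniform(15.0, 60.0, size=(8, 40))
        for r in range(8):
            for j in range(40):
                theta = 2 * np.pi * j / 40
                labs.append(
                    [chrom_L[r], radii[r, j] * np.cos(theta), radii[r, j] * np.sin(theta)]
                )
                rows.append(r + 1)
                cols.append(j)
                notation.append(f"{WCS_HUES[j]} {WCS_ROW_VALUES[r]:g}/synthetic")
        return cls(np.array(labs), np.array(rows), np.array(cols), notation)


_HUE_RE = re.compile(r"^(\d+(?:\.\d+)?)([A-Z]+)$")


def _canon_hue(h: str) -> str:
    m = _HUE_RE.match(h.strip().upper())
    if not m:
        return h.strip().upper()
    return f"{float(m.group(1)):g}{m.group(2)}"


def build_wcs_chip_array(renotation: StimulusSet) -> ChipArray:
    """Select the 330 WCS chips from a renotation stimulus set.

    For each of the 40 WCS hues and 8 chromatic row values the maximally
    saturated chip (largest chroma present in the table) is taken; the 10
    achromatic levels are constructed from the Munsell value -> Y relation.
    Raises listing the missing (hue, value) notations if the table lacks any.
    """
    if renotation.munsell is None:
        raise ValueError("renotation stimulus set lacks Munsell notations")
    by_hv: dict[tuple[str, float], tuple[float, int]] = {}
    for i, (h, v, c) in enumerate(renotation.munsell):
        key = (_canon_hue(h), float(v))
        if key not in by_hv or c > by_hv[key][0]:
            by_hv[key] = (float(c), i)
    missing = [
        f"{hue} {v:g}/"
        for v in WCS_ROW_VALUES
        for hue in WCS_HUES
        if (_canon_hue(hue), v) not in by_hv
    ]
    if missing:
        raise ValueError(
            f"renotation table lacks {len(missing)} WCS chips: {', '.join(missing[:8])}"
            + (" ..." if len(missing) > 8 else "")
        )
    labs, rows, cols, notation = [], [], [], []
    neutral_L = neutral_lab(np.asarray(WCS_NEUTRAL_VALUES))[:, 0]
    for r in range(10):
        labs.append([neutral_L[r], 0.0, 0.0])
        rows.append(r)
        cols.append(-1)
        notation.append(f"N{WCS_NEUTRAL_VALUES[r]:g}")
    for r, v in enumerate(WCS_ROW_VALUES, start=1):
        row_L = None
        for j, hue in enumerate(WCS_HUES):
            c, i = by_hv[(_canon_hue(hue), v)]
            lab = renotation.labs[i].copy()
            if row_L is None:
                row_L = lab[0]
            lab[0] = row_L  # row L* is constant by construction of the table
            labs.append(lab)
            rows.append(r)
            cols.append(j)
            notation.append(f"{hue} {v:g}/{c:g}")
    return ChipArray(np.array(labs), np.array(rows), np.array(cols), notation)


__all__ = [
    "DISTINCT_TOL",
    "WCS_HUES",
    "WCS_ROW_VALUES",
    "WCS_NEUTRAL_VALUES",
    "munsell_value_to_Y",
    "neutral_lab",
    "StimulusSet",
    "load_renotation",
    "write_renotation",
    "randomise_stimuli",
    "synth_stimuli",
    "synth_renotation_table",
    "write_synth_renotation",
    "ChipArray",
    "build_wcs_chip_array",
]
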