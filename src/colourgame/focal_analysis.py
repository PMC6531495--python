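"""Focal colours and the cross-language dispersion statistic.

Each simulation run is treated as one "language".  Its focal colours are the
top-M stimuli by the (normalised) proportion of agents whose term centroids
snap onto them, with M the rounded population-average number of categories.
The cross-language dispersion D of a set of languages accumulates, over all
ordered pairs of distinct languages, the minimum Euclidean Lab distance from
each focal colour of one language to the focal colours of the other:

    D = sum_{l1 != l2} sum_{c1 in l1} min_{c2 in l2} DeltaE(c1, c2)

Small D means the languages' focal colours are mutually aligned.  Its
significance is read off an empirical null of rotation-randomised language
sets: every language's foci rotated about L* by its own shared random angle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .category_game import SimResult, count_categories
from .colour_space import cie94_matrix, rotate_about_L
from .stimuli import StimulusSet


@dataclass
class EmergentLanguage:
    """One run's focal colours: M Lab points, each snapped to an input stimulus."""

    language_id: str
    foci: np.ndarray  # (M, 3)

    def __post_init__(self) -> None:
        self.foci = np.atleast_2d(np.asarray(self.foci, dtype=float))
        if self.foci.shape[0] < 1 or self.foci.shape[1] != 3:
            raise ValueError("a language needs at least one (L, a, b) focus")

    @property
    def M(self) -> int:
        return len(self.foci)


@dataclass
class LanguageSet:
    """A collection of languages with a provenance tag."""

    languages: list[EmergentLanguage]
    provenance: str = "real"

    def __post_init__(self) -> None:
        if not self.languages:
            raise ValueError("language set must be non-empty")

    def __len__(self) -> int:
        return len(self.languages)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (lang.language_id, k, *focus)
            for lang in self.languages
            for k, focus in enumerate(lang.foci)
        ]
        return pd.DataFrame(rows, columns=["language_id", "focus_index", "L", "a", "b"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "real") -> "LanguageSet":
        df = pd.read_csv(path)
        langs = []
        for lid, grp in df.groupby("language_id", sort=False):
            langs.append(EmergentLanguage(str(lid), grp[["L", "a", "b"]].to_numpy(float)))
        return cls(langs, provenance=provenance)


def read_focal_csv(path, provenance: str = "external") -> LanguageSet:
    """Import externally supplied foci (columns language_id, L, a, b)."""
    df = pd.read_csv(path)
    langs = [
        EmergentLanguage(str(lid), grp[["L", "a", "b"]].to_numpy(float))
        for lid, grp in df.groupby("language_id", sort=False)
    ]
    return LanguageSet(langs, provenance=provenance)


def focal_proportions(result: SimResult, stimuli: StimulusSet) -> np.ndarray:
    """Per-stimulus proportion of agents assigning it as a focal colour.

    For every agent and term, the centroid of the term's stimuli is snapped
    to the input stimulus at minimum CIE94 distance (centroid as reference);
    the per-stimulus counts of distinct assigning agents are normalised to
    sum to one.
    """
    if not result.population or all(not ag.assoc for ag in result.population):
        raise ValueError("blank population: no focal colours to extract")
    labs = stimuli.labs
    counts = np.zeros(stimuli.n)
    for agent in result.population:
        by_term: dict[int, list[int]] = {}
        for s, terms in agent.assoc.items():
            for t in terms:
                by_term.setdefault(t, []).append(s)
        hit: set[int] = set()
        for members in by_term.values():
            centroid = labs[members].mean(axis=0)
            snapped = int(np.argmin(cie94_matrix(centroid[None], labs)[0]))
            hit.add(snapped)
        for s in hit:
            counts[s] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no focal assignments in population")
    return counts / total


def extract_focal_colours(
    result: SimResult, stimuli: StimulusSet, language_id: str | None = None
) -> EmergentLanguage:
    """Top-M stimuli by focal proportion, M = rounded mean category count."""
    props = focal_proportions(result, stimuli)
    m = max(1, round(float(count_categories(result.population))))  # ties to even
    order = np.lexsort((np.arange(stimuli.n), -props))
    chosen = order[:m]
    lid = language_id if language_id is not None else f"run-{result.seed}"
    return EmergentLanguage(lid, stimuli.labs[chosen])


def _euclidean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return cdist(a, b)


def dispersion(
    languages: LanguageSet | Sequence[EmergentLanguage],
    metric: str | Callable[[np.ndarray, np.ndarray], np.ndarray] = "euclidean",
) -> float:
    """Cross-language dispersion D over ordered language pairs.

    ``metric`` is the Lab distance used between foci: ``"euclidean"`` (the
    statistic's definition), ``"cie94"`` for a sensitivity check, or a
    callable returning a pairwise matrix.
    """
    langs = languages.languages if isinstance(languages, LanguageSet) else list(languages)
    if len(langs) < 2:
        raise ValueError("dispersion needs at least 2 languages")
    if callable(metric):
        dist = metric
    elif metric == "euclidean":
        dist = _euclidean
    elif metric == "cie94":
        dist = lambda a, b: cie94_matrix(a, b)  # noqa: E731
    else:
        raise ValueError(f"unknown metric {metric!r}")
    total = 0.0
    for i, l1 in enumerate(langs):
        for j, l2 in enumerate(langs):
            if i == j:
                continue
            total += float(dist(l1.foci, l2.foci).min(axis=1).sum())
    return total


def randomise_language_foci(
    lang: EmergentLanguage, seed: int | None = None, rng: np.random.Generator | None = None
) -> EmergentLanguage:
    """Rotate all of a language's foci about L* by one shared random angle.

    The rotation preserves every within-language distance (self-structure)
    while destroying alignment with other languages.  No snapping to stimuli
    is applied: the rotated foci are abstract comparison points.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    angle = rng.uniform(0.0, 360.0)
    return EmergentLanguage(lang.language_id, rotate_about_L(lang.foci, angle))


def make_foci_rotation_null(languages: LanguageSet, seed: int) -> LanguageSet:
    """One null set: every language rotated by its own shared random angle."""
    rng = np.random.default_rng(seed)
    return LanguageSet(
        [randomise_language_foci(lang, rng=rng) for lang in languages.languages],
        provenance="randomised-foci",
    )


@dataclass
class ComparisonReport:
    """Dispersion of a real language set against an empirical null."""

    d_real: float
    null_dispersions: list[float]
    mode: str
    seed: int
    metric: str = "euclidean"

    @property
    def n_null(self) -> int:
        return len(self.null_dispersions)

    @property
    def rank(self) -> int:
        """Number of null dispersions <= D_real."""
        return int(sum(d <= self.d_real for d in self.null_dispersions))

    @property
    def p_value(self) -> float:
        """Empirical upper bound (rank + 1) / (n_null + 1); < 1/n_null when rank 0."""
        return (self.rank + 1) / (self.n_null + 1)

    @property
    def mean_null(self) -> float:
        return float(np.mean(self.null_dispersions))

    @property
    def ratio(self) -> float:
        """mean(D_null) / D_real; > 1 when the real set is the tighter one."""
        if self.d_real == 0:
            return float("inf")
        return self.mean_null / self.d_real

    def to_dict(self) -> dict:
        return {
            "d_real": self.d_real,
            "d_real_unordered": self.d_real / 2.0,
            "null_dispersions": list(self.null_dispersions),
            "mean_null": self.mean_null,
            "ratio": self.ratio,
            "rank": self.rank,
            "p_value": self.p_value,
            "mode": self.mode,
            "metric": self.metric,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def dispersion_comparison(
    real: LanguageSet,
    n_null: int = 20,
    mode: str = "foci-rotation",
    seed: int = 0,
    null_sets: Sequence[LanguageSet] | None = None,
    null_factory: Callable[[int], LanguageSet] | None = None,
    metric: str = "euclidean",
) -> ComparisonReport:
    """Compare D of a real language set against ``n_null`` null sets.

    ``mode='foci-rotation'`` builds the nulls internally by per-language
    rotation; ``mode='stimulus-rotation'`` requires the caller to supply
    pre-computed ``null_sets`` (language sets simulated under rotated
    stimuli) or a seeded ``null_factory``.
    """
    if n_null < 1:
        raise ValueError("need at least one null set")
    d_real = dispersion(real, metric=metric)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_null)]
    nulls: list[float] = []
    if null_sets is not None:
        if len(null_sets) < n_null:
            raise ValueError("fewer null_sets supplied than n_null")
        nulls = [dispersion(ns, metric=metric) for ns in list(null_sets)[:n_null]]
    elif mode == "foci-rotation":
        for s in child_seeds:
            nulls.append(dispersion(make_foci_rotation_null(real, s), metric=metric))
    elif mode == "stimulus-rotation":
        if null_factory is None:
            raise ValueError("stimulus-rotation mode needs null_sets or a null_factory")
        for s in child_seeds:
            nulls.append(dispersion(null_factory(s), metric=metric))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ComparisonReport(d_real, nulls, mode=mode, seed=seed, metric=metric)


__all__ = [
    "EmergentLanguage",
    "LanguageSet",
    "read_focal_csv",
    "focal_proportions",
    "extract_focal_colours",
    "dispersion",
    "randomise_language_foci",
    "make_foci_rotation_null",
    "ComparisonReport",
    "dispersion_comparison",
]
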