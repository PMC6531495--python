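"""The exemplar-based linguistic category game.

A population of agents plays iterated pairwise discrimination episodes over
a fixed set of colour stimuli.  Each agent keeps an exemplar lexicon: a map
from stimulus id to the set of term ids it associates with that stimulus.
One episode:

1. A speaker and a hearer are drawn at random, together with a context of
   ``context_size`` distinct stimuli whose pairwise CIE94 distance is at
   least ``d_min`` (a JND-scale discriminability floor), and a topic from
   the context.
2. If the speaker has no term for the topic it generalises: it inherits the
   term of its perceptually nearest labelled exemplar (CIE94), provided that
   exemplar is closer to the topic than every distractor is — otherwise it
   invents a fresh term.  Exemplar generalisation is what lets one term
   come to encode a whole perceptual neighbourhood of stimuli.
3. If the speaker's term set for the topic is entirely contained in some
   distractor's term set, it cannot discriminate and invents a fresh term.
4. The speaker utters one term for the topic, preferring (a) a term that
   labels no distractor in its own lexicon, (b) the most recently successful
   term, (c) a uniform random associated term.
5. The hearer succeeds iff the uttered term labels exactly one context
   stimulus in its lexicon and that stimulus is the topic.  On success both
   agents discard all competing terms for the topic; on failure the topic is
   revealed and the hearer adds the uttered term for it.

Dynamics are summarised per window as (communications per agent, success
rate, mean number of categories, mean number of synonymous terms).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colour_space import cie94_matrix
from .stimuli import StimulusSet

_TERM_STRIDE = 1 << 24  # term id = agent_id * stride + per-agent counter


class Agent:
    """One agent's exemplar lexicon: stimulus id -> list of term ids."""

    __slots__ = ("id", "assoc", "pref", "counter", "_labelled", "_n_labelled")

    def __init__(self, agent_id: int, n_stimuli: int):
        self.id = agent_id
        self.assoc: dict[int, list[int]] = {}
        self.pref: dict[int, int] = {}  # stimulus -> most recently successful term
        self.counter = 0
        self._labelled = np.empty(n_stimuli, dtype=np.intp)
        self._n_labelled = 0

    def invent(self) -> int:
        self.counter += 1
        return self.id * _TERM_STRIDE + self.counter

    def add(self, stim: int, term: int) -> None:
        lst = self.assoc.get(stim)
        if lst is None:
            self.assoc[stim] = [term]
            self._labelled[self._n_labelled] = stim
            self._n_labelled += 1
        elif term not in lst:
            lst.append(term)

    def labelled(self) -> np.ndarray:
        """Stimulus ids this agent has at least one term for."""
        return self._labelled[: self._n_labelled]

    def terms(self) -> set[int]:
        """Distinct terms with a non-empty association."""
        out: set[int] = set()
        for lst in self.assoc.values():
            out.update(lst)
        return out


@dataclass
class GameConfig:
    """Parameters of one simulation run."""

    stimulus_set: StimulusSet
    n_agents: int = 20
    comms_per_agent: int = 1000
    context_size: int = 2
    d_min: float = 1.0
    window: int | None = None  # episodes per checkpoint; default 50 * n_agents
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("need at least 2 agents")
        if self.context_size < 2:
            raise ValueError("context needs at least 2 stimuli")
        if self.d_min < 0:
            raise ValueError("d_min must be non-negative")

    @property
    def effective_window(self) -> int:
        return self.window if self.window is not None else 50 * self.n_agents

    def summary_dict(self) -> dict:
        return {
            "n_agents": self.n_agents,
            "n_stimuli": self.stimulus_set.n,
            "stimulus_label": self.stimulus_set.label,
            "comms_per_agent": self.comms_per_agent,
            "context_size": self.context_size,
            "d_min": self.d_min,
            "window": self.effective_window,
            "seed": self.seed,
        }


@dataclass
class DynamicsTrace:
    """Windowed metrics: (comms per agent, success rate, categories, synonyms)."""

    comms_per_agent: list[float] = field(default_factory=list)
    success_rate: list[float] = field(default_factory=list)
    n_categories: list[float] = field(default_factory=list)
    n_synonyms: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "comms_per_agent": self.comms_per_agent,
                "success_rate": self.success_rate,
                "n_categories": self.n_categories,
                "n_synonyms": self.n_synonyms,
            }
        )


@dataclass
class SimResult:
    """Final population plus its dynamics trace; reproducible from config+seed."""

    population: list[Agent]
    trace: DynamicsTrace
    config: GameConfig
    seed: int

    def save(self, json_path, trace_csv_path=None) -> None:
        payload = {
            "config": self.config.summary_dict(),
            "seed": self.seed,
            "associations": [
                {str(s): lst for s, lst in agent.assoc.items()} for agent in self.population
            ],
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh)
        if trace_csv_path is not None:
            self.trace.to_frame().to_csv(trace_csv_path, index=False)


def play_episode(
    speaker: Agent,
    hearer: Agent,
    context: list[int],
    topic: int,
    rng: random.Random,
    dmat: np.ndarray | None = None,
) -> tuple[bool, int]:
    """Play one discrimination episode; returns (success, uttered term).

    ``dmat`` is the CIE94 distance matrix over the stimulus set (rows are
    the reference colour); without it the generalisation step is skipped
    and an unlabelled topic always triggers invention.
    """
    if len(context) < 2:
        raise ValueError("context needs at least 2 stimuli")
    distractors = [s for s in context if s != topic]

    invented = -1
    tlist = speaker.assoc.get(topic)
    if not tlist:
        inherited = False
        if dmat is not None and speaker._n_labelled > 0:
            ids = speaker.labelled()
            d = dmat[topic, ids]
            j = int(np.argmin(d))
            d_context = min(dmat[topic, s] for s in distractors)
            if d[j] < d_context:
                src = int(ids[j])
                src_terms = speaker.assoc[src]
                term = speaker.pref.get(src, -1)
                if term not in src_terms:
                    term = src_terms[rng.randrange(len(src_terms))]
                speaker.add(topic, term)
                inherited = True
        if not inherited:
            invented = speaker.invent()
            speaker.add(topic, invented)
        tlist = speaker.assoc[topic]
    if invented < 0:
        # discrimination check: topic's terms entirely shared with a distractor
        for s in distractors:
            dlist = speaker.assoc.get(s)
            if dlist and all(t in dlist for t in tlist):
                invented = speaker.invent()
                speaker.add(topic, invented)
                tlist = speaker.assoc[topic]
                break

    # utterance choice
    if invented >= 0:
        uttered = invented
    else:
        discriminating = [
            t
            for t in tlist
            if all(t not in speaker.assoc.get(s, ()) for s in distractors)
        ]
        p = speaker.pref.get(topic, -1)
        if p in discriminating:
            uttered = p
        elif discriminating:
            uttered = discriminating[rng.randrange(len(discriminating))]
        elif p in tlist:
            uttered = p
        else:
            uttered = tlist[rng.randrange(len(tlist))]

    # hearer interpretation: uttered term must pick out the topic uniquely
    h_topic = hearer.assoc.get(topic)
    success = h_topic is not None and uttered in h_topic
    if success:
        for s in distractors:
            h_d = hearer.assoc.get(s)
            if h_d and uttered in h_d:
                success = False
                break

    if success:
        speaker.assoc[topic] = [uttered]
        hearer.assoc[topic] = [uttered]
        speaker.pref[topic] = uttered
        hearer.pref[topic] = uttered
    else:
        hearer.add(topic, uttered)
    return success, uttered


def count_categories(population: list[Agent]) -> float:
    """Mean over agents of the number of distinct terms in use."""
    if not population:
        return 0.0
    return float(np.mean([len(agent.terms()) for agent in population]))


def count_synonyms(population: list[Agent], reading: str = "polysemy") -> float:
    """Mean number of synonymous terms per agent.

    ``reading='polysemy'`` (default, the literal definition): terms that
    encode more than one stimulus.  ``reading='competition'``: stimuli that
    carry more than one term.
    """
    if not population:
        return 0.0
    vals = []
    for agent in population:
        if reading == "polysemy":
            cover: dict[int, int] = {}
            for lst in agent.assoc.values():
                for t in lst:
                    cover[t] = cover.get(t, 0) + 1
            vals.append(sum(1 for k in cover.values() if k >= 2))
        elif reading == "competition":
            vals.append(sum(1 for lst in agent.assoc.values() if len(lst) >= 2))
        else:
            raise ValueError(f"unknown synonym reading {reading!r}")
    return float(np.mean(vals))


def success_rate(successes: int, episodes: int) -> float:
    """Fraction of successful communications in a window."""
    if episodes <= 0:
        return 0.0
    return successes / episodes


def _valid_pairs(dmat: np.ndarray, d_min: float) -> tuple[np.ndarray, np.ndarray]:
    """Ordered stimulus pairs whose CIE94 distance (both directions) >= d_min."""
    ok = (dmat >= d_min) & (dmat.T >= d_min)
    np.fill_diagonal(ok, False)
    idx = np.argwhere(ok)
    return idx[:, 0].copy(), idx[:, 1].copy()


def run_simulation(config: GameConfig) -> SimResult:
    """Run one category-game simulation to ``comms_per_agent * n_agents`` episodes."""
    stim = config.stimulus_set
    n_stim = stim.n
    labs = stim.labs
    dmat = cie94_matrix(labs)
    rng = random.Random(config.seed)
    n_agents = config.n_agents
    population = [Agent(i, n_stim) for i in range(n_agents)]
    trace = DynamicsTrace()
    total = config.comms_per_agent * n_agents
    if total == 0:
        return SimResult(population, trace, config, config.seed)

    window = config.effective_window
    ctx_size = config.context_size
    if ctx_size == 2:
        pi, pj = _valid_pairs(dmat, config.d_min)
        n_pairs = len(pi)
        if n_pairs == 0:
            raise ValueError("no context satisfies the d_min constraint")
    else:
        sym = np.minimum(dmat, dmat.T)
        np.fill_diagonal(sym, np.inf)

    randrange = rng.randrange
    successes = 0
    in_window = 0
    for ep in range(total):
        s_idx = randrange(n_agents)
        h_idx = randrange(n_agents - 1)
        if h_idx >= s_idx:
            h_idx += 1
        if ctx_size == 2:
            k = randrange(n_pairs)
            topic, distractor = int(pi[k]), int(pj[k])
            context = [topic, distractor]
        else:
            context = _draw_context(rng, sym, n_stim, ctx_size, config.d_min)
            topic = context[randrange(ctx_size)]
        ok, _ = play_episode(
            population[s_idx], population[h_idx], context, topic, rng, dmat
        )
        successes += ok
        in_window += 1
        if in_window == window or ep == total - 1:
            trace.comms_per_agent.append((ep + 1) / n_agents)
            trace.success_rate.append(success_rate(successes, in_window))
            trace.n_categories.append(count_categories(population))
            trace.n_synonyms.append(count_synonyms(population))
            successes = 0
            in_window = 0
    return SimResult(population, trace, config, config.seed)


def _draw_context(
    rng: random.Random, sym: np.ndarray, n_stim: int, k: int, d_min: float
) -> list[int]:
    """Rejection-sample k distinct stimuli with pairwise distance >= d_min."""
    for _ in range(100000):
        ctx = rng.sample(range(n_stim), k)
        if sym[np.ix_(ctx, ctx)].min() >= d_min:
            return ctx
    raise ValueError("no context satisfies the d_min constraint")


__all__ = [
    "Agent",
    "GameConfig",
    "DynamicsTrace",
    "SimResult",
    "play_episode",
    "run_simulation",
    "success_rate",
    "count_categories",
    "count_synonyms",
]
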