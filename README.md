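# colourgame

An agent-based, exemplar-based **colour category game** in CIE L\*a\*b\* space,
with the comparison toolkit needed to ask whether emergent colour categories
are *universal*: cross-language dispersion with rotation-randomised nulls,
focal-colour distributions on the 330-chip Munsell (WCS) stimulus array, and
a weighted peak-to-peak distance between distribution grids.

It is aimed at computational cognitive scientists and students of cultural
language evolution who want to simulate how a population of agents, playing
iterated pairwise discrimination games over a fixed set of physical colour
stimuli, converges on shared colour terms — and to measure how strongly the
emergent focal colours are shaped by the perceptual displacement of the
stimuli rather than by the communication process itself.

## The model and statistics

**Category game.** Each agent keeps an exemplar lexicon mapping stimulus →
set of terms. Per episode a speaker names a topic against distractors (all
context stimuli at least `d_min` apart in CIE94 ΔE, a just-noticeable-
difference floor). A speaker without a term for the topic inherits the term
of its perceptually nearest labelled exemplar when that exemplar is closer
than every distractor (exemplar generalisation), otherwise it invents; a
speaker whose topic terms are all shared with a distractor invents. The
hearer succeeds iff the uttered term picks out the topic uniquely; success
makes both agents discard competing terms for the topic, failure makes the
hearer adopt the term. Agent perception uses CIE94 (graphic-arts constants);
the stimuli live in L\*a\*b\* under illuminant C / 2° observer.

**Cross-language dispersion.** Each run is a "language" whose focal colours
are the top-M stimuli by the proportion of agents whose per-term centroids
snap onto them (M = rounded mean category count). For a set S of languages,

    D = Σ_{l1≠l2} Σ_{c1∈l1} min_{c2∈l2} ΔE(c1, c2),

with ΔE the Euclidean L\*a\*b\* distance. Small D = tightly clustered focal
colours across languages. Significance comes from rotation nulls: rotating
each language's foci about the L\* axis by its own random angle (preserving
every within-language distance) or re-running the game on stimuli rotated
per-stimulus (destroying the perceptual displacement entirely).

**Chip grids and peaks.** Lab points project onto the WCS chip array by
nearest lightness row, then nearest hue angle, then nearest chroma radius.
Per-chip focal counts are normalised by how many stimuli project there.
Grid peaks (strict four-neighbour maxima, hue-circular) are compared by

    d(P, Q) = W_P Σ_{p∈P} min_q ΔE_{p,q} + W_Q Σ_{q∈Q} min_p ΔE_{p,q},
    W_P = |P| / (|P| + |Q|),

on grid coordinates.

## Worked example

```python
import numpy as np
from colourgame import synth_stimuli, universality_experiment

stimuli = synth_stimuli(n=300, n_clusters=6, spread=0.3, seed=1)
report = universality_experiment(stimuli, n_runs=10, n_null=20,
                                 n_agents=8, comms_per_agent=600, seed=42)
print(f"D_real                = {report.d_real:.1f}")
print(f"D_randomised_stimuli  = {report.d_rand:.1f}")
print(f"ratio (rand / real)   = {report.ratio_stimulus_rotation:.2f}")
print(f"foci-rotation nulls   : rank {report.foci_rotation.rank} of "
      f"{report.foci_rotation.n_null}, p <= {report.foci_rotation.p_value:.3f}")
```

prints

```
D_real                = 1719.5
D_randomised_stimuli  = 43687.6
ratio (rand / real)   = 25.41
foci-rotation nulls   : rank 0 of 20, p <= 0.048
```

The ten languages that emerged under the clustered ("real") stimuli
disperse ~25× less than the ten that emerged under a per-stimulus rotation
randomisation of the same stimuli, and beat all 20 foci-rotation null sets:
the perceptual displacement of the stimuli, not the communication dynamics,
fixes where the focal colours land.

There is also a CLI (`colourgame simulate / randomise-stimuli / analyse /
compare / fixtures`); see `colourgame --help`. Real Munsell renotation
tables (whitespace `H V C x y Y` columns) load with
`colourgame.load_renotation`, and external focal-colour tables
(`language_id, L, a, b` CSV) with `colourgame.read_focal_csv`.

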