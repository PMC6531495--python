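# Methods

## The model

A fixed set of `n` distinct colour stimuli lives in CIE L\*a\*b\* (white
point: illuminant C, 1931 2° observer, chromaticity (0.31006, 0.31616),
Y = 100). Agents perceive stimulus differences through the CIE94 formula
with graphic-arts constants (kL = kC = kH = 1, K1 = 0.045, K2 = 0.015).
CIE94 is asymmetric in its reference colour; the package uses the first
argument as reference throughout (the topic, or the query point when
snapping), and exposes a symmetrised geometric-mean-chroma variant behind
`symmetric=True` for sensitivity checks. Plain Euclidean Lab distance is
used only by the dispersion statistic, which historically was defined with
it.

Each agent holds an exemplar lexicon, a map stimulus → list of terms, plus
a record of the most recently successful term per stimulus. One episode:

1. **Pairing and context.** Speaker and hearer are drawn uniformly without
   replacement; a context of `context_size` (default 2) distinct stimuli
   with pairwise CIE94 distance ≥ `d_min` is drawn uniformly, and the topic
   uniformly from the context.
2. **Exemplar generalisation.** If the speaker has no term for the topic,
   it looks up its perceptually nearest labelled exemplar. If that exemplar
   is closer to the topic than every distractor is, the speaker extends
   that exemplar's (preferred) term to the topic; otherwise it invents a
   fresh term. This single parameter-free rule is what lets one term grow
   to encode a perceptual neighbourhood: it is the channel through which
   the geometry of the stimulus set — and nothing else — enters category
   formation. Without it every term would forever name exactly one
   stimulus, the lexicon would converge to one term per stimulus, and no
   measure of cross-run clustering could distinguish structured from
   randomised stimuli.
3. **Discrimination.** If the speaker's term set for the topic is entirely
   contained in some distractor's set, the speaker invents a fresh term for
   the topic (it cannot discriminate otherwise).
4. **Utterance.** Just-invented term if any; else a term labelling no
   distractor in the speaker's own lexicon (preferring the most recently
   successful, then uniform random among discriminating terms); else the
   most recently successful term; else uniform random. Preferring
   discriminating terms is needed so that within-category contexts can
   eventually be resolved instead of deadlocking on the habitual term.
5. **Resolution.** The hearer succeeds iff the uttered term labels exactly
   one context stimulus in its lexicon and that stimulus is the topic. On
   success both agents delete all competing terms for the topic and record
   the winner as preferred. On failure the topic is revealed and the hearer
   adds the uttered term for it.

Term ids are `agent_id * 2^24 + counter`, globally unique without
coordination. "Communications per agent" is total episodes / population
size. Metrics are recorded every `window` episodes (default
50 × `n_agents`): windowed success rate, mean number of distinct terms per
agent (categories), and mean number of terms encoding ≥ 2 stimuli per agent
(synonymous terms, the literal polysemy reading; the conventional reading —
stimuli carrying more than one term — is available via
`count_synonyms(..., reading="competition")`).

### Tunable parameters

| parameter         | default        | units  | rationale |
|-------------------|----------------|--------|-----------|
| `context_size`    | 2              | stimuli| minimal discrimination setting (topic + one distractor); configurable |
| `d_min`           | 1.0            | CIE94 ΔE | JND-scale floor so context stimuli are discriminable; 0 disables |
| `window`          | 50 × n_agents  | episodes | one checkpoint per ~50 communications per agent |
| `n_agents`        | 20             | agents | desk-scale default; the study design also uses 8 for replicate batches |
| `comms_per_agent` | 1000           | episodes/agent | enough for convergence on a few hundred clustered stimuli |

## Randomisation operators

*Per-stimulus rotation* rotates each stimulus about the L\* axis by its own
uniform(0, 360°) angle from a counter-based (Philox) stream keyed by the
seed, so each stimulus's angle depends only on (seed, index). L\* and
chroma radii are preserved exactly; the displacement (all pairwise
distances) is destroyed. *Per-language foci rotation* rotates all of a
language's focal colours by one shared angle, preserving within-language
structure while destroying cross-language alignment; rotated foci are
abstract comparison points and are not snapped back to stimuli.

## Focal colours and dispersion

Per agent and term, the centroid of the term's exemplars is snapped to the
input stimulus at minimum CIE94 distance (centroid as reference). A
stimulus's focal proportion is the number of distinct agents with a snapped
centroid there, normalised to sum 1 over stimuli. A run's language is the
top-M stimuli by proportion, M = rounded (half-to-even) mean category
count, floored at 1; ties in proportion break by stimulus index (stable).

Dispersion D sums, over *ordered* pairs of distinct languages, each focal
colour's minimum Euclidean Lab distance to the other language's foci — the
double-sum reading of the definition; the reported
`d_real_unordered = D / 2` is the per-unordered-pair total. The comparison
report gives the empirical rank of D_real among the null dispersions and
the upper bound p = (rank + 1) / (n_null + 1), so beating all n nulls gives
p < 1/n. The distance is injectable (`metric="cie94"`) for sensitivity
checks.

## The chip array and grids

The WCS-style array is 8 lightness rows × 40 hue columns of maximally
saturated chips plus 10 achromatic levels. Conventions chosen here: hue
columns 2.5R, 5R, … 10RP in chart order; chromatic rows carry Munsell
values 9 down to 2; the achromatic ladder is N9.5, N9 … N2, N1.5, with
neutral L\* from the ASTM D1535 value→Y quintic. When building the array
from a renotation table, the chip at each (hue, value) is the maximum
chroma present in the table; the achromatic chips are constructed, since
renotation tables carry no neutrals. A fully synthetic array
(`ChipArray.synthetic`) with the same layout supports download-free runs.

Projection of a Lab point: (1) nearest row by |ΔL\*| over the 10 row
levels; (2) between that row's achromatic chip and the chromatic chip with
the closest hue angle (atan2(b\*, a\*), wrap-aware — the naive atan(b/a) is
quadrant-ambiguous), the chip with the closest chroma radius wins (the
chromatic chip on exact ties). White/black rows are achromatic-only.

Focal-distribution grids count languages with ≥ 1 focus projected per chip,
divided by the number of input stimuli projecting there; chips receiving no
stimuli take value 0 by convention (the alternative — dropping them — only
matters for grids built from stimuli outside the array gamut). Peaks are
strict four-neighbour maxima of the 8 × 40 chromatic block; hue adjacency
wraps by default (Munsell hue is circular), so only the top and bottom
lightness rows are border chips; `hue_wrap=False` additionally excludes the
first and last hue columns. Peak selection keeps N = 4 for WCS-style grids
(red, yellow, green, blue) and N = rounded mean categories − 2 (black and
white excluded, floored at 1) for emergent grids; ties at the cut break by
(value desc, row asc, column asc). The peak-to-peak distance weighs each
set's sum of minimum Euclidean grid distances by its relative size; grid
coordinates do not wrap in this distance, following its printed definition.

## The synthetic stimulus generator

`synth_stimuli(n=300, n_clusters=6, spread=0.3, seed)` scatters points
(sd `spread` Lab units) around cluster centres ≥ 25 units apart inside
L\* ∈ [20, 85], chroma ≤ 70, rejection-sampled to pairwise distinctness
(tolerance 1e-6). The defaults are the package's desk-scale study
conditions: with `spread=0.3` most within-cluster pairs sit at or below the
`d_min = 1.0` discriminability floor — the desk-scale analogue of dense
perceptual regions separated by wide gaps — while cluster centres sit tens
of units apart. That is the regime in which a clustered-vs-rotated contrast
is meaningful at a few hundred stimuli.

What the generator does *not* emulate: the real renotation stimuli are
~2734 points with a continuous, anisotropic density gradient, not six
Gaussian islands; their clustering is far milder and their chroma range
varies strongly with lightness. Tests passing on the synthetic set
demonstrate that the machinery detects displacement structure when present
and destroys it under rotation — they do not calibrate effect sizes for the
real stimulus table, whose dispersion ratios will be smaller.

## Desk-scale study conditions

The dynamics run uses 20 agents, 300 clustered stimuli and 2 × 10⁴
communications per agent (4 × 10⁵ episodes, seconds of runtime). The
dispersion contrast uses 20 runs per condition with 8 agents and 600
communications per agent, against 20 foci-rotation nulls; the repeat-
robustness test replicates that whole experiment 20 times. These sizes were
chosen as the smallest at which the three-phase dynamics and the contrast
are stable across seeds.

## Numerical choices and degenerate inputs

- Rounding of M and of the peak count uses Python's banker's rounding.
- `xyY` input with chromaticity y = 0 raises (undefined chromaticity);
  Y = 0 maps to L\* = 0. The Lab→xyY inverse returns the white point
  chromaticity at zero luminance.
- Identical Lab rows in a renotation table are deduplicated with a warning
  (first occurrence kept); indistinct stimuli elsewhere raise.
- A blank population has no focal colours and raises on extraction;
  zero-episode simulations return empty agents and an empty trace.
- Dispersion of a singleton language set and peak matching with an empty
  set raise rather than returning 0.

## Known limitations

- The episode protocol is one concrete realisation of the exemplar
  category-game family; the package treats the S-shaped success curve and
  the rise–drop–plateau of the category count as the behavioural contract,
  not any particular micro-step sequence.
- No generational turnover, network topology, or stimulus-frequency
  weighting; pairing is uniform.
- The chip-array builder's "maximum chroma present" rule reconstructs the
  maximally saturated chart from whatever renotation table it is given; a
  gamut-reduced table yields a correspondingly desaturated array.
- Full-scale runs (hundreds of agents, 10⁷ communications per agent, the
  complete renotation table) are supported by the same code paths but are
  compute-bound; all shipped tests run at desk scale.
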