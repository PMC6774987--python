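# Methods

`levensong` quantifies similarity among humpback whale song transcriptions
and assigns singers recorded at a migratory stopover to a likely
wintering-ground population of origin. This note documents the models and
procedures, the parameters that matter, what the synthetic data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## The song hierarchy and its data model

Humpback song is nested: discrete sound **units** form stereotyped
**phrases**; repeated phrases form a **theme**; an ordered set of themes is
a **song type**. A transcription corpus stores, per singer, the ordered
phrase occurrences (unit strings tagged with a phrase-type code such as
`3B` — theme 3, variant B). Singer identifiers follow the field convention
`<location><recording>S<singer>[suffix]`; a lower-case suffix marks a
section of recording that could not be confidently linked to the same
animal (a silence over ~3 minutes, or several singers present). Suffixed
IDs are analysed as **separate** singers throughout — merging them would
fabricate continuity the recording cannot support.

A singer's **theme sequence** is the order in which themes were sung with
consecutive repeats collapsed (`[1,1,2,3,3] -> [1,2,3]`, revisits such as
`[1,2,1]` preserved).

## Edit distance and the similarity index

The core statistic is the Levenshtein (edit) distance between label
sequences: the minimum total cost of substitutions, insertions and
deletions converting one into the other, computed by full
`(|a|+1)x(|b|+1)` dynamic programming (strings are tens of symbols; no
banding needed). Similarity is the length-normalized index

    LSI(a, b) = 1 − LD(a, b) / max(|a|, |b|),

which lies in [0, 1]: substitutions never cost more than the indel cost of
1, so no optimal edit script can cost more than `max(|a|, |b|)`. The
longer-string denominator is the standard normalized-LD convention and is
the only simple normalization that guarantees the stated range.

Two analyses run at different levels of the hierarchy:

* **phrase level (fine scale)** — unit strings compared with *weighted*
  substitution costs (below); one item per (singer, phrase type) within a
  theme;
* **song level (broad scale)** — theme sequences compared *unweighted*.

Each singer is represented by its **medoid string**: the attested rendition
minimizing summed edit distance to the singer's other renditions of that
phrase type (ties break to the earliest rendition, keeping the choice
deterministic and the representative an actually-produced string). At the
song level the data model carries one phrase stream per singer, so the
representative theme sequence is the singer's collapsed theme sequence —
the medoid of a single attested rendition is itself.

## Substitution costs from acoustic features

Eleven per-unit measurements (duration; minimum, maximum, peak, start and
end frequency; bandwidth; frequency trend ratio start/end; frequency range
ratio min/max; number of inflections; pulse repetition rate, zero for
non-pulsed units) are summarized per unit type by the **median** over
exemplars — robust to the rare-unit case of one or two measured exemplars.
Each feature is min–max normalized to [0, 1] across the type centroids, and
the substitution cost between two types is the mean absolute normalized
difference over the features. Features constant across all types carry no
information and are dropped (with a warning). The construction is invariant
to affine rescaling of any input feature (units of Hz vs kHz cannot change
costs), bounded in [0, 1], symmetric, and zero on the diagonal. Indels cost
a fixed 1. The exact cost formula behind the original analysis is not
published; the matrix is therefore also loadable from CSV so externally
derived costs can be substituted without touching the pipeline. At build
time the matrix reports whether it satisfies the triangle inequality on the
inventory, in which case the weighted edit distance is a metric.

A cross-validated decision-tree (CART-style) classifier predicting the
human-assigned unit label from the 11 features provides a consistency check
on unit naming; its agreement fraction is a diagnostic, not a calibrated
quantity — tree hyperparameters and the cross-validation scheme are
deliberately ordinary defaults (stratified k-fold, k ≤ 5 capped by the
smallest class).

## Clustering and multiscale-bootstrap support

Similarity matrices are converted to distances `d = 1 − LSI` and clustered
by UPGMA (average linkage, via `scipy.cluster.hierarchy`). Node stability
is assessed by multiscale bootstrap. The resampling unit for a
distance-derived matrix is genuinely open (nothing in a pairwise LSI matrix
dictates one); the choice here, declared openly and isolated behind one
function, treats each item's vector of distances to all items as its
feature profile and resamples **profile coordinates** with replacement — a
common practice when bootstrapping distance-based trees. For each scale
ratio `r` in a ladder of ten values 0.5–1.4, `ceil(r·m)` of the `m` profile
rows are drawn with replacement `B` times (default B = 1000 per scale);
items are reclustered on scaled Euclidean profile distance and each
original node's recovery frequency `BP_r` (leaf-set equality) is recorded.

Per node, the probit-transformed frequencies `Φ⁻¹(1 − BP_r)` are fitted
against `(√r, 1/√r)` by weighted least squares (binomial-variance weights),
giving signed-distance and curvature coefficients `(v, c)`; then

    AU = 1 − Φ(v − c),   BP = 1 − Φ(v + c),

with a delta-method standard error from the fit covariance. Numerical
details: frequencies at 0 or 1 are clipped to `1/(2B)` from the boundary;
scales where the node was recovered in *all* or *no* replicates carry no
probit information and are excluded from the fit; a node with fewer than 3
informative scales is saturated to AU = BP = 1 (recovered essentially
always) or 0, SE = 0 — without this rule an always-recovered node would be
extrapolated from pure clipping noise to a meaningless AU ≈ 0.6. Nodes never
recovered at any scale get AU = 0 and are flagged. All resampling flows
from one seeded generator; identical seeds give identical AU/BP/SE.

A node with AU > 0.95 counts as **stable** (the BP > 0.70 convention is
reported alongside but does not gate stability). Two views of stability are
exposed:

* `stable_clusters` returns the *maximal* ("highest-level") stable nodes,
  excluding the root — the boxes a pvrect-style display would draw;
* origin calls (below) use the *tightest* stable cluster around a singer.

The **cophenetic correlation coefficient** (Pearson correlation between
input and tree-implied distances; > 0.8 conventionally a good fit, exactly
1 on ultrametric input) is an independent check of how well each dendrogram
represents its matrix.

Newick export writes ultrametric branch lengths (leaf depth = half the
merge height, so two items at distance 0.4 render as `(A:0.2,B:0.2);`) with
`AU=…|BP=…` internal labels, quoting names where the dialect requires it.

## Origin assignment

Three independent lines of evidence are computed per eligible stopover
singer:

1. **Percent matched phrases** — `100 × |shared phrase types| / |phrase
   types in the singer's recording|` against each ground's pooled phrase
   inventory (presence at a ground is a property of the ground as a whole,
   so the statistic is unchanged by duplicating a ground's singers). The
   unique strict maximum names a ground; ties leave the singer unassigned.
2. **Fine-scale LSI** — per theme, the tightest stable cluster around the
   singer's medoid unit string that contains wintering-ground members;
   exactly one ground represented gives a per-theme call, several grounds
   give none. The singer-level call is the unique ground among its theme
   calls; conflicts yield no call.
3. **Broad-scale LSI** — the same tightest-stable-cluster rule on the
   song-level tree.

The *tightest* (minimal) stable ancestor is used rather than the maximal
box because strong global structure — the song-type blocks — is itself
stable and always spans several grounds; the informative evidence is the
smallest strongly supported cluster linking a stopover singer to ground
singers. Stable ancestors containing only stopover singers are skipped
(they carry no origin information); the first ancestor with ground members
decides.

**Consensus** (strict, the default): an origin is assigned only when all
three methods produced a call and they agree. A lenient mode (any two
agreeing calls, none disagreeing) is available but off by default — the
strict rule is the conservative reading and the one that reproduces the
sparse consensus counts this style of analysis yields.

**Eligibility** is conservative: singers recorded with a single phrase type
or single theme are excluded (no sequence information), as are singers
combining a phrase type exclusive to one ground with phrase types absent
from that ground (internally contradictory evidence; both flags are
logged, never silently dropped).

## The synthetic song-culture generator

The generator emulates the structure the analysis assumes, with full ground
truth:

* a unit inventory generated in **acoustic-neighbour pairs** (`u03a`/`u03b`)
  whose centroids differ by a small (~4%) perturbation, over plausible
  humpback ranges (durations 0.1–3 s, frequencies within 30–5000 Hz),
  with ~5% exemplar scatter — so neighbour substitution costs sit well
  below the inventory median;
* populations, each assigned a song type (theme order); per population,
  each theme's canonical phrase is kept or replaced by a **private
  variant** (probability `variant_rate`, default 0.5) substituting one unit
  for its acoustic neighbour — the fine-scale population signature;
  distinct realized strings receive distinct phrase-type letters, and
  populations that happen to realize the same variant share its code;
* population-specific theme presence: each theme dropped from a
  population's repertoire with probability `theme_drop_rate` (default
  0.15, at least two themes kept) — the broad-scale population signature;
* per-singer incomplete recordings: each theme independently missed with
  probability `singer_theme_drop_rate` (default 0.1). This within-population
  song-level variation is what keeps intermediate dendrogram nodes unstable
  so that tight single-ground stable clusters can exist at all; without it
  every division is perfectly supported and the broad-scale method can
  never isolate one ground;
* independent per-unit **transcription noise** on every rendition:
  deletion (default 0.01), substitution *to the unit's neighbour* (default
  0.02 — a transcriber confuses similar sounds, not arbitrary ones),
  insertion of a random unit (default 0.01). Phrase-type labels follow the
  clean realization, as a human transcriber assigns the type from the
  phrase's overall identity;
* a stopover corpus whose singers draw a population of origin from a
  weighted mixture (weight 0 models populations whose migration does not
  pass the stopover); a `single_theme_rate` fraction are recorded with one
  theme only.

The `paper_scale_preset` reproduces the field design shape: six ground
populations with sample sizes 11/11/8/7/8/7 (eastern Australia, New
Caledonia, Tonga, Niue, Cook Islands, French Polynesia), 39 stopover
singers with mixture weights proportional to the sampled western/central
ground sizes and zero weight on eastern Australia and French Polynesia,
song type 2 in the west, 1a central, 3 east-Australian only, and a fifth of
stopover singers recorded with a single theme. Its default seed is 2015
(the field season); all generation is bit-reproducible from the config.

What the generator does **not** emulate: song evolution within or across
seasons, revolutions, transmission dynamics, singer-specific idiosyncrasy
beyond transcription noise, hybrid singers, recording-quality covariates,
and within-population variant diversity (each population realizes one
variant per theme). Passing recovery tests therefore show that the pipeline
recovers planted population signatures under edit-type noise at realistic
sample sizes — not that real wintering grounds are this cleanly separable.

## Problem sizes and runtime

Default test and example runs use B = 1000 bootstrap replicates per scale
across ten scales. At the preset's scale (52 + 39 singers; one song-level
and ~11 per-theme matrices of 20–60 items) a full assignment run completes
in well under a minute on one core; the library is pure Python + NumPy/SciPy
with the per-replicate linkage in compiled SciPy code.

## Known limitations

* The resampling axis for bootstrapping a distance-derived matrix is a
  declared convention (profile-coordinate resampling); published AU/BP
  values from analyses whose resampling unit differed will reproduce only
  approximately.
* The substitution-cost formula is this package's own (normalized
  centroid differences); externally derived costs can be loaded from CSV.
* The tightest-stable-cluster rule makes single-ground calls possible in
  the presence of stable global structure, but inherits the bootstrap's
  finite-B granularity near the AU threshold.
* Percent-matched inventories are presence-only: a ground sampled by few
  singers can miss phrase types it actually uses, biasing matches toward
  better-sampled grounds — inherent to the statistic, not corrected here.
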