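"""Origin assignment of migratory-stopover singers to wintering grounds.

Three independent lines of evidence give each eligible stopover singer a
candidate wintering ground of origin:

* **percent matched** -- the share of the singer's phrase types present in
  each ground's pooled phrase inventory; a unique strict maximum names the
  ground, ties leave the singer unassigned;
* **fine-scale LSI** -- per theme, the tightest stable cluster (AU above
  threshold) around the singer's medoid unit string that contains
  wintering-ground members must contain members of a single ground;
  conflicting per-theme calls leave it unassigned;
* **broad-scale LSI** -- the same single-ground stable-cluster rule applied
  to the song-level (theme sequence) tree.

The strict consensus assigns an origin only when all three methods produced
a call and they agree; a lenient mode (any two agreeing calls, no
disagreement) is available but off by default.

Eligibility is conservative: singers recorded with a single phrase type (or
theme) are excluded, as are singers combining a phrase type exclusive to one
ground with phrase types absent from that same ground (contradictory
evidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from levensong.cluster import (
    DEFAULT_SCALES,
    multiscale_bootstrap,
    stable_clusters,
)
from levensong.corpus import (
    CorpusError,
    SongCorpus,
    merge_corpora,
    phrase_inventory,
    theme_sequence_of,
)
from levensong.seqsim import phrase_similarity_matrix, song_similarity_matrix
from levensong.units import CostMatrix

__all__ = [
    "DEFAULT_SONG_TYPES",
    "SongTypeCall",
    "classify_song_type",
    "percent_matched",
    "filter_eligible",
    "assign_by_percent",
    "fine_scale_calls",
    "broad_scale_calls",
    "consensus",
    "AssignmentConfig",
    "build_assignment_table",
]

#: Song types defined by theme content.  Types 1a and 1b share themes 7, 9
#: and 11; themes 8/10 discriminate for 1a and 12/13/14 for 1b.
DEFAULT_SONG_TYPES: dict[str, frozenset[int]] = {
    "1a": frozenset({7, 8, 9, 10, 11}),
    "1b": frozenset({7, 9, 11, 12, 13, 14}),
    "2": frozenset({1, 2, 3, 4, 5, 6}),
    "3": frozenset({15, 16, 17}),
}


@dataclass(frozen=True)
class SongTypeCall:
    """Outcome of song-type classification.

    ``kind`` is ``"single"``, ``"hybrid"`` or ``"unclassified"``; ``types``
    names the matched type(s) (two for hybrids, ordered by the number of
    themes each contributes).  ``ambiguous`` marks singers whose themes are
    all shared between overlapping type definitions (no discriminating
    theme).
    """

    kind: str
    types: tuple[str, ...] = ()
    ambiguous: bool = False


def classify_song_type(
    theme_sequence: Sequence[int],
    definitions: Mapping[str, frozenset[int]] = DEFAULT_SONG_TYPES,
) -> SongTypeCall:
    """Classify a theme sequence as one song type, a hybrid, or unclassified.

    A unique type whose theme set covers all sung themes wins; where
    overlapping definitions both cover, any discriminating (non-shared)
    theme resolves the tie, and a sequence of only shared themes is flagged
    ambiguous.  Themes drawn from exactly two types make a hybrid, ordered
    by contribution.  An unknown theme raises ``ValueError``.
    """
    themes = set(theme_sequence)
    if not themes:
        raise ValueError("empty theme sequence")
    known = set().union(*definitions.values())
    unknown = themes - known
    if unknown:
        raise ValueError(f"unknown theme id(s): {sorted(unknown)}")

    covering = [name for name, ts in definitions.items() if themes <= ts]
    if len(covering) == 1:
        return SongTypeCall(kind="single", types=(covering[0],))
    if len(covering) > 1:
        # all sung themes shared between overlapping definitions; prefer a
        # type with a discriminating theme present (none is, by construction)
        return SongTypeCall(kind="single", types=(min(covering),), ambiguous=True)

    # no single cover: hybrid if exactly two types explain everything
    best_pair: tuple[str, str] | None = None
    names = sorted(definitions)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if themes <= (definitions[a] | definitions[b]):
                # order by number of themes uniquely attributable
                na = len(themes & definitions[a])
                nb = len(themes & definitions[b])
                pair = (a, b) if na >= nb else (b, a)
                if best_pair is None:
                    best_pair = pair
    if best_pair is not None:
        return SongTypeCall(kind="hybrid", types=best_pair)
    return SongTypeCall(kind="unclassified")


def percent_matched(
    singer_phrase_types: Iterable[str], ground_inventory: Iterable[str]
) -> float:
    """Percentage of a singer's phrase types present in a ground's inventory.

    ``100 * |shared| / |singer's phrase types|`` -- the denominator is the
    number of phrase types in the singer's own recording, so the statistic
    is unaffected by how many singers sampled the ground.
    """
    singer_set = set(singer_phrase_types)
    if not singer_set:
        raise ValueError("singer has no phrase types")
    ground_set = set(ground_inventory)
    return 100.0 * len(singer_set & ground_set) / len(singer_set)


@dataclass
class Exclusion:
    singer_id: str
    flag: str
    detail: str = ""


def filter_eligible(
    stopover: SongCorpus, grounds: SongCorpus
) -> tuple[list[str], list[Exclusion]]:
    """Conservative eligibility filter for stopover singers.

    Excludes (i) singers recorded with a single phrase type or a single
    theme (``single_phrase_type``) and (ii) singers who sang a phrase type
    found exclusively at one ground *and* at least one phrase type absent
    from that ground (``exclusive_phrase_conflict``): such a combination is
    internally contradictory evidence and no origin is suggested.
    """
    inventories = {loc: phrase_inventory(grounds, loc) for loc in grounds.locations}
    exclusive: dict[str, str] = {}  # phrase_type -> sole ground
    for loc, inv in inventories.items():
        for pt in inv:
            if all(pt not in other for l2, other in inventories.items() if l2 != loc):
                exclusive[pt] = loc

    eligible: list[str] = []
    excluded: list[Exclusion] = []
    for singer in stopover.singers.values():
        ptypes = singer.phrase_types
        if len(ptypes) < 2 or len(singer.themes) < 2:
            excluded.append(
                Exclusion(singer.singer_id, "single_phrase_type",
                          f"phrase types: {sorted(ptypes)}")
            )
            continue
        conflict = None
        for pt in ptypes:
            loc = exclusive.get(pt)
            if loc is not None and any(q not in inventories[loc] for q in ptypes):
                conflict = (pt, loc)
                break
        if conflict:
            excluded.append(
                Exclusion(
                    singer.singer_id,
                    "exclusive_phrase_conflict",
                    f"phrase {conflict[0]} exclusive to {conflict[1]} "
                    f"alongside phrases absent there",
                )
            )
            continue
        eligible.append(singer.singer_id)
    return eligible, excluded


def assign_by_percent(pct: Mapping[str, float]) -> str | None:
    """Ground with the unique strict maximum percentage, else ``None``."""
    if not pct:
        return None
    best = max(pct.values())
    winners = [loc for loc, v in pct.items() if v == best]
    return winners[0] if len(winners) == 1 else None


def _stable_cluster_call(
    tree,
    item: str,
    item_locations: Mapping[str, str],
    stopover_location: str,
    au_threshold: float,
) -> str | None:
    """Origin suggested by the tightest stable cluster around ``item``.

    Walk the item's ancestors from the leaf upward and take the first node
    with AU above threshold that contains at least one wintering-ground
    member: exactly one ground represented names that ground; multiple
    grounds mean the item is grouped with several origins and no call is
    made.  Stable ancestors containing only stopover items are skipped
    (they carry no origin information).
    """
    leaf = tree.ids.index(item)
    for k in range(tree.n_leaves - 1):
        if leaf not in tree.leafset(k):
            continue
        if tree.au[k] <= au_threshold:
            continue
        grounds = {
            item_locations[tree.ids[i]]
            for i in tree.leafset(k)
            if item_locations[tree.ids[i]] != stopover_location
        }
        if not grounds:
            continue
        return next(iter(grounds)) if len(grounds) == 1 else None
    return None


def fine_scale_calls(
    combined: SongCorpus,
    costs: CostMatrix,
    stopover_location: str = "KI",
    *,
    themes: Sequence[int] | None = None,
    au_threshold: float = 0.95,
    scales: Sequence[float] = DEFAULT_SCALES,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[dict[str, dict[int, str | None]], dict[str, str | None]]:
    """Per-theme and combined fine-scale LSI origin calls.

    For every theme sung by a stopover singer (restrictable via ``themes``),
    the (singer, phrase type) medoid strings of all singers are clustered
    with bootstrap support; a stopover item lying in a stable cluster whose
    ground members come from exactly one ground receives that theme call.
    A singer's combined call is the unique ground among its theme calls;
    conflicting grounds yield ``None``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stopover_ids = [
        s.singer_id for s in combined.singers.values()
        if s.location == stopover_location
    ]
    if themes is None:
        themes = sorted(
            {t for sid in stopover_ids for t in combined.singers[sid].themes}
        )
    per_theme: dict[str, dict[int, str | None]] = {sid: {} for sid in stopover_ids}
    for theme in themes:
        singers_with = [
            s for s in combined.singers.values() if theme in s.themes
        ]
        if len(singers_with) < 3:
            continue
        sim = phrase_similarity_matrix(combined, theme, costs)
        if len(sim.ids) < 3:
            continue
        tree = multiscale_bootstrap(sim, scales=scales, B=B, seed=rng)
        item_loc = {
            item: combined.singers[item.rsplit("_", 1)[0]].location
            for item in sim.ids
        }
        for item in sim.ids:
            sid = item.rsplit("_", 1)[0]
            if item_loc[item] != stopover_location:
                continue
            call = _stable_cluster_call(
                tree, item, item_loc, stopover_location, au_threshold
            )
            if call is None:
                continue
            prev = per_theme[sid].get(theme)
            if theme in per_theme[sid] and prev != call:
                per_theme[sid][theme] = None  # conflicting phrase types
            else:
                per_theme[sid][theme] = call

    combined_call: dict[str, str | None] = {}
    for sid in stopover_ids:
        calls = {c for c in per_theme[sid].values() if c is not None}
        combined_call[sid] = next(iter(calls)) if len(calls) == 1 else None
    return per_theme, combined_call


def broad_scale_calls(
    combined: SongCorpus,
    stopover_location: str = "KI",
    *,
    au_threshold: float = 0.95,
    scales: Sequence[float] = DEFAULT_SCALES,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> dict[str, str | None]:
    """Song-level (theme sequence) single-ground stable-cluster calls."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sim = song_similarity_matrix(combined)
    loc = {sid: combined.singers[sid].location for sid in sim.ids}
    stopover_ids = [sid for sid in sim.ids if loc[sid] == stopover_location]
    calls: dict[str, str | None] = {}
    if len(sim.ids) >= 3:
        tree = multiscale_bootstrap(sim, scales=scales, B=B, seed=rng)
        for sid in stopover_ids:
            calls[sid] = _stable_cluster_call(
                tree, sid, loc, stopover_location, au_threshold
            )
    else:
        calls = {sid: None for sid in stopover_ids}
    return calls


def consensus(
    origin_pct: str | None,
    origin_fine: str | None,
    origin_broad: str | None,
    mode: str = "strict",
) -> str | None:
    """Combine the three method calls into a consensus origin.

    Strict mode (default): all three methods must have produced a call and
    they must agree.  Lenient mode: at least two calls, all produced calls
    agreeing.
    """
    calls = [origin_pct, origin_fine, origin_broad]
    produced = [c for c in calls if c is not None]
    if mode == "strict":
        if len(produced) == 3 and len(set(produced)) == 1:
            return produced[0]
        return None
    if mode == "lenient":
        if len(produced) >= 2 and len(set(produced)) == 1:
            return produced[0]
        return None
    raise ValueError(f"unknown consensus mode {mode!r}")


@dataclass
class AssignmentConfig:
    """Thresholds and bootstrap settings for the assignment pipeline."""

    au_threshold: float = 0.95
    bp_threshold: float = 0.70  # reported only; AU alone gates stability
    consensus_mode: str = "strict"
    scales: tuple[float, ...] = DEFAULT_SCALES
    B: int = 1000
    seed: int | None = None
    stopover_location: str = "KI"

    def __post_init__(self) -> None:
        if not (0 < self.au_threshold < 1 and 0 < self.bp_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.B < 100:
            raise ValueError("B must be >= 100")


def build_assignment_table(
    grounds: SongCorpus,
    stopover: SongCorpus,
    costs: CostMatrix,
    config: AssignmentConfig | None = None,
) -> tuple[pd.DataFrame, list[Exclusion]]:
    """Full assignment table for eligible stopover singers.

    One row per eligible singer with the per-ground matched percentages, the
    three method calls, the consensus, and flags; plus the exclusion log.
    """
    config = config or AssignmentConfig()
    rng = np.random.default_rng(config.seed)
    ground_locs = grounds.locations
    inventories = {loc: phrase_inventory(grounds, loc) for loc in ground_locs}

    eligible, excluded = filter_eligible(stopover, grounds)
    columns = (
        ["singer_id", "n_phrase_types"]
        + [f"pct_{loc}" for loc in ground_locs]
        + ["song_type", "origin_pct", "origin_fine_lsi", "origin_broad_lsi",
           "consensus", "flags"]
    )
    if not eligible:
        return pd.DataFrame(columns=columns), excluded

    eligible_stopover = SongCorpus(
        singers={sid: stopover.singers[sid] for sid in eligible}
    )
    combined = merge_corpora(grounds, eligible_stopover)

    _, fine = fine_scale_calls(
        combined, costs, config.stopover_location,
        au_threshold=config.au_threshold, scales=config.scales,
        B=config.B, seed=rng,
    )
    broad = broad_scale_calls(
        combined, config.stopover_location,
        au_threshold=config.au_threshold, scales=config.scales,
        B=config.B, seed=rng,
    )

    rows = []
    for sid in eligible:
        singer = stopover.singers[sid]
        pct = {
            loc: percent_matched(singer.phrase_types, inventories[loc])
            for loc in ground_locs
        }
        origin_pct = assign_by_percent(pct)
        origin_fine = fine.get(sid)
        origin_broad = broad.get(sid)
        cons = consensus(origin_pct, origin_fine, origin_broad,
                         config.consensus_mode)
        try:
            stype = classify_song_type(theme_sequence_of(singer))
            stype_str = "+".join(stype.types) if stype.types else "unclassified"
            if stype.kind == "hybrid":
                stype_str = f"hybrid({stype_str})"
        except ValueError:
            stype_str = "unclassified"
        row = {"singer_id": sid, "n_phrase_types": len(singer.phrase_types)}
        row.update({f"pct_{loc}": pct[loc] for loc in ground_locs})
        row.update(
            {
                "song_type": stype_str,
                "origin_pct": origin_pct,
                "origin_fine_lsi": origin_fine,
                "origin_broad_lsi": origin_broad,
                "consensus": cons,
                "flags": "",
            }
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=columns), excluded
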