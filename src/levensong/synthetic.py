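"""Synthetic song cultures with known ground truth.

The generator emulates the statistical structure the analysis assumes:
several wintering-ground populations, each singing one song type (an ordered
set of themes) with a population-specific fine-scale realization -- private
phrase variants that substitute one unit for an acoustically similar
neighbour, and population-specific theme presence -- plus a mixed-origin
migratory-stopover corpus sampled from a subset of the populations, with
independent per-unit substitution/insertion/deletion transcription noise.
Every singer's true population, song type and clean (pre-noise) strings are
recorded, so recovery can be scored exactly.

Unit types are generated in acoustic-neighbour pairs (labels ``u03a`` /
``u03b``): the two members of a pair have nearly identical feature centroids
and hence a low substitution cost, which is what both phrase variants and
substitution noise exploit -- a transcriber confuses similar-sounding units,
not arbitrary ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from levensong.assignment import DEFAULT_SONG_TYPES
from levensong.corpus import PhraseString, Singer, SongCorpus
from levensong.units import FEATURE_NAMES, UnitFeatureTable

__all__ = [
    "SyntheticConfig",
    "GroundTruthRecord",
    "generate_unit_inventory",
    "generate_corpus",
    "paper_scale_preset",
    "apply_transcription_noise",
    "neighbour_of",
    "write_ground_truth",
]

#: Theme order sung for each song type.
DEFAULT_THEME_ORDERS: dict[str, tuple[int, ...]] = {
    "1a": (7, 8, 9, 10, 11),
    "1b": (7, 9, 11, 12, 13, 14),
    "2": (1, 2, 3, 4, 5, 6),
    "3": (15, 16, 17),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study design for a synthetic song culture.

    ``singers_per_population`` may be one count or a per-population mapping;
    ``stopover_mixture`` weights the population of origin of each stopover
    singer (weight 0 models populations that do not pass the stopover).
    ``seed`` is mandatory: every draw flows from it.
    """

    seed: int
    n_unit_types: int = 24
    song_type_assignments: Mapping[str, str] = field(
        default_factory=lambda: {"PA": "2", "PB": "2", "PC": "1a", "PD": "1a"}
    )
    themes_per_type: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_THEME_ORDERS)
    )
    units_per_phrase: tuple[int, int] = (5, 9)
    variant_rate: float = 0.5
    theme_drop_rate: float = 0.15
    singer_theme_drop_rate: float = 0.1
    renditions_per_phrase: int = 3
    singers_per_population: int | Mapping[str, int] = 8
    n_stopover_singers: int = 20
    stopover_mixture: Mapping[str, float] | None = None
    single_theme_rate: float = 0.0
    sub_rate: float = 0.02
    ins_rate: float = 0.01
    del_rate: float = 0.01
    exemplars_per_unit: int = 5
    stopover_location: str = "KI"

    def __post_init__(self) -> None:
        if self.n_unit_types < 2 or self.n_unit_types % 2:
            raise ValueError("n_unit_types must be an even number >= 2")
        for p in (self.variant_rate, self.theme_drop_rate, self.single_theme_rate,
                  self.singer_theme_drop_rate,
                  self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        mix = self.mixture()
        if any(w < 0 for w in mix.values()) or sum(mix.values()) <= 0:
            raise ValueError("mixture weights must be >= 0 and not all 0")
        unknown = set(mix) - set(self.song_type_assignments)
        if unknown:
            raise ValueError(f"mixture names unknown populations: {sorted(unknown)}")
        for pop, stype in self.song_type_assignments.items():
            if len(pop) != 2 or not pop.isupper():
                raise ValueError(f"population code {pop!r} must be 2 upper-case letters")
            if stype not in self.themes_per_type:
                raise ValueError(f"song type {stype!r} has no theme order")

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(self.song_type_assignments)

    def mixture(self) -> dict[str, float]:
        if self.stopover_mixture is None:
            return {p: 1.0 for p in self.song_type_assignments}
        return dict(self.stopover_mixture)

    def singers_for(self, pop: str) -> int:
        if isinstance(self.singers_per_population, Mapping):
            return int(self.singers_per_population[pop])
        return int(self.singers_per_population)


@dataclass(frozen=True)
class GroundTruthRecord:
    singer_id: str
    population: str
    song_type: str
    clean_phrases: Mapping[int, tuple[str, tuple[str, ...]]]  # theme -> (type, units)


def neighbour_of(label: str) -> str:
    """The acoustic neighbour of a paired unit label (``u03a`` <-> ``u03b``)."""
    if label.endswith("a"):
        return label[:-1] + "b"
    if label.endswith("b"):
        return label[:-1] + "a"
    raise ValueError(f"label {label!r} is not a paired unit label")


def _unit_labels(n: int) -> list[str]:
    return [f"u{k:02d}{s}" for k in range(n // 2) for s in ("a", "b")]


def generate_unit_inventory(config: SyntheticConfig) -> UnitFeatureTable:
    """Unit-measurement table for a synthetic inventory of paired unit types.

    Pair centroids are drawn over plausible humpback song ranges (durations
    0.1-3 s, frequencies within 30-5000 Hz); a pair's second member is a
    small perturbation of the first, so neighbour substitution costs are low
    relative to the inventory at large.  Exemplar scatter is ~5% relative.
    Deterministic for the config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    rows: list[dict] = []
    labels = _unit_labels(config.n_unit_types)
    for k in range(config.n_unit_types // 2):
        base = _draw_centroid(rng)
        for member, lab in enumerate(labels[2 * k: 2 * k + 2]):
            cen = base if member == 0 else _perturb_centroid(base, rng, rel=0.04)
            for _ in range(config.exemplars_per_unit):
                rows.append(
                    {"unit_label": lab, **_perturb_centroid(cen, rng, rel=0.05)}
                )
    df = pd.DataFrame(rows, columns=["unit_label", *FEATURE_NAMES])
    return UnitFeatureTable(data=df)


def _draw_centroid(rng: np.random.Generator) -> dict[str, float]:
    duration = rng.uniform(0.1, 3.0)
    fmin = rng.uniform(30.0, 2000.0)
    fmax = min(fmin * rng.uniform(1.3, 3.0), 5000.0)
    fpeak = rng.uniform(fmin, fmax)
    fstart = rng.uniform(fmin, fmax)
    fend = rng.uniform(fmin, fmax)
    pulsed = rng.random() < 0.2
    return _derive(
        duration, fmin, fmax, fpeak, fstart, fend,
        n_inflections=float(rng.poisson(1.5)),
        pulse_rate=float(rng.uniform(5.0, 50.0)) if pulsed else 0.0,
    )


def _perturb_centroid(
    cen: Mapping[str, float], rng: np.random.Generator, rel: float
) -> dict[str, float]:
    jit = lambda x: float(x * np.exp(rng.normal(0.0, rel)))  # noqa: E731
    duration = max(jit(cen["duration_s"]), 0.01)
    fmin = max(jit(cen["min_freq_hz"]), 10.0)
    fmax = max(jit(cen["max_freq_hz"]), fmin * 1.05)
    fpeak = float(np.clip(jit(cen["peak_freq_hz"]), fmin, fmax))
    fstart = float(np.clip(jit(cen["start_freq_hz"]), fmin, fmax))
    fend = float(np.clip(jit(cen["end_freq_hz"]), fmin, fmax))
    pulse = jit(cen["pulse_rate_hz"]) if cen["pulse_rate_hz"] > 0 else 0.0
    return _derive(duration, fmin, fmax, fpeak, fstart, fend,
                   n_inflections=cen["n_inflections"], pulse_rate=pulse)


def _derive(duration, fmin, fmax, fpeak, fstart, fend, n_inflections, pulse_rate):
    return {
        "duration_s": duration,
        "min_freq_hz": fmin,
        "max_freq_hz": fmax,
        "bandwidth_hz": fmax - fmin,
        "peak_freq_hz": fpeak,
        "start_freq_hz": fstart,
        "end_freq_hz": fend,
        "freq_trend_ratio": fstart / fend,
        "freq_range_ratio": fmin / fmax,
        "n_inflections": n_inflections,
        "pulse_rate_hz": pulse_rate,
    }


def apply_transcription_noise(
    units: Sequence[str],
    rng: np.random.Generator,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    inventory: Sequence[str],
) -> tuple[str, ...]:
    """Independent per-unit transcription noise.

    Each unit is dropped with ``del_rate``, otherwise mis-transcribed as its
    acoustic neighbour with ``sub_rate``; after each emitted unit a random
    inventory unit is inserted with ``ins_rate``.  Output is never empty (a
    phrase with no units cannot be transcribed): if everything was deleted
    one original unit survives.
    """
    out: list[str] = []
    for u in units:
        if rng.random() < del_rate:
            continue
        v = neighbour_of(u) if rng.random() < sub_rate else u
        out.append(v)
        if rng.random() < ins_rate:
            out.append(inventory[int(rng.integers(len(inventory)))])
    if not out:
        out.append(units[int(rng.integers(len(units)))])
    return tuple(out)


def _population_repertoires(
    config: SyntheticConfig, rng: np.random.Generator, labels: list[str]
) -> tuple[dict[str, dict[int, tuple[str, tuple[str, ...]]]], dict[str, tuple[int, ...]]]:
    """Canonical phrases per theme plus per-population private realizations.

    Returns ``repertoires[pop][theme] = (phrase_type, units)`` and the kept
    theme order per population.  Phrase-type letters are assigned per theme
    by distinct realized strings (canonical = 'A'), so two populations that
    happen to realize the same variant share its code.
    """
    lo, hi = config.units_per_phrase
    all_themes = sorted(
        {t for stype in set(config.song_type_assignments.values())
         for t in config.themes_per_type[stype]}
    )
    canonical: dict[int, tuple[str, ...]] = {}
    for theme in all_themes:
        length = int(rng.integers(lo, hi + 1))
        canonical[theme] = tuple(
            labels[int(rng.integers(len(labels)))] for _ in range(length)
        )
    variant_codes: dict[int, dict[tuple[str, ...], str]] = {
        t: {canonical[t]: f"{t}A"} for t in all_themes
    }

    repertoires: dict[str, dict[int, tuple[str, tuple[str, ...]]]] = {}
    kept_order: dict[str, tuple[int, ...]] = {}
    for pop in config.populations:
        stype = config.song_type_assignments[pop]
        order = config.themes_per_type[stype]
        kept = tuple(t for t in order if rng.random() >= config.theme_drop_rate)
        if len(kept) < 2:
            kept = order[:2]
        kept_order[pop] = kept
        rep: dict[int, tuple[str, tuple[str, ...]]] = {}
        for theme in kept:
            units = canonical[theme]
            if rng.random() < config.variant_rate:
                pos = int(rng.integers(len(units)))
                units = units[:pos] + (neighbour_of(units[pos]),) + units[pos + 1:]
            codes = variant_codes[theme]
            if units not in codes:
                codes[units] = f"{theme}{chr(ord('A') + len(codes))}"
            rep[theme] = (codes[units], units)
        repertoires[pop] = rep
    return repertoires, kept_order


def _recorded_themes(
    kept: tuple[int, ...], rng: np.random.Generator, rate: float
) -> tuple[int, ...]:
    """Per-singer incomplete recording: each theme missed independently.

    At least two themes always survive (a singer cut down further is the
    single-theme case, controlled separately).
    """
    if rate <= 0 or len(kept) <= 2:
        return kept
    recorded = tuple(t for t in kept if rng.random() >= rate)
    return recorded if len(recorded) >= 2 else kept[:2]


def _sing(
    singer_id: str,
    themes: Sequence[int],
    repertoire: Mapping[int, tuple[str, tuple[str, ...]]],
    config: SyntheticConfig,
    rng: np.random.Generator,
    labels: list[str],
) -> Singer:
    singer = Singer(singer_id=singer_id)
    for theme in themes:
        ptype, units = repertoire[theme]
        for _ in range(config.renditions_per_phrase):
            noisy = apply_transcription_noise(
                units, rng, config.sub_rate, config.ins_rate, config.del_rate,
                labels,
            )
            singer.phrases.append(PhraseString(units=noisy, phrase_type=ptype))
    return singer


def generate_corpus(
    config: SyntheticConfig,
) -> tuple[SongCorpus, SongCorpus, dict[str, GroundTruthRecord]]:
    """Generate (wintering-ground corpus, stopover corpus, ground truth).

    Ground singers sing their population's full kept-theme repertoire;
    stopover singers draw a population of origin from the mixture and sing
    that repertoire (a ``single_theme_rate`` fraction are recorded with one
    theme only, modelling incomplete recordings).  All strings carry
    independent transcription noise; phrase-type labels follow the clean
    realization (the transcriber's type assignment, not the noisy string).
    Deterministic and bit-identical for a fixed config.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    labels = _unit_labels(config.n_unit_types)
    repertoires, kept_order = _population_repertoires(config, rng, labels)

    truth: dict[str, GroundTruthRecord] = {}
    grounds = SongCorpus()
    for pop in config.populations:
        stype = config.song_type_assignments[pop]
        for i in range(config.singers_for(pop)):
            sid = f"{pop}{i + 1:02d}S1"
            themes = _recorded_themes(kept_order[pop], rng,
                                      config.singer_theme_drop_rate)
            singer = _sing(sid, themes, repertoires[pop], config, rng, labels)
            grounds.add(singer)
            truth[sid] = GroundTruthRecord(
                singer_id=sid, population=pop, song_type=stype,
                clean_phrases=dict(repertoires[pop]),
            )

    mix = config.mixture()
    pops = list(mix)
    weights = np.array([mix[p] for p in pops], dtype=float)
    weights = weights / weights.sum()
    stopover = SongCorpus(origin_truth={})
    for j in range(config.n_stopover_singers):
        pop = pops[int(rng.choice(len(pops), p=weights))]
        sid = f"{config.stopover_location}{j + 1:02d}S1"
        themes = _recorded_themes(kept_order[pop], rng,
                                  config.singer_theme_drop_rate)
        if len(themes) > 1 and rng.random() < config.single_theme_rate:
            themes = (themes[int(rng.integers(len(themes)))],)
        singer = _sing(sid, themes, repertoires[pop], config, rng, labels)
        stopover.add(singer)
        stopover.origin_truth[sid] = pop
        truth[sid] = GroundTruthRecord(
            singer_id=sid, population=pop,
            song_type=config.song_type_assignments[pop],
            clean_phrases={t: repertoires[pop][t] for t in themes},
        )
    return grounds, stopover, truth


def paper_scale_preset(seed: int = 2015) -> SyntheticConfig:
    """A configuration matching the South Pacific study design.

    Six wintering-ground populations with the field sample sizes (EA 11,
    NC 11, TO 8, NI 7, CI 8, FP 7; 52 singers in all), 39 stopover singers,
    and a stopover mixture proportional to the sampled western/central
    ground sizes with zero weight on eastern Australia and French Polynesia
    (populations whose migration does not pass the stopover).  Song types:
    type 2 in the west (NC, TO, NI), type 1a in the central Pacific (CI,
    FP), type 3 only in eastern Australia.  About a fifth of stopover
    singers are recorded with a single theme, mirroring the field corpus.
    """
    return SyntheticConfig(
        seed=seed,
        n_unit_types=24,
        song_type_assignments={
            "EA": "3", "NC": "2", "TO": "2", "NI": "2", "CI": "1a", "FP": "1a",
        },
        singers_per_population={
            "EA": 11, "NC": 11, "TO": 8, "NI": 7, "CI": 8, "FP": 7,
        },
        n_stopover_singers=39,
        stopover_mixture={"NC": 11.0, "TO": 8.0, "NI": 7.0, "CI": 8.0,
                          "EA": 0.0, "FP": 0.0},
        single_theme_rate=0.2,
    )


def write_ground_truth(
    truth: Mapping[str, GroundTruthRecord], path: str | Path
) -> None:
    """Ground-truth CSV: ``singer_id,population,song_type``."""
    pd.DataFrame(
        [
            {"singer_id": r.singer_id, "population": r.population,
             "song_type": r.song_type}
            for r in truth.values()
        ]
    ).to_csv(path, index=False)
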