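"""Data model and file I/O for transcribed song corpora.

A corpus is a collection of *singers*, each an ordered list of phrase
occurrences.  A phrase occurrence is a string of unit labels tagged with a
phrase-type code (theme number + variant letter, e.g. ``"3B"``).  Singer
identifiers follow the field convention ``<location><recording>S<singer>``
with an optional lower-case split suffix (``KI01S1a``) used when a silence
gap or multiple singers made it impossible to confirm the same animal was
still singing; suffixed IDs are treated as distinct singers throughout.

On-disk format is a UTF-8 TSV with header::

    singer_id  location  recording  phrase_index  phrase_type  theme  units

one row per phrase occurrence in sung order, ``units`` a space-separated
sequence of unit labels (canonically lower-cased on read).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CorpusError",
    "PhraseString",
    "Singer",
    "SongCorpus",
    "PAPER_LOCATIONS",
    "read_corpus",
    "write_corpus",
    "phrase_inventory",
    "theme_sequence_of",
    "merge_corpora",
    "corpus_summary",
]

#: Location codes used in the South Pacific field study: eastern Australia,
#: New Caledonia, Tonga, Niue, Cook Islands, French Polynesia and the
#: Kermadec Islands migratory stopover.  Corpora are not restricted to these.
PAPER_LOCATIONS = ("EA", "NC", "TO", "NI", "CI", "FP", "KI")

TSV_COLUMNS = (
    "singer_id",
    "location",
    "recording",
    "phrase_index",
    "phrase_type",
    "theme",
    "units",
)

_SINGER_ID_RE = re.compile(r"^([A-Z]{2})(\d+)S(\d+)([a-z]?)$")
_PHRASE_TYPE_RE = re.compile(r"^(\d+)([A-Z])$")


class CorpusError(ValueError):
    """Malformed transcription data."""


@dataclass(frozen=True)
class PhraseString:
    """One phrase occurrence: an ordered string of unit labels.

    ``phrase_type`` is a theme number plus a variant letter (``"1A"``,
    ``"12B"``); the theme is derived from the leading digits.
    """

    units: tuple[str, ...]
    phrase_type: str

    def __post_init__(self) -> None:
        if len(self.units) < 1:
            raise CorpusError("phrase must contain at least one unit")
        if any((not u) or any(c.isspace() for c in u) for u in self.units):
            raise CorpusError(f"invalid unit labels in {self.units!r}")
        if not _PHRASE_TYPE_RE.match(self.phrase_type):
            raise CorpusError(
                f"phrase_type {self.phrase_type!r} is not of the form '3B'"
            )

    @property
    def theme(self) -> int:
        """Theme number encoded in the phrase-type digits."""
        return int(_PHRASE_TYPE_RE.match(self.phrase_type).group(1))


@dataclass
class Singer:
    """A singer: identity plus its ordered phrase occurrences."""

    singer_id: str
    phrases: list[PhraseString] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.parse_id(self.singer_id)  # validates

    @staticmethod
    def parse_id(singer_id: str) -> tuple[str, int, int, str]:
        """Split ``'KI01S1a'`` into (location, recording, singer number, suffix)."""
        m = _SINGER_ID_RE.match(singer_id)
        if not m:
            raise CorpusError(
                f"singer_id {singer_id!r} does not match "
                "<LOCATION><recording>S<singer>[suffix]"
            )
        loc, rec, num, suffix = m.groups()
        return loc, int(rec), int(num), suffix

    @property
    def location(self) -> str:
        return self.parse_id(self.singer_id)[0]

    @property
    def recording(self) -> int:
        return self.parse_id(self.singer_id)[1]

    @property
    def phrase_types(self) -> set[str]:
        return {p.phrase_type for p in self.phrases}

    @property
    def themes(self) -> set[int]:
        return {p.theme for p in self.phrases}

    @property
    def theme_sequence(self) -> list[int]:
        return theme_sequence_of(self)


def theme_sequence_of(singer: Singer) -> list[int]:
    """The order in which themes were sung, consecutive repeats collapsed.

    Phrases of the same theme are repeated back-to-back within a song, so
    e.g. phrase themes ``[1, 1, 2, 3, 3]`` yield ``[1, 2, 3]`` while a
    revisit ``[1, 2, 1]`` is preserved.
    """
    if not singer.phrases:
        raise CorpusError(f"singer {singer.singer_id} has no phrases")
    seq: list[int] = []
    for p in singer.phrases:
        if not seq or seq[-1] != p.theme:
            seq.append(p.theme)
    return seq


@dataclass
class SongCorpus:
    """A set of singers, optionally carrying synthetic ground-truth origins."""

    singers: dict[str, Singer] = field(default_factory=dict)
    origin_truth: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for sid, s in self.singers.items():
            if sid != s.singer_id:
                raise CorpusError(f"singer keyed {sid!r} has id {s.singer_id!r}")

    @property
    def unit_inventory(self) -> set[str]:
        return {u for s in self.singers.values() for p in s.phrases for u in p.units}

    @property
    def locations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.singers.values():
            seen.setdefault(s.location, None)
        return list(seen)

    def singers_at(self, location: str) -> list[Singer]:
        return [s for s in self.singers.values() if s.location == location]

    def add(self, singer: Singer) -> None:
        if singer.singer_id in self.singers:
            raise CorpusError(f"duplicate singer_id {singer.singer_id!r}")
        self.singers[singer.singer_id] = singer


def read_corpus(path: str | Path, locations: Sequence[str] | None = None) -> SongCorpus:
    """Read a transcription TSV into a validated :class:`SongCorpus`.

    Rows with the same ``singer_id`` are appended to that singer in file
    order.  Unit labels are lower-cased on read.  ``locations``, when given,
    restricts the admissible location codes (e.g. :data:`PAPER_LOCATIONS`).

    Raises :class:`CorpusError` naming the offending line on malformed input.
    """
    path = Path(path)
    corpus = SongCorpus()
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cols = tuple(header.split("\t"))
        if cols != TSV_COLUMNS:
            raise CorpusError(
                f"{path}: expected columns {TSV_COLUMNS}, found {cols}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(TSV_COLUMNS):
                raise CorpusError(
                    f"{path}:{lineno}: expected {len(TSV_COLUMNS)} columns, "
                    f"found {len(fields)}"
                )
            row = dict(zip(TSV_COLUMNS, fields))
            try:
                loc, rec, _, _ = Singer.parse_id(row["singer_id"])
            except CorpusError as exc:
                raise CorpusError(f"{path}:{lineno}: {exc}") from None
            if row["location"] != loc:
                raise CorpusError(
                    f"{path}:{lineno}: location {row['location']!r} does not "
                    f"match singer_id prefix {loc!r}"
                )
            if locations is not None and loc not in locations:
                raise CorpusError(f"{path}:{lineno}: unknown location code {loc!r}")
            try:
                if int(row["recording"]) != rec:
                    raise CorpusError(
                        f"recording {row['recording']} does not match "
                        f"singer_id {row['singer_id']!r}"
                    )
                units = tuple(u.lower() for u in row["units"].split())
                phrase = PhraseString(units=units, phrase_type=row["phrase_type"])
                if int(row["theme"]) != phrase.theme:
                    raise CorpusError(
                        f"theme column {row['theme']} inconsistent with "
                        f"phrase_type {row['phrase_type']!r}"
                    )
            except CorpusError as exc:
                raise CorpusError(f"{path}:{lineno}: {exc}") from None
            except ValueError as exc:
                raise CorpusError(f"{path}:{lineno}: {exc}") from None
            sid = row["singer_id"]
            if sid not in corpus.singers:
                corpus.singers[sid] = Singer(singer_id=sid)
            corpus.singers[sid].phrases.append(phrase)
    return corpus


def write_corpus(corpus: SongCorpus, path: str | Path) -> None:
    """Write ``corpus`` as a transcription TSV re-readable by :func:`read_corpus`.

    Ground-truth origins, when present, are not part of the transcription
    format; write them separately (see :mod:`levensong.synthetic`).
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for singer in corpus.singers.values():
            loc, rec, _, _ = Singer.parse_id(singer.singer_id)
            for i, p in enumerate(singer.phrases):
                fh.write(
                    "\t".join(
                        (
                            singer.singer_id,
                            loc,
                            str(rec),
                            str(i),
                            p.phrase_type,
                            str(p.theme),
                            " ".join(p.units),
                        )
                    )
                    + "\n"
                )


def phrase_inventory(corpus: SongCorpus, location: str) -> set[str]:
    """Distinct phrase-type codes sung by any singer at ``location``.

    Pooled over all singers: presence of a phrase type at a wintering ground
    is a property of the ground as a whole.
    """
    singers = corpus.singers_at(location)
    if not singers:
        raise CorpusError(f"no singers at location {location!r}")
    return {pt for s in singers for pt in s.phrase_types}


def merge_corpora(*corpora: SongCorpus) -> SongCorpus:
    """Union of corpora; singer IDs must not collide."""
    merged = SongCorpus()
    truth: dict[str, str] = {}
    for c in corpora:
        for s in c.singers.values():
            merged.add(s)
        if c.origin_truth:
            truth.update(c.origin_truth)
    if truth:
        merged.origin_truth = truth
    return merged


def corpus_summary(corpus: SongCorpus) -> str:
    """Plain-text report: singer counts and phrase inventory per location."""
    lines = [f"singers: {len(corpus.singers)}", f"unit types: {len(corpus.unit_inventory)}"]
    for loc in corpus.locations:
        singers = corpus.singers_at(loc)
        inv = sorted(phrase_inventory(corpus, loc))
        lines.append(f"{loc}: {len(singers)} singers, phrase types: {' '.join(inv)}")
    return "\n".join(lines)
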