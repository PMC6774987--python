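"""Weighted Levenshtein distance and the Levenshtein similarity index (LSI).

The edit distance between two unit (or theme) sequences is the minimum total
cost of substitutions, insertions and deletions converting one into the
other.  At the phrase level, substitution costs in [0, 1] reflect acoustic
similarity between unit types while indels cost 1; at the song (theme
sequence) level the analysis is unweighted (all operations cost 1).

The LSI normalizes distance by the longer sequence length::

    LSI(a, b) = 1 - LD(a, b) / max(|a|, |b|)

which lies in [0, 1] because no optimal edit script can cost more than
``max(|a|, |b|)`` when substitutions cost at most the indel cost of 1.

Each singer is represented by its medoid ("median") string: the attested
rendition minimizing summed edit distance to the singer's other renditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from levensong.corpus import SongCorpus, theme_sequence_of
from levensong.units import CostMatrix

__all__ = [
    "weighted_ld",
    "lsi",
    "medoid_string",
    "SimilarityMatrix",
    "phrase_similarity_matrix",
    "song_similarity_matrix",
]

Labels = Sequence


def weighted_ld(a: Labels, b: Labels, costs: CostMatrix | None = None) -> float:
    """Minimum-cost edit distance between label sequences ``a`` and ``b``.

    With ``costs`` given, substituting *x* for *y* costs ``costs.cost(x, y)``
    and indels cost ``costs.indel_cost``; unweighted (``costs=None``) uses
    substitution cost 1 for unequal labels and indel cost 1.  Computed by
    full dynamic programming; sequences here are short (tens of symbols).

    Raises ``KeyError`` naming the label if a label is missing from the cost
    matrix.
    """
    la, lb = len(a), len(b)
    if costs is None:
        sub = lambda x, y: 0.0 if x == y else 1.0  # noqa: E731
        indel = 1.0
    else:
        sub = lambda x, y: costs.cost(x, y)  # noqa: E731
        indel = costs.indel_cost
        for lab in set(a) | set(b):
            costs.index_of(lab)  # fail early, naming the label
    prev = [j * indel for j in range(lb + 1)]
    for i in range(1, la + 1):
        cur = [i * indel] + [0.0] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cur[j] = min(
                prev[j] + indel,            # delete a[i-1]
                cur[j - 1] + indel,         # insert b[j-1]
                prev[j - 1] + sub(ai, b[j - 1]),
            )
        prev = cur
    return float(prev[lb])


def lsi(a: Labels, b: Labels, costs: CostMatrix | None = None) -> float:
    """Levenshtein similarity index: ``1 - LD(a, b) / max(|a|, |b|)``."""
    m = max(len(a), len(b))
    if m == 0:
        raise ValueError("LSI undefined for two empty sequences")
    return 1.0 - weighted_ld(a, b, costs) / m


def medoid_string(
    strings: Sequence[Labels], costs: CostMatrix | None = None
) -> Labels:
    """The input string minimizing total edit distance to all the others.

    Ties break to the earliest occurrence in input order, so the result is
    deterministic and always an attested production.
    """
    if not strings:
        raise ValueError("medoid of an empty list is undefined")
    if len(strings) == 1:
        return strings[0]
    n = len(strings)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = weighted_ld(strings[i], strings[j], costs)
    return strings[int(np.argmin(d.sum(axis=1)))]


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise LSI scores with item identifiers."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise ValueError("self-similarity must be 1")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("similarities must lie in [0, 1]")

    def to_distance(self) -> np.ndarray:
        """Distance matrix ``d = 1 - LSI`` with an exactly zero diagonal."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return np.clip(d, 0.0, 1.0)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids)).to_csv(
            path, float_format="%.6f"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column labels differ")
        vals = df.to_numpy(dtype=float)
        vals = (vals + vals.T) / 2.0
        np.fill_diagonal(vals, 1.0)
        return cls(ids=tuple(str(c) for c in df.columns), values=vals)


def _pairwise_lsi(
    strings: list[Labels], costs: CostMatrix | None
) -> np.ndarray:
    n = len(strings)
    vals = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = lsi(strings[i], strings[j], costs)
    return vals


def phrase_similarity_matrix(
    corpus: SongCorpus, theme: int, costs: CostMatrix | None
) -> SimilarityMatrix:
    """Weighted LSI between medoid unit strings for one theme.

    One item per (singer, phrase type) that sang the theme, identified as
    ``"<singer_id>_<phrase_type>"``; the item's string is the medoid over
    that singer's renditions of that phrase type.
    """
    items: list[str] = []
    strings: list[Labels] = []
    for singer in corpus.singers.values():
        by_type: dict[str, list] = {}
        for p in singer.phrases:
            if p.theme == theme:
                by_type.setdefault(p.phrase_type, []).append(p.units)
        for ptype, rends in by_type.items():
            items.append(f"{singer.singer_id}_{ptype}")
            strings.append(medoid_string(rends, costs))
    if not items:
        raise ValueError(f"theme {theme} absent from corpus")
    n_singers = len({i.rsplit("_", 1)[0] for i in items})
    if n_singers < 2:
        raise ValueError(f"theme {theme} sung by fewer than 2 singers")
    return SimilarityMatrix(ids=tuple(items), values=_pairwise_lsi(strings, costs))


def song_similarity_matrix(corpus: SongCorpus) -> SimilarityMatrix:
    """Unweighted LSI between singers' representative theme sequences.

    Singers recorded with only one theme carry no sequence information at the
    song level and are excluded.  The representative sequence is the singer's
    collapsed theme sequence (the medoid of its attested renditions).
    """
    ids: list[str] = []
    seqs: list[list[int]] = []
    for singer in corpus.singers.values():
        seq = theme_sequence_of(singer)
        if len(set(seq)) < 2:
            continue
        ids.append(singer.singer_id)
        seqs.append(seq)
    if len(ids) < 2:
        raise ValueError("fewer than 2 singers with more than one theme")
    return SimilarityMatrix(ids=tuple(ids), values=_pairwise_lsi(seqs, None))
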