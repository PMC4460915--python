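"""The 12-level ordinal count scale used for individual counts.

Volunteers (and experts) estimate group size on the scale
1, 2, ..., 10, 11-50, 51+ rather than as an exact integer. The scale is
totally ordered; medians and "within one bin" distances are taken on the
ordinal levels, never on interpolated numbers.
"""

from __future__ import annotations

import functools
from typing import Iterable, Sequence

__all__ = ["CountBin", "COUNT_BINS", "ordinal_median", "combine_counts"]

_LABELS: tuple[str, ...] = tuple(str(i) for i in range(1, 11)) + ("11-50", "51+")
_LEVEL_OF = {label: i for i, label in enumerate(_LABELS)}
# Lower bound of each bin, used for the saturating sum when duplicate
# species rows are merged within one classification.
_LOWER_BOUND = tuple(range(1, 11)) + (11, 51)


@functools.total_ordering
class CountBin:
    """One level of the ordinal count scale.

    Instances are interned per level; equality and ordering follow the
    scale order 1 < 2 < ... < 10 < 11-50 < 51+.
    """

    __slots__ = ("level",)
    _cache: dict[int, "CountBin"] = {}

    def __new__(cls, level: int) -> "CountBin":
        if not 0 <= level < len(_LABELS):
            raise ValueError(f"count-bin level out of range: {level}")
        try:
            return cls._cache[level]
        except KeyError:
            obj = super().__new__(cls)
            object.__setattr__(obj, "level", level)
            cls._cache[level] = obj
            return obj

    def __setattr__(self, name: str, value: object) -> None:
        raise AttributeError("CountBin is immutable")

    @classmethod
    def parse(cls, text: str | int) -> "CountBin":
        """Parse a bin from its table representation.

        Accepts the literal strings ``"1"`` ... ``"10"``, ``"11-50"``,
        ``"51+"`` (en dash tolerated) and plain integers 1-10.
        """
        if isinstance(text, int):
            text = str(text)
        label = text.strip().replace("–", "-")
        if label.endswith(".0"):  # pandas may float-ify a numeric column
            label = label[:-2]
        try:
            return cls(_LEVEL_OF[label])
        except KeyError:
            raise ValueError(f"not a count bin: {text!r}") from None

    @classmethod
    def from_number(cls, n: int) -> "CountBin":
        """Bin containing an exact individual count ``n`` >= 1."""
        if n < 1:
            raise ValueError("counts start at 1")
        if n <= 10:
            return cls(n - 1)
        if n <= 50:
            return cls(10)
        return cls(11)

    @property
    def label(self) -> str:
        return _LABELS[self.level]

    @property
    def lower_bound(self) -> int:
        return _LOWER_BOUND[self.level]

    def distance(self, other: "CountBin") -> int:
        """Ordinal distance in bins; 10 and 11-50 are adjacent (distance 1)."""
        return abs(self.level - other.level)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountBin) and self.level == other.level

    def __lt__(self, other: "CountBin") -> bool:
        return self.level < other.level

    def __hash__(self) -> int:
        return hash(("CountBin", self.level))

    def __repr__(self) -> str:
        return f"CountBin({self.label!r})"

    def __str__(self) -> str:
        return self.label


#: All twelve bins in scale order.
COUNT_BINS: tuple[CountBin, ...] = tuple(CountBin(i) for i in range(len(_LABELS)))


def ordinal_median(bins: Sequence[CountBin] | Iterable[CountBin]) -> CountBin:
    """Median on the ordinal scale; even-length inputs take the lower
    of the two middle bins so the result stays a real bin."""
    ordered = sorted(bins, key=lambda b: b.level)
    if not ordered:
        raise ValueError("median of empty count list")
    return ordered[(len(ordered) - 1) // 2]


def combine_counts(a: CountBin, b: CountBin) -> CountBin:
    """Combine two counts of one species reported within one classification.

    Lower-bound arithmetic with saturation: numeric bins sum exactly
    (1 + 1 -> 2); any sum landing in 11..50 gives the 11-50 bin; anything
    beyond 50 (including any operand of 51+) saturates at 51+.
    """
    return CountBin.from_number(a.lower_bound + b.lower_bound)
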