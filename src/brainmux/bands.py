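"""Frequency band schemes.

A band scheme is an ordered list of ``(name, f_low, f_high)`` tuples with
non-overlapping, increasing frequency ranges in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence


@dataclass(frozen=True)
class Band:
    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not self.f_low < self.f_high:
            raise ValueError(f"band {self.name!r}: f_low must be < f_high")
        if self.f_low < 0:
            raise ValueError(f"band {self.name!r}: negative frequency")


class BandScheme:
    """Ordered, non-overlapping set of frequency bands."""

    def __init__(self, bands: Sequence[tuple[str, float, float]] | Sequence[Band]):
        parsed = [b if isinstance(b, Band) else Band(*b) for b in bands]
        if not parsed:
            raise ValueError("band scheme must contain at least one band")
        for prev, cur in zip(parsed, parsed[1:]):
            if cur.f_low <= prev.f_high:
                raise ValueError(
                    f"bands must be increasing and non-overlapping: "
                    f"{prev.name!r} ({prev.f_low}-{prev.f_high}) vs "
                    f"{cur.name!r} ({cur.f_low}-{cur.f_high})"
                )
        self._bands = tuple(parsed)

    def __iter__(self) -> Iterator[Band]:
        return iter(self._bands)

    def __len__(self) -> int:
        return len(self._bands)

    def __getitem__(self, i: int) -> Band:
        return self._bands[i]

    @property
    def names(self) -> list[str]:
        return [b.name for b in self._bands]

    def index(self, name: str) -> int:
        for i, b in enumerate(self._bands):
            if b.name == name:
                return i
        raise KeyError(f"unknown band {name!r}")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BandScheme) and self._bands == other._bands

    def __repr__(self) -> str:
        inner = ", ".join(f"{b.name}:{b.f_low}-{b.f_high}Hz" for b in self._bands)
        return f"BandScheme({inner})"


#: Canonical 7-band scheme (Hz) used throughout: delta through gamma.
DEFAULT_BANDS = BandScheme(
    [
        ("delta", 2.0, 4.0),
        ("theta", 4.5, 7.5),
        ("alpha1", 8.0, 10.5),
        ("alpha2", 11.0, 13.0),
        ("beta1", 13.5, 20.0),
        ("beta2", 20.5, 29.5),
        ("gamma", 30.0, 45.0),
    ]
)
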