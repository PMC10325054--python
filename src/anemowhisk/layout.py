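"""Whisker-pad layout and spatial arrangement schemes.

The pad layout places every tracked whisker on an integer (row, column)
grid: the two supra-orbital whiskers (lSO, sSO), the straddlers
(alpha, beta, gamma, delta) and the mystacial whiskers of rows A-E,
arcs 1-4.  Arrangement schemes partition the laid-out whiskers into
spatial groups (arcs, rows, concentric semicircles, oblique bands) and
feed the shuffle test in :mod:`anemowhisk.morphometrics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

#: Canonical whisker identities on the default pad.
DEFAULT_WHISKERS = (
    "lSO", "sSO",
    "alpha", "A1", "A2", "A3", "A4",
    "beta", "B1", "B2", "B3", "B4",
    "gamma", "C1", "C2", "C3", "C4",
    "delta", "D1", "D2", "D3", "D4",
    "E1", "E2", "E3", "E4",
)

SCHEME_NAMES = (
    "arcs",
    "rows",
    "semicircles_A1",
    "oblique45_A1",
    "oblique135_A4",
    "opposite_semicircle_E4",
)


@dataclass(frozen=True)
class ArrangementScheme:
    """A named partition of whisker identities into spatial groups."""

    name: str
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.groups.values())) < 2:
            raise ValueError(f"scheme {self.name!r} needs at least 2 groups")


@dataclass(frozen=True)
class PadLayout:
    """Grid positions of whiskers plus the declared scheme rules."""

    positions: Mapping[str, tuple[int, int]]
    scheme_rules: Mapping[str, Mapping[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.positions) != len(set(self.positions)):
            raise ValueError("duplicate whisker ids in layout")

    @property
    def whiskers(self) -> tuple[str, ...]:
        return tuple(self.positions)

    def scheme(self, name: str) -> ArrangementScheme:
        """Build the arrangement scheme ``name`` from its grid rule."""
        try:
            rule_spec = self.scheme_rules[name]
        except KeyError:
            raise KeyError(
                f"unknown scheme {name!r}; declared: {sorted(self.scheme_rules)}"
            ) from None
        rule = rule_spec["rule"]
        groups: dict[str, str] = {}
        if rule == "by_column":
            for w, (_, c) in self.positions.items():
                groups[w] = f"arc{c}"
        elif rule == "by_row":
            for w, (r, _) in self.positions.items():
                groups[w] = f"row{r}"
        elif rule == "chebyshev_from":
            ar, ac = self.positions[rule_spec["anchor"]]
            for w, (r, c) in self.positions.items():
                groups[w] = f"ring{max(abs(r - ar), abs(c - ac))}"
        elif rule == "diagonal_sum":
            for w, (r, c) in self.positions.items():
                groups[w] = f"diag{r + c}"
        elif rule == "diagonal_diff":
            for w, (r, c) in self.positions.items():
                groups[w] = f"diag{r - c}"
        else:
            raise ValueError(f"unknown scheme rule {rule!r}")
        return ArrangementScheme(name=name, groups=groups)

    def all_schemes(self) -> list[ArrangementScheme]:
        return [self.scheme(n) for n in self.scheme_rules]


def load_layout(path: str | None = None) -> PadLayout:
    """Load a pad layout from YAML; default is the packaged rat layout."""
    if path is None:
        text = (
            resources.files("anemowhisk.resources")
            .joinpath("pad_layout.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    positions = {str(k): (int(v[0]), int(v[1])) for k, v in raw["positions"].items()}
    return PadLayout(positions=positions, scheme_rules=raw.get("schemes", {}))


def default_layout() -> PadLayout:
    return load_layout(None)
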