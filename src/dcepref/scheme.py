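"""Attribute schemes, dummy coding and care-model profiles.

A discrete choice experiment (DCE) describes each hypothetical alternative by a
small set of attributes, each taking one of a few levels.  One level per
attribute is the *reference*: its coefficient is constrained to zero and every
other level gets a 0/1 indicator column (dummy coding).  A :class:`Profile` is
one full level assignment — one hypothetical care model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Attribute",
    "AttributeScheme",
    "Profile",
    "enumerate_full_factorial",
    "study_scheme",
]


def _slug(level: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", level.lower()).strip("_")


@dataclass(frozen=True)
class Attribute:
    """One DCE attribute: a name, its levels and the reference level.

    ``code`` is a short prefix for the indicator columns; each non-reference
    level maps to the column ``{code}_{level_codes[level]}``.
    """

    name: str
    levels: tuple[str, ...]
    reference: str
    code: str
    level_codes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"attribute {self.name!r} needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"attribute {self.name!r} has duplicate levels")
        if self.reference not in self.levels:
            raise ValueError(
                f"reference {self.reference!r} is not a level of {self.name!r}"
            )

    @property
    def nonreference_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference)

    def column(self, level: str) -> str:
        """Indicator column name for a non-reference level."""
        if level == self.reference:
            raise ValueError(f"{level!r} is the reference level of {self.name!r}")
        if level not in self.levels:
            raise ValueError(f"{level!r} is not a level of {self.name!r}")
        return f"{self.code}_{self.level_codes.get(level, _slug(level))}"


@dataclass(frozen=True)
class Profile:
    """One level assignment per attribute, in scheme attribute order."""

    levels: tuple[str, ...]

    def label(self, sep: str = "/") -> str:
        return sep.join(self.levels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.levels)


@dataclass(frozen=True)
class AttributeScheme:
    """Ordered attributes plus the dummy-coding map they induce."""

    attributes: tuple[Attribute, ...]

    def __post_init__(self) -> None:
        if not self.attributes:
            raise ValueError("scheme needs at least one attribute")
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ValueError("attribute names must be unique")
        cols = self.columns
        if len(set(cols)) != len(cols):
            raise ValueError("indicator column names must be unique")

    @property
    def columns(self) -> list[str]:
        """Indicator columns, attribute-major: sum over attributes of (levels - 1)."""
        return [a.column(l) for a in self.attributes for l in a.nonreference_levels]

    @property
    def n_params(self) -> int:
        return len(self.columns)

    def attribute(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    def validate_profile(self, profile: Profile) -> None:
        if len(profile.levels) != len(self.attributes):
            raise ValueError(
                f"profile has {len(profile.levels)} levels, scheme has "
                f"{len(self.attributes)} attributes"
            )
        for attr, level in zip(self.attributes, profile.levels):
            if level not in attr.levels:
                raise ValueError(f"{level!r} is not a level of {attr.name!r}")

    def profile(self, *levels: str) -> Profile:
        p = Profile(tuple(levels))
        self.validate_profile(p)
        return p

    def encode(self, profile: Profile) -> np.ndarray:
        """0/1 indicator vector of length ``n_params`` for a profile."""
        self.validate_profile(profile)
        x = np.zeros(self.n_params)
        cols = self.columns
        for attr, level in zip(self.attributes, profile.levels):
            if level != attr.reference:
                x[cols.index(attr.column(level))] = 1.0
        return x

    def full_factorial(self) -> list[Profile]:
        """Every distinct level combination once, in lexicographic order.

        Lexicographic with respect to the declared attribute order and each
        attribute's declared level order, so the enumeration is stable.
        """
        return [
            Profile(combo)
            for combo in product(*(a.levels for a in self.attributes))
        ]


def enumerate_full_factorial(scheme: AttributeScheme) -> list[Profile]:
    """All distinct profiles of the scheme (see :meth:`AttributeScheme.full_factorial`)."""
    return scheme.full_factorial()


#: Canonical level names of the MDR-TB community-based DOT study scheme.
FAMILY = "family member"
CHW = "community health worker"
EXPERT = "expert client"
WORK = "workplace"
HOME = "home"
SMS = "SMS"
PHONE = "phone call"
VOUCHER = "travel voucher"


def study_scheme() -> AttributeScheme:
    """The three-attribute scheme of the MDR-TB community-based care study.

    DOT provider (family member reference, community health worker, expert
    client), location of care (workplace reference, home) and additional
    support (SMS reference, phone call, travel voucher).  Dummy coding yields
    the five indicator columns ``c_chw, c_expert, l_home, s_phcall, s_tvouch``.
    """
    return AttributeScheme(
        (
            Attribute(
                name="provider",
                levels=(FAMILY, CHW, EXPERT),
                reference=FAMILY,
                code="c",
                level_codes={CHW: "chw", EXPERT: "expert"},
            ),
            Attribute(
                name="location",
                levels=(WORK, HOME),
                reference=WORK,
                code="l",
                level_codes={HOME: "home"},
            ),
            Attribute(
                name="support",
                levels=(SMS, PHONE, VOUCHER),
                reference=SMS,
                code="s",
                level_codes={PHONE: "phcall", VOUCHER: "tvouch"},
            ),
        )
    )


def scheme_from_dict(spec: Mapping) -> AttributeScheme:
    """Build a scheme from a plain mapping (as parsed from a YAML file).

    Expected shape::

        attributes:
          - name: provider
            code: c
            reference: family member
            levels: [family member, community health worker, expert client]
            level_codes: {community health worker: chw, expert client: expert}
    """
    attrs = []
    for a in spec["attributes"]:
        attrs.append(
            Attribute(
                name=a["name"],
                levels=tuple(a["levels"]),
                reference=a["reference"],
                code=a.get("code", _slug(a["name"])[0]),
                level_codes=dict(a.get("level_codes", {})),
            )
        )
    return AttributeScheme(tuple(attrs))


def scheme_to_dict(scheme: AttributeScheme) -> dict:
    return {
        "attributes": [
            {
                "name": a.name,
                "code": a.code,
                "reference": a.reference,
                "levels": list(a.levels),
                "level_codes": dict(a.level_codes),
            }
            for a in scheme.attributes
        ]
    }
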