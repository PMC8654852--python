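"""Strategy space of the donation game with private, binary opinions.

A strategy is ten bits: an action pair ``(a1, a0)`` saying whether to
cooperate with a recipient currently deemed good (``a1``) or bad (``a0``),
and two four-bit assessment tables.  ``c_ij`` is the new opinion assigned
to a donor who *cooperated*, indexed by the observer's current opinion of
the donor (``i``) and of the recipient (``j``); ``d_ij`` is the same for a
donor who *defected*.

The full space has 1024 strategies; swapping the good/bad labels
everywhere (the *mirror*) or noting that unconditional actors never read
their opinions reduces it to 258 canonical strategies: the 256
discriminators with action pair ``(1, 0)`` plus one unconditional
cooperator and one unconditional defector.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, fields
from enum import Enum
from typing import Iterator, Union

__all__ = [
    "BIT_FIELDS",
    "WILDCARD",
    "BehavioralClass",
    "Strategy",
    "RulePattern",
    "encode",
    "decode",
    "mirror",
    "behavioral_class",
    "canonical_set",
    "reduce_raw_space",
    "match_pattern",
    "catalog",
    "ALLC",
    "ALLD",
    "IMAGE_SCORING",
    "STANDING",
]

#: Bit order of the integer encoding, most significant bit first.
BIT_FIELDS = ("a1", "a0", "c11", "c10", "c01", "c00", "d11", "d10", "d01", "d00")

WILDCARD = "*"


class BehavioralClass(str, Enum):
    """Coarse behaviour determined by the action pair alone."""

    DISCRIMINATOR = "discriminator"  # (a1, a0) = (1, 0)
    PARADOXICAL = "paradoxical"      # (a1, a0) = (0, 1)
    ALLC = "allc"                    # a1 = a0 = 1
    ALLD = "alld"                    # a1 = a0 = 0


@dataclass(frozen=True, order=True)
class Strategy:
    """A ten-bit strategy ``(a1, a0 | c11 c10 c01 c00 | d11 d10 d01 d00)``."""

    a1: int
    a0: int
    c11: int
    c10: int
    c01: int
    c00: int
    d11: int
    d10: int
    d01: int
    d00: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v not in (0, 1):
                raise ValueError(
                    f"strategy bit {f.name!r} must be 0 or 1, got {v!r}"
                )

    # -- views -----------------------------------------------------------
    @property
    def bits(self) -> tuple[int, ...]:
        """The ten bits in encoding order."""
        return tuple(getattr(self, name) for name in BIT_FIELDS)

    @property
    def action(self) -> tuple[int, int]:
        return (self.a1, self.a0)

    @property
    def C(self) -> tuple[int, int, int, int]:
        """Assessment table after observed cooperation, (c11, c10, c01, c00)."""
        return (self.c11, self.c10, self.c01, self.c00)

    @property
    def D(self) -> tuple[int, int, int, int]:
        """Assessment table after observed defection, (d11, d10, d01, d00)."""
        return (self.d11, self.d10, self.d01, self.d00)

    @property
    def code(self) -> int:
        return encode(self)

    @property
    def bitstring(self) -> str:
        return "".join(str(b) for b in self.bits)

    def __str__(self) -> str:
        b = self.bitstring
        return f"{b[:2]}|{b[2:6]}|{b[6:]}"

    @classmethod
    def from_bits(cls, bits) -> "Strategy":
        bits = tuple(bits)
        if len(bits) != 10:
            raise ValueError(f"expected 10 bits, got {len(bits)}")
        return cls(*bits)


def encode(strategy: Strategy) -> int:
    """Pack a strategy into an integer in [0, 1023], ``a1`` most significant."""
    code = 0
    for bit in strategy.bits:
        code = (code << 1) | bit
    return code


def decode(code: int) -> Strategy:
    """Inverse of :func:`encode`."""
    if not isinstance(code, (int,)) or isinstance(code, bool):
        raise ValueError(f"strategy code must be an integer, got {code!r}")
    if not 0 <= code <= 1023:
        raise ValueError(f"strategy code must be in [0, 1023], got {code}")
    return Strategy.from_bits((code >> (9 - i)) & 1 for i in range(10))


def mirror(strategy: Strategy) -> Strategy:
    """Swap the good/bad labels everywhere.

    Actions are re-indexed (``a'_i = a_{1-i}``) and assessments are both
    re-indexed and negated (``c'_ij = 1 - c_{(1-i)(1-j)}``, same for d),
    so the mirrored strategy behaves identically to the original when all
    of its opinions are flipped.  The map is an involution.
    """
    s = strategy
    return Strategy(
        a1=s.a0,
        a0=s.a1,
        c11=1 - s.c00,
        c10=1 - s.c01,
        c01=1 - s.c10,
        c00=1 - s.c11,
        d11=1 - s.d00,
        d10=1 - s.d01,
        d01=1 - s.d10,
        d00=1 - s.d11,
    )


def behavioral_class(strategy: Strategy) -> BehavioralClass:
    a = strategy.action
    if a == (1, 1):
        return BehavioralClass.ALLC
    if a == (0, 0):
        return BehavioralClass.ALLD
    if a == (1, 0):
        return BehavioralClass.DISCRIMINATOR
    return BehavioralClass.PARADOXICAL


#: Canonical unconditional strategies.  The assessment bits of an
#: unconditional actor never influence behaviour (neither its own actions
#: nor any payoff-relevant opinion of others about third parties feed back
#: into play), so all-1 / all-0 tables are an arbitrary documented choice.
ALLC = Strategy(1, 1, 1, 1, 1, 1, 1, 1, 1, 1)
ALLD = Strategy(0, 0, 0, 0, 0, 0, 0, 0, 0, 0)

IMAGE_SCORING = Strategy(1, 0, 1, 1, 1, 1, 0, 0, 0, 0)
STANDING = Strategy(1, 0, 1, 1, 1, 1, 0, 1, 0, 1)


def canonical_set() -> list[Strategy]:
    """The 258 canonical strategies, sorted by integer code.

    256 discriminators (every assessment-table combination with action
    pair ``(1, 0)``) plus the canonical unconditional cooperator and
    defector.  Every raw strategy is behaviourally equivalent to a member
    or to the mirror of a member.
    """
    out = [ALLD]
    out.extend(
        Strategy(1, 0, *bits)
        for bits in itertools.product((0, 1), repeat=8)
    )
    out.append(ALLC)
    return sorted(out, key=encode)


def reduce_raw_space() -> list[Strategy]:
    """Enumerate all 1024 raw strategies and collapse equivalences.

    Unconditional strategies map to the canonical ALLC/ALLD
    representative; paradoxical strategies map to their (discriminator)
    mirror; discriminators represent themselves.  Returns the sorted,
    de-duplicated representative set (equals :func:`canonical_set`).
    """
    reps: set[Strategy] = set()
    for code in range(1024):
        s = decode(code)
        cls = behavioral_class(s)
        if cls is BehavioralClass.ALLC:
            reps.add(ALLC)
        elif cls is BehavioralClass.ALLD:
            reps.add(ALLD)
        elif cls is BehavioralClass.PARADOXICAL:
            reps.add(mirror(s))
        else:
            reps.add(s)
    return sorted(reps, key=encode)


Slot = Union[int, str]


@dataclass(frozen=True)
class RulePattern:
    """Ten slots, each 0, 1 or ``"*"``, with an optional cap on how many
    wildcard slots may be 0 in a matching strategy."""

    slots: tuple[Slot, ...]
    max_zero_wildcards: int | None = None

    def __post_init__(self) -> None:
        slots = tuple(self.slots)
        object.__setattr__(self, "slots", slots)
        if len(slots) != 10:
            raise ValueError(f"pattern needs 10 slots, got {len(slots)}")
        for k, v in zip(BIT_FIELDS, slots):
            if v not in (0, 1, WILDCARD):
                raise ValueError(f"pattern slot {k!r} must be 0, 1 or '*', got {v!r}")
        n_wild = sum(1 for v in slots if v == WILDCARD)
        m = self.max_zero_wildcards
        if m is not None and not (isinstance(m, int) and 0 <= m <= n_wild):
            raise ValueError(
                f"max_zero_wildcards must be an int in [0, {n_wild}], got {m!r}"
            )

    def matches(self, strategy: Strategy) -> bool:
        zero_wild = 0
        for slot, bit in zip(self.slots, strategy.bits):
            if slot == WILDCARD:
                zero_wild += 1 - bit
            elif slot != bit:
                return False
        if self.max_zero_wildcards is not None and zero_wild > self.max_zero_wildcards:
            return False
        return True

    def members(self) -> list[Strategy]:
        """All strategies matching the pattern, sorted by code."""
        return [s for s in map(decode, range(1024)) if self.matches(s)]


def match_pattern(strategy: Strategy, pattern: RulePattern) -> bool:
    if not isinstance(pattern, RulePattern):
        raise ValueError(f"expected a RulePattern, got {type(pattern).__name__}")
    return pattern.matches(strategy)


def catalog() -> dict[str, Strategy | RulePattern]:
    """Named strategies and rule patterns.

    Pattern slots follow the encoding order; cooperator patterns fix the
    action pair to (1, 0).  ``c1_4`` / ``c5_11`` / ``c12_15`` carry their
    maximum-zero-wildcard restriction (the matching strategies must keep
    the resident-on-resident opinion dynamics strictly increasing).
    """
    star = WILDCARD
    return {
        "allc": ALLC,
        "alld": ALLD,
        "image_scoring": IMAGE_SCORING,
        "standing": STANDING,
        # cooperator ESS families
        "c1_4": RulePattern((1, 0, 1, 1, 1, star, 0, star, 0, star), 1),
        "c5_11": RulePattern((1, 0, 1, 1, 1, star, 0, star, 1, star), 2),
        "c12_15": RulePattern((1, 0, 1, 1, 0, star, 1, star, 0, star), 1),
        # the eight public-assessment benchmark rules
        "leading_eight": RulePattern((1, 0, 1, star, 1, star, 0, 1, 0, star)),
        # shared structure of full-range defector ESSs
        "defector_d": RulePattern((1, 0, star, star, star, star, star, 0, star, 0)),
        "defector_c": RulePattern((1, 0, star, 0, star, 0, star, star, star, star)),
    }


def names_for(strategy: Strategy) -> list[str]:
    """Catalog names that the given strategy matches (exact or by pattern)."""
    out = []
    for name, entry in catalog().items():
        if isinstance(entry, Strategy):
            if entry == strategy:
                out.append(name)
        elif entry.matches(strategy):
            out.append(name)
    return out
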