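"""Four-digit root canal configuration (RCC) codes.

An RCC code ``c-m-a/f`` gives the number of root canals at the coronal limit
of the coronal, middle and apical root thirds, plus (after the slash) the
number of physiological foramina.  Two-rooted teeth carry one code per root,
labelled buccal/lingual.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["RCCCode", "RCCParseError", "parse_rcc", "format_rcc", "classify_rcc"]

_RCC_RE = re.compile(r"^(\d+)-(\d+)-(\d+)/(\d+)$")

ROOT_LABELS = ("single", "buccal", "lingual")


class RCCParseError(ValueError):
    """Malformed RCC text; carries the character position of the defect."""

    def __init__(self, text: str, position: int, message: str):
        self.text = text
        self.position = position
        super().__init__(f"invalid RCC {text!r} at position {position}: {message}")


@dataclass(frozen=True)
class RCCCode:
    """Canal counts at the three third limits plus physiological foramen count."""

    coronal: int
    middle: int
    apical: int
    foramina: int
    root_label: str = "single"
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        for name in ("coronal", "middle", "apical", "foramina"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"RCC digit {name} must be a non-negative integer, got {v!r}")
        if self.root_label not in ROOT_LABELS:
            raise ValueError(f"root_label must be one of {ROOT_LABELS}")

    @property
    def digits(self) -> tuple[int, int, int]:
        return (self.coronal, self.middle, self.apical)

    def __str__(self) -> str:
        return format_rcc(self)


def parse_rcc(text: str, root_label: str = "single") -> RCCCode:
    """Parse ``"c-m-a/f"`` text into an :class:`RCCCode`.

    The grammar is strict: three dash-separated integers, a slash, and the
    foramen count.  Multi-digit integers are allowed.
    """
    if not isinstance(text, str):
        raise RCCParseError(str(text), 0, "not a string")
    m = _RCC_RE.match(text.strip())
    if m is None:
        # locate the first position where the pattern breaks, for the message
        probe = re.compile(r"\d+-\d+-\d+/|\d+-\d+-|\d+-|")
        good = probe.match(text.strip())
        pos = good.end() if good else 0
        raise RCCParseError(text, pos, "expected digit-digit-digit/digit")
    c, mm_, a, f = (int(g) for g in m.groups())
    flags = ("no canal",) if (c, mm_, a, f) == (0, 0, 0, 0) else ()
    return RCCCode(c, mm_, a, f, root_label=root_label, flags=flags)


def format_rcc(code: RCCCode) -> str:
    """Render an :class:`RCCCode` in the standard ``c-m-a/f`` notation."""
    return f"{code.coronal}-{code.middle}-{code.apical}/{code.foramina}"


def classify_rcc(
    counts: tuple[int, int, int],
    n_physiological: int,
    root_label: str = "single",
) -> RCCCode:
    """Compose a code from per-third canal counts and the foramen count.

    ``counts`` are canal numbers at the coronal limits of the coronal, middle
    and apical thirds, in coronal->apical order; ``n_physiological`` is the
    number of physiological foramen records for the same root.
    """
    if len(counts) != 3:
        raise ValueError("need exactly three per-third canal counts")
    c, m, a = (int(x) for x in counts)
    f = int(n_physiological)
    if min(c, m, a, f) < 0:
        raise ValueError(f"negative canal/foramen counts: {counts}, {n_physiological}")
    flags = ("no canal",) if (c, m, a, f) == (0, 0, 0, 0) else ()
    return RCCCode(c, m, a, f, root_label=root_label, flags=flags)
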