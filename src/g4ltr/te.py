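"""Transposable-element records with LTR annotation and region calls.

An LTR retrotransposon is flanked by two long terminal repeats (LTRs)
which carry its promoter; the sequence between them is the internal (INT)
region.  Positions are classified as LTR, NEAR_LTR (within a configurable
margin of an LTR boundary; 350 bp reproduces the "immediate neighborhood"
used for count statements) or INT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "Superfamily",
    "Region",
    "RegionCall",
    "TERecord",
    "classify_position",
    "normalized_position",
]


class Superfamily(str, Enum):
    GYPSY = "Gypsy"
    COPIA = "Copia"
    OTHER = "Other"


class Region(str, Enum):
    LTR = "LTR"
    NEAR_LTR = "NEAR_LTR"
    INT = "INT"


@dataclass(frozen=True)
class RegionCall:
    region: Region
    which_ltr: str  # "5prime", "3prime" or "none"


Interval = tuple[int, int]


@dataclass(frozen=True)
class TERecord:
    """One TE family consensus with its LTR intervals (0-based half-open).

    Records without LTR annotation carry ``ltr5 = ltr3 = None`` and are
    flagged via ``has_ltrs``.
    """

    te_id: str
    superfamily: Superfamily
    sequence: str
    family_name: str = ""
    ltr5: Interval | None = None
    ltr3: Interval | None = None
    domains: tuple[tuple[str, Interval], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name, iv in (("ltr5", self.ltr5), ("ltr3", self.ltr3)):
            if iv is not None:
                s, e = iv
                if not (0 <= s < e <= n):
                    raise ValueError(
                        f"{self.te_id}: {name} interval {iv} outside sequence "
                        f"of length {n}"
                    )
        if self.ltr5 is not None and self.ltr3 is not None:
            if self.ltr5[1] > self.ltr3[0]:
                raise ValueError(
                    f"{self.te_id}: 5' LTR must precede and not overlap 3' LTR"
                )

    @property
    def has_ltrs(self) -> bool:
        return self.ltr5 is not None and self.ltr3 is not None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def ltr_len_total(self) -> int:
        total = 0
        for iv in (self.ltr5, self.ltr3):
            if iv is not None:
                total += iv[1] - iv[0]
        return total

    @property
    def int_len_total(self) -> int:
        return self.length - self.ltr_len_total


def classify_position(te: TERecord, pos: int, margin: int = 0) -> RegionCall:
    """Region of a position: LTR, NEAR_LTR (within ``margin`` nt of an LTR
    boundary, both flanks) or INT.  With margin 0, NEAR_LTR never occurs.
    """
    if not (0 <= pos < te.length):
        raise ValueError(f"position {pos} outside {te.te_id} (len {te.length})")
    for which, iv in (("5prime", te.ltr5), ("3prime", te.ltr3)):
        if iv is not None and iv[0] <= pos < iv[1]:
            return RegionCall(Region.LTR, which)
    if margin > 0:
        for which, iv in (("5prime", te.ltr5), ("3prime", te.ltr3)):
            if iv is None:
                continue
            if iv[0] - margin <= pos < iv[0] or iv[1] <= pos < iv[1] + margin:
                return RegionCall(Region.NEAR_LTR, which)
    return RegionCall(Region.INT, "none")


def normalized_position(te: TERecord, pos: int) -> float:
    """Position as a fraction of element length, in [0, 1)."""
    if te.length == 0:
        raise ValueError(f"{te.te_id}: zero-length element")
    if not (0 <= pos < te.length):
        raise ValueError(f"position {pos} outside {te.te_id}")
    return pos / te.length
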