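"""HLA allele nomenclature: parsing, formatting and allele-group truncation.

Alleles follow standard colon-delimited nomenclature, e.g. ``HLA-A*02:01`` or
``DQB1*03``. Only the eight classical loci analysed here are accepted; the
DRB3/4/5 loci are rejected explicitly because they travel in tight linkage
with DRB1 and are excluded from homozygosity analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: Loci supported by the analysis, in canonical order.
LOCI: tuple[str, ...] = ("A", "B", "C", "DRB1", "DQA1", "DQB1", "DPA1", "DPB1")
CLASS_I: tuple[str, ...] = ("A", "B", "C")
CLASS_II: tuple[str, ...] = ("DRB1", "DQA1", "DQB1", "DPA1", "DPB1")
#: Loci deliberately excluded (tight LD with DRB1).
EXCLUDED_LOCI: tuple[str, ...] = ("DRB3", "DRB4", "DRB5")

LOCUS_CLASS: dict[str, str] = {**{l: "I" for l in CLASS_I}, **{l: "II" for l in CLASS_II}}

_ALLELE_RE = re.compile(r"^(?:HLA-)?([A-Z0-9]+)\*([0-9A-Z:]+)$")
_EXPRESSION_SUFFIXES = ("N", "L", "S", "C", "A", "Q")


class AlleleParseError(ValueError):
    """Raised when an allele string cannot be interpreted."""


@dataclass(frozen=True, order=True)
class HlaAllele:
    """A structured HLA allele call.

    Parameters
    ----------
    locus:
        One of :data:`LOCI`.
    fields:
        One to four numeric field strings, e.g. ``("02", "01")`` for A*02:01.
    """

    locus: str
    fields: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise AlleleParseError(f"unsupported locus {self.locus!r}")
        if not 1 <= len(self.fields) <= 4:
            raise AlleleParseError(
                f"allele must have 1-4 fields, got {len(self.fields)}"
            )

    @property
    def resolution(self) -> int:
        """Number of nomenclature fields present (1 = allele group)."""
        return len(self.fields)

    def truncate(self, depth: int) -> "HlaAllele":
        """Return the allele truncated to at most ``depth`` fields."""
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if depth >= len(self.fields):
            return self
        return HlaAllele(self.locus, self.fields[:depth])

    def __str__(self) -> str:
        return f"{self.locus}*{':'.join(self.fields)}"


def parse_allele(text: str) -> HlaAllele:
    """Parse an allele string such as ``"HLA-A*02:01"`` or ``"DQB1*03"``.

    Whitespace anywhere in the string is ignored. Expression-variant
    suffixes (N, L, Q, ...) are rejected, as are the DRB3/4/5 loci.
    """
    if not isinstance(text, str):
        raise AlleleParseError(f"expected a string, got {type(text).__name__}")
    compact = re.sub(r"\s+", "", text)
    m = _ALLELE_RE.match(compact)
    if m is None:
        raise AlleleParseError(f"malformed allele string {text!r}")
    locus, rest = m.group(1), m.group(2)
    if locus in EXCLUDED_LOCI:
        raise AlleleParseError(
            f"locus {locus} is excluded from this analysis (tight linkage with DRB1)"
        )
    if locus not in LOCI:
        raise AlleleParseError(f"unknown locus {locus!r} in {text!r}")
    fields = rest.split(":")
    if any(f == "" for f in fields):
        raise AlleleParseError(f"malformed field separator in {text!r}")
    last = fields[-1]
    if last and last[-1] in _EXPRESSION_SUFFIXES and last[:-1].isdigit():
        raise AlleleParseError(
            f"expression suffix {last[-1]!r} not supported in {text!r}"
        )
    for f in fields:
        if not f.isdigit():
            raise AlleleParseError(f"non-numeric field {f!r} in {text!r}")
    return HlaAllele(locus, tuple(fields))


def to_group(allele: HlaAllele) -> HlaAllele:
    """Truncate an allele to its allele group (first field). Idempotent."""
    return allele.truncate(1)
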