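"""Fork substrate descriptions.

The unwinding substrate is a 40-bp duplex flanked by single-stranded
poly-dT tails that mimic a replication fork.  For the stepping analysis
only the base-pair *class* matters: AT base pairs melt fast, GC base
pairs act as thermodynamic barriers.  Named presets place between zero
and three consecutive GC base pairs after ten AT base pairs (positions
11-13, 1-based from the fork junction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

AT = "AT"
GC = "GC"

_VALID = frozenset({AT, GC})


@dataclass(frozen=True)
class SubstrateSpec:
    """Layout of the duplex to be unwound.

    Parameters
    ----------
    pairs:
        Ordered base-pair classes from the fork junction inward, each
        ``"AT"`` or ``"GC"``.
    tail_5, tail_3:
        Single-stranded tail lengths in nucleotides (metadata; the
        default 31-nt tails match the fork design).
    label_positions:
        Base-pair indices of donor and acceptor attachment (metadata
        only; the dyes do not enter the kinetics).
    """

    pairs: Tuple[str, ...]
    tail_5: int = 31
    tail_3: int = 31
    label_positions: Tuple[int, int] = (0, 0)
    name: str = field(default="custom", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        if len(self.pairs) < 1:
            raise ValueError("substrate must contain at least one base pair")
        bad = set(self.pairs) - _VALID
        if bad:
            raise ValueError(f"base-pair classes must be AT or GC, got {sorted(bad)}")
        if self.tail_5 < 0 or self.tail_3 < 0:
            raise ValueError("tail lengths must be non-negative")

    @property
    def length(self) -> int:
        """Duplex length in base pairs."""
        return len(self.pairs)

    @property
    def gc_positions(self) -> Tuple[int, ...]:
        """1-based positions (from the fork) of GC base pairs."""
        return tuple(i + 1 for i, p in enumerate(self.pairs) if p == GC)

    def is_gc(self, position: int) -> bool:
        """True if the 1-based base pair ``position`` is GC."""
        return self.pairs[position - 1] == GC


def make_substrate(length: int = 40, gc_positions: Sequence[int] = (),
                   name: str = "custom") -> SubstrateSpec:
    """Build an all-AT duplex of ``length`` bp with GC at ``gc_positions`` (1-based)."""
    gc = set(gc_positions)
    if gc and (min(gc) < 1 or max(gc) > length):
        raise ValueError("gc_positions out of range")
    pairs = tuple(GC if i + 1 in gc else AT for i in range(length))
    return SubstrateSpec(pairs=pairs, name=name)


#: 40-bp all-AT fork.
AT40 = make_substrate(40, (), name="AT40")
#: single GC barrier at position 11.
GC1 = make_substrate(40, (11,), name="1GC")
#: two consecutive GC base pairs at 11-12.
GC2 = make_substrate(40, (11, 12), name="2GC")
#: three consecutive GC base pairs at 11-13.
GC3 = make_substrate(40, (11, 12, 13), name="3GC")

PRESETS = {"AT40": AT40, "1GC": GC1, "2GC": GC2, "3GC": GC3}


def get_substrate(name: str) -> SubstrateSpec:
    """Look up a preset substrate by name (``AT40``, ``1GC``, ``2GC``, ``3GC``)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown substrate preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
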