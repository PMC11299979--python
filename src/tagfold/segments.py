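"""Secondary-structure segment maps for the beta-grasp fold.

Ubiquitin-like modifiers share the beta-grasp topology but not sequence, so
per-residue comparison between, say, ubiquitin and a Fat10 domain is not
meaningful.  Observables (temperature coefficients, order parameters,
entropies) are instead averaged over named secondary-structure segments and
compared segment-wise.  A :class:`SegmentMap` names each element and the
residue range it covers in a particular protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# Canonical ubiquitin secondary-structure boundaries (residue numbers,
# inclusive).  Overridable: homologous proteins need their own map.
UBIQUITIN_SEGMENTS: dict[str, tuple[int, int]] = {
    "b1": (2, 7),
    "b2": (11, 17),
    "a1": (23, 34),
    "b3": (40, 45),
    "b4": (48, 50),
    "a2-loop": (51, 63),
    "b5": (66, 71),
}


@dataclass
class SegmentMap:
    """Named secondary-structure elements mapped to inclusive residue ranges."""

    segments: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(UBIQUITIN_SEGMENTS)
    )

    def __post_init__(self) -> None:
        occupied: dict[int, str] = {}
        for name, (lo, hi) in self.segments.items():
            if lo > hi:
                raise ValueError(f"segment {name!r} has inverted range ({lo}, {hi})")
            for r in range(lo, hi + 1):
                if r in occupied:
                    raise ValueError(
                        f"segment {name!r} overlaps {occupied[r]!r} at residue {r}"
                    )
                occupied[r] = name

    def segment_of(self, residue: int) -> str | None:
        for name, (lo, hi) in self.segments.items():
            if lo <= residue <= hi:
                return name
        return None

    def residues_in(self, name: str) -> list[int]:
        lo, hi = self.segments[name]
        return list(range(lo, hi + 1))

    @property
    def names(self) -> list[str]:
        return list(self.segments)
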