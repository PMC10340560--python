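"""Bipolar 10-20 montage definitions and channel-name resolution.

The pipeline works on longitudinal bipolar derivations. Eighteen channels
are recorded; the two midline derivations (Fz-Cz, Cz-Pz) carry no
lateralization information and are dropped for analysis, leaving eight
symmetric (left, right) pairs. The canonical 16-channel order is
pair-major: the eight left members first, then the eight right members,
so pair ``i`` is the channel index pair ``(i, i + 8)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import MontageError

#: The eight symmetric (left hemisphere, right hemisphere) bipolar pairs.
SYMMETRIC_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1-F7", "Fp2-F8"),
    ("F7-T3", "F8-T4"),
    ("T3-T5", "T4-T6"),
    ("T5-O1", "T6-O2"),
    ("Fp1-F3", "Fp2-F4"),
    ("F3-C3", "F4-C4"),
    ("C3-P3", "C4-P4"),
    ("P3-O1", "P4-O2"),
)

#: Midline derivations present in the full recording montage only.
MIDLINE_CHANNELS: tuple[str, ...] = ("Fz-Cz", "Cz-Pz")

#: The 18-channel recording montage, in acquisition order.
FULL_CHANNELS: tuple[str, ...] = (
    "Fp1-F7", "F7-T3", "T3-T5", "T5-O1",
    "Fp2-F8", "F8-T4", "T4-T6", "T6-O2",
    "Fp1-F3", "F3-C3", "C3-P3", "P3-O1",
    "Fp2-F4", "F4-C4", "C4-P4", "P4-O2",
    "Fz-Cz", "Cz-Pz",
)


def normalize_channel_name(name: str) -> str:
    """Canonicalize a derivation label for matching.

    Matching is case-insensitive and treats ``-`` and ``_`` as the same
    separator, so ``"Fp1-F7"``, ``"FP1_F7"`` and ``"fp1-f7 "`` all resolve
    to the same key.
    """
    return name.strip().upper().replace("_", "-").replace(" ", "")


@dataclass(frozen=True)
class MontageSpec:
    """The bipolar montage: full channel list and symmetric pair table.

    Attributes
    ----------
    full_channels
        All recorded derivations (18 by default).
    symmetric_pairs
        Eight (left, right) derivation pairs.
    """

    full_channels: tuple[str, ...] = FULL_CHANNELS
    symmetric_pairs: tuple[tuple[str, str], ...] = SYMMETRIC_PAIRS
    _index: dict[str, str] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(self.symmetric_pairs) != 8:
            raise MontageError(
                f"expected 8 symmetric pairs, got {len(self.symmetric_pairs)}"
            )
        lefts = [l for l, _ in self.symmetric_pairs]
        rights = [r for _, r in self.symmetric_pairs]
        flat = lefts + rights
        if len({normalize_channel_name(c) for c in flat}) != 16:
            raise MontageError("pair members must be 16 distinct channels")
        norm_full = {normalize_channel_name(c) for c in self.full_channels}
        missing = [c for c in flat if normalize_channel_name(c) not in norm_full]
        if missing:
            raise MontageError(f"pair channels absent from full montage: {missing}")
        object.__setattr__(
            self, "_index", {normalize_channel_name(c): c for c in self.full_channels}
        )

    @property
    def analysis_channels(self) -> tuple[str, ...]:
        """The 16 lateral channels in canonical pair-major order."""
        return tuple(l for l, _ in self.symmetric_pairs) + tuple(
            r for _, r in self.symmetric_pairs
        )

    @property
    def n_pairs(self) -> int:
        return len(self.symmetric_pairs)

    def resolve(self, name: str) -> str | None:
        """Map an arbitrary label to its canonical name, or None if unknown."""
        return self._index.get(normalize_channel_name(name))

    def pair_indices(self) -> list[tuple[int, int]]:
        """(left, right) index pairs into the canonical 16-channel order."""
        n = self.n_pairs
        return [(i, i + n) for i in range(n)]


#: Default montage shared across the package.
DEFAULT_MONTAGE = MontageSpec()
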