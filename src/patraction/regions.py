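"""Tissue region labels for the lumbar phantom.

Nine tissue classes plus the bed-mat layer. Vertebra and disc labels carry
their spinal level (T12..S for vertebral bodies, T12-L1..L5-S for the six
lumbar intervertebral discs). Each label maps to a stable small integer so
meshes can store a single ``region_id`` cell array.
"""

from __future__ import annotations

from dataclasses import dataclass

VERTEBRA_LEVELS: tuple[str, ...] = ("T12", "L1", "L2", "L3", "L4", "L5", "S")
DISC_LEVELS: tuple[str, ...] = ("T12-L1", "L1-L2", "L2-L3", "L3-L4", "L4-L5", "L5-S")


@dataclass(frozen=True)
class RegionLabel:
    """A tissue class, optionally qualified by spinal level."""

    kind: str
    level: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "VERTEBRA":
            if self.level not in VERTEBRA_LEVELS:
                raise ValueError(f"unknown vertebral level {self.level!r}; "
                                 f"expected one of {VERTEBRA_LEVELS}")
        elif self.kind == "DISC":
            if self.level not in DISC_LEVELS:
                raise ValueError(f"unknown disc level {self.level!r}; "
                                 f"expected one of {DISC_LEVELS}")
        elif self.level is not None:
            raise ValueError(f"region kind {self.kind!r} carries no level")

    @property
    def id(self) -> int:
        return _LABEL_TO_ID[self]

    def __str__(self) -> str:
        return self.kind if self.level is None else f"{self.kind}({self.level})"


SKIN = RegionLabel("SKIN")
SUBCUT_FAT = RegionLabel("SUBCUT_FAT")
SOFT_TISSUE = RegionLabel("SOFT_TISSUE")
MUSCLE = RegionLabel("MUSCLE")
EPIDURAL_FAT = RegionLabel("EPIDURAL_FAT")
CSF = RegionLabel("CSF")
CORD = RegionLabel("CORD")
MAT = RegionLabel("MAT")


def VERTEBRA(level: str) -> RegionLabel:
    return RegionLabel("VERTEBRA", level)


def DISC(level: str) -> RegionLabel:
    return RegionLabel("DISC", level)


_LABEL_TO_ID: dict[RegionLabel, int] = {
    SKIN: 1, SUBCUT_FAT: 2, SOFT_TISSUE: 3, MUSCLE: 4,
    EPIDURAL_FAT: 5, CSF: 6, CORD: 7, MAT: 8,
}
for _i, _lv in enumerate(VERTEBRA_LEVELS):
    _LABEL_TO_ID[VERTEBRA(_lv)] = 10 + _i
for _i, _lv in enumerate(DISC_LEVELS):
    _LABEL_TO_ID[DISC(_lv)] = 20 + _i

ID_TO_LABEL: dict[int, RegionLabel] = {v: k for k, v in _LABEL_TO_ID.items()}

ALL_LABELS: tuple[RegionLabel, ...] = tuple(_LABEL_TO_ID)


def label_map() -> dict[str, int]:
    """Region-name -> integer id map, suitable as a sidecar for mesh files."""
    return {str(lab): i for lab, i in _LABEL_TO_ID.items()}
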