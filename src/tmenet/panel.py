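"""Marker panels for multiplexed immunofluorescence cores."""

from __future__ import annotations

from dataclasses import dataclass, field


DEFAULT_MARKERS = ("DAPI", "CK", "CD8", "CD68", "FOXP3", "PD-1", "PD-L1")


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker labels of a multiplexed panel.

    The channel order of every core, TIFF page order, and every feature
    vector in the pipeline follows ``names``.  DAPI must be present because
    nucleus morphology is computed from it.
    """

    names: tuple = field(default=DEFAULT_MARKERS)

    def __post_init__(self):
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        if "DAPI" not in names:
            raise ValueError("panel must contain a DAPI channel")

    @property
    def C(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def dapi_index(self) -> int:
        return self.index("DAPI")


DEFAULT_PANEL = MarkerPanel()
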