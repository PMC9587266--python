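"""Marker panel definitions for a 35-plex imaging-mass-cytometry antibody panel.

The default panel mirrors a melanoma TME study design: 20 lineage markers used
for cell-type calling, plus functional/checkpoint markers that are excluded
from unsupervised subtyping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 20 markers used to define cell types (lineage / structural markers).
LINEAGE_MARKERS: tuple[str, ...] = (
    "CD45", "CD3", "CD4", "CD8a", "FoxP3", "CD20", "CD68", "CD14", "CD16",
    "CD11c", "CD11b", "IDO", "Vimentin", "aSMA", "E-cadherin", "EpCAM",
    "CAIX", "VEGF", "PDGFRb", "CollagenI",
)

#: Immune-checkpoint proteins and PD-L1, excluded from subtype clustering.
CHECKPOINT_MARKERS: tuple[str, ...] = (
    "PD-1", "PD-L1", "CTLA-4", "LAG-3", "TIM-3", "ICOS", "TIGIT",
)

#: Additional functional / identity markers completing the 35-plex panel.
EXTRA_MARKERS: tuple[str, ...] = (
    "HLA-DR", "Ki67", "FAP", "CD19", "GranzymeB", "CD45RA", "CD45RO", "TOX",
)

DEFAULT_PANEL_NAMES: tuple[str, ...] = LINEAGE_MARKERS + EXTRA_MARKERS + CHECKPOINT_MARKERS
assert len(DEFAULT_PANEL_NAMES) == 35


@dataclass(frozen=True)
class MarkerPanel:
    """An antibody panel with the marker subsets used at each phenotyping stage.

    Parameters
    ----------
    names
        All channel names, in acquisition (channel) order.
    lineage_markers
        Markers used for the main-type clustering stage.
    excluded_for_subtyping
        Markers (checkpoints + PD-L1) dropped at the subtype stage.
    """

    names: tuple[str, ...] = DEFAULT_PANEL_NAMES
    lineage_markers: tuple[str, ...] = LINEAGE_MARKERS
    excluded_for_subtyping: tuple[str, ...] = CHECKPOINT_MARKERS

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("panel names contain duplicates")
        missing = set(self.lineage_markers) - set(self.names)
        if missing:
            raise ValueError(f"lineage markers not in panel: {sorted(missing)}")
        missing = set(self.excluded_for_subtyping) - set(self.names)
        if missing:
            raise ValueError(f"excluded markers not in panel: {sorted(missing)}")

    @property
    def subtyping_markers(self) -> tuple[str, ...]:
        """All markers minus the checkpoint set — used at the subtype stage."""
        excl = set(self.excluded_for_subtyping)
        return tuple(m for m in self.names if m not in excl)

    def index(self, marker: str) -> int:
        return self.names.index(marker)


DEFAULT_PANEL = MarkerPanel()

#: Fixed two-level cell ontology: subtype -> main type.
SUBTYPE_ONTOLOGY: dict[str, str] = {
    "CD4+T": "lymphoid", "CD8+T": "lymphoid", "DPT": "lymphoid",
    "Treg": "lymphoid", "B": "lymphoid",
    "MC1": "myeloid", "MC2": "myeloid", "MC3": "myeloid",
    "MC4": "myeloid", "MC5": "myeloid", "MC6": "myeloid",
    "S1": "stromal", "S2": "stromal", "S3": "stromal",
    "S4": "stromal", "S5": "stromal",
    "T1": "tumor", "T2": "tumor", "T3": "tumor", "T4": "tumor",
}

SUBTYPES: tuple[str, ...] = tuple(SUBTYPE_ONTOLOGY)
MAIN_TYPES: tuple[str, ...] = ("lymphoid", "myeloid", "stromal", "tumor")
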