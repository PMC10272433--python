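"""AAL-116 parcellation table and basal-ganglia region names.

The automated anatomical labelling (AAL) atlas divides the brain into 116
named regions. The label table ships as a packaged text resource listing
``(label_value, region_name)`` in atlas order; label values follow the
original sparse AAL numbering, so indices are label *values*, never
positions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "BG_REGIONS",
    "BG_STRUCTURES",
    "LabelTable",
    "Parcellation",
    "load_aal116",
]

#: The six basal-ganglia regions analysed (bilateral caudate, putamen, pallidum).
BG_REGIONS = (
    "Caudate_L",
    "Caudate_R",
    "Putamen_L",
    "Putamen_R",
    "Pallidum_L",
    "Pallidum_R",
)

#: Bilateral structures -> their two hemispheric region names.
BG_STRUCTURES = {
    "Caudate": ("Caudate_L", "Caudate_R"),
    "Putamen": ("Putamen_L", "Putamen_R"),
    "Pallidum": ("Pallidum_L", "Pallidum_R"),
}


@dataclass(frozen=True)
class LabelTable:
    """Ordered atlas label table: 116 unique ``(label_value, name)`` entries."""

    labels: tuple[int, ...]
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.names):
            raise ValueError("labels and names differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("label values are not unique")
        if len(self.names) != 116:
            raise ValueError(f"expected 116 regions, got {len(self.names)}")
        missing = [r for r in BG_REGIONS if r not in self.names]
        if missing:
            raise ValueError(f"basal-ganglia regions missing from table: {missing}")

    def __len__(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        """Positional (column) index of a region name."""
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown region name: {name!r}") from None


@dataclass(frozen=True)
class Parcellation:
    """A 3-D integer label image together with its label table.

    ``bg_regions`` is fixed to the six basal-ganglia names; the invariant
    that they appear in the table is enforced by :class:`LabelTable`.
    """

    label_image: np.ndarray
    label_table: LabelTable
    bg_regions: tuple[str, ...] = field(default=BG_REGIONS)

    def __post_init__(self) -> None:
        img = np.asarray(self.label_image)
        if img.ndim != 3:
            raise ValueError(f"label image must be 3-D, got shape {img.shape}")
        if not np.issubdtype(img.dtype, np.integer):
            raise ValueError("label image must be integer-valued")


def load_aal116() -> LabelTable:
    """Load the packaged AAL-116 label table."""
    text = (resources.files("bgfc.data") / "aal116_labels.tsv").read_text()
    labels: list[int] = []
    names: list[str] = []
    for line in text.strip().splitlines()[1:]:
        value, name = line.split("\t")
        labels.append(int(value))
        names.append(name)
    return LabelTable(tuple(labels), tuple(names))
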