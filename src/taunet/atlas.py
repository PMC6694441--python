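"""Region atlas: the fixed 90-region AAL parcellation used for all matrices.

The atlas order is canonical: every subject-by-region table, correlation
matrix and adjacency matrix in this package indexes regions in this order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered list of region labels shared by all matrices.

    Parameters
    ----------
    names : tuple of str
        Distinct region labels; the order is fixed and defines matrix axes.
    """

    names: tuple[str, ...]
    hemisphere: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("atlas region labels must be distinct")
        hemi = tuple("L" if n.endswith("_L") else "R" if n.endswith("_R") else "?"
                     for n in self.names)
        object.__setattr__(self, "hemisphere", hemi)

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def indices(self, names) -> list[int]:
        return [self.names.index(n) for n in names]


def load_aal90() -> RegionAtlas:
    """Load the packaged 90-region AAL atlas (45 labels per hemisphere)."""
    text = resources.files("taunet.data").joinpath("aal90.txt").read_text()
    names = tuple(line.strip() for line in text.splitlines() if line.strip())
    atlas = RegionAtlas(names)
    if len(atlas) != 90:
        raise RuntimeError(f"packaged AAL atlas has {len(atlas)} labels, expected 90")
    return atlas
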