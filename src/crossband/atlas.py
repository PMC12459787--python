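"""Region atlas: names, tissue classes, and bilateral groupings.

The default atlas is the 84-region parcellation used throughout the
pipeline: 62 Desikan-Killiany cortical parcels (31 per hemisphere,
excluding temporal pole, frontal pole and entorhinal cortex), 14
subcortical parcels (7 per hemisphere) and 8 non-gray-matter parcels
(white matter and ventricles) that index systemic physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["RegionAtlas", "default_atlas", "synthetic_atlas", "load_atlas", "write_atlas"]

CLASSES = ("cortical", "subcortical", "nongray")

# 31 DK cortical labels retained after excluding temporalpole, frontalpole
# and entorhinal (not covered by the acquisition volume in all subjects).
_DK_CORTICAL = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "fusiform", "inferiorparietal", "inferiortemporal", "isthmuscingulate",
    "lateraloccipital", "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "parahippocampal", "paracentral", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "transversetemporal", "insula",
]

_SUBCORTICAL = [
    "thalamus", "pallidum", "amygdala", "caudate", "putamen", "accumbens",
    "hippocampus",
]


class AtlasError(ValueError):
    """Raised for structurally invalid atlas tables."""


@dataclass
class RegionAtlas:
    """Ordered region table with hemisphere, tissue class and bilateral group.

    The backing table has columns ``name``, ``hemisphere`` (L/R/midline),
    ``class`` (cortical/subcortical/nongray) and ``bilateral_group``.
    Bilateral groups partition the regions; single-region models are
    trained on one bilateral group at a time.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"name", "hemisphere", "class", "bilateral_group"}
        missing = required - set(self.table.columns)
        if missing:
            raise AtlasError(f"atlas table missing columns: {sorted(missing)}")
        if self.table["name"].duplicated().any():
            dups = self.table.loc[self.table["name"].duplicated(), "name"].tolist()
            raise AtlasError(f"duplicate region names: {dups}")
        bad = set(self.table["class"]) - set(CLASSES)
        if bad:
            raise AtlasError(f"unknown tissue classes: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RegionAtlas) and self.table.equals(other.table)

    def class_of(self, name: str) -> str:
        return str(self.table.set_index("name").loc[name, "class"])

    def regions_of_class(self, cls: str) -> list[str]:
        if cls not in CLASSES:
            raise AtlasError(f"unknown class {cls!r}")
        return self.table.loc[self.table["class"] == cls, "name"].tolist()

    @property
    def gray_regions(self) -> list[str]:
        return self.table.loc[self.table["class"] != "nongray", "name"].tolist()

    @property
    def nongray_regions(self) -> list[str]:
        return self.regions_of_class("nongray")

    def bilateral_groups(self, classes: tuple[str, ...] | None = None) -> dict[str, list[str]]:
        """Map bilateral-group id -> member region names, in table order."""
        tab = self.table
        if classes is not None:
            tab = tab[tab["class"].isin(classes)]
        out: dict[str, list[str]] = {}
        for name, grp in zip(tab["name"], tab["bilateral_group"]):
            out.setdefault(str(grp), []).append(name)
        return out

    def gray_bilateral_groups(self) -> dict[str, list[str]]:
        return self.bilateral_groups(classes=("cortical", "subcortical"))

    def indices(self, names: list[str]) -> list[int]:
        pos = {n: i for i, n in enumerate(self.names)}
        try:
            return [pos[n] for n in names]
        except KeyError as exc:
            raise AtlasError(f"region {exc.args[0]!r} not in atlas") from None


def default_atlas() -> RegionAtlas:
    """The 84-region atlas: 62 cortical + 14 subcortical + 8 non-gray.

    Bilateral groups: 31 cortical pairs, 7 subcortical pairs, a white-matter
    pair, a ventricle group (lateral + inferior-lateral, both hemispheres)
    and the midline third/fourth ventricles as singleton groups: 42 groups.
    """
    rows = []
    for label in _DK_CORTICAL:
        for hemi in ("L", "R"):
            rows.append((f"ctx-{hemi.lower()}h-{label}", hemi, "cortical", label))
    for label in _SUBCORTICAL:
        for hemi in ("L", "R"):
            rows.append((f"{hemi.lower()}h-{label}", hemi, "subcortical", label))
    for hemi in ("L", "R"):
        rows.append((f"{hemi.lower()}h-cerebral-white-matter", hemi, "nongray", "cerebral-white-matter"))
    for hemi in ("L", "R"):
        rows.append((f"{hemi.lower()}h-lateral-ventricle", hemi, "nongray", "ventricles"))
    for hemi in ("L", "R"):
        rows.append((f"{hemi.lower()}h-inf-lat-vent", hemi, "nongray", "ventricles"))
    rows.append(("third-ventricle", "midline", "nongray", "third-ventricle"))
    rows.append(("fourth-ventricle", "midline", "nongray", "fourth-ventricle"))
    return RegionAtlas(pd.DataFrame(rows, columns=["name", "hemisphere", "class", "bilateral_group"]))


def synthetic_atlas(n_cortical: int = 62, n_subcortical: int = 14,
                    n_nongray: int = 8, bilateral: bool = True) -> RegionAtlas:
    """Reduced atlas with generated names, used for scaled-down simulations.

    With ``bilateral=True`` even class counts are laid out as L/R pairs
    sharing a bilateral group (an odd trailing region becomes a midline
    singleton); with ``bilateral=False`` every region is its own midline
    singleton group, useful when the analysis unit should be one region.
    """
    if min(n_cortical, n_subcortical, n_nongray) < 0:
        raise AtlasError("region counts must be nonnegative")
    if n_cortical + n_subcortical + n_nongray < 1:
        raise AtlasError("atlas must contain at least one region")
    rows = []
    prefixes = {"cortical": "ctx", "subcortical": "sub", "nongray": "ngm"}
    for cls, n in (("cortical", n_cortical), ("subcortical", n_subcortical), ("nongray", n_nongray)):
        pre = prefixes[cls]
        if not bilateral:
            for i in range(n):
                rows.append((f"{pre}{i:02d}", "midline", cls, f"{pre}{i:02d}"))
            continue
        for pair in range(n // 2):
            group = f"{pre}{pair:02d}"
            rows.append((f"{pre}{pair:02d}-lh", "L", cls, group))
            rows.append((f"{pre}{pair:02d}-rh", "R", cls, group))
        if n % 2:
            group = f"{pre}{n // 2:02d}m"
            rows.append((group, "midline", cls, group))
    return RegionAtlas(pd.DataFrame(rows, columns=["name", "hemisphere", "class", "bilateral_group"]))


def load_atlas(path) -> RegionAtlas:
    """Read an atlas TSV (columns: name, hemisphere, class, bilateral_group)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    return RegionAtlas(table)


def write_atlas(atlas: RegionAtlas, path) -> None:
    atlas.table.to_csv(path, sep="\t", index=False)
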