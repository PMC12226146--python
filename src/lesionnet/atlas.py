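"""Region parcellation skeleton.

Every matrix in the pipeline (time series, connectome, metric tables) is
indexed by a :class:`RegionAtlas`.  The default atlas mirrors a bilateral
cortical/subcortical parcellation with 78 regions: per hemisphere,
31 cortical regions, 7 subcortical structures, and 1 cerebellar region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Region", "RegionAtlas", "make_atlas"]

_SUBCORTICAL_NAMES = [
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "amygdala",
    "hippocampus",
    "accumbens",
]


@dataclass(frozen=True)
class Region:
    region_id: int
    name: str
    hemisphere: str  # "left" | "right"
    region_class: str  # "cortical" | "subcortical" | "cerebellar"


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered collection of brain regions.

    Regions are stored left hemisphere first, then right, each hemisphere
    ordered cortical, subcortical, cerebellar.  ``region_id`` equals the
    position in this ordering, so matrices indexed by the atlas need no
    separate lookup table.
    """

    regions: tuple[Region, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if ids != list(range(len(ids))):
            raise ValueError("region_ids must be consecutive integers starting at 0")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i: int) -> Region:
        return self.regions[i]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def ids_in_hemisphere(self, hemisphere: str) -> list[int]:
        return [r.region_id for r in self.regions if r.hemisphere == hemisphere]

    def ids_in_class(self, region_class: str) -> list[int]:
        return [r.region_id for r in self.regions if r.region_class == region_class]


def make_atlas(
    n_cortical_per_hemi: int = 31,
    n_subcortical_per_hemi: int = 7,
    n_cerebellar_per_hemi: int = 1,
) -> RegionAtlas:
    """Build a bilateral atlas with deterministic region naming.

    Defaults give the 78-region parcellation used throughout the package
    (2 x (31 cortical + 7 subcortical + 1 cerebellar)).

    Raises
    ------
    ValueError
        If any count is negative or the total number of regions is < 2.
    """
    counts = (n_cortical_per_hemi, n_subcortical_per_hemi, n_cerebellar_per_hemi)
    if any(c < 0 for c in counts):
        raise ValueError("region counts must be non-negative")
    per_hemi = sum(counts)
    if 2 * per_hemi < 2:
        raise ValueError(f"atlas must contain at least 2 regions, got {2 * per_hemi}")

    regions: list[Region] = []
    for hemi in ("left", "right"):
        prefix = "lh" if hemi == "left" else "rh"
        for k in range(n_cortical_per_hemi):
            regions.append(
                Region(len(regions), f"{prefix}_cortical_{k:02d}", hemi, "cortical")
            )
        for k in range(n_subcortical_per_hemi):
            name = (
                _SUBCORTICAL_NAMES[k]
                if k < len(_SUBCORTICAL_NAMES)
                else f"subcortical_{k:02d}"
            )
            regions.append(Region(len(regions), f"{prefix}_{name}", hemi, "subcortical"))
        for k in range(n_cerebellar_per_hemi):
            regions.append(
                Region(len(regions), f"{prefix}_cerebellum_{k:02d}", hemi, "cerebellar")
            )
    return RegionAtlas(tuple(regions))
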