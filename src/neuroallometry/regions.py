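"""Canonical registry of the investigated regional brain volumes.

The analysis operates on 22 regional volumes — cerebral white matter, the
brain stem, and left/right pairs of ten structures (ventral diencephalon,
cerebellum cortex, accumbens, amygdala, caudate, hippocampus, pallidum,
putamen, thalamus, hemispheric cortex) — plus total gray matter, which
together with cerebral white matter defines total brain volume (TBV).

Each region carries a default allometric exponent (slope of log10 volume on
log10 TBV), a typical volume at the reference TBV, and a residual SD on the
log10 scale.  Cerebral white matter is hyperallometric, the hemispheric
cortices isometric, and the subcortical structures hypoallometric, which is
the scaling pattern reported for typically developing cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: log10 of the reference TBV (~1.2e6 mm^3) at which typical volumes are pinned
REFERENCE_LOG10_TBV = 6.0792


@dataclass(frozen=True)
class Region:
    name: str
    fs_name: str          # FreeSurfer aseg-style column name
    typical_mm3: float    # typical volume at the reference TBV
    alpha: float          # default allometric exponent
    residual_sd: float    # residual SD of log10(volume) given log10(TBV)
    pair: str | None = None   # homologous contralateral region, if any
    subcortical: bool = False

    @property
    def intercept(self) -> float:
        """Default log10 intercept implied by the typical volume and exponent."""
        return math.log10(self.typical_mm3) - self.alpha * REFERENCE_LOG10_TBV


def _bilateral(base, fs_base, typical, alpha, sd, subcortical=True):
    left = Region(f"left_{base}", f"Left-{fs_base}", typical, alpha, sd,
                  pair=f"right_{base}", subcortical=subcortical)
    right = Region(f"right_{base}", f"Right-{fs_base}", typical, alpha, sd,
                   pair=f"left_{base}", subcortical=subcortical)
    return [right, left]


#: The 22 investigated regional volumes (model indicators), in table order.
REGIONS: list[Region] = [
    Region("cerebral_white_matter", "CerebralWhiteMatterVol", 470_000.0, 1.15, 0.015),
    Region("brain_stem", "Brain-Stem", 20_000.0, 0.85, 0.030, subcortical=True),
    *_bilateral("ventral_dc", "VentralDC", 4_100.0, 0.82, 0.030),
    *_bilateral("cerebellum_cortex", "Cerebellum-Cortex", 53_000.0, 0.90, 0.025),
    *_bilateral("accumbens", "Accumbens-area", 600.0, 0.63, 0.035),
    *_bilateral("amygdala", "Amygdala", 1_600.0, 0.74, 0.035),
    *_bilateral("caudate", "Caudate", 3_900.0, 0.70, 0.035),
    *_bilateral("hippocampus", "Hippocampus", 4_250.0, 0.75, 0.030),
    *_bilateral("pallidum", "Pallidum", 1_800.0, 0.80, 0.035),
    *_bilateral("putamen", "Putamen", 5_600.0, 0.78, 0.030),
    *_bilateral("thalamus", "Thalamus-Proper", 7_500.0, 0.85, 0.025),
    *_bilateral("cortex", "CortexVol", 240_000.0, 1.00, 0.010, subcortical=False),
]

#: Total gray matter is carried alongside the 22 indicators; TBV = GM + WM.
TOTAL_GRAY = Region("total_gray_matter", "TotalGrayVol", 730_000.0, 1.0, 0.01)

REGION_NAMES: list[str] = [r.name for r in REGIONS]
VOLUME_COLUMNS: list[str] = REGION_NAMES + [TOTAL_GRAY.name]

BY_NAME: dict[str, Region] = {r.name: r for r in REGIONS}
BY_NAME[TOTAL_GRAY.name] = TOTAL_GRAY

#: Homologous left/right pairs (each pair listed once, right first).
HOMOLOGOUS_PAIRS: list[tuple[str, str]] = [
    (r.name, r.pair) for r in REGIONS
    if r.pair is not None and r.name.startswith("right_")
]

#: Default alias map: FreeSurfer-style column name -> canonical name.
FREESURFER_ALIASES: dict[str, str] = {r.fs_name: r.name for r in REGIONS}
FREESURFER_ALIASES[TOTAL_GRAY.fs_name] = TOTAL_GRAY.name


def subcortical_names() -> list[str]:
    return [r.name for r in REGIONS if r.subcortical]
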