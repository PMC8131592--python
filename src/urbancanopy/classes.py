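"""Surface-class taxonomy shared across the pipeline.

Eight urban surface classes, in a fixed band order used by every fraction
stack and element-temperature stack in the package.  Emissivities are
class-constant broadband values typical of thermal-infrared retrievals over
the respective materials.
"""

from __future__ import annotations

import numpy as np

#: Fixed class order for all 8-band stacks.
SURFACE_CLASSES: tuple[str, ...] = (
    "tree_canopy",
    "grass_shrub",
    "bare_earth",
    "water",
    "building",
    "road",
    "other_impervious",
    "railroad",
)

N_CLASSES: int = len(SURFACE_CLASSES)

#: Index of each class in the band order.
CLASS_INDEX: dict[str, int] = {name: i for i, name in enumerate(SURFACE_CLASSES)}

TREE = CLASS_INDEX["tree_canopy"]
GRASS = CLASS_INDEX["grass_shrub"]
WATER = CLASS_INDEX["water"]
BUILDING = CLASS_INDEX["building"]

#: Class-constant broadband emissivities (unitless, in (0.8, 1]).
DEFAULT_EMISSIVITY: np.ndarray = np.array(
    [0.982, 0.976, 0.950, 0.991, 0.920, 0.955, 0.935, 0.945]
)


def emissivity_vector(table: dict[str, float] | None = None) -> np.ndarray:
    """Return an 8-vector of class emissivities in band order.

    ``table`` overrides defaults by class name; unknown names raise.
    """
    eps = DEFAULT_EMISSIVITY.copy()
    if table:
        for name, value in table.items():
            if name not in CLASS_INDEX:
                raise KeyError(f"unknown surface class {name!r}")
            if not (0.0 < value <= 1.0):
                raise ValueError(f"emissivity for {name} must be in (0, 1], got {value}")
            eps[CLASS_INDEX[name]] = value
    return eps
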