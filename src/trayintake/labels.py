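"""Fixed label tables shared by the renderer, the network and the volumetry.

The food head has 8 classes (background, the six food categories, plate);
the plate head has 5 (background + the four container types).  Every
container pixel not covered by food carries food-head label 7 ("plate").
"""

from __future__ import annotations

from .menu_db import FOOD_CATEGORIES

#: Food-head labels: 0 background, 1..6 food categories, 7 plate.
FOOD_LABELS: dict[str, int] = {"background": 0}
FOOD_LABELS.update({cat: i + 1 for i, cat in enumerate(FOOD_CATEGORIES)})
FOOD_LABELS["plate"] = 7

#: Plate-head labels: 0 background, then the four container types.
CONTAINER_TYPES: tuple[str, ...] = ("round_plate", "soup_bowl", "square_bowl", "glass")
PLATE_LABELS: dict[str, int] = {"background": 0}
PLATE_LABELS.update({name: i + 1 for i, name in enumerate(CONTAINER_TYPES)})

N_FOOD_CLASSES = len(FOOD_LABELS)  # 8
N_PLATE_CLASSES = len(PLATE_LABELS)  # 5

FOOD_LABEL_NAMES = {v: k for k, v in FOOD_LABELS.items()}
PLATE_LABEL_NAMES = {v: k for k, v in PLATE_LABELS.items()}


from dataclasses import dataclass

import numpy as np


@dataclass
class SegMaskPair:
    """Per-pixel food-class and plate-class label maps for one frame."""

    food_mask: np.ndarray
    plate_mask: np.ndarray

    def __post_init__(self) -> None:
        food = np.asarray(self.food_mask)
        plate = np.asarray(self.plate_mask)
        if food.shape != plate.shape:
            raise ValueError(
                f"mask shapes differ: food {food.shape} vs plate {plate.shape}"
            )
        if food.min() < 0 or food.max() >= N_FOOD_CLASSES:
            raise ValueError("food mask labels outside 0..7")
        if plate.min() < 0 or plate.max() >= N_PLATE_CLASSES:
            raise ValueError("plate mask labels outside 0..4")
        self.food_mask = food
        self.plate_mask = plate
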