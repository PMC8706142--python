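import numpy as np
import pytest

from trayintake.labels import SegMaskPair
from trayintake.synthetic_scene import (
    SYNTHETIC_INTRINSICS,
    random_scene,
    render_scene,
)

TABLE1_CSV = """date,variant,category,name,quantity,unit,energy_kcal,cho_g,protein_g,fat_g,fatty_acids_g
2021-01-11,A,soup,Potato and carrot cream soup (protein+),0.25,litres,150,14,9,6,3
2021-01-11,A,meat_fish,Trout fillet,0.12,kilograms,180,0,26,8,2.5
2021-01-11,A,side_dish,Potato wedges,0.2,kilograms,210,34,4,6,1.5
2021-01-11,A,vegetables_salad,Creamed spinach,0.15,kilograms,70,5,3,4,2
2021-01-11,A,dessert,Pineapple mousse (protein+),1,pieces,160,22,8,5,3
2021-01-11,B,soup,Potato and carrot cream soup (protein+),0.25,litres,150,14,9,6,3
2021-01-11,B,side_dish,Pappardelle noodles (soft homogenous),0.25,kilograms,280,48,9,4,1
2021-01-11,B,sauce,Bolognaise Sauce,0.1,litres,90,6,5,5,2
2021-01-11,B,dessert,Pineapple mousse (protein+),1,pieces,160,22,8,5,3
2021-01-11,C,soup,Potato and carrot cream soup (protein+),0.25,litres,150,14,9,6,3
2021-01-11,C,meat_fish,Trout fillet,0.12,kilograms,180,0,26,8,2.5
2021-01-11,C,side_dish,Potato wedges,0.2,kilograms,210,34,4,6,1.5
2021-01-11,C,vegetables_salad,Creamed spinach,0.15,kilograms,70,5,3,4,2
"""


@pytest.fixture()
def table1_menu_path(tmp_path):
    """A menu file encoding a typical day's three meal variants."""
    p = tmp_path / "menu.csv"
    p.write_text(TABLE1_CSV)
    return p


@pytest.fixture(scope="session")
def k_full():
    """Full-resolution synthetic camera (640 x 480, 0.25 mm depth counts)."""
    return SYNTHETIC_INTRINSICS


@pytest.fixture(scope="session")
def k96():
    """Reduced 128 x 96 camera for desk-scale segmentation experiments."""
    return SYNTHETIC_INTRINSICS.scaled(0.2)


def make_seg_scenes(n, seed, k, style="A"):
    """Render n random scenes as (rgb, SegMaskPair) training examples."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        frame, gt = render_scene(random_scene(rng, intrinsics=k, style=style))
        out.append((frame.rgb, SegMaskPair(gt.food_mask, gt.plate_mask)))
    return out


@pytest.fixture(scope="session")
def seg_scenes_small(k96):
    """Five small scenes shared by fast segmentation tests."""
    return make_seg_scenes(5, 42, k96)
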