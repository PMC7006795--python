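import numpy as np
import pandas as pd
import pytest


def make_plot(plot_id, records, *, latitude=48.0, longitude=10.0, area=200.0,
              tree_cover=60.0, continent="Eurasia"):
    """Long-format rows for one plot; records = (species, cover, woody, alien)."""
    return pd.DataFrame(
        [
            {
                "plot_id": plot_id,
                "latitude": latitude,
                "longitude": longitude,
                "area_m2": area,
                "tree_layer_cover": tree_cover,
                "continent": continent,
                "species_id": s,
                "cover": c,
                "woody": w,
                "alien_here": a,
            }
            for (s, c, w, a) in records
        ]
    )


@pytest.fixture
def simple_plot():
    return make_plot(
        "p1",
        [("focal", 30.0, True, False), ("A", 50.0, True, False),
         ("B", 20.0, True, False)],
    )


@pytest.fixture
def trait_table():
    """Six woody species with distinct, positive trait values."""
    rng = np.random.default_rng(11)
    species = ["focal", "A", "B", "C", "D", "E"]
    return pd.DataFrame(
        {
            "species_id": species,
            "sla_cm2_g": rng.uniform(80, 300, 6),
            "height_m": rng.uniform(5, 40, 6),
            "seed_mass_mg": rng.uniform(1, 500, 6),
            "wood_density_g_cm3": rng.uniform(0.3, 0.9, 6),
        }
    )
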