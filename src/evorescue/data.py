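"""Published reference data for the Taita Hills study system.

``TAITA_FRAGMENT_TABLE`` is the published per-fragment admixture summary
for the 19 montane-forest fragments known to hold the montane species:
fragment name, area (ha), mean population heterozygosity (% extraspecific
chromosomes, 50-replicate means after 300 years) under each of the five
habitat scenarios, and the across-scenario mean and standard deviation.
The one uninhabited fragment-scenario combination is missing (None); the
printed across-scenario mean for that row averages the defined cells
only. These values serve as regression inputs and as a cross-check for
the fragment-area analysis, not as simulator parameters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_COLUMNS = (
    "fragment", "area_ha", "control", "edge_depletion", "fragment_clearing",
    "corridor_planting", "plantation_conversion", "mean", "sd",
)

_ROWS = [
    ("Mbololo",       180, 6.07,  3.60,  5.95,  4.81,  6.04,  5.29, 1.08),
    ("Ngangao",       145, 4.98, 12.17,  3.97,  5.31,  4.24,  6.13, 3.42),
    ("Chawia",         91, 6.64,  6.85,  6.48,  5.00,  6.69,  6.33, 0.76),
    ("Msidunyi",       26, 5.53,  8.73,  7.13, 12.25,  0.91,  6.91, 4.18),
    ("Vuria extra 1",  22, 10.19, 10.76, 10.98, 15.09, 0.71,  9.55, 5.31),
    ("Ronge",          15, 10.83, 10.47, 10.52, 10.59, 10.57, 10.60, 0.14),
    ("Susu",           14, 11.36, 13.76, 34.15, 12.63, 11.31, 16.64, 9.84),
    ("Fururu",          8, 6.50,  7.08, 13.64,  7.19,  6.74,  8.23, 3.04),
    ("Vuria",           7, 11.02, 8.45, 12.96, 14.76,  None, 11.80, 2.70),
    ("Ndiwenyi",        5, 19.45, 19.85, 21.97, 17.27, 13.71, 18.45, 3.13),
    ("Macha E",         4, 11.94, 12.75, 15.91, 10.03, 15.60, 13.25, 2.50),
    ("Susu extra 1",    4, 17.99, 15.52, 22.63, 16.18, 12.69, 17.00, 3.68),
    ("Yale S",          4, 6.45,  6.37,  5.86,  5.92, 14.21,  7.76, 3.61),
    ("Yale extra N",    3, 16.05, 3.06,  5.86, 10.47, 10.24,  9.14, 4.96),
    ("Mwachora",        2, 4.20,  1.94,  1.81,  1.28,  3.05,  2.46, 1.17),
    ("Kichuchenyi",     1, 18.18, 28.69, 9.09, 16.48, 17.23, 17.93, 7.01),
    ("Wundanyi",        1, 21.59, 14.77, 13.64, 11.24, 18.94, 16.04, 4.17),
    ("Yale extra 1",    1, 18.10, 14.04, 14.65, 12.04, 18.54, 15.47, 2.78),
    ("Yale extra 2",    1, 20.08, 15.91, 12.50, 23.30, 17.56, 17.87, 4.10),
]


def taita_fragment_table() -> pd.DataFrame:
    """The published fragment heterozygosity summary as a tidy DataFrame."""
    frame = pd.DataFrame(_ROWS, columns=_COLUMNS)
    return frame.astype({c: float for c in _COLUMNS[2:]} | {"area_ha": int})


#: Fragment areas (ha) of the reference archipelago, largest first. Used as
#: the default fragment-size distribution for synthetic landscapes.
TAITA_FRAGMENT_AREAS: tuple[int, ...] = tuple(int(r[1]) for r in _ROWS)
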