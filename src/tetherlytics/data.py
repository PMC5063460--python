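"""Bundled reference values for archaebacterial tethered membranes.

Literature-reported lateral diffusion coefficients (nm^2/us) from
coarse-grained simulations of DphPC/GDPE tethered bilayers at 0% and 25%
tether density, by species and region.  These serve as inputs to the
ratio arithmetic in :func:`tetherlytics.diffusion.diffusion_reduction_factors`
and as realistic scales for the synthetic generators.
"""
from __future__ import annotations

import pandas as pd

_ROWS = [
    # density, species, region, D_par (nm^2/us), uncertainty
    ("0%", "DphPC", "proximal", 290.0, 23.0),
    ("0%", "GDPE", "proximal", 256.0, 36.0),
    ("0%", "DphPC", "distal", 289.0, 24.0),
    ("0%", "GDPE", "distal", 256.0, 38.0),
    ("0%", "W", "bulk_water", 2105.0, 288.0),
    ("0%", "W", "reservoir_water", 2730.0, 258.0),
    ("25%", "DphPC", "proximal", 87.0, 10.0),
    ("25%", "GDPE", "proximal", 116.0, 16.0),
    ("25%", "DphPC", "distal", 115.0, 12.0),
    ("25%", "GDPE", "distal", 128.0, 13.0),
    ("25%", "W", "bulk_water", 2010.0, 233.0),
    ("25%", "W", "reservoir_water", 1236.0, 110.0),
]


def lateral_diffusion_table() -> pd.DataFrame:
    """Reported lateral diffusion coefficients as a tidy DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=["tether_density", "species", "region", "D_par", "uncertainty"],
    )


#: Reported membrane thickness (nm) by tether density.
MEMBRANE_THICKNESS = {"0%": 3.48, "25%": 3.53}

#: Reported tethering-reservoir height (nm).
RESERVOIR_THICKNESS = 3.30

#: Reported PMF landmarks (kJ/mol): desorption and flip-flop barriers.
DESORPTION_ENERGY = {"0%": 85.93, "25%": 91.0}
FLIPFLOP_BARRIER = {"0%": 89.0, "25%": 103.17}

#: Equilibrium lipid position along the membrane normal (nm from centre).
PMF_MINIMUM_Z = 1.82

#: Area per headgroup of a free-standing DphPC bilayer (nm^2).
AREA_PER_LIPID = 0.69
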