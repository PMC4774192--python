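"""Unit conventions and conversions.

The model follows the conventions used throughout hepatic-metabolism
literature for perfused rat liver: metabolite concentrations in mM,
reaction rates in micromole per gram wet tissue per hour, time in hours,
hormone concentrations in pM.

Tissue amounts (umol per g wet weight) are converted to intracellular
concentrations (mM) through the cell-water content of liver tissue
(0.46 mL water per g) and the density of liver tissue (1.067 g/mL).
"""

CELL_WATER_PER_G = 0.46  # mL cell water per g wet weight
LIVER_DENSITY = 1.067  # g wet weight per mL tissue

#: multiply a flux in umol/g/h by this factor to obtain d[conc]/dt in mM/h
TISSUE_WATER_FACTOR = LIVER_DENSITY / CELL_WATER_PER_G


def convert_tissue_units(value_umol_per_g: float) -> float:
    """Convert a tissue amount in umol per g wet weight into mM.

    mM = (umol/g) / 0.46 * 1.067. The conversion is linear; negative
    amounts are rejected.
    """
    if value_umol_per_g < 0:
        raise ValueError(f"tissue amount must be >= 0, got {value_umol_per_g}")
    return value_umol_per_g / CELL_WATER_PER_G * LIVER_DENSITY


def flux_to_mM_per_h(flux_umol_per_g_per_h: float) -> float:
    """Convert a flux in umol/g/h into a concentration derivative in mM/h."""
    return flux_umol_per_g_per_h * TISSUE_WATER_FACTOR
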