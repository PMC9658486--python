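"""Published reference values for the *Acacia longifolia* harvest campaign.

These are the printed summary statistics of the destructive-harvest dataset
(37 single trees; 11 clear-cut 25 m^2 stand plots in SW Portugal) that the
synthetic generator emulates, the tissue chemistry table, and the constants
of the whole-plot validation exercise. They are treated as *inputs*: the
generator is calibrated against the min-max envelopes and means, and the
worked-example validation consumes the printed coefficients and masses.

Units follow the field conventions: heights in m, basal diameters in cm,
canopy areas in m^2, volumes in m^3, dry masses in kg, SOM in % of soil dry
mass, litter in kg/m^2, element concentrations in % (C, N) or permil (P),
isotope ratios in permil vs. VPDB (d13C) and vs. Air (d15N).
"""

from __future__ import annotations

from typing import NamedTuple


class SummaryRange(NamedTuple):
    """Published min, max and arithmetic mean of one campaign variable."""

    min: float
    max: float
    mean: float


#: Single-tree summary statistics (n = 37).
TREE_SUMMARY: dict[str, SummaryRange] = {
    "V": SummaryRange(2.4, 169.1, 26.9),
    "A": SummaryRange(1.2, 24.6, 7.2),
    "H": SummaryRange(2.1, 10.6, 4.9),
    "D": SummaryRange(1.9, 25.5, 9.8),
    "trunk_dry": SummaryRange(0.3, 110.3, 12.5),
    "branch_dry": SummaryRange(0.1, 11.2, 3.3),
    "foliage_dry": SummaryRange(0.2, 12.0, 4.1),
    "fb_dry": SummaryRange(0.3, 23.2, 7.3),
    "total_dry": SummaryRange(0.7, 129.9, 19.8),
}

#: Published min-max difference (range) as printed for single trees.
TREE_PRINTED_DELTA: dict[str, float] = {
    "V": 166.7,
    "A": 23.4,
    "H": 8.5,
    "D": 23.6,
    "trunk_dry": 110.0,
    "branch_dry": 11.1,
    "foliage_dry": 11.8,
    "fb_dry": 22.9,
    "total_dry": 129.2,
}

#: Stand-plot summary statistics (n = 11, ~25 m^2 clear-cut quadrats).
#: Litter minimum was printed as "<0.01"; stored as 0.0.
STAND_SUMMARY: dict[str, SummaryRange] = {
    "V": SummaryRange(3.9, 187.5, 70.5),
    "A": SummaryRange(1.2, 29.2, 15.0),
    "NrS": SummaryRange(3, 45, 10.8),
    "D_mean": SummaryRange(7.2, 34.1, 19.9),
    "H_mean": SummaryRange(0.4, 7.0, 3.0),
    "trunk_dry": SummaryRange(4.3, 133.6, 50.2),
    "fb_dry": SummaryRange(5.2, 50.4, 24.1),
    "total_dry": SummaryRange(9.5, 184.0, 74.4),
    "SOM": SummaryRange(0.3, 1.4, 0.7),
    "litter": SummaryRange(0.0, 1.9, 0.7),
}

STAND_PRINTED_DELTA: dict[str, float] = {
    "V": 183.6,
    "A": 28.0,
    "NrS": 42.0,
    "D_mean": 26.9,
    "H_mean": 6.6,
    "trunk_dry": 129.3,
    "fb_dry": 45.2,
    "total_dry": 174.5,
    "SOM": 1.1,
    "litter": 1.9,
}

#: Tissue chemistry: {(unit, tissue): {analyte: (mean, standard error) | None}}.
#: `None` marks analytes not measured for that tissue (e.g. branch P).
DEFAULT_CHEMISTRY: dict[tuple[str, str], dict[str, tuple[float, float] | None]] = {
    ("tree", "trunk"): {
        "C_pct": (43.2, 0.1),
        "N_pct": (0.6, 0.1),
        "P_permil": (0.8, 0.1),
        "d15N": (-1.2, 0.1),
        "d13C": (-27.5, 0.2),
    },
    ("tree", "branch"): {
        "C_pct": (45.1, 0.2),
        "N_pct": (1.1, 0.1),
        "P_permil": None,
        "d15N": (-1.7, 0.1),
        "d13C": (-25.9, 0.4),
    },
    ("tree", "foliage"): {
        "C_pct": (48.1, 0.2),
        "N_pct": (2.3, 0.1),
        "P_permil": (2.4, 0.2),
        "d15N": (-1.1, 0.1),
        "d13C": (-28.4, 0.2),
    },
    ("tree", "fb"): {
        "C_pct": (47.7, 0.2),
        "N_pct": (2.2, 0.1),
        "P_permil": None,
        "d15N": (-1.2, 0.1),
        "d13C": (-28.1, 0.3),
    },
    ("stand", "trunk"): {
        "C_pct": (44.1, 0.7),
        "N_pct": (0.6, 0.0),
        "P_permil": None,
        "d15N": (-2.2, 0.1),
        "d13C": (-27.5, 0.2),
    },
    ("stand", "fb"): {
        "C_pct": (47.2, 0.5),
        "N_pct": (2.0, 0.1),
        "P_permil": None,
        "d15N": (-2.1, 0.2),
        "d13C": (-29.0, 0.4),
    },
}

#: Whole-plot validation: the simplified volumetric model applied to the
#: final clear-cut area, with all inputs as printed.
WORKED_EXAMPLE = {
    "plot_volume_m3": 31711.0,      # DTM surface volume of the cut stand
    "intercept_kg": 6.297,          # combined model: BM ~ a + b * Vol
    "slope_kg_per_m3": 0.982,
    "fresh_biomass_kg": 52847.0,    # lorry-scale fresh weight of the cut
    "dry_matter_fraction": 0.6031,  # subsample dry/fresh mass ratio
    "measured_dry_kg": 31869.0,     # printed dry mass of the harvest
    "printed_deviation_pct": 2.3,
}

#: Ratio of the largest stand-plot to the largest single-tree compartment
#: masses, as printed (stand trunk 1.2x the tree maximum; F+B 2.2x).
PRINTED_MAX_RATIOS = {"trunk_dry": 1.2, "fb_dry": 2.2}
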