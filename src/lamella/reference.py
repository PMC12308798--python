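"""Literature-reported reference values for MMG stereoisomer membranes.

Gel-phase membrane properties reported for the two monomycoloyl-glycerol
analogs (MMG-1, non-native lipid-acid stereochemistry; MMG-6, native-like)
in three lamellar configurations, used as comparison baselines and as
inputs to in-table arithmetic checks: the interdigitated systems expand
the area per lipid by roughly 1.7x (MMG-1) relative to the
noninterdigitated double bilayer, and MMG-6 membranes run roughly 6 A
thinner than MMG-1 in the single-bilayer configuration.
"""

from __future__ import annotations

#: (system, analog) -> dict of membrane properties: APL_xy (A^2), membrane
#: thickness (A), per-bilayer thickness (A), each with standard deviation
MEMBRANE_PROPERTIES = {
    ("single_bilayer", "MMG-1"): {
        "apl_xy": 39.8, "apl_xy_sd": 0.1,
        "membrane_thickness": 36.3, "membrane_thickness_sd": 0.5,
        "bilayer_thickness": 36.3, "bilayer_thickness_sd": 0.5,
    },
    ("single_bilayer", "MMG-6"): {
        "apl_xy": 42.9, "apl_xy_sd": 0.2,
        "membrane_thickness": 30.5, "membrane_thickness_sd": 1.1,
        "bilayer_thickness": 30.5, "bilayer_thickness_sd": 1.1,
    },
    ("double_bilayer", "MMG-1"): {
        "apl_xy": 41.2, "apl_xy_sd": 0.1,
        "membrane_thickness": 83.2, "membrane_thickness_sd": 0.9,
        "bilayer_thickness": 41.6, "bilayer_thickness_sd": 3.7,
    },
    ("double_bilayer", "MMG-6"): {
        "apl_xy": 45.7, "apl_xy_sd": 0.1,
        "membrane_thickness": 63.7, "membrane_thickness_sd": 2.4,
        "bilayer_thickness": 31.9, "bilayer_thickness_sd": 2.3,
    },
    ("interdigitated", "MMG-1"): {
        "apl_xy": 72.0, "apl_xy_sd": 0.1,
        "membrane_thickness": 47.7, "membrane_thickness_sd": 0.1,
        "bilayer_thickness": 23.9, "bilayer_thickness_sd": 0.7,
    },
    ("interdigitated", "MMG-6"): {
        "apl_xy": 73.2, "apl_xy_sd": 0.1,
        "membrane_thickness": 46.1, "membrane_thickness_sd": 0.5,
        "bilayer_thickness": 23.1, "bilayer_thickness_sd": 0.7,
    },
}

#: (system, stereoisomer) -> glycerol-vector rotational decay parameters:
#: fast/slow characteristic times tau1/tau2 (ns) and amplitudes a1/a2
GLYCEROL_ROTATION = {
    ("single_bilayer", "2R3S"): {"tau1": 2.1, "a1": 0.23, "tau2": 57.3, "a2": 0.12},
    ("single_bilayer", "2S3R"): {"tau1": 2.0, "a1": 0.22, "tau2": 45.1, "a2": 0.12},
    ("single_bilayer", "2R3R"): {"tau1": 1.6, "a1": 0.22, "tau2": 77.0, "a2": 0.10},
    ("single_bilayer", "2S3S"): {"tau1": 1.6, "a1": 0.21, "tau2": 86.0, "a2": 0.10},
    ("double_bilayer", "2R3S"): {"tau1": 3.9, "a1": 0.13, "tau2": 104.9, "a2": 0.11},
    ("double_bilayer", "2S3R"): {"tau1": 3.5, "a1": 0.12, "tau2": 90.9, "a2": 0.10},
    ("double_bilayer", "2R3R"): {"tau1": 2.9, "a1": 0.11, "tau2": 115.6, "a2": 0.12},
    ("double_bilayer", "2S3S"): {"tau1": 2.9, "a1": 0.11, "tau2": 124.9, "a2": 0.12},
    ("interdigitated", "2R3S"): {"tau1": 6.6, "a1": 0.13, "tau2": 104.4, "a2": 0.13},
    ("interdigitated", "2S3R"): {"tau1": 5.5, "a1": 0.13, "tau2": 91.3, "a2": 0.12},
    ("interdigitated", "2R3R"): {"tau1": 3.8, "a1": 0.09, "tau2": 132.1, "a2": 0.14},
    ("interdigitated", "2S3S"): {"tau1": 3.8, "a1": 0.09, "tau2": 129.0, "a2": 0.13},
}


def apl_expansion_ratio(analog: str = "MMG-1") -> float:
    """Interdigitated vs noninterdigitated double-bilayer APL_xy ratio."""
    inter = MEMBRANE_PROPERTIES[("interdigitated", analog)]["apl_xy"]
    double = MEMBRANE_PROPERTIES[("double_bilayer", analog)]["apl_xy"]
    return inter / double


def single_bilayer_thinning() -> float:
    """MMG-1 minus MMG-6 single-bilayer membrane thickness (A)."""
    t1 = MEMBRANE_PROPERTIES[("single_bilayer", "MMG-1")]["membrane_thickness"]
    t6 = MEMBRANE_PROPERTIES[("single_bilayer", "MMG-6")]["membrane_thickness"]
    return t1 - t6
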