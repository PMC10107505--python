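"""Published reference values for myoglobin (Mb) and GFP.

These numbers come from published all-atom non-equilibrium MD studies of
hydrated proteins and serve as input data for internal-consistency checks
(they are *not* computed by this package): per-protein heat capacities and
gyration radii, and the reported kappa / G table for proteins in pure
water, averaged over solvent-box sizes of 3.0, 4.0 and 4.5 nm after
two-sided Grubbs screening.

Layout of :data:`TABLE_WATER`: ``TABLE_WATER[quantity][protein][basis]``
maps direction (``sphere``, ``radial``, ``longitudinal``) to
``(mean, sd)``.  kappa in W/K/m, G in MW/K/m^2.
"""

from __future__ import annotations

#: Heat capacity per mole of protein molecules, kJ/mol/K.
CP_KJ_MOL_K = {"Mb": 27.0, "GFP": 47.0}

#: Spherical gyration radius, nm.
GYRATION_RADIUS_NM = {"Mb": 1.529, "GFP": 1.667}

#: Reported Biot numbers (spherical model, mean +/- sd).
BIOT = {"Mb": (4.0, 0.7), "GFP": (4.6, 1.9)}

TABLE_WATER = {
    "kappa": {
        "Mb": {
            "gyration": {
                "sphere": (0.10, 0.02),
                "radial": (0.18, 0.03),
                "longitudinal": (0.28, 0.08),
            },
            "filling": {
                "sphere": (0.08, 0.01),
                "radial": (0.10, 0.02),
                "longitudinal": (0.24, 0.07),
            },
        },
        "GFP": {
            "gyration": {
                "sphere": (0.15, 0.03),
                "radial": (0.22, 0.04),
                "longitudinal": (0.86, 0.16),
            },
            "filling": {
                "sphere": (0.12, 0.02),
                "radial": (0.13, 0.02),
                "longitudinal": (0.75, 0.14),
            },
        },
    },
    "G": {
        "Mb": {
            "gyration": {
                "sphere": (255.0, 8.0),
                "radial": (732.0, 90.0),
                "longitudinal": (2230.0, 840.0),
            },
            "filling": {
                "sphere": (151.0, 5.0),
                "radial": (301.0, 37.0),
                "longitudinal": (1120.0, 420.0),
            },
        },
        "GFP": {
            "gyration": {
                "sphere": (309.0, 65.0),
                "radial": (967.0, 265.0),
                "longitudinal": (3670.0, 670.0),
            },
            "filling": {
                "sphere": (185.0, 39.0),
                "radial": (398.0, 109.0),
                "longitudinal": (1850.0, 340.0),
            },
        },
    },
}
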