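"""Published reference measurements for a five-patient brain-tumour
follow-up cohort, used as fixed numeric fixtures for the measurement
routines.

Diameters (cm) and ellipsoid volumes (cm^3) were read twice per patient:
a manual conventional reading and the automated subtraction reading, each
at the baseline (t1) and follow-up (t2) acquisitions.  The translation
table gives the root-mean-square error (mm) of the recovered x/y shift
per patient.
"""

from __future__ import annotations

__all__ = [
    "DIAMETERS_CM",
    "VOLUMES_CM3",
    "TRANSLATION_RMSE_MM",
    "PATIENT_IDS",
]

PATIENT_IDS = ("1", "2", "3", "4", "5")

# patient -> {method -> {timepoint -> diameter_cm}}
DIAMETERS_CM: dict[str, dict[str, dict[str, float]]] = {
    "1": {"manual": {"t2": 3.34, "t1": 4.43}, "auto": {"t2": 2.92, "t1": 4.47}},
    "2": {"manual": {"t2": 3.45, "t1": 3.34}, "auto": {"t2": 3.11, "t1": 2.85}},
    "3": {"manual": {"t2": 3.03, "t1": 2.43}, "auto": {"t2": 2.52, "t1": 2.29}},
    "4": {"manual": {"t2": 4.58, "t1": 2.91}, "auto": {"t2": 4.03, "t1": 2.13}},
    "5": {"manual": {"t2": 1.00, "t1": 1.04}, "auto": {"t2": 1.68, "t1": 1.06}},
}

# patient -> {method -> {timepoint -> volume_cm3}}; the printed progression
# column (v_t2 - v_t1) is kept alongside for arithmetic cross-checks.
VOLUMES_CM3: dict[str, dict[str, dict[str, float]]] = {
    "1": {"manual": {"t1": 45.52, "t2": 19.51, "dv": -26.01},
          "auto": {"t1": 46.77, "t2": 13.04, "dv": -33.73}},
    "2": {"manual": {"t1": 19.44, "t2": 21.56, "dv": 2.12},
          "auto": {"t1": 12.12, "t2": 15.75, "dv": 3.63}},
    "3": {"manual": {"t1": 7.51, "t2": 14.57, "dv": 7.06},
          "auto": {"t1": 6.29, "t2": 8.38, "dv": 2.09}},
    "4": {"manual": {"t1": 12.90, "t2": 50.30, "dv": 37.4},
          "auto": {"t1": 5.06, "t2": 34.27, "dv": 29.21}},
    "5": {"manual": {"t1": 0.59, "t2": 3.62, "dv": 3.03},
          "auto": {"t1": 0.62, "t2": 2.48, "dv": 1.86}},
}

# patient -> (dtx_rmse_mm, dty_rmse_mm)
TRANSLATION_RMSE_MM: dict[str, tuple[float, float]] = {
    "1": (0.41, 0.13),
    "2": (0.48, 0.20),
    "3": (1.03, 0.93),
    "4": (0.82, 0.32),
    "5": (0.41, 0.15),
}
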