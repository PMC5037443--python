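"""Published group-level summary statistics of the reference femorotibial T2 cohort.

The package emulates a three-group osteoarthritis imaging cohort: knees with
risk factors for radiographic osteoarthritis but no osteophytes (``riskROA``,
n = 28 at baseline), knees with a definite osteophyte but no joint space
narrowing (``earlyROA``, n = 32), and healthy reference knees free of risk
factors (``healthy``, n = 89).  The dictionaries below hold the published
per-group demographics, the baseline T2 mean/SD per cartilage plate and layer,
and the one-year T2 change mean/SD.  They are the defaults of the synthetic
cohort generator and the inputs of the summary-statistics reproductions.

Plates: MT/LT = medial/lateral tibia, cMF/cLF = weight-bearing (central)
medial/lateral femoral condyle, Avg = average over the four plates.
Layers: ``deep`` (bone half) and ``superficial`` (articular half) of the
cartilage thickness.  All T2 values in ms.
"""

from __future__ import annotations

GROUPS = ("riskROA", "earlyROA", "healthy")
PLATES = ("MT", "LT", "cMF", "cLF")
LAYERS = ("deep", "superficial")

#: MRI protocol of the reference acquisition.
ECHO_TIMES_MS = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0)
TR_MS = 2700.0
VOXEL_SPACING_MM = (3.0, 0.3125, 0.3125)  # (slice, row, column)

#: Voxel rejection threshold on the goodness of fit.
R2_THRESHOLD = 0.66

#: Six parallel primary comparisons (3 group pairs x 2 layers).
PRIMARY_FAMILY_SIZE = 6

#: Demographics per group: n at baseline, n with one-year follow-up,
#: age (years), BMI (kg/m^2), fraction of female participants.
DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "riskROA": {
        "n": 28, "n_followup": 26,
        "age_mean": 61.1, "age_sd": 9.4,
        "bmi_mean": 28.0, "bmi_sd": 5.0,
        "female_fraction": 0.50,
    },
    "earlyROA": {
        "n": 32, "n_followup": 24,
        "age_mean": 60.2, "age_sd": 10.0,
        "bmi_mean": 27.6, "bmi_sd": 4.6,
        "female_fraction": 0.563,
    },
    "healthy": {
        "n": 89, "n_followup": 89,
        "age_mean": 55.0, "age_sd": 7.5,
        "bmi_mean": 24.4, "bmi_sd": 3.1,
        "female_fraction": 0.596,
    },
}

#: Baseline T2 (mean, SD) in ms per (group, plate, layer).
BASELINE_T2: dict[tuple[str, str, str], tuple[float, float]] = {
    ("riskROA", "Avg", "deep"): (37.3, 1.8),
    ("riskROA", "Avg", "superficial"): (48.1, 3.1),
    ("riskROA", "MT", "deep"): (34.0, 1.8),
    ("riskROA", "MT", "superficial"): (43.6, 2.5),
    ("riskROA", "cMF", "deep"): (41.8, 3.8),
    ("riskROA", "cMF", "superficial"): (52.8, 5.8),
    ("riskROA", "LT", "deep"): (32.0, 1.4),
    ("riskROA", "LT", "superficial"): (45.5, 3.6),
    ("riskROA", "cLF", "deep"): (41.2, 2.8),
    ("riskROA", "cLF", "superficial"): (50.5, 4.1),
    ("earlyROA", "Avg", "deep"): (37.3, 2.5),
    ("earlyROA", "Avg", "superficial"): (48.0, 3.5),
    ("earlyROA", "MT", "deep"): (33.3, 1.8),
    ("earlyROA", "MT", "superficial"): (43.4, 2.9),
    ("earlyROA", "cMF", "deep"): (42.5, 5.9),
    ("earlyROA", "cMF", "superficial"): (53.4, 6.0),
    ("earlyROA", "LT", "deep"): (32.5, 2.1),
    ("earlyROA", "LT", "superficial"): (44.5, 4.3),
    ("earlyROA", "cLF", "deep"): (40.8, 3.2),
    ("earlyROA", "cLF", "superficial"): (50.7, 4.0),
    ("healthy", "Avg", "deep"): (35.8, 1.8),
    ("healthy", "Avg", "superficial"): (45.4, 2.3),
    ("healthy", "MT", "deep"): (33.0, 1.9),
    ("healthy", "MT", "superficial"): (41.6, 2.9),
    ("healthy", "cMF", "deep"): (39.3, 3.4),
    ("healthy", "cMF", "superficial"): (49.6, 3.8),
    ("healthy", "LT", "deep"): (31.0, 1.9),
    ("healthy", "LT", "superficial"): (42.4, 2.6),
    ("healthy", "cLF", "deep"): (39.7, 2.8),
    ("healthy", "cLF", "superficial"): (48.1, 2.9),
}

#: One-year T2 change (mean, SD) in ms per (group, plate, layer), computed
#: on the follow-up subset of each group.
T2_CHANGE: dict[tuple[str, str, str], tuple[float, float]] = {
    ("riskROA", "Avg", "deep"): (0.0, 1.7),
    ("riskROA", "Avg", "superficial"): (-0.4, 1.8),
    ("riskROA", "MT", "deep"): (-0.3, 1.8),
    ("riskROA", "MT", "superficial"): (-0.4, 1.8),
    ("riskROA", "cMF", "deep"): (0.3, 2.9),
    ("riskROA", "cMF", "superficial"): (-0.5, 4.5),
    ("riskROA", "LT", "deep"): (-0.1, 1.9),
    ("riskROA", "LT", "superficial"): (-0.2, 1.8),
    ("riskROA", "cLF", "deep"): (0.1, 1.8),
    ("riskROA", "cLF", "superficial"): (-0.5, 1.0),
    ("earlyROA", "Avg", "deep"): (-0.2, 1.1),
    ("earlyROA", "Avg", "superficial"): (-0.1, 1.5),
    ("earlyROA", "MT", "deep"): (0.0, 1.6),
    ("earlyROA", "MT", "superficial"): (0.1, 1.8),
    ("earlyROA", "cMF", "deep"): (-0.3, 2.5),
    ("earlyROA", "cMF", "superficial"): (-0.5, 4.2),
    ("earlyROA", "LT", "deep"): (-0.2, 0.9),
    ("earlyROA", "LT", "superficial"): (-0.1, 0.9),
    ("earlyROA", "cLF", "deep"): (-0.2, 1.3),
    ("earlyROA", "cLF", "superficial"): (0.0, 1.1),
    ("healthy", "Avg", "deep"): (0.8, 1.3),
    ("healthy", "Avg", "superficial"): (0.5, 1.4),
    ("healthy", "MT", "deep"): (0.8, 1.7),
    ("healthy", "MT", "superficial"): (0.7, 1.8),
    ("healthy", "cMF", "deep"): (1.0, 2.1),
    ("healthy", "cMF", "superficial"): (0.4, 2.6),
    ("healthy", "LT", "deep"): (0.9, 1.5),
    ("healthy", "LT", "superficial"): (0.6, 1.5),
    ("healthy", "cLF", "deep"): (0.6, 1.8),
    ("healthy", "cLF", "superficial"): (0.6, 2.1),
}
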