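"""Normative per-axis head-motion standard deviations per group and exercise.

These are the cohort summary statistics (cohort mean and cohort SD of the
per-trial standard deviation of head motion) for each of the six axes —
linear acceleration in mG along fore-aft, lateral, and vertical, and angular
velocity in deg/s about roll, pitch, and yaw — for healthy controls and for
vestibular-schwannoma subjects measured preoperatively and about six weeks
postoperatively.  They parameterize the default synthetic cohorts: the cohort
mean is the stationary SD target of the sway process, and the cohort SD sets
the between-subject dispersion scale.
"""

from __future__ import annotations

GROUPS = ("control", "preoperative", "postoperative")

#: axis order used throughout the package
AXES = ("foreaft", "lateral", "vertical", "roll", "pitch", "yaw")
LINEAR_AXES = AXES[:3]   # mG
ANGULAR_AXES = AXES[3:]  # deg/s

# (group, exercise id) -> cohort mean of per-trial SD, one value per axis
SWAY_SD_MEAN: dict[tuple[str, int], tuple[float, ...]] = {
    ("control", 1): (95, 69, 63, 7.0, 10, 6.7),
    ("control", 2): (106, 68, 72, 6.9, 9.0, 6.4),
    ("control", 3): (83, 77, 62, 7.4, 8.2, 6.9),
    ("control", 4): (30, 22, 18, 1.5, 2.3, 1.8),
    ("control", 5): (28, 33, 21, 2.2, 2.3, 3.0),
    ("control", 6): (23, 18, 14, 0.9, 1.4, 1.2),
    ("control", 7): (27, 23, 18, 1.5, 1.9, 2.0),
    ("control", 8): (28, 20, 15, 1.0, 1.7, 1.7),
    ("control", 9): (139, 52, 54, 3.6, 8.8, 4.9),
    ("control", 10): (90, 100, 59, 7.6, 8.7, 7.8),
    ("preoperative", 1): (104, 106, 68, 9.6, 9.7, 8.2),
    ("preoperative", 2): (91, 93, 74, 8.7, 8.8, 7.7),
    ("preoperative", 3): (101, 107, 62, 10, 9.4, 8.2),
    ("preoperative", 4): (50, 40, 22, 3.5, 3.9, 3.8),
    ("preoperative", 5): (63, 94, 41, 8.4, 7.2, 7.6),
    ("preoperative", 6): (41, 27, 15, 2.1, 2.8, 2.1),
    ("preoperative", 7): (55, 42, 34, 3.8, 4.4, 3.7),
    ("preoperative", 8): (32, 25, 15, 2.2, 2.4, 2.1),
    ("preoperative", 9): (93, 86, 46, 7.0, 7.0, 6.1),
    ("preoperative", 10): (74, 111, 53, 9.6, 7.7, 8.5),
    ("postoperative", 1): (81, 95, 66, 8.7, 6.8, 6.5),
    ("postoperative", 2): (94, 84, 67, 7.6, 7.3, 6.5),
    ("postoperative", 3): (86, 89, 65, 8.2, 7.1, 6.8),
    ("postoperative", 4): (67, 40, 23, 3.5, 3.0, 3.5),
    ("postoperative", 5): (73, 66, 46, 5.9, 6.4, 6.3),
    ("postoperative", 6): (39, 26, 16, 1.8, 2.6, 2.2),
    ("postoperative", 7): (65, 56, 38, 4.8, 6.2, 6.0),
    ("postoperative", 8): (59, 23, 25, 1.9, 3.1, 2.6),
    ("postoperative", 9): (92, 74, 48, 6.2, 6.7, 5.8),
    ("postoperative", 10): (65, 112, 56, 8.4, 6.3, 8.4),
}

# (group, exercise id) -> cohort SD of per-trial SD (between-subject spread)
SWAY_SD_SPREAD: dict[tuple[str, int], tuple[float, ...]] = {
    ("control", 1): (40, 29, 21, 2.5, 6.4, 1.9),
    ("control", 2): (87, 38, 44, 3.3, 5.6, 2.4),
    ("control", 3): (22, 42, 24, 3.6, 1.7, 2.3),
    ("control", 4): (12, 6.9, 9.7, 0.9, 1.4, 0.6),
    ("control", 5): (9.9, 16, 8.6, 1.1, 1.0, 1.5),
    ("control", 6): (6.5, 3.9, 5.5, 0.2, 0.6, 0.2),
    ("control", 7): (5.9, 4.0, 4.1, 0.4, 0.5, 0.6),
    ("control", 8): (14, 3.4, 6.7, 0.3, 1.0, 0.8),
    ("control", 9): (72, 29, 45, 1.9, 4.5, 2.0),
    ("control", 10): (38, 46, 22, 3.2, 3.2, 3.1),
    ("preoperative", 1): (57, 48, 34, 4.4, 5.6, 4.2),
    ("preoperative", 2): (43, 46, 41, 4.1, 3.9, 3.7),
    ("preoperative", 3): (52, 54, 31, 4.9, 5.1, 3.9),
    ("preoperative", 4): (24, 28, 12, 2.3, 2.0, 1.9),
    ("preoperative", 5): (29, 56, 20, 4.7, 4.8, 3.4),
    ("preoperative", 6): (23, 23, 9.6, 2.0, 2.4, 1.6),
    ("preoperative", 7): (34, 21, 27, 1.7, 2.4, 1.4),
    ("preoperative", 8): (12, 15, 6.6, 1.3, 1.1, 0.8),
    ("preoperative", 9): (73, 53, 28, 4.2, 3.6, 2.6),
    ("preoperative", 10): (29, 28, 11, 2.7, 2.3, 2.7),
    ("postoperative", 1): (48, 63, 44, 6.1, 4.2, 4.3),
    ("postoperative", 2): (64, 53, 45, 4.9, 5.0, 4.0),
    ("postoperative", 3): (51, 59, 44, 5.3, 4.3, 4.3),
    ("postoperative", 4): (54, 24, 12, 2.3, 1.8, 1.7),
    ("postoperative", 5): (44, 39, 29, 2.4, 2.8, 2.5),
    ("postoperative", 6): (15, 9.4, 7.6, 0.7, 1.3, 0.7),
    ("postoperative", 7): (42, 23, 22, 2.8, 3.3, 3.3),
    ("postoperative", 8): (50, 9.2, 23, 0.8, 2.2, 1.4),
    ("postoperative", 9): (55, 42, 22, 3.8, 3.3, 2.3),
    ("postoperative", 10): (14, 39, 13, 2.9, 0.9, 1.9),
}

# Reference correlations between per-axis log sway variability and clinical
# measures in the preoperative cohort (used as default generator targets).
# Ipsilesional dynamic visual acuity rises (worsens) with variability;
# functional gait assessment falls.
DVA_IPSI_CORR: dict[str, float] = {"lateral": 0.95, "roll": 0.88, "yaw": 0.95}
FGA_CORR: dict[str, float] = {
    "foreaft": -0.84, "lateral": -0.75, "vertical": -0.75,
    "roll": -0.78, "pitch": -0.85, "yaw": -0.75,
}
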