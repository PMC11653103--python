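"""Published reference values used as generator inputs and worked examples.

These are the printed group summaries of the study the package models:
striatal interneuron densities (cells/mm^2, mean +/- SEM, n = 7 brains per
group), per-brain totals, behavioral summaries (mean +/- SEM per group), and
the quartiles of the facilitation/depression adaptation slopes. They serve
as calibration inputs for the synthetic-data generator and as inputs to the
worked percent-decrease / summary-t-test examples.
"""

from __future__ import annotations

import pandas as pd

N_ANIMALS_HISTOLOGY = 7

#: total density of immunopositive cells per mm^2 by striatal region
#: (control vs prenatal-VPA), mean +/- SEM over animals.
TOTAL_DENSITY = pd.DataFrame(
    [
        ("ChAT", "DLSt", 50.32, 2.460, 21.69, 2.139),
        ("ChAT", "DMSt", 45.25, 2.266, 32.65, 2.3111),
        ("ChAT", "VSt", 46.88, 2.3777, 29.62, 2.728),
        ("PV", "DLSt", 28.81, 0.7142, 14.38, 0.6615),
        ("PV", "DMSt", 27.04, 0.5762, 16.76, 0.7669),
        ("PV", "VSt", 33.20, 1.022, 23.61, 4.410),
    ],
    columns=["marker", "region", "control_mean", "control_sem", "vpa_mean", "vpa_sem"],
)

#: per-brain total immunopositive cell counts (mean, SEM) per group.
TOTAL_CELLS = {
    "ChAT": {"control": (2335.0, 93.98), "VPA": (1443.0, 187.1)},
    "PV": {"control": (3617.0, 207.3), "VPA": (2080.0, 88.67)},
}

#: ChAT+ density per rostrocaudal slice (1 = rostral ... 4 = caudal).
SLICE_DENSITY_CHAT = pd.DataFrame(
    [
        ("DLSt", "control", 1, 37.84, 2.595),
        ("DLSt", "control", 2, 47.54, 2.055),
        ("DLSt", "control", 3, 56.10, 6.142),
        ("DLSt", "control", 4, 66.90, 4.254),
        ("DLSt", "VPA", 1, 19.98, 4.071),
        ("DLSt", "VPA", 2, 20.63, 3.858),
        ("DLSt", "VPA", 3, 21.30, 3.723),
        ("DLSt", "VPA", 4, 28.03, 7.190),
        ("DMSt", "control", 1, 63.62, 2.117),
        ("DMSt", "control", 2, 40.70, 2.83),
        ("DMSt", "control", 3, 38.25, 4.253),
        ("DMSt", "control", 4, 33.30, 25.55),
        ("DMSt", "VPA", 1, 51.79, 4.873),
        ("DMSt", "VPA", 2, 26.46, 1.899),
        ("DMSt", "VPA", 3, 23.25, 1.064),
        ("DMSt", "VPA", 4, 1.725, 1.673),
        ("VSt", "control", 1, 44.16, 3.552),
        ("VSt", "control", 2, 49.59, 3.119),
        ("VSt", "VPA", 1, 32.91, 4.709),
        ("VSt", "VPA", 2, 26.55, 2.862),
    ],
    columns=["region", "group", "slice", "mean", "sem"],
)

#: PV+ density per rostrocaudal slice.
SLICE_DENSITY_PV = pd.DataFrame(
    [
        ("DLSt", "control", 1, 29.46, 1.038),
        ("DLSt", "control", 2, 31.07, 1.817),
        ("DLSt", "control", 3, 29.99, 2.377),
        ("DLSt", "control", 4, 24.81, 1.658),
        ("DLSt", "VPA", 1, 16.31, 0.804),
        ("DLSt", "VPA", 2, 11.76, 0.868),
        ("DLSt", "VPA", 3, 15.51, 2.534),
        ("DLSt", "VPA", 4, 14.18, 2.403),
        ("DMSt", "control", 1, 22.97, 1.312),
        ("DMSt", "control", 2, 28.76, 0.757),
        ("DMSt", "control", 3, 28.03, 0.600),
        ("DMSt", "control", 4, 28.4, 0.872),
        ("DMSt", "VPA", 1, 17.64, 2.145),
        ("DMSt", "VPA", 2, 13.92, 0.502),
        ("DMSt", "VPA", 3, 18.22, 1.473),
        ("DMSt", "VPA", 4, 17.81, 3.735),
        ("VSt", "control", 1, 33.26, 1.934),
        ("VSt", "control", 2, 32.88, 2.731),
        ("VSt", "VPA", 1, 36.91, 6.692),
        ("VSt", "VPA", 2, 11.22, 2.788),
    ],
    columns=["region", "group", "slice", "mean", "sem"],
)

#: behavioral summaries (mean, SEM, n animals) per measure and group.
#: n = 18 per group as reported for the social-interaction cohort; the
#: open-field / hole-board cohorts are not given an explicit n in the
#: source, so the same n is assumed.
BEHAVIOR_SUMMARY = pd.DataFrame(
    [
        ("compartment_time", "control", 352.8, 12.26, 18),
        ("compartment_time", "VPA", 314.1, 10.68, 18),
        ("contacts", "control", 10.67, 0.46, 18),
        ("contacts", "VPA", 7.33, 0.57, 18),
        ("interaction_time", "control", 49.31, 2.78, 18),
        ("interaction_time", "VPA", 37.15, 1.56, 18),
        ("distance", "control", 2308.0, 266.1, 18),
        ("distance", "VPA", 2563.0, 285.0, 18),
        ("grooming_events", "control", 7.86, 0.6218, 18),
        ("grooming_events", "VPA", 12.43, 1.142, 18),
        ("grooming_time", "control", 84.96, 9.957, 18),
        ("grooming_time", "VPA", 170.7, 12.21, 18),
        ("dip_frequency", "control", 44.33, 1.35, 18),
        ("dip_frequency", "VPA", 34.83, 1.09, 18),
        ("dip_time", "control", 99.77, 2.74, 18),
        ("dip_time", "VPA", 144.0, 3.41, 18),
    ],
    columns=["measure", "group", "mean", "sem", "n"],
)

#: quartiles (25th, 50th, 75th) of the per-neuron linear growth/decay rate
#: of the long-latency response amplitude (z-units per stimulus), S1.
GROWTH_QUARTILES = {"control": (0.03, 0.11, 0.23), "VPA": (0.04, 0.11, 0.23)}
DECAY_QUARTILES = {"control": (-0.33, -0.19, -0.08), "VPA": (-0.28, -0.17, -0.07)}

#: share of units whose spike waveform matches the wide/low-rate class
#: (putative medium spiny neurons) per group.
MSN_WAVEFORM_SHARE = {"control": 0.555, "VPA": 0.615, "PV-depleted": 0.529}

#: share of striatal units that express no clear sensory-evoked response.
DLST_NONRESPONSIVE_SHARE = 0.30

__all__ = [
    "N_ANIMALS_HISTOLOGY", "TOTAL_DENSITY", "TOTAL_CELLS",
    "SLICE_DENSITY_CHAT", "SLICE_DENSITY_PV", "BEHAVIOR_SUMMARY",
    "GROWTH_QUARTILES", "DECAY_QUARTILES",
    "MSN_WAVEFORM_SHARE", "DLST_NONRESPONSIVE_SHARE",
]
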