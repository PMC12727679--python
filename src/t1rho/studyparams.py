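"""Default group-level tissue parameters and cohort schedule.

These constants parameterise the synthetic cohort generator with the
group-average relaxometry of a preclinical (3 T) glioma study design with
three groups of five mice: naive controls (group 1), IDH1-wild-type glioma
(group 2) and IDH1-mutant glioma (group 3).  T1/T2 are group averages per
tissue class; T1rho is given as a per-FSL mean ± SD over pooled
measurements, along with the per-measurement tumour-vs-brain percent
difference (delta) distribution for the tumour-bearing groups.

The default imaging schedule reproduces the pooled tumour/brain
measurement counts over weeks 2-4 of 0/15 (group 1), 9/14 (group 2) and
7/12 (group 3): tumours become MRI-visible from week 3 (week 2 for one
early mutant tumour), some mice leave the study early, and the naive group
is imaged through week 6.
"""

from __future__ import annotations

GROUP_NAMES = {1: "naive", 2: "IDH1-wild-type", 3: "IDH1-mutant"}

FSLS_HZ = (100.0, 500.0, 1000.0, 2000.0)

#: group -> tissue -> (T1 ms, T2 ms)
T1_T2_MS: dict[int, dict[str, tuple[float, float]]] = {
    1: {"brain": (669.0, 79.0)},
    2: {"brain": (670.0, 98.0), "tumour": (827.0, 120.0)},
    3: {"brain": (882.0, 120.0), "tumour": (988.0, 139.0)},
}

#: group -> fsl -> (mean, sd) of brain T1rho (ms)
BRAIN_T1RHO_MS: dict[int, dict[float, tuple[float, float]]] = {
    1: {100.0: (159.0, 36.0), 500.0: (141.0, 22.0),
        1000.0: (136.0, 20.0), 2000.0: (148.0, 26.0)},
    2: {100.0: (115.0, 16.0), 500.0: (119.0, 21.0),
        1000.0: (119.0, 15.0), 2000.0: (127.0, 16.0)},
    3: {100.0: (119.0, 22.0), 500.0: (100.0, 10.0),
        1000.0: (98.0, 9.0), 2000.0: (108.0, 10.0)},
}

#: group -> fsl -> (mean, sd) of tumour T1rho (ms); used by the bivariate
#: tumour model
TUMOUR_T1RHO_MS: dict[int, dict[float, tuple[float, float]]] = {
    2: {100.0: (121.0, 16.0), 500.0: (127.0, 21.0),
        1000.0: (125.0, 18.0), 2000.0: (133.0, 19.0)},
    3: {100.0: (147.0, 25.0), 500.0: (127.0, 19.0),
        1000.0: (126.0, 20.0), 2000.0: (137.0, 26.0)},
}

#: group -> fsl -> (mean, sd) of per-measurement delta-T1rho (%); used by
#: the default (delta) tumour model
DELTA_T1RHO_PCT: dict[int, dict[float, tuple[float, float]]] = {
    2: {100.0: (2.0, 13.0), 500.0: (6.0, 13.0),
        1000.0: (3.0, 11.0), 2000.0: (2.0, 14.0)},
    3: {100.0: (27.0, 18.0), 500.0: (31.0, 15.0),
        1000.0: (29.0, 13.0), 2000.0: (28.0, 15.0)},
}

#: (mouse_id, group, week, has_tumour) records of the default schedule
DEFAULT_SCHEDULE: tuple[tuple[str, int, int, bool], ...] = tuple(
    [(f"g1m{i}", 1, w, False) for i in range(1, 6) for w in range(1, 7)]
    # wild-type group: tumours visible from week 3; one mouse exits after week 3
    + [(f"g2m{i}", 2, w, w >= 3) for i in range(1, 5) for w in range(1, 5)]
    + [("g2m5", 2, w, w >= 3) for w in range(1, 4)]
    # mutant group: one mouse never develops a tumour, one early tumour at
    # week 2, two early exits, one mouse with a single usable session
    + [("g3m1", 3, w, False) for w in range(1, 7)]
    + [("g3m2", 3, w, w >= 2) for w in range(1, 5)]
    + [("g3m3", 3, w, w >= 3) for w in range(1, 5)]
    + [("g3m4", 3, w, w >= 3) for w in range(1, 4)]
    + [("g3m5", 3, 3, True)]
)
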