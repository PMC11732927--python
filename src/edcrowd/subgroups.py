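"""Canonical ED subgroup names, integer codes and bed capacities.

The ED is partitioned into three operational sections -- medical, surgical
and critical (resuscitation) -- plus the combined "bedoccupying" series
covering all bed patients.  Integer codes are fixed package-wide (they enter
the design matrix as a categorical feature): bedoccupying=0, critical=1,
medical=2, surgical=3.
"""

from __future__ import annotations

#: All four occupancy series, in code order.
SUBGROUPS: tuple[str, ...] = ("bedoccupying", "critical", "medical", "surgical")

#: The three independently simulated sections (bedoccupying is their sum).
SECTIONS: tuple[str, ...] = ("medical", "surgical", "critical")

#: Fixed integer coding used in the design matrix.
SUBGROUP_CODES: dict[str, int] = {
    "bedoccupying": 0,
    "critical": 1,
    "medical": 2,
    "surgical": 3,
}

CODE_TO_SUBGROUP: dict[int, str] = {v: k for k, v in SUBGROUP_CODES.items()}

#: Default bed capacities: 65 beds in total, 6 resuscitation, 36 medical,
#: 23 surgical.
DEFAULT_CAPACITIES: dict[str, int] = {
    "bedoccupying": 65,
    "medical": 36,
    "surgical": 23,
    "critical": 6,
}

#: Subgroups whose daily crowding is forecast and evaluated.  The critical
#: (resuscitation) series is used as an explanatory variable only.
EVALUATED_SUBGROUPS: tuple[str, ...] = ("bedoccupying", "medical", "surgical")
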