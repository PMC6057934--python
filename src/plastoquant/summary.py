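"""The per-network descriptor record shared across the pipeline.

Each analysed network yields 25 scalar descriptors: seven gross-morphology
(wrapped hull) descriptors and eighteen element descriptors computed from the
spatial graph.  Missing values (e.g. theta_c4 for a network without any
4-way junction) are carried as NaN, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed descriptor order used in tables and reports.
DESCRIPTOR_NAMES = [
    # gross morphology (wrapped hull)
    "V_EN",        # enclosed volume, um^3
    "V_PN",        # network (material) volume, um^3
    "rho_PN",      # volume density V_PN / V_EN
    "d_max",       # greatest hull diameter, um
    "d_min",       # smallest hull diameter, um
    "St",          # stretch in [0, 1]
    "Ob",          # oblateness in [-1, 1]
    # nodes
    "N_n",         # node count (junctions + open nodes)
    "th_n",        # mean node thickness, nm
    "rho_n",       # node density N_n / V_EN, um^-3
    "d_nn",        # mean nearest-neighbour node distance, um
    "d_ns",        # mean node-to-surface distance, um
    "d_nc",        # mean node-to-centre distance, um
    "ratio_ns_nc", # mean of per-node d_ns / d_nc
    "C_PN",        # compactness (mean d_nc - mean d_ns) / mean d_nc
    # segments
    "N_s",         # segment count
    "L_s",         # mean segment length, um
    "kappa_s",     # mean segment Menger curvature, um^-1
    "th_s",        # mean segment thickness, nm
    "I_s",         # mean segment inhomogeneity (change-point count)
    "d_pp",        # mean point-to-point distance, nm
    # connections
    "n_c",         # mean connections per junction node
    "n_oe",        # open-node percentage, %
    "theta_c3",    # mean inter-segment angle at 3-way junctions, deg
    "theta_c4",    # mean inter-segment angle at 4-way junctions, deg
]

#: Units for reporting, keyed like DESCRIPTOR_NAMES.
DESCRIPTOR_UNITS = {
    "V_EN": "um^3", "V_PN": "um^3", "rho_PN": "", "d_max": "um", "d_min": "um",
    "St": "", "Ob": "", "N_n": "", "th_n": "nm", "rho_n": "um^-3",
    "d_nn": "um", "d_ns": "um", "d_nc": "um", "ratio_ns_nc": "", "C_PN": "",
    "N_s": "", "L_s": "um", "kappa_s": "um^-1", "th_s": "nm", "I_s": "",
    "d_pp": "nm", "n_c": "", "n_oe": "%", "theta_c3": "deg", "theta_c4": "deg",
}


@dataclass
class NetworkSummary:
    """All descriptors of one network plus raw per-element distributions.

    ``scalars`` maps every name in :data:`DESCRIPTOR_NAMES` to a float (NaN
    when undefined); ``arrays`` holds the per-element values behind the means
    (node thicknesses, segment lengths, curvatures, distances, angles, ...)
    for histogram statistics.
    """

    group: str
    source: str
    scalars: dict[str, float]
    arrays: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        missing = [k for k in DESCRIPTOR_NAMES if k not in self.scalars]
        if missing:
            raise ValueError(f"summary for {self.source!r} lacks descriptors {missing}")
        self.scalars = {k: float(self.scalars[k]) for k in DESCRIPTOR_NAMES}
        self.arrays = {k: np.asarray(v, dtype=float) for k, v in self.arrays.items()}
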