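"""Two-group comparison of network descriptors.

All 25 scalar descriptors are compared by the classic equal-variance unpaired
Student's t-test (two-sided, df = n_a + n_b - 2); element-level distributions
are summarised as the mean +/- SD over networks of each network's normalised
(or cumulative) histogram on fixed bins.  No multiple-testing correction is
applied — 25 tests are run at the chosen alpha, and the report carries an
advisory note saying so.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .summary import DESCRIPTOR_NAMES, NetworkSummary

ADVISORY_NOTE = ("25 descriptors tested at the stated alpha without "
                 "multiple-testing correction; expect ~alpha*25 false "
                 "positives under the null.")

#: Fixed histogram bins for the distribution summaries.  Thickness bins are
#: 40 nm wide covering 0-600 nm, so 480-520 nm (the meganode range) is one bin.
DEFAULT_BINS = {
    "node_thickness_nm": np.arange(0.0, 640.0, 40.0),
    "segment_thickness_nm": np.arange(0.0, 640.0, 40.0),
    "segment_length_um": np.arange(0.0, 3.25, 0.25),
    "segment_curvature_per_um": np.arange(0.0, 3.25, 0.25),
    "segment_inhomogeneity": np.arange(0.0, 42.0, 2.0),
    "point_to_point_nm": np.arange(0.0, 210.0, 10.0),
    "d_nn_um": np.arange(0.0, 2.1, 0.1),
    "d_ns_um": np.arange(0.0, 2.1, 0.1),
    "d_nc_um": np.arange(0.0, 6.25, 0.25),
    "ratio_ns_nc": np.arange(0.0, 1.05, 0.05),
    "angles3_deg": np.arange(0.0, 190.0, 10.0),
    "angles4_deg": np.arange(0.0, 190.0, 10.0),
}
#: Distributions reported cumulatively (node-distance curves).
CUMULATIVE_KEYS = {"d_nn_um", "d_ns_um", "d_nc_um", "ratio_ns_nc"}


def unpaired_t_test(a, b) -> tuple[float, float]:
    """Equal-variance two-sample Student's t, two-sided p.

    Degenerate inputs: zero pooled variance with equal means gives
    (0, 1); zero pooled variance with different means gives (+/-inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in t-test input")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sstats.t.sf(abs(t), df)
    return float(t), float(p)


def normalized_distribution(values_per_network: list, bin_edges,
                            cumulative: bool = False) -> dict:
    """Mean +/- SD over networks of per-network normalised histograms.

    Each network's values are binned on ``bin_edges`` and normalised to sum to
    one (cumulative variant: running sum of that); empty networks are skipped
    with a logged count.  Values beyond the last edge land in the final bin so
    every histogram truly sums to 1.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    curves, skipped = [], 0
    for vals in values_per_network:
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            skipped += 1
            continue
        clipped = np.clip(vals, bin_edges[0], np.nextafter(bin_edges[-1], -np.inf))
        hist, _ = np.histogram(clipped, bins=bin_edges)
        curve = hist / hist.sum()
        if cumulative:
            curve = np.cumsum(curve)
        curves.append(curve)
    if not curves:
        raise ValueError("no network carries any values for this distribution")
    arr = np.vstack(curves)
    return {
        "bin_edges": bin_edges,
        "mean": arr.mean(axis=0),
        "sd": arr.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros(arr.shape[1]),
        "n_networks": len(curves),
        "skipped_empty": skipped,
        "cumulative": cumulative,
    }


@dataclass
class GroupComparison:
    groups: tuple[str, str]
    table: pd.DataFrame
    distributions: dict = field(default_factory=dict)
    alpha: float = 0.05
    note: str = ADVISORY_NOTE

    @property
    def significant(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "descriptor"])


def compare_groups(summaries: list[NetworkSummary], alpha: float = 0.05,
                   distribution_keys=None) -> GroupComparison:
    """Full two-group report: 25 t-tests plus distribution curves per group.

    Descriptor values that are NaN for some networks (e.g. theta_c4 when a
    network has no 4-way junction) are dropped from that descriptor's test;
    a test needs two finite values per group, else its p is reported as NaN.
    """
    labels = sorted({s.group for s in summaries})
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {labels}")
    ga = [s for s in summaries if s.group == labels[0]]
    gb = [s for s in summaries if s.group == labels[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs at least two networks")
    rows = []
    for name in DESCRIPTOR_NAMES:
        a = np.array([s.scalars[name] for s in ga])
        b = np.array([s.scalars[name] for s in gb])
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) >= 2 and len(b) >= 2:
            t, p = unpaired_t_test(a, b)
        else:
            t, p = np.nan, np.nan
        rows.append({
            "descriptor": name,
            f"mean_{labels[0]}": a.mean() if len(a) else np.nan,
            f"sd_{labels[0]}": a.std(ddof=1) if len(a) > 1 else np.nan,
            f"n_{labels[0]}": len(a),
            f"mean_{labels[1]}": b.mean() if len(b) else np.nan,
            f"sd_{labels[1]}": b.std(ddof=1) if len(b) > 1 else np.nan,
            f"n_{labels[1]}": len(b),
            "t": t,
            "p": p,
            "significant": bool(np.isfinite(p) and p < alpha),
        })
    table = pd.DataFrame(rows)
    keys = distribution_keys if distribution_keys is not None else list(DEFAULT_BINS)
    distributions = {}
    for key in keys:
        edges = DEFAULT_BINS[key]
        cumulative = key in CUMULATIVE_KEYS
        per_group = {}
        for label, grp in ((labels[0], ga), (labels[1], gb)):
            vals = [s.arrays.get(key, np.array([])) for s in grp]
            if all(np.asarray(v).size == 0 for v in vals):
                continue
            per_group[label] = normalized_distribution(vals, edges, cumulative)
        if per_group:
            distributions[key] = per_group
    return GroupComparison(groups=(labels[0], labels[1]), table=table,
                           distributions=distributions, alpha=alpha)


def format_p(p: float) -> str:
    """p to three significant digits; never truncated to 0."""
    if not np.isfinite(p):
        return "nan"
    return f"{p:.3g}" if p > 0 else "<1e-300"
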