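"""Leverage-ratio trends across the phylogeny.

The evolutionary questions about the hip-to-knee locomotor transition are
tested on ratios of *summed absolute* ancestral moment arms.  For each
internal node and degree of freedom, the absolute ancestral estimates of
all muscles acting in one direction (by the sign of their estimate at that
node) are summed; the three hypothesis ratios are

* H1  hip extension / hip flexion   - predicted constant (rejected),
* H2  knee flexion / knee extension - predicted to decrease,
* H3  hip medial long-axis rotation / hip abduction - predicted to increase.

Changes between consecutive main-line nodes of >= 20% magnitude count as
reliable; >= 10% as notable.  Sign switches and per-muscle extrema mirror
the per-muscle annotations of the trend figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import MAIN_LINE_NODES, OFF_LINE_NODES

RELIABLE_THRESHOLD_PCT = 20.0
NOTABLE_THRESHOLD_PCT = 10.0

#: labels of the positive and negative moment-arm signs per joint and DoF
ACTION_SIGN_CONVENTION = {
    ("hip", "FLEXEX"): ("flexion", "extension"),
    ("hip", "ABAD"): ("adduction", "abduction"),
    ("hip", "LAR"): ("medial_rotation", "lateral_rotation"),
    ("knee", "FLEXEX"): ("extension", "flexion"),
    ("ankle", "FLEXEX"): ("dorsiflexion", "plantarflexion"),
}

#: hypothesis id -> (joint, dof, numerator action, denominator action)
HYPOTHESES = {
    "H1": ("hip", "FLEXEX", "extension", "flexion"),
    "H2": ("knee", "FLEXEX", "flexion", "extension"),
    "H3": ("hip", "LAR", "medial_rotation", "abduction"),
}
#: H3's denominator lives on a different DoF (hip ABAD) than its numerator
H3_DENOM_DOF = ("hip", "ABAD")


def sum_by_action(ace_table: pd.DataFrame, joint: str, dof: str) -> pd.DataFrame:
    """Summed |estimate| per node and action direction.

    ``ace_table``: rows = MTUs, columns = nodes.  Membership in a direction
    is decided per node by the estimate's sign there, so a muscle whose
    action switches migrates between the two sums; exact zeros contribute to
    neither.  Returns a (node x action) table of non-negative sums.
    """
    pos_label, neg_label = ACTION_SIGN_CONVENTION[(joint, dof)]
    vals = ace_table.to_numpy(dtype=float)
    pos = np.where(vals > 0, vals, 0.0).sum(axis=0)
    neg = np.where(vals < 0, -vals, 0.0).sum(axis=0)
    return pd.DataFrame(
        {pos_label: pos, neg_label: neg}, index=ace_table.columns
    )


def ratio_series(sums_num: pd.DataFrame, sums_den: pd.DataFrame,
                 num_action: str, den_action: str) -> pd.Series:
    """Node-wise ratio of two summed-action columns.  Nodes with a zero
    denominator yield NaN (flagged undefined) rather than an error."""
    num = sums_num[num_action]
    den = sums_den[den_action]
    out = num / den.where(den > 0, np.nan)
    out.name = f"{num_action}/{den_action}"
    return out


def hypothesis_ratio(ace_tables: dict[str, pd.DataFrame], hypothesis: str) -> pd.Series:
    """The H1/H2/H3 ratio series from a dict of ACE tables keyed by
    ``"{joint}_{dof}"`` (e.g. ``"hip_FLEXEX"``)."""
    joint, dof, num_action, den_action = HYPOTHESES[hypothesis]
    num_sums = sum_by_action(ace_tables[f"{joint}_{dof}"], joint, dof)
    if hypothesis == "H3":
        dj, dd = H3_DENOM_DOF
        den_sums = sum_by_action(ace_tables[f"{dj}_{dd}"], dj, dd)
    else:
        den_sums = num_sums
    return ratio_series(num_sums, den_sums, num_action, den_action)


@dataclass
class ChangeReport:
    series_name: str
    internodal: pd.DataFrame  # per consecutive main-line pair
    off_line: pd.DataFrame  # side-branch nodes vs their parent
    overall_pct: float  # first -> last main-line % change

    def reliable_steps(self) -> pd.DataFrame:
        return self.internodal[self.internodal["reliable"]]


def _pct_change(a: float, b: float) -> float:
    return (b - a) / a * 100.0


def internodal_changes(series: pd.Series,
                       main_line: tuple[str, ...] = MAIN_LINE_NODES,
                       off_line: dict[str, str] | None = None) -> ChangeReport:
    """Percent changes of a node-indexed series along the ancestor main line.

    Side-branch nodes (by default Dromaeosauridae, compared against its
    parent Eumaniraptora) are reported separately.  Flags: ``reliable`` for
    |change| >= 20%, ``notable`` for >= 10%; thresholds are applied to the
    unrounded values.
    """
    if off_line is None:
        off_line = {n: "Eumaniraptora" for n in OFF_LINE_NODES if n in series.index}
    line = [n for n in main_line if n in series.index]
    if len(line) < 2:
        raise ValueError("need at least two main-line nodes")
    rows = []
    for a, b in zip(line[:-1], line[1:]):
        pct = _pct_change(series[a], series[b])
        rows.append({
            "from": a, "to": b, "pct_change": pct,
            "reliable": abs(pct) >= RELIABLE_THRESHOLD_PCT,
            "notable": abs(pct) >= NOTABLE_THRESHOLD_PCT,
        })
    off_rows = []
    for node, parent in off_line.items():
        if node in series.index and parent in series.index:
            pct = _pct_change(series[parent], series[node])
            off_rows.append({
                "from": parent, "to": node, "pct_change": pct,
                "reliable": abs(pct) >= RELIABLE_THRESHOLD_PCT,
                "notable": abs(pct) >= NOTABLE_THRESHOLD_PCT,
            })
    return ChangeReport(
        series_name=str(series.name),
        internodal=pd.DataFrame(rows),
        off_line=pd.DataFrame(off_rows),
        overall_pct=_pct_change(series[line[0]], series[line[-1]]),
    )


def _effective_signs(values: np.ndarray) -> np.ndarray:
    """Signs of a node series with zeros inheriting the nearer nonzero
    neighbour's sign (equidistant ties resolve to the earlier neighbour)."""
    signs = np.sign(values)
    nz = np.nonzero(signs)[0]
    if nz.size == 0:
        return signs
    for i in np.where(signs == 0)[0]:
        nearest = nz[np.argmin(np.abs(nz - i))]
        signs[i] = signs[nearest]
    return signs


def detect_switches(ace_table: pd.DataFrame,
                    node_order: list[str] | None = None) -> pd.DataFrame:
    """Sign-switch events per MTU across an ordered node sequence.

    Returns one row per event: (mtu, node) where the effective sign at the
    node differs from the previous node's.
    """
    cols = node_order or list(ace_table.columns)
    events = []
    for mtu, row in ace_table[cols].iterrows():
        signs = _effective_signs(row.to_numpy(dtype=float))
        for i in range(1, len(signs)):
            if signs[i] != 0 and signs[i - 1] != 0 and signs[i] != signs[i - 1]:
                events.append({"mtu": mtu, "node": cols[i], "prev_node": cols[i - 1]})
    return pd.DataFrame(events, columns=["mtu", "node", "prev_node"])


def detect_extrema(ace_table: pd.DataFrame,
                   node_order: list[str] | None = None) -> pd.DataFrame:
    """Peak (max |value|) and minimum node per MTU.

    The minimum (value closest to zero) is only reported for muscles that
    never switch sign, mirroring the figure annotations; for switching
    muscles the peaks of both signs are reported.  Ties break toward the
    earlier node and are flagged.
    """
    cols = node_order or list(ace_table.columns)
    switching = set(detect_switches(ace_table, cols)["mtu"])
    rows = []
    for mtu, row in ace_table[cols].iterrows():
        vals = row.to_numpy(dtype=float)
        absvals = np.abs(vals)
        peak_i = int(np.argmax(absvals))  # argmax takes the first == earlier
        entry = {
            "mtu": mtu,
            "switches": mtu in switching,
            "peak_node": cols[peak_i],
            "peak_value": vals[peak_i],
            "peak_tie": int(np.sum(absvals == absvals[peak_i])) > 1,
            "min_node": None,
            "min_value": np.nan,
            "min_tie": False,
            "peak_node_negative": None,
            "peak_node_positive": None,
        }
        if mtu in switching:
            pos = np.where(vals > 0, vals, -np.inf)
            neg = np.where(vals < 0, -vals, -np.inf)
            if np.isfinite(pos).any():
                entry["peak_node_positive"] = cols[int(np.argmax(pos))]
            if np.isfinite(neg).any():
                entry["peak_node_negative"] = cols[int(np.argmax(neg))]
        else:
            min_i = int(np.argmin(absvals))
            entry["min_node"] = cols[min_i]
            entry["min_value"] = vals[min_i]
            entry["min_tie"] = int(np.sum(absvals == absvals[min_i])) > 1
        rows.append(entry)
    return pd.DataFrame(rows)


@dataclass
class HypothesisVerdicts:
    verdicts: dict[str, str]
    reports: dict[str, ChangeReport]

    def __getitem__(self, h: str) -> str:
        return self.verdicts[h]


def hypothesis_report(ace_tables: dict[str, pd.DataFrame],
                      main_line: tuple[str, ...] = MAIN_LINE_NODES) -> HypothesisVerdicts:
    """Verdicts on the three leverage-ratio hypotheses from ACE tables.

    * H1 is "constant" iff no reliable (>= 20%) internodal change occurs on
      the main line, else "rejected".
    * H2 is "supported" iff the overall first-to-last change is negative
      with at least one reliable decrease, else "not supported".
    * H3 is "supported" iff the overall change is positive with at least one
      reliable increase, else "not supported".
    """
    verdicts, reports = {}, {}
    for h in ("H1", "H2", "H3"):
        series = hypothesis_ratio(ace_tables, h)
        rep = internodal_changes(series, main_line=main_line)
        reports[h] = rep
        steps = rep.internodal
        if h == "H1":
            verdicts[h] = (
                "constant" if not steps["reliable"].any() else "rejected"
            )
        elif h == "H2":
            ok = rep.overall_pct < 0 and (
                steps["reliable"] & (steps["pct_change"] < 0)
            ).any()
            verdicts[h] = "supported" if ok else "not supported"
        else:
            ok = rep.overall_pct > 0 and (
                steps["reliable"] & (steps["pct_change"] > 0)
            ).any()
            verdicts[h] = "supported" if ok else "not supported"
    return HypothesisVerdicts(verdicts=verdicts, reports=reports)
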