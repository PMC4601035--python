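"""Cross-subject correlation of P3 measures with network indexes and edges.

All correlations are Pearson product-moment coefficients with two-sided
p-values from the exact t-distribution, ``t = r * sqrt((n-2) / (1-r**2))``
on ``n - 2`` degrees of freedom — preferable to the Fisher-z normal
approximation at the small n typical of EEG cohorts.

Edge-wise screening tests every upper-triangle edge of the coherence
network against P3 amplitude and latency.  The default keeps the
uncorrected ``p < alpha`` threshold (a deliberate choice worth scrutinizing
with 210 simultaneous tests); a Benjamini-Hochberg FDR option is exposed
via ``correction="bh"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import Adjacency, montage_positions

__all__ = [
    "pearson",
    "metric_correlations",
    "edgewise_correlations",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("MFC", "C", "Ge", "Le", "L")


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and two-sided t-distribution p-value.

    Requires equal-length vectors of n >= 3 with nonzero variance;
    ``r = +/-1`` gives ``p = 0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _require_aligned(a: pd.DataFrame, b: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    a = a.set_index("subject_id") if "subject_id" in a.columns else a
    b = b.set_index("subject_id") if "subject_id" in b.columns else b
    only_a = sorted(set(a.index) - set(b.index))
    only_b = sorted(set(b.index) - set(a.index))
    if only_a or only_b:
        raise ValueError(
            f"subject IDs do not align: {only_a} only in the metrics table, "
            f"{only_b} only in the P3 table"
        )
    order = sorted(a.index)
    return a.loc[order], b.loc[order]


def metric_correlations(metrics: pd.DataFrame, p3: pd.DataFrame
                        ) -> pd.DataFrame:
    """Correlate every network index with P3 amplitude and latency.

    Both tables need a ``subject_id`` column (or index); rows are joined by
    ID, so row order is irrelevant.  Returns a tidy frame with columns
    ``x, y, r, p, n`` covering all index x {amplitude, latency} pairs plus
    the amplitude-latency correlation itself.
    """
    m, p = _require_aligned(metrics, p3)
    n = len(m)
    rows = []
    for x_name in METRIC_COLUMNS:
        if x_name not in m.columns:
            continue
        for y_name in ("amplitude", "latency"):
            r, pv = pearson(m[x_name].to_numpy(), p[y_name].to_numpy())
            rows.append({"x": x_name, "y": y_name, "r": r, "p": pv, "n": n})
    r, pv = pearson(p["amplitude"].to_numpy(), p["latency"].to_numpy())
    rows.append({"x": "amplitude", "y": "latency", "r": r, "p": pv, "n": n})
    return pd.DataFrame(rows)


def edgewise_correlations(adjacencies: dict[str, Adjacency],
                          p3: pd.DataFrame,
                          alpha: float = 0.01,
                          correction: str = "none") -> pd.DataFrame:
    """Per-edge Pearson correlation of coherence strength with P3 measures.

    ``adjacencies`` maps subject_id -> Adjacency (all sharing one node
    order).  Returns one row per upper-triangle edge with r/p against
    amplitude and latency, significance flags at ``alpha`` (after the
    requested correction: ``"none"`` or ``"bh"``), the correlation signs,
    and 2-D montage coordinates of both nodes; sorted by |r_amp|
    descending.
    """
    if correction not in ("none", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    if not adjacencies:
        raise ValueError("no adjacencies supplied")
    ids = sorted(adjacencies)
    ref_labels = list(adjacencies[ids[0]].labels)
    for sid in ids:
        if list(adjacencies[sid].labels) != ref_labels:
            raise ValueError(
                f"adjacency node order for {sid} differs from {ids[0]}"
            )
    p3 = p3.set_index("subject_id") if "subject_id" in p3.columns else p3
    missing = sorted(set(ids) - set(p3.index))
    if missing:
        raise ValueError(f"subjects missing from the P3 table: {missing}")
    amp = p3.loc[ids, "amplitude"].to_numpy(dtype=float)
    lat = p3.loc[ids, "latency"].to_numpy(dtype=float)

    n_nodes = len(ref_labels)
    iu, ju = np.triu_indices(n_nodes, k=1)
    weights = np.stack([adjacencies[sid].w[iu, ju] for sid in ids])  # (S, E)

    rows = []
    try:
        pos = montage_positions(ref_labels)
    except KeyError:
        pos = None
    for e in range(len(iu)):
        r_a, p_a = pearson(weights[:, e], amp)
        r_l, p_l = pearson(weights[:, e], lat)
        row = {
            "node_i": ref_labels[iu[e]], "node_j": ref_labels[ju[e]],
            "r_amp": r_a, "p_amp": p_a, "r_lat": r_l, "p_lat": p_l,
        }
        if pos is not None:
            row.update({"x_i": pos[iu[e], 0], "y_i": pos[iu[e], 1],
                        "x_j": pos[ju[e], 0], "y_j": pos[ju[e], 1]})
        rows.append(row)
    out = pd.DataFrame(rows)
    if correction == "bh":
        out["q_amp"] = sps.false_discovery_control(out["p_amp"], method="bh")
        out["q_lat"] = sps.false_discovery_control(out["p_lat"], method="bh")
        out["sig_amp"] = out["q_amp"] < alpha
        out["sig_lat"] = out["q_lat"] < alpha
    else:
        out["sig_amp"] = out["p_amp"] < alpha
        out["sig_lat"] = out["p_lat"] < alpha
    out["direction_amp"] = np.where(out["r_amp"] >= 0, "positive", "negative")
    out["direction_lat"] = np.where(out["r_lat"] >= 0, "positive", "negative")
    out = out.sort_values("r_amp", key=np.abs, ascending=False,
                          kind="mergesort").reset_index(drop=True)
    return out
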