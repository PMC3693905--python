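"""Joining-locus merge of matched linkage groups and map summary statistics.

Two linkage groups mapped in different populations are combined through
their joining (anchor) loci: a one-dimensional generalized-Procrustes fit
rescales each source map affinely onto a common frame defined by
least-squares agreement over the joining-locus positions, joining loci are
placed at the (population-size-weighted) mean of their rescaled positions,
and population-specific loci are interpolated between flanking joining
loci (segments beyond the terminal joining loci use the local scale of the
nearest joined segment).  The merged group is re-anchored to start at 0.

Relative locus order within each source map is preserved by construction;
conflicting joining-locus orders between the two maps are an error, not a
silent resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from clovermap.genomestats import method4_expected

__all__ = [
    "IntegrationError",
    "combine_groups",
    "integrate_maps",
    "map_statistics",
]


class IntegrationError(ValueError):
    """Raised when groups cannot be merged (too few or conflicting anchors)."""


def _consensus_frame(
    pos_a: np.ndarray, pos_b: np.ndarray, weights: tuple[float, float]
) -> np.ndarray:
    """Symmetric least-squares consensus frame over anchor positions.

    The provisional frame is the weighted mean of the raw anchor
    positions; each source map is then rescaled affinely onto it by
    weighted least squares, and the consensus anchor positions are the
    weighted mean of the two rescaled maps.  With two anchors this reduces
    to exact placement at the weighted mean positions.
    """
    wa, wb = weights
    wt = wa + wb
    c = (wa * pos_a + wb * pos_b) / wt
    fitted = []
    for pos in (pos_a, pos_b):
        if len(pos) >= 2 and np.ptp(pos) > 0:
            slope, intercept = np.polyfit(pos, c, 1)
        else:
            slope, intercept = 1.0, float(c.mean() - pos.mean())
        fitted.append(slope * pos + intercept)
    return (wa * fitted[0] + wb * fitted[1]) / wt


def _interpolate(
    df: pd.DataFrame, anchors: pd.DataFrame, consensus: np.ndarray
) -> np.ndarray:
    """Map non-anchor source positions into the consensus frame.

    Piecewise-linear between flanking anchors; beyond terminal anchors the
    scale of the nearest anchored segment applies.
    """
    src = anchors["position"].to_numpy()
    n_seg = len(src) - 1
    scales = np.array(
        [
            (consensus[k + 1] - consensus[k]) / (src[k + 1] - src[k])
            if src[k + 1] > src[k]
            else 1.0
            for k in range(n_seg)
        ]
    )
    out = np.empty(len(df))
    for i, x in enumerate(df["position"].to_numpy()):
        if x <= src[0]:
            out[i] = consensus[0] - (src[0] - x) * scales[0]
        elif x >= src[-1]:
            out[i] = consensus[-1] + (x - src[-1]) * scales[-1]
        else:
            k = int(np.searchsorted(src, x, side="right")) - 1
            k = min(k, n_seg - 1)
            t = (x - src[k]) / (src[k + 1] - src[k])
            out[i] = consensus[k] + t * (consensus[k + 1] - consensus[k])
    return out


def combine_groups(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    weights: tuple[float, float] = (1.0, 1.0),
) -> pd.DataFrame:
    """Merge two linkage groups sharing joining loci into one integrated group.

    Parameters
    ----------
    group_a, group_b : DataFrame
        Columns ``locus`` and ``position`` (cM), one row per locus; loci
        present in both frames are the joining loci.
    weights : tuple of float
        Relative weight of each source map (typically the population
        sizes) for the mean joining-locus placement.

    Returns
    -------
    DataFrame with columns ``locus``, ``position`` and ``provenance``
    (``A``, ``B`` or ``joining``), sorted by position and re-anchored to
    start at 0.

    Raises :class:`IntegrationError` with fewer than two joining loci or
    when the joining-locus orders conflict between the maps.
    """
    a = group_a[["locus", "position"]].copy()
    b = group_b[["locus", "position"]].copy()
    joining = sorted(set(a["locus"]) & set(b["locus"]))
    if len(joining) < 2:
        raise IntegrationError(
            f"cannot integrate: {len(joining)} joining locus/loci shared (need >= 2)"
        )
    ja = a[a["locus"].isin(joining)].sort_values("position")
    jb = b[b["locus"].isin(joining)].set_index("locus")

    # orient B to match A's joining order
    order_a = ja["locus"].tolist()
    pos_b = jb.loc[order_a, "position"].to_numpy()
    if len(order_a) >= 2:
        rho = np.corrcoef(np.arange(len(order_a)), pos_b)[0, 1] if np.ptp(pos_b) > 0 else 0.0
        if rho < 0:
            b["position"] = b["position"].max() - b["position"]
            jb = b[b["locus"].isin(joining)].set_index("locus")
            pos_b = jb.loc[order_a, "position"].to_numpy()
    if np.any(np.diff(pos_b) < 0):
        bad = [
            order_a[k]
            for k in range(len(order_a) - 1)
            if pos_b[k + 1] < pos_b[k]
        ]
        raise IntegrationError(
            "conflicting joining-locus order between maps at: " + ", ".join(bad)
        )

    pos_a = ja["position"].to_numpy()
    consensus = _consensus_frame(pos_a, pos_b, weights)

    anchors_a = pd.DataFrame({"locus": order_a, "position": pos_a})
    anchors_b = pd.DataFrame({"locus": order_a, "position": pos_b})
    only_a = a[~a["locus"].isin(joining)]
    only_b = b[~b["locus"].isin(joining)]
    rows = [
        pd.DataFrame({"locus": order_a, "position": consensus, "provenance": "joining"})
    ]
    if len(only_a):
        rows.append(
            pd.DataFrame(
                {
                    "locus": only_a["locus"].to_numpy(),
                    "position": _interpolate(only_a, anchors_a, consensus),
                    "provenance": "A",
                }
            )
        )
    if len(only_b):
        rows.append(
            pd.DataFrame(
                {
                    "locus": only_b["locus"].to_numpy(),
                    "position": _interpolate(only_b, anchors_b, consensus),
                    "provenance": "B",
                }
            )
        )
    out = pd.concat(rows, ignore_index=True).sort_values(
        "position", kind="stable"
    )
    out["position"] -= out["position"].min()
    return out.reset_index(drop=True)


def integrate_maps(
    map_a: pd.DataFrame,
    map_b: pd.DataFrame,
    pairings: dict[str, str],
    weights: tuple[float, float] = (1.0, 1.0),
    group_names: dict[str, str] | None = None,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Integrate two full maps over accepted homoeologue pairings.

    ``map_a``/``map_b`` have columns ``locus``, ``group``, ``position``;
    ``pairings`` maps group labels of A to their matched group in B.
    Groups of either map not covered by an accepted pairing are passed
    through unintegrated with a warning note.

    Returns ``(named integrated/passthrough group frames, warnings)``.
    """
    out: dict[str, pd.DataFrame] = {}
    notes: list[str] = []
    groups_a = {g: df for g, df in map_a.groupby("group")}
    groups_b = {g: df for g, df in map_b.groupby("group")}
    used_b: set = set()
    for ga, df_a in groups_a.items():
        name = (group_names or {}).get(ga, str(ga))
        gb = pairings.get(ga)
        if gb is None or gb not in groups_b:
            notes.append(f"group {ga}: no accepted pairing; passed through")
            df = df_a[["locus", "position"]].copy()
            df["provenance"] = "A"
            out[name] = df.reset_index(drop=True)
            continue
        used_b.add(gb)
        out[name] = combine_groups(
            df_a[["locus", "position"]], groups_b[gb][["locus", "position"]], weights
        )
    for gb, df_b in groups_b.items():
        if gb not in used_b:
            notes.append(f"group {gb} (population B): unpaired; passed through")
            df = df_b[["locus", "position"]].copy()
            df["provenance"] = "B"
            out[f"B:{gb}"] = df.reset_index(drop=True)
    return out, notes


@dataclass(frozen=True)
class GroupStats:
    """Per-group map statistics."""

    group_id: str
    m: int
    l_obs: float
    l_est: float | None
    density: float


def map_statistics(groups: dict[str, pd.DataFrame]) -> dict:
    """Per-group and whole-map summary statistics.

    For each group: locus count m, observed length L_obs (max position),
    expected length L_est (Method-4 inflation, requires m >= 2) and
    density L_obs/m.  Totals sum over groups; means and SEM are across
    groups.  Overall density is reported both as the mean of per-group
    densities and as total length over total loci.
    """
    per_group: list[GroupStats] = []
    for name, df in groups.items():
        m = len(df)
        l_obs = float(df["position"].max()) if m else 0.0
        if m >= 2:
            l_est = method4_expected(l_obs, m)
        else:
            warnings.warn(f"group {name}: m < 2, excluded from expected-length estimate")
            l_est = None
        per_group.append(GroupStats(name, m, l_obs, l_est, l_obs / m if m else 0.0))

    frame = pd.DataFrame(
        [(g.group_id, g.m, g.l_obs, g.l_est, g.density) for g in per_group],
        columns=["group", "m", "l_obs", "l_est", "density"],
    ).set_index("group")
    est = frame["l_est"].dropna()
    n_groups = len(frame)

    def sem(col: pd.Series) -> float:
        return float(col.std(ddof=1) / np.sqrt(len(col))) if len(col) > 1 else float("nan")

    totals = {
        "loci": int(frame["m"].sum()),
        "l_obs": float(frame["l_obs"].sum()),
        "l_est": float(est.sum()),
    }
    return {
        "per_group": frame,
        "totals": totals,
        "means": {
            "m": float(frame["m"].mean()),
            "l_obs": float(frame["l_obs"].mean()),
            "l_est": float(est.mean()) if len(est) else float("nan"),
            "density": float(frame["density"].mean()),
        },
        "sem": {
            "m": sem(frame["m"]),
            "l_obs": sem(frame["l_obs"]),
            "l_est": sem(est),
            "density": sem(frame["density"]),
        },
        "overall_density_mean_of_groups": float(frame["density"].mean()),
        "overall_density_total": totals["l_obs"] / totals["loci"] if totals["loci"] else float("nan"),
        "coverage": totals["l_obs"] / totals["l_est"] if totals["l_est"] else float("nan"),
        "n_groups": n_groups,
    }
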