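"""Macrosynteny alignment of an integrated map to a reference genome.

Mapped marker source sequences are aligned to a reference assembly by an
external BLAST run; this module consumes the tabular hits.  Linkage-map
and physical coordinates are both standardized to proportions of their
axis (cM along the conflated homoeologous group; bp along the reference
pseudomolecule), hits are filtered to a single best hit per query under an
E-value threshold, and the resulting dot matrix is scored for
co-linearity (robust repeated-median line fits per block) and scanned for
translocations (change-point segmentation of reference-chromosome labels
along each map group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BLAST6_COLUMNS",
    "read_blast_table",
    "conflate_homoeologues",
    "filter_hits",
    "build_matrix",
    "colinearity_fraction",
    "detect_translocation",
    "SyntenySegment",
]

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_table(path_or_buffer) -> pd.DataFrame:
    """Parse BLAST tabular output (outfmt 6 column convention).

    Malformed rows are reported with their line numbers.
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer) as fh:
            text = fh.read()
    rows = []
    bad = []
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 12:
            bad.append(ln)
            continue
        try:
            rows.append(
                (
                    parts[0], parts[1], float(parts[2]), int(parts[3]), int(parts[4]),
                    int(parts[5]), int(parts[6]), int(parts[7]), int(parts[8]),
                    int(parts[9]), float(parts[10]), float(parts[11]),
                )
            )
        except ValueError:
            bad.append(ln)
    if bad:
        raise ValueError(f"malformed BLAST tabular rows at lines: {bad}")
    return pd.DataFrame(rows, columns=BLAST6_COLUMNS)


def conflate_homoeologues(
    integrated_map: pd.DataFrame,
) -> pd.DataFrame:
    """Collapse the 16 homoeologue groups onto 8 proportional axes.

    Each locus keeps its own homoeologue's scale: ``tr_position`` is its
    cM position divided by its homoeologue's observed length, and
    ``tr_group`` is the homoeologous-pair number shared by the "-1" and
    "-2" groups.  Homoeoloci of the same marker therefore contribute one
    point per mapped locus (homoeologue disagreements stay visible).

    ``integrated_map`` needs columns ``locus``, ``group`` (labels like
    "3-2") and ``position``.
    """
    out = []
    for group, df in integrated_map.groupby("group"):
        label = str(group)
        if "-" not in label:
            warnings.warn(f"locus group {label!r} lacks pair-homoeologue form; excluded")
            continue
        pair = int(label.split("-")[0])
        length = float(df["position"].max())
        rel = df["position"] / length if length > 0 else 0.0
        out.append(
            pd.DataFrame(
                {
                    "locus": df["locus"].to_numpy(),
                    "tr_group": pair,
                    "homoeologue": label,
                    "tr_position": np.asarray(rel, dtype=float),
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["locus", "tr_group", "homoeologue", "tr_position"])
    return pd.concat(out, ignore_index=True)


def filter_hits(
    hits: pd.DataFrame,
    e_max: float = 1e-20,
    max_hits: int = 5,
) -> pd.DataFrame:
    """Reduce raw hits to a single strongest hit per query.

    Per query: discard hits above the E-value threshold, keep at most
    ``max_hits`` by ascending E-value, and retain the single strongest
    (lowest E, ties broken by higher bit score, then first occurrence).
    The result is a pure function of the (query, E, bit score) triples —
    input order only breaks exact ties.
    """
    df = hits[hits["evalue"] <= e_max].copy()
    if df.empty:
        return df
    df["_order"] = np.arange(len(df))
    df = df.sort_values(["qseqid", "evalue", "bitscore", "_order"],
                        ascending=[True, True, False, True], kind="stable")
    df = df.groupby("qseqid", sort=True).head(max_hits)
    best = df.groupby("qseqid", sort=True).head(1)
    return best.drop(columns="_order").reset_index(drop=True)


def normalize_hits(
    best_hits: pd.DataFrame,
    conflated: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Join best hits to map positions and standardize reference coordinates.

    Reference positions use the hit midpoint divided by the chromosome
    length; strand is retained as metadata (``sstart > send`` marks the
    minus strand) but ignored for position.
    """
    merged = best_hits.merge(conflated, left_on="qseqid", right_on="locus", how="inner")
    lengths = merged["sseqid"].map(chrom_lengths)
    if lengths.isna().any():
        missing = sorted(merged.loc[lengths.isna(), "sseqid"].unique())
        raise KeyError(f"no chromosome length for: {missing}")
    mid = (merged["sstart"] + merged["send"]) / 2.0
    merged["ref_chromosome"] = merged["sseqid"]
    merged["ref_position"] = mid / lengths
    merged["minus_strand"] = merged["sstart"] > merged["send"]
    return merged[
        ["locus", "tr_group", "homoeologue", "tr_position",
         "ref_chromosome", "ref_position", "evalue", "bitscore", "minus_strand"]
    ]


def build_matrix(records: pd.DataFrame) -> dict:
    """Contingency counts of hits by (map group x reference chromosome).

    Returns the count matrix, the dominant reference chromosome per map
    group, and the dot-plot table of proportional coordinate pairs.
    """
    if records.empty:
        return {"counts": pd.DataFrame(), "dominant": {}, "dots": records}
    counts = pd.crosstab(records["tr_group"], records["ref_chromosome"])
    dominant = {g: counts.loc[g].idxmax() for g in counts.index}
    dots = records[["tr_group", "tr_position", "ref_chromosome", "ref_position"]].copy()
    return {"counts": counts, "dominant": dominant, "dots": dots}


def _repeated_median_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Siegel repeated-median regression: robust to up to 50% outliers."""
    n = len(x)
    slopes = np.full(n, np.nan)
    for i in range(n):
        dx = x - x[i]
        dy = y - y[i]
        mask = dx != 0
        if mask.any():
            slopes[i] = np.median(dy[mask] / dx[mask])
    slope = float(np.nanmedian(slopes))
    intercept = float(np.median(y - slope * x))
    return slope, intercept


def colinearity_fraction(
    records: pd.DataFrame,
    residual_threshold: float = 0.1,
) -> tuple[float, pd.DataFrame]:
    """Proportion of hits lying on their block's dominant linear trend.

    Per (map group, dominant reference chromosome) block with at least 3
    hits, a repeated-median line is fitted to (tr_position, ref_position);
    a hit is co-linear when its absolute residual is within
    ``residual_threshold`` (in proportional units).  Hits on
    non-dominant chromosomes and in undersized blocks count as
    non-co-linear in the overall fraction.

    Returns ``(overall fraction, per-record table with colinear flags)``.
    """
    if records.empty:
        return float("nan"), records
    out = records.copy()
    out["colinear"] = False
    counts = pd.crosstab(out["tr_group"], out["ref_chromosome"])
    for g in counts.index:
        dom = counts.loc[g].idxmax()
        block = out[(out["tr_group"] == g) & (out["ref_chromosome"] == dom)]
        if len(block) < 3:
            continue
        x = block["tr_position"].to_numpy()
        y = block["ref_position"].to_numpy()
        slope, intercept = _repeated_median_line(x, y)
        resid = np.abs(y - (slope * x + intercept))
        out.loc[block.index, "colinear"] = resid <= residual_threshold
    return float(out["colinear"].mean()), out


@dataclass(frozen=True)
class SyntenySegment:
    """A contiguous map interval dominated by one reference chromosome.

    ``purity`` is the fraction of the segment's hits matching its label;
    interleaved label sequences collapse to a single low-purity segment.
    """

    tr_group: int
    start: float
    end: float
    ref_chromosome: str
    n_hits: int
    purity: float


def _best_segmentation(
    labels: Sequence[str], max_breakpoints: int = 3
) -> tuple[list[tuple[int, int, str]], int]:
    """Minimal-misclassification segmentation of a label sequence.

    Finds the segmentation with at most ``max_breakpoints`` breakpoints
    minimizing the number of hits not matching their segment's majority
    reference chromosome (alphabetical tie-break within a segment; fewer
    breakpoints win overall ties, so pure sequences yield one segment).
    Dynamic program over (position, segments used), equivalent to
    exhaustive enumeration of every breakpoint placement.
    """
    n = len(labels)
    uniq = sorted(set(labels))
    code = {c: k for k, c in enumerate(uniq)}
    prefix = np.zeros((n + 1, len(uniq)), dtype=int)
    for i, lab in enumerate(labels):
        prefix[i + 1] = prefix[i]
        prefix[i + 1, code[lab]] += 1

    def seg_cost(a: int, b: int) -> tuple[int, str]:
        counts = prefix[b] - prefix[a]
        top = int(counts.max())
        winner = uniq[int(np.argmax(counts))]  # argmax = first = alphabetical
        return (b - a) - top, winner

    max_segs = max_breakpoints + 1
    INF = n + 1
    # best[j][i]: minimal misclassifications covering labels[:i] with j segments
    best = np.full((max_segs + 1, n + 1), INF, dtype=int)
    back = np.zeros((max_segs + 1, n + 1), dtype=int)
    best[0, 0] = 0
    for j in range(1, max_segs + 1):
        for i in range(1, n + 1):
            for a in range(j - 1, i):
                if best[j - 1, a] >= INF:
                    continue
                c, _ = seg_cost(a, i)
                if best[j - 1, a] + c < best[j, i]:
                    best[j, i] = best[j - 1, a] + c
                    back[j, i] = a
    j_opt = min(range(1, max_segs + 1), key=lambda j: (best[j, n], j))
    mis = int(best[j_opt, n])
    bounds = [n]
    j, i = j_opt, n
    while j > 0:
        i = int(back[j, i])
        bounds.append(i)
        j -= 1
    bounds = bounds[::-1]
    segs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        _, winner = seg_cost(a, b)
        segs.append((a, b, winner))
    return segs, mis


def plot_dot_matrix(records: pd.DataFrame, ax=None):
    """Dot plot of map position vs reference position, panelled by group.

    Both axes are proportional coordinates; points are coloured by
    reference chromosome so translocated segments stand out.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 8))
    chroms = sorted(records["ref_chromosome"].unique())
    cmap = plt.get_cmap("tab10")
    groups = sorted(records["tr_group"].unique())
    n = len(groups)
    for gi, g in enumerate(groups):
        block = records[records["tr_group"] == g]
        x = (gi + block["tr_position"]) / max(n, 1)
        for ci, c in enumerate(chroms):
            sel = block["ref_chromosome"] == c
            ax.scatter(x[sel], block.loc[sel, "ref_position"], s=8,
                       color=cmap(ci % 10), label=c if gi == 0 else None)
    for gi in range(1, n):
        ax.axvline(gi / n, color="grey", lw=0.5)
    ax.set_xlabel("map group (proportional position)")
    ax.set_ylabel("reference position (proportional)")
    ax.legend(fontsize=7, title="reference")
    return ax


def detect_translocation(
    records: pd.DataFrame,
    max_breakpoints: int = 3,
    min_secondary_hits: int = 3,
) -> list[SyntenySegment]:
    """Segment one map group's hits by reference chromosome.

    Hits are ordered along the map axis and segmented to minimize
    misclassified chromosome labels over at most ``max_breakpoints``
    breakpoints.  A segmentation is only confident when every segment is
    supported by at least ``min_secondary_hits`` hits — matching the
    minimum support observed for a secondary chromosome call — otherwise
    the breakpoint budget is reduced, so interleaved label sequences
    collapse to a single low-purity segment.  Adjacent segments sharing a
    label are merged.

    ``records`` must cover a single ``tr_group``.
    """
    groups = records["tr_group"].unique()
    if len(groups) != 1:
        raise ValueError("detect_translocation expects records for exactly one map group")
    g = int(groups[0])
    df = records.sort_values("tr_position", kind="stable").reset_index(drop=True)
    labels = df["ref_chromosome"].tolist()
    if not labels:
        return []
    merged: list[tuple[int, int, str]] = []
    for budget in range(max_breakpoints, -1, -1):
        segs, _ = _best_segmentation(labels, budget)
        merged = []
        for a, b, lab in segs:
            if merged and merged[-1][2] == lab:
                merged[-1] = (merged[-1][0], b, lab)
            else:
                merged.append((a, b, lab))
        if all(b - a >= min_secondary_hits for a, b, _ in merged) or len(merged) == 1:
            break
    dominant = pd.Series(labels).value_counts().idxmax()
    out = []
    for a, b, lab in merged:
        n_hits = b - a
        if lab != dominant and n_hits < min_secondary_hits:
            continue
        purity = sum(1 for x in labels[a:b] if x == lab) / n_hits
        out.append(
            SyntenySegment(
                tr_group=g,
                start=float(df["tr_position"].iloc[a]),
                end=float(df["tr_position"].iloc[b - 1]),
                ref_chromosome=lab,
                n_hits=n_hits,
                purity=purity,
            )
        )
    return out
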