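"""Two-point linkage analysis for outbred (CP-type) F1 populations.

In a double pseudo-testcross, each highly heterozygous parent of an F1
cross segregates independently, so every marker locus is classified by its
segregation configuration — ab x cd (four alleles), ab x ac (three),
ab x ab (shared heterozygote), ab x aa / aa x ab (single-parent
informative), each optionally with null (non-amplifying) alleles.  For
each parent whose transmitted allele can be deduced from the observed
progeny phenotype, the locus contributes one scored meiosis per progeny;
two-point recombination fractions are maximum-likelihood estimates over
both phase assignments, with a base-10 LOD against independence (r = 0.5).

Loci are grouped at a LOD threshold (default 8) by connected components,
ordered within groups by greedy seriation against the matrix of pairwise
Kosambi distances, and positioned by cumulative adjacent distances.
Segregation-distortion scans test observed progeny class counts against
the configuration's expected ratios by chi-square, with a signed
-log10(P) profile by parental origin (positive = female-derived,
negative = male-derived).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "UninformativeLocusError",
    "classify_segregation",
    "transmission_table",
    "transmissions",
    "PairwiseLinkage",
    "estimate_rf",
    "pairwise_linkage",
    "informative_loci",
    "group_loci",
    "order_group",
    "kosambi_d",
    "kosambi_r",
    "haldane_d",
    "haldane_r",
    "build_parental_consensus",
    "DistortionRecord",
    "distortion_scan",
]

Genotype = tuple[int, int]  # allele sizes in bp; 0 encodes a null allele
Call = "tuple[int, ...] | None"  # observed distinct visible sizes; None = missing


class UninformativeLocusError(ValueError):
    """Raised when neither parent segregates at a locus."""


# ---------------------------------------------------------------------------
# segregation typing


def _visible(g1: int, g2: int) -> tuple[int, ...]:
    return tuple(sorted({g1, g2} - {0}))


def classify_segregation(p1: Genotype, p2: Genotype) -> tuple[str, dict[tuple[int, ...], float]]:
    """Segregation type and expected observable progeny-class ratios.

    Enumerates the four equiprobable gamete unions and pools those with
    identical *observable* phenotypes (distinct visible allele sizes, null
    alleles invisible), so null-allele configurations collapse classes
    automatically.

    Returns ``(type_string, {observed-class tuple: probability})``.
    Raises :class:`UninformativeLocusError` when both parents are
    (effectively) homozygous.
    """
    a, b = p1
    c, d = p2
    het1 = a != b
    het2 = c != d
    if not het1 and not het2:
        raise UninformativeLocusError(f"neither parent segregates: {p1} x {p2}")

    s1 = {a, b} - {0}
    s2 = {c, d} - {0}
    has_null = 0 in p1 or 0 in p2
    if het1 and het2:
        shared = len(s1 & s2)
        distinct = len(s1 | s2)
        if has_null:
            seg = "abxcd_null"
        elif distinct == 4:
            seg = "abxcd"
        elif shared == 1 and distinct == 3:
            seg = "abxac"
        elif shared == 2:
            seg = "abxab"
        else:
            seg = "abxac"
    elif het1:
        seg = "abxaa" if not has_null else "abxaa_null"
    else:
        seg = "aaxab" if not has_null else "aaxab_null"

    classes: dict[tuple[int, ...], float] = {}
    for g1 in (a, b):
        for g2 in (c, d):
            cls = _visible(g1, g2)
            classes[cls] = classes.get(cls, 0.0) + 0.25
    return seg, classes


def transmission_table(p1: Genotype, p2: Genotype) -> dict[tuple[int, ...], tuple[int, int]]:
    """Map each observable progeny class to deducible parental transmissions.

    Values are ``(t1, t2)`` where ``t`` is the transmitting parent's allele
    slot (0 or 1) when it is uniquely determined by the phenotype and -1
    when ambiguous (e.g. the heterozygous class of an ab x ab locus).
    """
    table: dict[tuple[int, ...], list[tuple[int, int]]] = {}
    for i, g1 in enumerate(p1):
        for j, g2 in enumerate(p2):
            cls = _visible(g1, g2)
            table.setdefault(cls, []).append((i, j))
    out = {}
    for cls, combos in table.items():
        t1s = {i for i, _ in combos}
        t2s = {j for _, j in combos}
        out[cls] = (
            t1s.pop() if len(t1s) == 1 else -1,
            t2s.pop() if len(t2s) == 1 else -1,
        )
    return out


def transmissions(
    parents: tuple[Genotype, Genotype], calls: Sequence[Call]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-progeny transmitted-allele slots for each parent.

    Returns two int8 arrays of length n with values {0, 1} where the
    transmission is deducible and -1 where it is not (missing call,
    ambiguous class, or a phenotype inconsistent with the parents —
    a putative genotyping error).
    """
    table = transmission_table(*parents)
    n = len(calls)
    t1 = np.full(n, -1, dtype=np.int8)
    t2 = np.full(n, -1, dtype=np.int8)
    for k, call in enumerate(calls):
        if call is None:
            continue
        hit = table.get(tuple(call))
        if hit is None:
            continue
        t1[k], t2[k] = hit
    return t1, t2


# ---------------------------------------------------------------------------
# mapping functions


def kosambi_d(r: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance (cM) from recombination fraction.

    ``d = 25 ln((1 + 2r) / (1 - 2r))``; defined for r in [0, 0.5).
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_r(d: float | np.ndarray) -> float | np.ndarray:
    """Inverse Kosambi: recombination fraction from map distance (cM)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def haldane_d(r: float) -> float:
    """Haldane map distance (cM): ``-50 ln(1 - 2r)``."""
    if not 0 <= r < 0.5:
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    return -50.0 * math.log(1 - 2 * r)


def haldane_r(d: float) -> float:
    """Inverse Haldane: ``(1 - exp(-d/50)) / 2``."""
    if d < 0:
        raise ValueError("map distance must be non-negative")
    return (1 - math.exp(-d / 50.0)) / 2.0


# ---------------------------------------------------------------------------
# two-point estimation


@dataclass(frozen=True)
class PairwiseLinkage:
    """Two-point linkage estimate between two loci."""

    locus_a: str
    locus_b: str
    r: float
    lod: float
    phase: tuple[int, int]  # chosen phase flip per parent (0 = as stored, 1 = flipped)
    n_informative: int
    low_confidence: bool


def _pair_counts(ta: np.ndarray, tb: np.ndarray) -> tuple[int, int]:
    """(non-recombinant, recombinant) counts under the better phase."""
    valid = (ta >= 0) & (tb >= 0)
    n = int(valid.sum())
    if n == 0:
        return 0, 0
    mism = int((ta[valid] != tb[valid]).sum())
    return n - mism, mism


def _lod_term(nr: int, rec: int, r: float) -> float:
    lod = 0.0
    if nr:
        lod += nr * math.log10(2.0 * (1.0 - r))
    if rec:
        lod += rec * math.log10(2.0 * r)
    return lod


def estimate_rf(
    locus_a: str,
    locus_b: str,
    parents_a: tuple[Genotype, Genotype],
    parents_b: tuple[Genotype, Genotype],
    calls_a: Sequence[Call],
    calls_b: Sequence[Call],
    min_informative: int = 10,
) -> PairwiseLinkage:
    """Maximum-likelihood two-point recombination fraction and LOD.

    Each parent informative at both loci contributes an independent meiosis
    set; within each parent the phase with fewer recombinants (higher
    likelihood) is chosen, ties broken toward coupling.  The pooled MLE is
    the recombinant fraction over all scored meioses and the LOD sums the
    per-parent log10 likelihood ratios against r = 0.5.

    Pairs with fewer than ``min_informative`` scored meioses are flagged
    low-confidence (excluded from grouping by default).
    """
    t1a, t2a = transmissions(parents_a, calls_a)
    t1b, t2b = transmissions(parents_b, calls_b)
    phases = []
    total_n = 0
    total_rec = 0
    per_parent = []
    for ta, tb in ((t1a, t1b), (t2a, t2b)):
        nr, rec = _pair_counts(ta, tb)
        flip = 1 if rec > nr else 0
        if flip:
            nr, rec = rec, nr
        phases.append(flip)
        per_parent.append((nr, rec))
        total_n += nr + rec
        total_rec += rec
    if total_n == 0:
        return PairwiseLinkage(locus_a, locus_b, 0.5, 0.0, (0, 0), 0, True)
    r = total_rec / total_n
    if r >= 0.5:
        lod = 0.0
    else:
        lod = sum(_lod_term(nr, rec, max(r, 1e-12)) for nr, rec in per_parent if nr + rec)
        if total_rec == 0:
            lod = total_n * math.log10(2.0)
    return PairwiseLinkage(
        locus_a,
        locus_b,
        float(r),
        float(max(lod, 0.0)),
        (phases[0], phases[1]),
        total_n,
        total_n < min_informative,
    )


def informative_loci(
    parents: Mapping[str, tuple[Genotype, Genotype]],
    calls: Mapping[str, Sequence[Call]],
) -> list[str]:
    """Loci contributing at least one deducible parental meiosis.

    Loci where no observed phenotype pins down either parent's transmitted
    allele (both parents effectively homozygous, or nulls masking all
    segregation) cannot enter linkage analysis.
    """
    out = []
    for lid, locus_calls in calls.items():
        t1, t2 = transmissions(parents[lid], locus_calls)
        if (t1 >= 0).any() or (t2 >= 0).any():
            out.append(lid)
    return out


def _transmission_matrices(
    loci: Sequence[str],
    parents: Mapping[str, tuple[Genotype, Genotype]],
    calls: Mapping[str, Sequence[Call]],
) -> tuple[np.ndarray, np.ndarray]:
    n = len(next(iter(calls.values())))
    T1 = np.full((len(loci), n), -1, dtype=np.int8)
    T2 = np.full((len(loci), n), -1, dtype=np.int8)
    for k, lid in enumerate(loci):
        t1, t2 = transmissions(parents[lid], calls[lid])
        T1[k] = t1
        T2[k] = t2
    return T1, T2


def pairwise_linkage(
    loci: Sequence[str],
    parents: Mapping[str, tuple[Genotype, Genotype]],
    calls: Mapping[str, Sequence[Call]],
    min_informative: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized all-pairs two-point estimation.

    Returns ``(r, lod, n_informative)`` square arrays aligned with
    ``loci``.  Pairs with fewer than ``min_informative`` scored meioses
    get LOD 0 (and r 0.5) so they never drive grouping.
    """
    T1, T2 = _transmission_matrices(loci, parents, calls)
    m = len(loci)
    total_nr = np.zeros((m, m))
    total_rec = np.zeros((m, m))
    lod = np.zeros((m, m))
    parts = []
    for T in (T1, T2):
        V = (T >= 0).astype(np.float64)
        X = ((T == 1) & (T >= 0)).astype(np.float64)
        Y = ((T == 0)).astype(np.float64)
        match = X @ X.T + Y @ Y.T
        mism = X @ Y.T + Y @ X.T
        nr = np.maximum(match, mism)
        rec = np.minimum(match, mism)
        parts.append((nr, rec))
        total_nr += nr
        total_rec += rec
    n_inf = total_nr + total_rec
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(n_inf > 0, total_rec / np.maximum(n_inf, 1), 0.5)
        r_safe = np.clip(r, 1e-12, None)
        for nr, rec in parts:
            term = nr * np.log10(2.0 * (1.0 - r_safe)) + rec * np.log10(
                np.clip(2.0 * r_safe, 1e-300, None)
            )
            # rec == 0 contributes only the non-recombinant term
            term = np.where(rec > 0, term, nr * np.log10(2.0 * (1.0 - r_safe)))
            lod += np.where(nr + rec > 0, term, 0.0)
    lod = np.where((r < 0.5) & (n_inf >= min_informative), np.maximum(lod, 0.0), 0.0)
    np.fill_diagonal(lod, 0.0)
    np.fill_diagonal(r, 0.0)
    return r, lod, n_inf.astype(int)


# ---------------------------------------------------------------------------
# grouping and ordering


def group_loci(
    loci: Sequence[str], lod: np.ndarray, threshold: float = 8.0
) -> list[list[str]]:
    """Linkage groups: connected components of the LOD >= threshold graph."""
    adj = csr_matrix(lod >= threshold)
    n_comp, labels = connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    for lid, lab in zip(loci, labels):
        groups.setdefault(int(lab), []).append(lid)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0]))


def _path_positions(order: list[int], d: np.ndarray) -> np.ndarray:
    pos = np.zeros(len(order))
    for k in range(1, len(order)):
        pos[k] = pos[k - 1] + d[order[k - 1], order[k]]
    return pos


def _seriation_error(order: list[int], d: np.ndarray, w: np.ndarray) -> float:
    pos = _path_positions(order, d)
    idx = np.asarray(order)
    dd = d[np.ix_(idx, idx)]
    ww = w[np.ix_(idx, idx)]
    path = np.abs(pos[:, None] - pos[None, :])
    return float((ww * (dd - path) ** 2).sum() / 2.0)


def order_group(
    group: Sequence[str],
    loci: Sequence[str],
    r: np.ndarray,
    lod: np.ndarray,
) -> pd.DataFrame:
    """Order a linkage group and assign cumulative Kosambi positions.

    Greedy seriation: seed with the highest-LOD pair, then insert each
    remaining locus (taken in order of its strongest LOD to the placed
    set) at the slot minimizing the LOD-weighted squared error between
    pairwise Kosambi distances and path distances; finish with adjacent
    swaps to a local optimum.  The orientation placing the
    lexicographically smaller terminal locus first is canonical.

    Returns a DataFrame with columns ``locus`` and ``position`` (cM).
    """
    index = {lid: k for k, lid in enumerate(loci)}
    ids = [index[g] for g in group]
    if len(ids) == 1:
        return pd.DataFrame({"locus": list(group), "position": [0.0]})
    sub_r = np.clip(r[np.ix_(ids, ids)], 0.0, 0.4999)
    d = kosambi_d(sub_r)
    # pairs estimated as effectively unlinked carry no usable distance
    # signal (their mapped distance diverges as r -> 0.5); exclude them
    # from the ordering objective and repair their distances by shortest
    # paths through confidently linked pairs, so that any candidate order
    # can be positioned without unlinked adjacencies exploding the path
    w = np.where(sub_r < 0.45, lod[np.ix_(ids, ids)], 0.0)
    np.fill_diagonal(w, 0.0)
    linked = w > 0
    if linked.any():
        graph = csr_matrix(np.where(linked, d + 1e-9, 0.0))
        repaired = shortest_path(graph, directed=False)
        use = np.isfinite(repaired)
        np.fill_diagonal(use, False)
        d = np.where(use, repaired, d)

    m = len(ids)
    if m == 2:
        order = [0, 1]
    else:
        seed = np.unravel_index(np.argmax(w), w.shape)
        order = [int(seed[0]), int(seed[1])]
        placed = set(order)
        while len(order) < m:
            remaining = [k for k in range(m) if k not in placed]
            nxt = max(remaining, key=lambda k: w[k, list(placed)].max())
            best = None
            for slot in range(len(order) + 1):
                cand = order[:slot] + [nxt] + order[slot:]
                err = _seriation_error(cand, d, w)
                if best is None or err < best[0]:
                    best = (err, cand)
            order = best[1]
            placed.add(nxt)
        # local optimization: adjacent swaps, segment reversals (fixes
        # folded ends) and single-locus relocations, to a joint optimum
        improved = True
        passes = 0
        current = _seriation_error(order, d, w)
        while improved and passes < 30:
            improved = False
            passes += 1
            for i in range(m - 1):
                for j in range(i + 1, m):
                    cand = order[:i] + order[i : j + 1][::-1] + order[j + 1 :]
                    err = _seriation_error(cand, d, w)
                    if err < current - 1e-12:
                        order, current = cand, err
                        improved = True
            # relocate short blocks (misattached weakly linked segments)
            for size in (1, 2, 3):
                for i in range(m - size + 1):
                    block = order[i : i + size]
                    rest = order[:i] + order[i + size :]
                    for slot in range(len(rest) + 1):
                        for seg in (block, block[::-1]):
                            cand = rest[:slot] + seg + rest[slot:]
                            if cand == order:
                                continue
                            err = _seriation_error(cand, d, w)
                            if err < current - 1e-12:
                                order, current = cand, err
                                improved = True
                                break

    names = [group[k] for k in order]
    if names[-1] < names[0]:
        order = order[::-1]
        names = names[::-1]
    pos = _path_positions(order, d)
    return pd.DataFrame({"locus": names, "position": pos})


# ---------------------------------------------------------------------------
# parental consensus


def build_parental_consensus(
    maternal_map: pd.DataFrame,
    paternal_map: pd.DataFrame,
    weights: tuple[float, float] = (1.0, 1.0),
    min_bridge: int = 2,
) -> tuple[list[pd.DataFrame], list[str]]:
    """Merge single-parent maps into a bi-parental consensus map.

    Bridge loci (segregating through both parents, hence present in both
    single-parent maps) anchor the merge; each pair of groups sharing at
    least ``min_bridge`` bridge loci is combined with the joining-locus
    merge of :func:`clovermap.integration.combine_groups`.  Groups without
    a bridged partner are passed through unmerged and reported.

    Both inputs are DataFrames with columns ``locus``, ``group``,
    ``position``.  Returns ``(list of merged group frames, warnings)``.
    """
    from clovermap.integration import combine_groups

    merged: list[pd.DataFrame] = []
    notes: list[str] = []
    pat_groups = {g: df for g, df in paternal_map.groupby("group")}
    used_pat: set = set()
    for g, mat in maternal_map.groupby("group"):
        best = None
        for pg, pat in pat_groups.items():
            if pg in used_pat:
                continue
            shared = set(mat["locus"]) & set(pat["locus"])
            if len(shared) >= min_bridge and (best is None or len(shared) > best[0]):
                best = (len(shared), pg, pat)
        if best is None:
            notes.append(f"maternal group {g}: no bridged paternal partner; emitted unmerged")
            out = mat[["locus", "position"]].copy()
            out["provenance"] = "maternal"
            merged.append(out)
            continue
        _, pg, pat = best
        used_pat.add(pg)
        combined = combine_groups(
            mat[["locus", "position"]], pat[["locus", "position"]], weights=weights
        )
        merged.append(combined)
    for pg, pat in pat_groups.items():
        if pg not in used_pat:
            notes.append(f"paternal group {pg}: no bridged maternal partner; emitted unmerged")
            out = pat[["locus", "position"]].copy()
            out["provenance"] = "paternal"
            merged.append(out)
    return merged, notes


# ---------------------------------------------------------------------------
# segregation distortion


@dataclass(frozen=True)
class DistortionRecord:
    """Chi-square segregation test for one mapped locus."""

    locus: str
    chi_square: float
    p_value: float
    parental_origin: str  # "female" | "male" | "both"
    signed_log10p: float
    relative_position: float
    distorted: bool
    removable: bool = False


def _exact_multinomial_p(observed: Sequence[int], probs: Sequence[float]) -> float:
    """Exact multinomial test: total probability of outcomes at least as
    extreme (by chi-square statistic) as observed.  Enumeration — intended
    for the small-n fallback when an expected class count is below 1."""
    n = int(sum(observed))
    k = len(probs)
    exp = [n * p for p in probs]
    def chi2(counts):
        return sum((o - e) ** 2 / e for o, e in zip(counts, exp) if e > 0)
    obs_stat = chi2(observed)
    p_total = 0.0
    for combo in itertools.product(range(n + 1), repeat=k - 1):
        if sum(combo) > n:
            continue
        counts = list(combo) + [n - sum(combo)]
        if chi2(counts) >= obs_stat - 1e-12:
            p_total += math.exp(
                math.lgamma(n + 1)
                - sum(math.lgamma(c + 1) for c in counts)
                + sum(c * math.log(p) if c else 0.0 for c, p in zip(counts, probs))
            )
    return min(p_total, 1.0)


def distortion_scan(
    ordered_map: pd.DataFrame,
    parents: Mapping[str, tuple[Genotype, Genotype]],
    calls: Mapping[str, Sequence[Call]],
    alpha: float = 0.05,
    female_index: int = 0,
) -> list[DistortionRecord]:
    """Scan ordered loci for segregation distortion.

    For each locus the observed progeny class counts are tested against the
    configuration's expected ratios by chi-square with (classes - 1)
    degrees of freedom (exact multinomial when an expected count falls
    below 1).  The signed profile encodes parental origin: -log10(P)
    (positive) for loci whose distortion traces to the female parent,
    +log10(P) (negative) for the male parent; for loci informative through
    both parents the sign follows the parent with the stronger per-parent
    transmission departure from 1:1.

    Loci with P < ``alpha`` are flagged distorted; a flagged locus is
    additionally marked removable when both flanking loci are
    non-distorted and its |signed log10 P| exceeds both flanks' by more
    than 2 (a distortion pattern incongruous with its neighbours).

    ``ordered_map`` needs columns ``locus`` and ``position``.
    """
    length = float(ordered_map["position"].max()) or 1.0
    records: list[DistortionRecord] = []
    for _, row in ordered_map.iterrows():
        lid = row["locus"]
        seg, expected = classify_segregation(*parents[lid])
        obs_counts = {cls: 0 for cls in expected}
        for call in calls[lid]:
            if call is None:
                continue
            key = tuple(call)
            if key in obs_counts:
                obs_counts[key] += 1
        classes = sorted(expected)
        obs = [obs_counts[c] for c in classes]
        probs = [expected[c] for c in classes]
        n = sum(obs)
        if n == 0:
            continue
        exp_counts = [n * p for p in probs]
        if min(exp_counts) < 1.0 and n <= 60:
            p_val = _exact_multinomial_p(obs, probs)
            chi2 = float(
                sum((o - e) ** 2 / e for o, e in zip(obs, exp_counts) if e > 0)
            )
        else:
            chi2, p_val = stats.chisquare(obs, exp_counts)
            chi2, p_val = float(chi2), float(p_val)

        # parental origin from per-parent transmission departures
        t1, t2 = transmissions(parents[lid], calls[lid])
        p_parent = []
        for t in (t1, t2):
            scored = t[t >= 0]
            if len(scored) == 0:
                p_parent.append(None)
            else:
                k1 = int((scored == 1).sum())
                p_parent.append(float(stats.binomtest(k1, len(scored), 0.5).pvalue))
        female_p = p_parent[female_index]
        male_p = p_parent[1 - female_index]
        if female_p is not None and male_p is None:
            origin = "female"
        elif male_p is not None and female_p is None:
            origin = "male"
        elif female_p is None and male_p is None:
            origin = "female"
        else:
            origin = "both"
        if origin == "both":
            sign = 1.0 if female_p <= male_p else -1.0
        else:
            sign = 1.0 if origin == "female" else -1.0
        log10p = -math.log10(max(p_val, 1e-300))
        records.append(
            DistortionRecord(
                locus=lid,
                chi_square=chi2,
                p_value=p_val,
                parental_origin=origin,
                signed_log10p=sign * log10p,
                relative_position=float(row["position"]) / length,
                distorted=p_val < alpha,
            )
        )
    # incongruity flag against flanking loci
    final: list[DistortionRecord] = []
    for k, rec in enumerate(records):
        removable = False
        if rec.distorted and 0 < k < len(records) - 1:
            left, right = records[k - 1], records[k + 1]
            if not left.distorted and not right.distorted:
                mag = abs(rec.signed_log10p)
                if mag > abs(left.signed_log10p) + 2 and mag > abs(right.signed_log10p) + 2:
                    removable = True
        final.append(
            DistortionRecord(
                rec.locus, rec.chi_square, rec.p_value, rec.parental_origin,
                rec.signed_log10p, rec.relative_position, rec.distorted, removable,
            )
        )
    return final
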