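"""Homoeologue-specific marker designation and inter-population pairing.

In an allotetraploid, an SSR primer pair may amplify one homoeolocus or
both.  A marker showing single-locus segregation in a mapping population
is designated *single-locus homoeologue-specific* (SL-HS) when no
individual of a diversity panel ever shows more than two alleles at it —
evidence that the primer targets exactly one homoeolocus genome-wide.

Matching linkage groups between two unrelated populations uses two
evidence classes, in order of precedence:

1. SL-HS joining loci: an SL-HS marker mapped in both populations links
   its two groups directly.  Multiple SL-HS markers from one homoeologue
   mapping to *different* homoeologues in the other population is a hard
   conflict and leaves the pairing unresolved.
2. Allele sizes: where a marker's two homoeoloci occupy distinct size
   ranges, agreement of the observed size range across populations
   supports a pairing (match), the alternative range contradicts it
   (mismatch), and overlapping ranges are ambiguous.

A pairing is accepted when SL-HS evidence is conflict-free and either at
least one SL-HS locus supports it or the net allele-size evidence does;
matching one inter-population pair fixes the sister pairing by
elimination.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "InsufficientEvidenceError",
    "designate_slhs",
    "allele_size_evidence",
    "HomoeologueAssignment",
    "assign_pairing",
    "support_table",
    "summarize_support",
]

EVIDENCE_CLASSES = ("match", "mismatch", "ambiguous")


class InsufficientEvidenceError(ValueError):
    """Raised when SL-HS designation is requested without panel evidence."""


def designate_slhs(panel_calls: Iterable["Sequence[int] | None"]) -> bool:
    """True iff every panel individual shows at most two distinct alleles.

    ``panel_calls`` iterates observed allele-size collections, one per
    panel individual; ``None`` (missing) entries carry no evidence.
    Raises :class:`InsufficientEvidenceError` on an empty panel.
    """
    seen_any = False
    ok = True
    for call in panel_calls:
        if call is None:
            continue
        seen_any = True
        if len(set(call)) > 2:
            ok = False
    if not seen_any:
        raise InsufficientEvidenceError("empty panel: cannot designate SL-HS status")
    return ok


def _interval(sizes: Iterable[int]) -> tuple[int, int]:
    s = list(sizes)
    return (min(s), max(s))


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def allele_size_evidence(
    sizes_a: "Sequence[int] | None",
    sizes_b: "Sequence[int] | None",
    range_consistent: tuple[int, int],
    range_alternative: tuple[int, int],
) -> str:
    """Classify one joining locus's allele-size support for a candidate pairing.

    ``range_consistent`` is the homoeolocus allele-size range implied by
    the candidate pairing; ``range_alternative`` is the sister
    homoeolocus's range.  Overlapping ranges cannot discriminate and are
    ambiguous; so is a locus whose observed sizes straddle both ranges
    within one population, or one with missing sizes (with a warning).
    """
    if not sizes_a or not sizes_b:
        warnings.warn("joining locus with missing allele sizes classed ambiguous")
        return "ambiguous"
    if _overlaps(range_consistent, range_alternative):
        return "ambiguous"

    def side(sizes: Sequence[int]) -> str:
        in_c = all(range_consistent[0] <= s <= range_consistent[1] for s in sizes)
        in_alt = all(range_alternative[0] <= s <= range_alternative[1] for s in sizes)
        if in_c and not in_alt:
            return "c"
        if in_alt and not in_c:
            return "alt"
        return "?"

    sa, sb = side(sizes_a), side(sizes_b)
    if "?" in (sa, sb):
        return "ambiguous"
    if sa == sb == "c":
        return "match"
    if sa != sb:
        return "mismatch"
    # both populations' sizes sit in the alternative range: the ranges agree
    # with each other, which under the candidate pairing is still agreement
    # of homoeolocus identity between populations
    return "match"


@dataclass(frozen=True)
class HomoeologueAssignment:
    """A pairing decision between linkage groups of two populations."""

    group_id: str
    pairing: "tuple[str, str] | None"  # (group in A, matched group in B)
    slhs_support: int
    slhs_conflicts: int
    size_matches: int
    size_mismatches: int
    size_ambiguous: int
    status: str  # accepted | accepted_single_slhs | unresolved

    def __post_init__(self) -> None:
        if self.status.startswith("accepted") and self.slhs_conflicts > 0:
            raise ValueError("an assignment with SL-HS conflicts can never be accepted")


def assign_pairing(
    group_a: str,
    candidates_b: tuple[str, str],
    slhs_links: Sequence[str],
    size_evidence: Sequence[str],
) -> HomoeologueAssignment:
    """Decide the homoeologue pairing for one linkage group of population A.

    Parameters
    ----------
    group_a : str
        The group in population A being aligned.
    candidates_b : tuple
        The two candidate homoeologue groups in population B.
    slhs_links : sequence of str
        For each SL-HS joining locus mapped on ``group_a``, the population-B
        group it mapped to (one of ``candidates_b``).
    size_evidence : sequence of {"match", "mismatch", "ambiguous"}
        Per joining locus, allele-size support evaluated against the
        *first* candidate pairing ``group_a <-> candidates_b[0]``.

    SL-HS evidence takes precedence: links to both candidates are a
    conflict (unresolved).  Otherwise the pairing maximizing net
    allele-size agreement is chosen; a tie without SL-HS support is
    unresolved, as is a disagreement between the SL-HS choice and a
    strictly opposing net size vote.
    """
    b1, b2 = candidates_b
    links = Counter(slhs_links)
    unknown = set(links) - {b1, b2}
    if unknown:
        raise ValueError(f"SL-HS links to unknown groups: {sorted(unknown)}")
    ev = Counter(size_evidence)
    bad = set(ev) - set(EVIDENCE_CLASSES)
    if bad:
        raise ValueError(f"unknown evidence classes: {sorted(bad)}")
    m1, m2, amb = ev["match"], ev["mismatch"], ev["ambiguous"]

    if not slhs_links and not size_evidence:
        return HomoeologueAssignment(group_a, None, 0, 0, 0, 0, 0, "unresolved")

    def unresolved(support: int, conflicts: int) -> HomoeologueAssignment:
        return HomoeologueAssignment(group_a, None, support, conflicts, m1, m2, amb, "unresolved")

    if links[b1] and links[b2]:
        # SL-HS markers from one homoeologue split across both sister
        # groups of the other population: the hard mismatch case
        return unresolved(max(links[b1], links[b2]), min(links[b1], links[b2]))

    if links[b1] or links[b2]:
        chosen = b1 if links[b1] else b2
        support = links[chosen]
        net_other = (m2 - m1) if chosen == b1 else (m1 - m2)
        if net_other > 0:
            # allele-size evidence strictly favours the other pairing
            return unresolved(support, 0)
    else:
        if m1 == m2:
            return unresolved(0, 0)
        chosen = b1 if m1 > m2 else b2
        support = 0

    matches, mismatches = (m1, m2) if chosen == b1 else (m2, m1)
    status = "accepted_single_slhs" if support == 1 else "accepted"
    return HomoeologueAssignment(
        group_a, (group_a, chosen), support, 0, matches, mismatches, amb, status
    )


def support_table(assignments: Iterable[HomoeologueAssignment]) -> pd.DataFrame:
    """Tabulate per-group pairing evidence counts.

    Columns mirror the published integration-evidence layout: SL-HS
    match/mismatch counts and allele-size match/mismatch/ambiguous counts,
    plus the matched group and decision status.
    """
    rows = []
    for a in assignments:
        rows.append(
            (
                a.group_id,
                a.pairing[1] if a.pairing else None,
                a.slhs_support,
                a.slhs_conflicts,
                a.size_matches,
                a.size_mismatches,
                a.size_ambiguous,
                a.status,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "matched_group", "slhs_match", "slhs_mismatch",
            "size_match", "size_mismatch", "size_ambiguous", "status",
        ],
    ).set_index("group")


def summarize_support(counts: pd.DataFrame) -> dict:
    """Summary statistics over a per-group evidence-count table.

    Expects columns ``slhs_match``, ``slhs_mismatch``, ``size_match``,
    ``size_mismatch``, ``size_ambiguous`` (as produced by
    :func:`support_table` or loaded from
    :func:`clovermap.datasets.load_integration_evidence`).

    Returns ``mean_joining_loci`` (mean of the summed evidence columns per
    group, i.e. joining loci contributing evidence) and
    ``n_groups_multi_slhs`` (groups supported by at least two SL-HS loci).
    """
    cols = ["slhs_match", "slhs_mismatch", "size_match", "size_mismatch", "size_ambiguous"]
    totals = counts[cols].sum(axis=1)
    return {
        "mean_joining_loci": float(totals.mean()),
        "n_groups_multi_slhs": int((counts["slhs_match"] >= 2).sum()),
        "n_groups": int(len(counts)),
    }
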