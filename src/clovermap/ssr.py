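"""Microsatellite (SSR) mining from nucleotide sequence.

Detects perfect tandem repeats of di- to hexanucleotide motifs with
class-specific minimum repeat counts (default: at least six repeats for
dinucleotide motifs, at least five for longer motifs), summarizes motif
composition, screens whether an array's flanks could host PCR primers with
an amplicon in the desired size window, and predicts amplicons for exact
primer matches (in-silico PCR) to flag redundant marker candidates.

Coordinates are 0-based, half-open throughout.  Arrays are reported at
their shortest-period representation: a motif that is itself a repetition
of a shorter motif (e.g. ``ATAT``) is reported once under the shorter
motif.  ``N`` (or any non-ACGT character) breaks an array.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "SSRArray",
    "PrimerFeasibility",
    "DEFAULT_THRESHOLDS",
    "CLASS_NAMES",
    "find_ssr_arrays",
    "canonical_motif",
    "motif_summary",
    "primer_feasibility",
    "in_silico_pcr",
    "find_redundant_pairs",
    "quality_filter",
]

CLASS_NAMES = {2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}

#: minimum repeat count per motif length
DEFAULT_THRESHOLDS = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class SSRArray:
    """A maximal perfect tandem repeat found in a source sequence."""

    sequence_id: str
    start: int
    end: int
    motif: str
    canonical_motif: str
    motif_class: str
    repeat_count: int

    def __post_init__(self) -> None:
        if self.end - self.start != self.repeat_count * len(self.motif):
            raise ValueError("array span must equal repeat_count x motif length")


@dataclass(frozen=True)
class PrimerFeasibility:
    """Whether an SSR array's context permits primer design.

    ``passes`` requires both flanks to host a full-length primer (27 nt)
    and some amplicon spanning the array to fit the configured size window.
    Melting temperature is deliberately not evaluated.
    """

    array_id: str
    left_flank_ok: bool
    right_flank_ok: bool
    candidate_amplicon_length: int | None
    passes: bool


def _is_primitive(motif: str) -> bool:
    """True if the motif is not a whole-number repetition of a shorter motif."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def find_ssr_arrays(
    sequence: str,
    sequence_id: str = "seq",
    thresholds: Mapping[int, int] | None = None,
) -> list[SSRArray]:
    """All maximal perfect SSR arrays meeting class thresholds, left to right.

    Parameters
    ----------
    sequence : str
        Nucleotide sequence over ``{A, C, G, T, N}`` (case-insensitive).
        ``N`` and any other non-ACGT character terminate arrays.
    sequence_id : str
        Identifier attached to reported arrays.
    thresholds : mapping, optional
        Minimum repeat count keyed by motif length (2–6); defaults to
        di >= 6 and >= 5 for the other classes.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    s = sequence.upper()
    if any(c not in _ACGT and c != "N" for c in s):
        bad = sorted({c for c in s if c not in _ACGT and c != "N"})
        raise ValueError(f"sequence contains non-nucleotide characters: {bad}")
    n = len(s)
    found: list[SSRArray] = []
    for period in range(2, 7):
        thr = thresholds.get(period, DEFAULT_THRESHOLDS[period])
        j = period
        while j < n:
            # extend a maximal run of positions satisfying s[j] == s[j - period]
            if s[j] == s[j - period] and s[j] in _ACGT and s[j - period] in _ACGT:
                run_start = j
                while (
                    j < n
                    and s[j] == s[j - period]
                    and s[j] in _ACGT
                ):
                    j += 1
                start = run_start - period
                total = j - start
                count = total // period
                motif = s[start : start + period]
                if count >= thr and _is_primitive(motif) and _ACGT.issuperset(motif):
                    found.append(
                        SSRArray(
                            sequence_id=sequence_id,
                            start=start,
                            end=start + count * period,
                            motif=motif,
                            canonical_motif=canonical_motif(motif),
                            motif_class=CLASS_NAMES[period],
                            repeat_count=count,
                        )
                    )
            else:
                j += 1
    found.sort(key=lambda a: (a.start, a.end, len(a.motif)))
    return found


def canonical_motif(motif: str) -> str:
    """Normalized motif: smallest rotation of the motif or its reverse complement.

    Aggregating "all permutations" of a repeat motif requires a canonical
    representative — e.g. ``TA``, ``AT`` and their complements all reduce
    to ``AT``.
    """
    m = motif.upper()
    if not (2 <= len(m) <= 6) or not _ACGT.issuperset(m):
        raise ValueError(f"motif must be 2-6 nt over ACGT, got {motif!r}")
    rc = str(Seq(m).reverse_complement())
    candidates = [m[i:] + m[:i] for i in range(len(m))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def motif_summary(arrays: Iterable[SSRArray]) -> dict:
    """Per-class array counts and a repeat-count histogram.

    Returns a dict with ``class_counts`` (di/tri/tetra/penta/hexa -> count),
    ``repeat_histogram`` (repeat count -> number of arrays) and ``total``.
    """
    class_counts = {name: 0 for name in CLASS_NAMES.values()}
    hist: dict[int, int] = {}
    total = 0
    for arr in arrays:
        class_counts[arr.motif_class] += 1
        hist[arr.repeat_count] = hist.get(arr.repeat_count, 0) + 1
        total += 1
    return {"class_counts": class_counts, "repeat_histogram": dict(sorted(hist.items())), "total": total}


def primer_feasibility(
    array: SSRArray,
    sequence: str,
    min_primer: int = 20,
    max_primer: int = 27,
    amplicon_range: tuple[int, int] = (95, 395),
) -> PrimerFeasibility:
    """Screen whether an array's flanks could host primers with a valid amplicon.

    A design is feasible when each flank offers at least ``max_primer``
    bases and an amplicon containing the array plus two minimal primers
    fits within ``amplicon_range`` and within the available sequence.
    """
    n = len(sequence)
    if array.start < 0 or array.end > n:
        raise ValueError("array lies outside the sequence")
    left = array.start
    right = n - array.end
    left_ok = left >= max_primer
    right_ok = right >= max_primer
    arr_len = array.end - array.start
    lo = max(amplicon_range[0], arr_len + 2 * min_primer)
    hi = min(amplicon_range[1], arr_len + left + right)
    feasible = left_ok and right_ok and lo <= hi
    return PrimerFeasibility(
        array_id=f"{array.sequence_id}:{array.start}-{array.end}",
        left_flank_ok=left_ok,
        right_flank_ok=right_ok,
        candidate_amplicon_length=lo if feasible else None,
        passes=feasible,
    )


def _occurrences(pattern: str, text: str) -> list[int]:
    out = []
    i = text.find(pattern)
    while i != -1:
        out.append(i)
        i = text.find(pattern, i + 1)
    return out


def in_silico_pcr(
    forward: str,
    reverse: str,
    database: Mapping[str, str],
    max_length: int = 5000,
) -> list[tuple[str, int, int, int]]:
    """Predicted amplicons for an exact-match primer pair over a sequence set.

    Primers bind with zero mismatches on opposite strands in convergent
    orientation; the product interval spans from the 5' end of the
    plus-strand primer to the 3' end of the minus-strand primer
    (0-based half-open), so product length includes both primers.
    Both orientations are enumerated and duplicates removed.

    Returns a sorted list of ``(sequence_id, start, end, length)``.
    """
    f = forward.upper()
    r = reverse.upper()
    products: set[tuple[str, int, int]] = set()
    for seq_id, seq in database.items():
        s = seq.upper()
        # orientation 1: forward on + strand, reverse on - strand
        # orientation 2: reverse on + strand, forward on - strand
        for plus, minus in ((f, r), (r, f)):
            minus_rc = str(Seq(minus).reverse_complement())
            plus_hits = _occurrences(plus, s)
            minus_hits = _occurrences(minus_rc, s)
            for i in plus_hits:
                for j in minus_hits:
                    end = j + len(minus_rc)
                    if end > i + len(plus) and end - i <= max_length:
                        products.add((seq_id, i, end))
    return sorted((sid, a, b, b - a) for sid, a, b in products)


def find_redundant_pairs(
    amplicons_by_pair: Mapping[str, Sequence[tuple[str, int, int, int]]],
) -> list[tuple[str, str]]:
    """Flag primer-pair redundancy: two pairs amplifying an identical interval."""
    seen: dict[tuple[str, int, int], str] = {}
    redundant: list[tuple[str, str]] = []
    for pair_id in sorted(amplicons_by_pair):
        for sid, a, b, _ in amplicons_by_pair[pair_id]:
            key = (sid, a, b)
            if key in seen and seen[key] != pair_id:
                redundant.append((seen[key], pair_id))
            else:
                seen.setdefault(key, pair_id)
    return sorted(set(redundant))


def quality_filter(qualities: Sequence[float], threshold: float = 50.0) -> bool:
    """Pass a sequence iff its mean per-base quality reaches the threshold."""
    if qualities is None or len(qualities) == 0:
        raise ValueError("quality filtering requested but no quality values present")
    return float(pd.Series(qualities).mean()) >= threshold


def arrays_to_frame(arrays: Iterable[SSRArray]) -> pd.DataFrame:
    """Tabulate arrays as a DataFrame matching the delimited output format."""
    rows = [
        (a.sequence_id, a.start, a.end, a.motif, a.canonical_motif, a.motif_class, a.repeat_count)
        for a in arrays
    ]
    return pd.DataFrame(
        rows,
        columns=["sequence_id", "start", "end", "motif", "canonical_motif", "class", "repeats"],
    )
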