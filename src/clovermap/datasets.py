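"""Published white clover map summaries bundled as reference inputs.

The integrated white clover map (IM) was built from two unrelated F1
mapping populations: MP2 (n=184, GeneThresher-derived genomic SSRs) and MP1
(n=92, EST-SSRs).  The raw genotype matrices behind those maps were never
deposited, but the per-linkage-group summary statistics and the
homoeologue-matching evidence counts were published, and they are
sufficient inputs for the genome-length, coverage, saturation and
integration-support computations in this package.

Two loaders are provided:

- :func:`load_map_summary` — per-group locus counts and observed Kosambi
  map lengths for IM, MP2 and MP1, plus the published expected-length
  totals;
- :func:`load_integration_evidence` — per-group counts of single-locus
  homoeologue-specific (SL-HS) joining-marker matches/mismatches and
  allele-size matches/mismatches/ambiguous calls used to pair homoeologues
  between the two populations.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_map_summary", "load_integration_evidence", "MP1_EXPECTED_TOTAL"]

_GROUPS = [
    "1-1", "1-2", "2-1", "2-2", "3-1", "3-2", "4-1", "4-2",
    "5-1", "5-2", "6-1", "6-2", "7-1", "7-2", "8-1", "8-2",
]

# columns: loci (IM, MP2, MP1) then observed length cM (IM, MP2, MP1)
_MAP_SUMMARY = [
    (66, 44, 31, 86.7, 84.9, 91.0),
    (87, 70, 27, 92.8, 93.1, 72.0),
    (42, 24, 22, 70.2, 63.2, 72.0),
    (48, 38, 18, 71.4, 70.9, 76.0),
    (77, 47, 35, 89.4, 92.4, 76.0),
    (85, 53, 38, 88.1, 87.8, 77.0),
    (98, 59, 52, 82.5, 76.9, 82.0),
    (78, 52, 47, 80.0, 76.7, 94.0),
    (60, 50, 26, 76.3, 62.3, 77.0),
    (63, 46, 14, 72.7, 65.4, 28.0),
    (57, 41, 22, 70.1, 68.5, 69.0),
    (44, 22, 23, 66.5, 70.3, 60.0),
    (70, 41, 38, 88.3, 94.8, 69.0),
    (62, 47, 20, 72.9, 76.6, 62.0),
    (95, 59, 41, 86.2, 93.8, 70.0),
    (77, 40, 39, 79.6, 87.2, 69.0),
]

#: Published expected (Method-4) genome-length total for MP1, cM.  MP1's
#: per-group expected column is not reproducible from its printed observed
#: lengths, so only this total is carried.
MP1_EXPECTED_TOTAL = 1220.7

# per-group joining-locus evidence:
# SL-HS match, SL-HS mismatch, size match, size mismatch, size ambiguous
_INTEGRATION_EVIDENCE = [
    (3, 0, 2, 0, 2),
    (4, 0, 3, 2, 2),
    (1, 0, 1, 0, 3),
    (2, 0, 5, 0, 4),
    (3, 0, 3, 0, 1),
    (2, 0, 1, 0, 0),
    (2, 0, 4, 0, 2),
    (1, 0, 7, 0, 2),
    (1, 0, 7, 2, 5),
    (0, 0, 2, 0, 3),
    (2, 0, 2, 2, 3),
    (0, 0, 2, 1, 0),
    (2, 0, 3, 1, 2),
    (1, 0, 3, 0, 4),
    (4, 0, 2, 0, 1),
    (2, 0, 0, 0, 2),
]


def load_map_summary() -> pd.DataFrame:
    """Per-linkage-group locus counts and observed map lengths.

    Returns a DataFrame indexed by linkage group ("1-1" … "8-2") with
    columns ``loci_im``, ``loci_mp2``, ``loci_mp1`` (marker locus counts)
    and ``length_im``, ``length_mp2``, ``length_mp1`` (observed Kosambi map
    lengths, cM).
    """
    df = pd.DataFrame(
        _MAP_SUMMARY,
        index=pd.Index(_GROUPS, name="group"),
        columns=[
            "loci_im", "loci_mp2", "loci_mp1",
            "length_im", "length_mp2", "length_mp1",
        ],
    )
    return df


def load_integration_evidence() -> pd.DataFrame:
    """Per-group homoeologue-matching evidence counts.

    Columns: ``slhs_match``, ``slhs_mismatch`` (single-locus
    homoeologue-specific joining markers agreeing/conflicting with the
    accepted pairing) and ``size_match``, ``size_mismatch``,
    ``size_ambiguous`` (allele-size evidence classes).
    """
    return pd.DataFrame(
        _INTEGRATION_EVIDENCE,
        index=pd.Index(_GROUPS, name="group"),
        columns=["slhs_match", "slhs_mismatch", "size_match", "size_mismatch", "size_ambiguous"],
    )
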