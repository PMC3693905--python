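"""Delimited file formats for genotype tables, map tables and truth labels.

Genotype table (tab-delimited, one row per marker locus)::

    locus  seg_type  parent1  parent2  ind1  ind2  ...

Parental genotypes are slash-joined allele sizes in bp with ``0`` for a
null allele (e.g. ``120/0``).  Progeny calls list the distinct visible
allele sizes (``120/124``), ``0`` for no amplification (all transmitted
alleles null) and ``-`` for a missing genotype.

Map table: ``locus  group  position`` (cM).  Truth table (from the
simulator): ``locus  marker  group  homoeologue  position  seg_type
joining  population``.

A reader for JoinMap-style CP ``.loc`` segregation coding (``<abxcd>``,
``<efxeg>``, ``<hkxhk>``, ``<lmxll>``, ``<nnxnp>``) is provided for
interoperability; symbolic alleles are mapped to surrogate integer sizes.
"""

from __future__ import annotations

from typing import Mapping, Sequence, TextIO

import pandas as pd

__all__ = [
    "write_genotype_table",
    "read_genotype_table",
    "write_map_table",
    "read_map_table",
    "write_truth_table",
    "read_joinmap_loc",
]


def _fmt_genotype(g: tuple[int, int]) -> str:
    return f"{g[0]}/{g[1]}"


def _fmt_call(call: "tuple[int, ...] | None") -> str:
    if call is None:
        return "-"
    if len(call) == 0:
        return "0"
    return "/".join(str(s) for s in call)


def write_genotype_table(
    fh: TextIO,
    parents: Mapping[str, tuple[tuple[int, int], tuple[int, int]]],
    calls: Mapping[str, Sequence["tuple[int, ...] | None"]],
    seg_types: Mapping[str, str],
) -> None:
    n = len(next(iter(calls.values())))
    header = ["locus", "seg_type", "parent1", "parent2"] + [f"ind{i+1}" for i in range(n)]
    fh.write("\t".join(header) + "\n")
    for locus in calls:
        p1, p2 = parents[locus]
        row = [locus, seg_types.get(locus, "?"), _fmt_genotype(p1), _fmt_genotype(p2)]
        row += [_fmt_call(c) for c in calls[locus]]
        fh.write("\t".join(row) + "\n")


def _parse_call(token: str) -> "tuple[int, ...] | None":
    token = token.strip()
    if token in ("-", ""):
        return None
    if token == "0":
        return ()
    return tuple(sorted(int(t) for t in token.split("/")))


def read_genotype_table(
    fh: TextIO,
) -> tuple[dict, dict, dict]:
    """Returns ``(parents, calls, seg_types)`` keyed by locus."""
    header = fh.readline().rstrip("\n").split("\t")
    n = len(header) - 4
    parents: dict = {}
    calls: dict = {}
    seg: dict = {}
    for line in fh:
        parts = line.rstrip("\n").split("\t")
        if len(parts) != n + 4:
            raise ValueError(f"genotype row for {parts[0]!r} has {len(parts)} fields, expected {n + 4}")
        locus = parts[0]
        seg[locus] = parts[1]
        p1 = tuple(int(x) for x in parts[2].split("/"))
        p2 = tuple(int(x) for x in parts[3].split("/"))
        parents[locus] = (p1, p2)
        calls[locus] = [_parse_call(t) for t in parts[4:]]
    return parents, calls, seg


def write_map_table(fh: TextIO, groups: Mapping[str, pd.DataFrame]) -> None:
    fh.write("locus\tgroup\tposition\n")
    for name, df in groups.items():
        for _, row in df.iterrows():
            fh.write(f"{row['locus']}\t{name}\t{row['position']:.3f}\n")


def read_map_table(fh: TextIO) -> pd.DataFrame:
    df = pd.read_csv(fh, sep="\t", dtype={"locus": str, "group": str})
    expected = {"locus", "group", "position"}
    if not expected.issubset(df.columns):
        raise ValueError(f"map table must have columns {sorted(expected)}")
    return df


def write_truth_table(fh: TextIO, truth: pd.DataFrame) -> None:
    truth.reset_index().to_csv(fh, sep="\t", index=False)


# JoinMap CP coding: per segregation type, genotype code -> allele pair
# (symbolic).  Surrogate sizes are assigned per distinct symbol.
_LOC_SYMBOLS = {"a": 1, "b": 2, "c": 3, "d": 4, "e": 1, "f": 2, "g": 3,
                "h": 1, "k": 2, "l": 1, "m": 2, "n": 1, "p": 2}

_LOC_PARENTS = {
    "<abxcd>": (("a", "b"), ("c", "d")),
    "<efxeg>": (("e", "f"), ("e", "g")),
    "<hkxhk>": (("h", "k"), ("h", "k")),
    "<lmxll>": (("l", "m"), ("l", "l")),
    "<nnxnp>": (("n", "n"), ("n", "p")),
}


def read_joinmap_loc(fh: TextIO, size_base: int = 100, size_step: int = 2) -> tuple[dict, dict, dict]:
    """Read a JoinMap CP ``.loc``-style file.

    Each data line is ``name <type> code code code ...`` where codes are
    two-letter genotype classes (``--`` missing).  Symbolic alleles become
    surrogate sizes ``size_base + size_step * symbol_rank`` so downstream
    analysis treats them like measured amplicon sizes.  Shared symbols
    across the two parents (e.g. the ``e`` of ``<efxeg>``) share one size.

    Returns ``(parents, calls, seg_types)`` in the genotype-table
    convention.
    """
    parents: dict = {}
    calls: dict = {}
    seg: dict = {}
    for line in fh:
        line = line.strip()
        if not line or line.startswith((";", "#")) or "=" in line:
            continue
        parts = line.split()
        if len(parts) < 3 or not parts[1].startswith("<"):
            continue
        name, seg_code, *codes = parts
        if seg_code not in _LOC_PARENTS:
            raise ValueError(f"unsupported CP segregation code {seg_code!r} for {name!r}")
        sym1, sym2 = _LOC_PARENTS[seg_code]

        def size(sym: str) -> int:
            return size_base + size_step * _LOC_SYMBOLS[sym]

        p1 = (size(sym1[0]), size(sym1[1]))
        p2 = (size(sym2[0]), size(sym2[1]))
        row: list = []
        for code in codes:
            if code in ("--", "-", "."):
                row.append(None)
            else:
                row.append(tuple(sorted({size(ch) for ch in code})))
        parents[name] = (p1, p2)
        calls[name] = row
        seg[name] = seg_code
    return parents, calls, seg
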