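"""Synthetic allotetraploid F1 mapping populations with truth labels.

White clover is a strict disomic allotetraploid: each of the 8 homoeologous
chromosome pairs behaves as two independent diploid chromosomes at meiosis
(homoeologues never pair).  The generator emulates the study design used
for SSR-based map integration:

- two unrelated outbred F1 ("CP-type") populations produced by crossing
  highly heterozygous parents, default sizes 92 and 184;
- SSR markers that amplify one homoeolocus or (with configurable
  probability) both homoeoloci of a pair, with homoeologue-specific
  allele-size ranges separated by a configurable base-pair offset;
- null (non-amplifying) alleles and missing genotype calls;
- a subset of "joining" markers genotyped in both populations;
- a diversity panel of unrelated genotypes (default 16) for single-locus
  homoeologue-specific (SL-HS) marker designation;
- localized segregation distortion implemented as gametic viability
  weights with rejection sampling, so the distortion signal decays with
  map distance from the selected locus.

Meiosis places crossovers by a Poisson process with expectation
(length cM)/100 per chromosome and no interference, giving an exact
Haldane closed form for expected recombinant fractions.  Every quantity is
a deterministic function of the configuration (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from clovermap.linkage import classify_segregation, UninformativeLocusError

__all__ = [
    "SimConfig",
    "DistortionLocus",
    "Parent",
    "TruePopulation",
    "Study",
    "build_markers",
    "build_parents",
    "simulate_gamete",
    "simulate_population",
    "build_panel",
    "simulate_study",
    "InfeasibleDistortionError",
]


class InfeasibleDistortionError(RuntimeError):
    """Rejection sampling could not produce a gamete under the viability weights."""


@dataclass(frozen=True)
class DistortionLocus:
    """Gametic viability selection acting at one map position.

    ``parent`` selects whose gametes are under selection (0 = maternal,
    1 = paternal); ``weights`` are the relative viabilities of gametes
    carrying the parent's phase-0 vs phase-1 allele at the marker nearest
    ``position`` on chromosome (``group``, ``homoeologue``).
    """

    group: int
    homoeologue: int
    position: float
    parent: int = 0
    weights: tuple[float, float] = (1.0, 0.25)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic allotetraploid cross."""

    n_chromosome_pairs: int = 8
    chromosome_length: float = 80.0  # cM per homoeologue
    markers_per_group: int = 20
    population_sizes: tuple[int, int] = (92, 184)
    joining_marker_fraction: float = 0.3
    dual_homoeolocus_probability: float = 0.25
    allele_size_base: int = 100
    homoeologue_size_offset: int = 30
    allele_size_spread: int = 10
    allele_step: int = 2
    null_allele_probability: float = 0.05
    missing_data_rate: float = 0.02
    distortion_loci: tuple[DistortionLocus, ...] = ()
    panel_size: int = 16
    force_heterozygosity: bool = False
    rng_seed: int = 0
    max_rejection_attempts: int = 10_000

    def validate(self) -> None:
        for name in (
            "joining_marker_fraction",
            "dual_homoeolocus_probability",
            "null_allele_probability",
            "missing_data_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.chromosome_length < 0:
            raise ValueError("chromosome length must be >= 0")
        if any(n < 2 for n in self.population_sizes):
            raise ValueError("population sizes must be >= 2")
        if self.n_chromosome_pairs < 1 or self.markers_per_group < 1:
            raise ValueError("need at least one chromosome pair and one marker per group")
        if self.panel_size < 0:
            raise ValueError("panel size must be >= 0")
        for d in self.distortion_loci:
            if d.parent not in (0, 1):
                raise ValueError("distortion parent must be 0 (maternal) or 1 (paternal)")
            if min(d.weights) < 0 or max(d.weights) <= 0:
                raise ValueError("viability weights must be non-negative with a positive maximum")


# ---------------------------------------------------------------------------
# marker scaffold


@dataclass(frozen=True)
class MarkerDef:
    """A simulated SSR marker and the homoeoloci it amplifies."""

    marker: str
    group: int          # homoeologous pair, 1-based
    homoeologue: int    # primary homoeolocus, 1 or 2
    position: float     # cM, identical for both homoeoloci of a dual marker
    dual: bool
    joining: bool
    population: int | None  # None for joining markers, else 0 or 1

    def loci(self) -> list[tuple[str, int]]:
        """(locus_id, homoeologue) for every amplified homoeolocus."""
        out = [(f"{self.marker}a", self.homoeologue)]
        if self.dual:
            out.append((f"{self.marker}b", 3 - self.homoeologue))
        return out


def build_markers(config: SimConfig, rng: np.random.Generator) -> list[MarkerDef]:
    """Lay markers evenly along every linkage group and draw their roles."""
    markers: list[MarkerDef] = []
    idx = 0
    m = config.markers_per_group
    positions = (
        np.linspace(0.0, config.chromosome_length, m)
        if m > 1
        else np.array([config.chromosome_length / 2.0])
    )
    for g in range(1, config.n_chromosome_pairs + 1):
        for h in (1, 2):
            for pos in positions:
                idx += 1
                dual = bool(rng.random() < config.dual_homoeolocus_probability)
                joining = bool(rng.random() < config.joining_marker_fraction)
                population = None if joining else int(rng.integers(0, 2))
                markers.append(
                    MarkerDef(
                        marker=f"gtrs{idx:04d}",
                        group=g,
                        homoeologue=h,
                        position=float(pos),
                        dual=dual,
                        joining=joining,
                        population=population,
                    )
                )
    return markers


def allele_pool(config: SimConfig, homoeologue: int) -> np.ndarray:
    """Allele sizes (bp) available at a homoeolocus.

    Homoeologue 2 sizes are shifted by ``homoeologue_size_offset`` so the
    two ranges are disjoint when the offset exceeds the spread, and overlap
    (deliberately ambiguous) otherwise.
    """
    lo = config.allele_size_base + (homoeologue - 1) * config.homoeologue_size_offset
    return np.arange(lo, lo + config.allele_size_spread + 1, config.allele_step)


# ---------------------------------------------------------------------------
# parents


@dataclass
class Parent:
    """A phased multilocus parental genotype.

    ``alleles`` maps locus_id -> (size_phase0, size_phase1); size 0 encodes
    a null (non-amplifying) allele.  ``chromosomes`` maps (group,
    homoeologue) -> ordered (locus_ids, positions) so gametes can be drawn
    chromosome by chromosome.
    """

    name: str
    alleles: dict[str, tuple[int, int]]
    chromosomes: dict[tuple[int, int], tuple[list[str], np.ndarray]]
    chromosome_length: float


def _chromosome_layout(
    markers: Sequence[MarkerDef],
) -> dict[tuple[int, int], tuple[list[str], np.ndarray]]:
    per_chrom: dict[tuple[int, int], list[tuple[float, str]]] = {}
    for mk in markers:
        for locus_id, h in mk.loci():
            per_chrom.setdefault((mk.group, h), []).append((mk.position, locus_id))
    layout = {}
    for chrom, items in per_chrom.items():
        items.sort()
        layout[chrom] = ([lid for _, lid in items], np.array([p for p, _ in items]))
    return layout


def _draw_parent(
    name: str,
    config: SimConfig,
    markers: Sequence[MarkerDef],
    rng: np.random.Generator,
) -> Parent:
    layout = _chromosome_layout(markers)
    homoeologue_of = {
        lid: h for mk in markers for lid, h in mk.loci()
    }
    alleles: dict[str, tuple[int, int]] = {}
    for (g, h), (locus_ids, _) in sorted(layout.items()):
        pool = allele_pool(config, h)
        for lid in locus_ids:
            if config.force_heterozygosity:
                pair = rng.choice(pool, size=2, replace=False)
            else:
                pair = rng.choice(pool, size=2, replace=True)
            a, b = int(pair[0]), int(pair[1])
            if config.null_allele_probability > 0:
                if rng.random() < config.null_allele_probability:
                    a = 0
                if rng.random() < config.null_allele_probability:
                    b = 0
            alleles[lid] = (a, b)
    del homoeologue_of
    return Parent(
        name=name,
        alleles=alleles,
        chromosomes=layout,
        chromosome_length=config.chromosome_length,
    )


def build_parents(
    config: SimConfig,
    markers: Sequence[MarkerDef] | None = None,
    rng: np.random.Generator | None = None,
    names: tuple[str, str] = ("P1", "P2"),
) -> tuple[Parent, Parent]:
    """Draw a pair of phased, highly heterozygous parents."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if markers is None:
        markers = build_markers(config, rng)
    return (
        _draw_parent(names[0], config, markers, rng),
        _draw_parent(names[1], config, markers, rng),
    )


# ---------------------------------------------------------------------------
# meiosis


def simulate_gamete(
    parent: Parent, rng: np.random.Generator
) -> dict[tuple[int, int], np.ndarray]:
    """One gamete: a phase vector (0/1) per chromosome.

    Crossovers follow a Poisson process with expectation length/100 per
    chromosome (Haldane model, no interference); homoeologues assort
    independently and never exchange (strict disomy).
    """
    gamete = {}
    length = parent.chromosome_length
    for chrom, (locus_ids, positions) in parent.chromosomes.items():
        start = int(rng.integers(0, 2))
        n_xo = rng.poisson(length / 100.0) if length > 0 else 0
        if n_xo:
            xo = np.sort(rng.uniform(0.0, length, size=n_xo))
            crossings = np.searchsorted(xo, positions, side="right")
            phase = (start + crossings) % 2
        else:
            phase = np.full(len(locus_ids), start)
        gamete[chrom] = phase.astype(np.int8)
    return gamete


def _gamete_accepted(
    gamete: Mapping[tuple[int, int], np.ndarray],
    parent: Parent,
    loci: Sequence[DistortionLocus],
    rng: np.random.Generator,
) -> bool:
    for d in loci:
        chrom = (d.group, d.homoeologue)
        if chrom not in parent.chromosomes:
            continue
        locus_ids, positions = parent.chromosomes[chrom]
        nearest = int(np.argmin(np.abs(positions - d.position)))
        phase = int(gamete[chrom][nearest])
        w = d.weights[phase] / max(d.weights)
        if rng.random() >= w:
            return False
    return True


def _draw_viable_gamete(
    parent: Parent,
    loci: Sequence[DistortionLocus],
    rng: np.random.Generator,
    max_attempts: int,
) -> dict[tuple[int, int], np.ndarray]:
    for _ in range(max_attempts):
        g = simulate_gamete(parent, rng)
        if not loci or _gamete_accepted(g, parent, loci, rng):
            return g
    raise InfeasibleDistortionError(
        f"no viable gamete from {parent.name} within {max_attempts} attempts; "
        "viability weights may be infeasible"
    )


# ---------------------------------------------------------------------------
# populations


@dataclass
class TruePopulation:
    """A simulated F1 population with observed calls and truth labels.

    ``calls`` maps locus_id -> list (length n) of observed allele-size
    tuples; ``()`` means no amplification (all transmitted alleles null)
    and ``None`` means a missing genotype.  ``truth`` is a DataFrame
    indexed by locus_id with columns marker, group, homoeologue, position,
    seg_type, joining and single_locus.
    """

    name: str
    config: SimConfig
    parents: tuple[Parent, Parent]
    calls: dict[str, list[tuple[int, ...] | None]]
    truth: pd.DataFrame
    maternal_phase: dict[tuple[int, int], np.ndarray]
    paternal_phase: dict[tuple[int, int], np.ndarray]

    @property
    def n(self) -> int:
        return len(next(iter(self.calls.values())))

    def locus_parent_genotypes(self, locus_id: str) -> tuple[tuple[int, int], tuple[int, int]]:
        return self.parents[0].alleles[locus_id], self.parents[1].alleles[locus_id]


def _truth_frame(config: SimConfig, markers: Sequence[MarkerDef],
                 parents: tuple[Parent, Parent]) -> pd.DataFrame:
    rows = []
    for mk in markers:
        for lid, h in mk.loci():
            try:
                seg, _ = classify_segregation(parents[0].alleles[lid], parents[1].alleles[lid])
            except UninformativeLocusError:
                seg = "uninformative"
            rows.append(
                (lid, mk.marker, mk.group, h, mk.position, seg, mk.joining, not mk.dual, mk.population)
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "locus", "marker", "group", "homoeologue", "position",
            "seg_type", "joining", "single_locus", "population",
        ],
    ).set_index("locus")
    return df


def simulate_population(
    config: SimConfig,
    population_index: int = 0,
    markers: Sequence[MarkerDef] | None = None,
    parents: tuple[Parent, Parent] | None = None,
    rng: np.random.Generator | None = None,
    name: str | None = None,
) -> TruePopulation:
    """Simulate one F1 population (maternal + paternal gamete per progeny)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + population_index)
    if markers is None:
        markers = build_markers(config, rng)
    if parents is None:
        parents = build_parents(config, markers=markers, rng=rng)
    n = config.population_sizes[population_index]
    mother, father = parents

    # keep only markers typed in this population
    own = [mk for mk in markers if mk.joining or mk.population == population_index]

    d_mat = [d for d in config.distortion_loci if d.parent == 0]
    d_pat = [d for d in config.distortion_loci if d.parent == 1]

    mat_gametes = [
        _draw_viable_gamete(mother, d_mat, rng, config.max_rejection_attempts)
        for _ in range(n)
    ]
    pat_gametes = [
        _draw_viable_gamete(father, d_pat, rng, config.max_rejection_attempts)
        for _ in range(n)
    ]

    # per-chromosome phase matrices (n_loci x n) for parameter-recovery checks
    mat_phase = {
        chrom: np.stack([g[chrom] for g in mat_gametes], axis=1)
        for chrom in mother.chromosomes
    }
    pat_phase = {
        chrom: np.stack([g[chrom] for g in pat_gametes], axis=1)
        for chrom in father.chromosomes
    }

    locus_index: dict[str, tuple[tuple[int, int], int]] = {}
    for chrom, (locus_ids, _) in mother.chromosomes.items():
        for k, lid in enumerate(locus_ids):
            locus_index[lid] = (chrom, k)

    calls: dict[str, list[tuple[int, ...] | None]] = {}
    for mk in own:
        missing = rng.random(n) < config.missing_data_rate
        for lid, _h in mk.loci():
            chrom, k = locus_index[lid]
            ma, mb = mother.alleles[lid]
            fa, fb = father.alleles[lid]
            mat_allele = np.where(mat_phase[chrom][k] == 0, ma, mb)
            pat_allele = np.where(pat_phase[chrom][k] == 0, fa, fb)
            col: list[tuple[int, ...] | None] = []
            for i in range(n):
                if missing[i]:
                    col.append(None)
                else:
                    visible = {int(mat_allele[i]), int(pat_allele[i])} - {0}
                    col.append(tuple(sorted(visible)))
            calls[lid] = col

    truth = _truth_frame(config, markers, parents)
    own_loci = [lid for mk in own for lid, _ in mk.loci()]
    return TruePopulation(
        name=name or f"MP{population_index + 1}",
        config=config,
        parents=parents,
        calls=calls,
        truth=truth.loc[own_loci],
        maternal_phase=mat_phase,
        paternal_phase=pat_phase,
    )


def build_panel(
    config: SimConfig,
    markers: Sequence[MarkerDef] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """A panel of unrelated genotypes for SL-HS designation.

    Each panel individual carries two alleles per homoeolocus drawn from
    the same allele-frequency model as the mapping parents, so a
    single-homoeolocus marker can never show more than two alleles while a
    dual-homoeolocus marker (with non-null alleles) can show up to four.

    Returns a DataFrame (marker x individual) of observed allele-size
    tuples — the union over the marker's amplified homoeoloci, nulls
    dropped.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1009)
    if markers is None:
        markers = build_markers(config, rng)
    cols = [f"panel{i + 1:02d}" for i in range(config.panel_size)]
    data: dict[str, list[tuple[int, ...]]] = {c: [] for c in cols}
    marker_ids = [mk.marker for mk in markers]
    for mk in markers:
        for i, c in enumerate(cols):
            sizes: set[int] = set()
            for _lid, h in mk.loci():
                pool = allele_pool(config, h)
                if config.force_heterozygosity:
                    pair = rng.choice(pool, size=2, replace=False)
                else:
                    pair = rng.choice(pool, size=2, replace=True)
                for a in pair:
                    if config.null_allele_probability > 0 and rng.random() < config.null_allele_probability:
                        continue
                    sizes.add(int(a))
            data[c].append(tuple(sorted(sizes)))
    return pd.DataFrame(data, index=pd.Index(marker_ids, name="marker"))


@dataclass
class Study:
    """A complete synthetic study: two populations sharing joining markers,
    a diversity panel, and the common marker scaffold."""

    config: SimConfig
    markers: list[MarkerDef]
    populations: tuple[TruePopulation, TruePopulation]
    panel: pd.DataFrame


def simulate_study(config: SimConfig) -> Study:
    """Simulate the full study design deterministically from the config seed.

    The two populations have independent (unrelated) parent pairs but share
    the marker scaffold, so joining markers are genotyped in both; the
    panel is drawn from the same allele-frequency model.
    """
    config.validate()
    root = np.random.default_rng(config.rng_seed)
    markers = build_markers(config, root)
    pops = []
    for p in range(2):
        rng = np.random.default_rng([config.rng_seed, p])
        parents = build_parents(
            config, markers=markers, rng=rng, names=(f"MP{p+1}-mother", f"MP{p+1}-father")
        )
        pops.append(
            simulate_population(
                config, population_index=p, markers=markers, parents=parents, rng=rng
            )
        )
    panel_rng = np.random.default_rng([config.rng_seed, 99])
    panel = build_panel(config, markers=markers, rng=panel_rng)
    return Study(config=config, markers=markers, populations=(pops[0], pops[1]), panel=panel)
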