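"""Forward simulation of a balancer-chromosome lethal screen.

The generator emulates the data-generating process the analysis assumes:
wild flies each carry two second chromosomes; lethal loss-of-function
mutations land on chromosomes as Poisson(``lambda_true``) draws and are
placed in genes (with configurable per-gene fragility, since transposable
elements show insertion-site preferences); one to three balanced sublines
are sampled per fly — male sublines carry one of the fly's two chromosomes
intact, female-derived sublines carry a single-crossover recombinant; a
panel of deficiency stocks with kit-scale sizes interrogates most of the
chromosome; cross outcomes follow Punnett-square logic with Poisson offspring
totals; and sequenced lines get variant tables containing their causal
mutations plus identity-by-descent and private background noise.

Every stage draws from its own seeded stream, so changing one stage's
parameters never perturbs another stage's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .complementation_mapping import CrossResult, DeficiencyPanel
from .variant_filtering import VariantRecord

__all__ = [
    "SimConfig",
    "Mutation",
    "WildChromosome",
    "Fly",
    "SublineRecord",
    "GeneCatalog",
    "PopulationSample",
    "simulate_population",
    "sample_sublines",
    "simulate_deficiency_panel",
    "simulate_cross",
    "simulate_screen_crosses",
    "simulate_allelism_crosses",
    "simulate_variant_tables",
    "simulate_read_depths",
    "simulate_screen",
    "stage_rng",
]

MUTATION_CLASSES = ("TE_insertion", "premature_stop", "deletion", "splice_site")
#: Mix of lethal mutation classes; TE insertions dominate the observed spectrum.
MUTATION_CLASS_WEIGHTS = (0.55, 0.18, 0.17, 0.10)

_STAGES = ("catalog", "population", "sublines", "panel", "crosses", "variants", "depths")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for one simulation stage."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES.index(stage),))
    return np.random.default_rng(ss)


@dataclass
class SimConfig:
    """Study conditions for one simulated screen.

    Defaults mirror the screen being emulated: a ~48 Mb second chromosome,
    a lethal-mutation mean of 0.639 per chromosome (the value implied by a
    47% lethal fraction), ~410 wild flies contributing mostly 1-2 sublines
    each (~555 sublines), 70 deficiencies of 160 kb - 1.6 Mb, and ~60 scored
    offspring per cross so the 35-curly scoring threshold is usually met.
    """

    chromosome_length: int = 48_000_000
    lambda_true: float = 0.639
    n_flies: int = 410
    female_fraction: float = 0.15
    sublines_per_fly_weights: tuple[float, ...] = (0.68, 0.29, 0.03)
    gene_catalog_size: int = 2000
    coding_fraction: float = 0.25
    gene_fragility_weights: np.ndarray | None = None  # None -> mild power law
    n_deficiencies: int = 70
    deficiency_size_range: tuple[int, int] = (160_000, 1_600_000)
    offspring_mean: float = 60.0
    miss_probability: float = 0.0
    ibd_fraction: float = 0.05
    collection_years: tuple[int, ...] = (2018, 2020, 2021)
    year_weights: tuple[float, ...] = (0.5, 0.2, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be > 0")
        if self.lambda_true < 0:
            raise ValueError("lambda_true must be >= 0")
        for name in ("female_fraction", "miss_probability", "ibd_fraction",
                     "coding_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("sublines_per_fly_weights", "year_weights"):
            w = np.asarray(getattr(self, name), dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError(f"{name} must be nonnegative with positive sum")
            setattr(self, name, tuple(w / w.sum()))
        if self.n_flies <= 0 or self.gene_catalog_size <= 0 or self.n_deficiencies <= 0:
            raise ValueError("n_flies, gene_catalog_size, n_deficiencies must be > 0")
        lo, hi = self.deficiency_size_range
        if not 0 < lo <= hi:
            raise ValueError("deficiency_size_range must satisfy 0 < lo <= hi")
        if hi > self.chromosome_length:
            raise ValueError("deficiency_size_range exceeds chromosome_length")
        if self.gene_fragility_weights is not None:
            w = np.asarray(self.gene_fragility_weights, dtype=float)
            if len(w) != self.gene_catalog_size or (w < 0).any() or w.sum() <= 0:
                raise ValueError(
                    "gene_fragility_weights must be nonnegative, sum > 0, and "
                    "of length gene_catalog_size"
                )
            self.gene_fragility_weights = w / w.sum()


@dataclass(frozen=True)
class Mutation:
    position: int
    gene_id: int
    mutation_class: str


@dataclass(frozen=True)
class WildChromosome:
    chrom_id: str
    lethal_mutations: tuple[Mutation, ...]
    ibd_group: str | None = None

    @property
    def lethal(self) -> bool:
        return len(self.lethal_mutations) > 0

    def genes_hit(self) -> frozenset:
        return frozenset(m.gene_id for m in self.lethal_mutations)


@dataclass(frozen=True)
class Fly:
    fly_id: str
    sex: str  # "M" or "F"
    collection_year: int
    chromosome_pair: tuple[WildChromosome, WildChromosome]


@dataclass(frozen=True)
class SublineRecord:
    subline_id: str
    fly_id: str
    sex: str  # sex of the source fly
    year: int
    chromosome: WildChromosome
    lethal: bool


@dataclass
class GeneCatalog:
    """Non-overlapping gene intervals tiled over the chromosome."""

    starts: np.ndarray
    ends: np.ndarray
    fragility: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)

    def interval(self, gene_id: int) -> tuple[int, int]:
        return int(self.starts[gene_id]), int(self.ends[gene_id])

    def coding_intervals(self) -> list[tuple[int, int]]:
        return [(int(s), int(e)) for s, e in zip(self.starts, self.ends)]


@dataclass
class PopulationSample:
    flies: list[Fly]
    catalog: GeneCatalog
    config: SimConfig
    sublines: list[SublineRecord] = field(default_factory=list)

    def subline_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subline_id": s.subline_id,
                    "fly_id": s.fly_id,
                    "sex": s.sex,
                    "year": s.year,
                    "lethal": s.lethal,
                }
                for s in self.sublines
            ]
        )


def build_gene_catalog(config: SimConfig) -> GeneCatalog:
    """Tile ``gene_catalog_size`` genes evenly; coding_fraction of bases code.

    Fragility defaults to a mild power law (rank^-0.5), permuted along the
    chromosome so fragile genes are not positionally clustered.
    """
    g = config.gene_catalog_size
    spacing = config.chromosome_length / g
    gene_len = max(1, int(round(spacing * config.coding_fraction)))
    starts = (np.round(np.arange(g) * spacing) + 1).astype(np.int64)
    ends = starts + gene_len - 1
    if config.gene_fragility_weights is not None:
        fragility = np.asarray(config.gene_fragility_weights, dtype=float)
    else:
        w = (np.arange(1, g + 1, dtype=float)) ** -0.5
        rng = stage_rng(config.seed, "catalog")
        fragility = rng.permutation(w / w.sum())
    return GeneCatalog(starts=starts, ends=ends, fragility=fragility)


def _draw_chromosome(
    chrom_id: str,
    catalog: GeneCatalog,
    config: SimConfig,
    rng: np.random.Generator,
    ibd_group: str | None = None,
) -> WildChromosome:
    k = rng.poisson(config.lambda_true)
    muts = []
    if k:
        genes = rng.choice(len(catalog), size=k, p=catalog.fragility)
        classes = rng.choice(MUTATION_CLASSES, size=k, p=MUTATION_CLASS_WEIGHTS)
        for gene, cls in zip(genes, classes):
            s, e = catalog.interval(int(gene))
            pos = int(rng.integers(s, e + 1))
            muts.append(Mutation(position=pos, gene_id=int(gene), mutation_class=str(cls)))
    return WildChromosome(
        chrom_id=chrom_id,
        lethal_mutations=tuple(sorted(muts, key=lambda m: m.position)),
        ibd_group=ibd_group,
    )


def simulate_population(config: SimConfig) -> PopulationSample:
    """Draw wild flies, each carrying two chromosomes.

    Lethal-mutation counts per chromosome are independent Poisson draws;
    an ``ibd_fraction`` of flies receive one chromosome copied from a small
    shared-ancestor pool (identity by descent), emulating related flies
    caught days apart.
    """
    catalog = build_gene_catalog(config)
    rng = stage_rng(config.seed, "population")
    n_ibd = int(round(config.ibd_fraction * config.n_flies))
    pool_size = max(1, round(n_ibd / 3)) if n_ibd else 0
    pool = [
        _draw_chromosome(f"anc{a:03d}", catalog, config, rng, ibd_group=f"ibd{a:03d}")
        for a in range(pool_size)
    ]
    ibd_flies = set(rng.choice(config.n_flies, size=n_ibd, replace=False)) if n_ibd else set()

    flies = []
    for i in range(config.n_flies):
        sex = "F" if rng.random() < config.female_fraction else "M"
        year = int(rng.choice(config.collection_years, p=config.year_weights))
        a = _draw_chromosome(f"fly{i:04d}.a", catalog, config, rng)
        if i in ibd_flies:
            src = pool[int(rng.integers(len(pool)))]
            b = WildChromosome(
                chrom_id=f"fly{i:04d}.b",
                lethal_mutations=src.lethal_mutations,
                ibd_group=src.ibd_group,
            )
        else:
            b = _draw_chromosome(f"fly{i:04d}.b", catalog, config, rng)
        flies.append(Fly(f"fly{i:04d}", sex, year, (a, b)))
    return PopulationSample(flies=flies, catalog=catalog, config=config)


def _recombine(
    pair: tuple[WildChromosome, WildChromosome],
    child_id: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> WildChromosome:
    """Single uniform crossover between a female fly's two chromosomes."""
    breakpoint_ = int(rng.integers(1, config.chromosome_length + 1))
    left, right = (pair[0], pair[1]) if rng.random() < 0.5 else (pair[1], pair[0])
    muts = tuple(
        sorted(
            [m for m in left.lethal_mutations if m.position <= breakpoint_]
            + [m for m in right.lethal_mutations if m.position > breakpoint_],
            key=lambda m: m.position,
        )
    )
    # a recombinant of two IBD-copied chromosomes is a new haplotype
    return WildChromosome(chrom_id=child_id, lethal_mutations=muts, ibd_group=None)


def sample_sublines(population: PopulationSample, config: SimConfig) -> list[SublineRecord]:
    """Sample balanced sublines from each fly.

    Male sublines each carry one of the fly's two chromosomes chosen
    uniformly (a male's germline does not recombine); female-derived
    sublines carry a single-crossover recombinant of the pair. The subline
    lethality flag is the truth flag of the carried chromosome; scoring
    noise enters only through simulated crosses.
    """
    rng = stage_rng(config.seed, "sublines")
    counts = 1 + np.arange(len(config.sublines_per_fly_weights))
    sublines = []
    for fly in population.flies:
        k = int(rng.choice(counts, p=config.sublines_per_fly_weights))
        for j in range(k):
            sid = f"{fly.fly_id}-s{j + 1}"
            if fly.sex == "M":
                chrom = fly.chromosome_pair[int(rng.integers(2))]
            else:
                chrom = _recombine(fly.chromosome_pair, sid, config, rng)
            sublines.append(
                SublineRecord(
                    subline_id=sid,
                    fly_id=fly.fly_id,
                    sex=fly.sex,
                    year=fly.collection_year,
                    chromosome=chrom,
                    lethal=chrom.lethal,
                )
            )
    population.sublines = sublines
    return sublines


def _draw_panel(config: SimConfig, rng: np.random.Generator) -> DeficiencyPanel:
    lo, hi = config.deficiency_size_range
    if hi > config.chromosome_length:
        raise ValueError("requested deficiency sizes exceed the chromosome length")
    # Sizes are log-uniform over the kit's range: deletion stocks skew small,
    # and the implied mean (~625 kb for 160 kb - 1.6 Mb) reproduces the
    # ~67-73% chromosome coverage a 70-stock kit achieves.
    sizes = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=config.n_deficiencies)
    ).astype(np.int64)
    # Deficiency kits are curated tiling paths, not uniform scatters: place
    # one deficiency per equal-width slot, jittered within the slot, so the
    # panel covers most of the chromosome with modest pairwise overlap.
    slot = config.chromosome_length / config.n_deficiencies
    starts = np.empty(config.n_deficiencies, dtype=np.int64)
    for i, s in enumerate(sizes):
        slot_lo = int(i * slot) + 1
        slot_hi = min(int((i + 1) * slot), config.chromosome_length - int(s) + 1)
        starts[i] = rng.integers(slot_lo, max(slot_lo, slot_hi) + 1)
    df = pd.DataFrame(
        {
            "deficiency_id": [f"Df{i + 1:03d}" for i in range(config.n_deficiencies)],
            "start": starts,
            "end": np.minimum(starts + sizes - 1, config.chromosome_length),
        }
    )
    return DeficiencyPanel(deficiencies=df, chromosome_length=config.chromosome_length)


def simulate_deficiency_panel(config: SimConfig) -> DeficiencyPanel:
    """Draw a deficiency panel with kit-scale deletion sizes; overlaps permitted."""
    return _draw_panel(config, stage_rng(config.seed, "panel"))


def _uncomplemented(line_chromosome: WildChromosome, tester) -> bool:
    """True when the non-balancer offspring class dies (Punnett logic)."""
    if tester == "balancer_sibling":
        return line_chromosome.lethal
    kind = tester[0]
    if kind == "deficiency":
        _, _, start, end = tester
        return any(start <= m.position <= end for m in line_chromosome.lethal_mutations)
    if kind == "knockout":
        return tester[1] in line_chromosome.genes_hit()
    if kind == "allelism":
        partner: WildChromosome = tester[1]
        return bool(line_chromosome.genes_hit() & partner.genes_hit())
    raise ValueError(f"unknown tester {tester!r}")


def simulate_cross(
    line_chromosome: WildChromosome,
    tester,
    config: SimConfig,
    rng: np.random.Generator,
    line_id: str = "",
) -> CrossResult:
    """Simulate one cross and return scored offspring counts.

    ``tester`` is ``"balancer_sibling"``, ``("deficiency", id, start, end)``,
    ``("knockout", gene_id)``, or ``("allelism", partner_chromosome)``. In
    every cross type the balancer-homozygote class dies and the surviving
    classes are equally likely, so when the balancer-free class survives it
    is one third of scored offspring; when an uncomplemented lethal kills it,
    all survivors are curly-winged apart from rare escapers
    (``miss_probability``).
    """
    dead_straight = _uncomplemented(line_chromosome, tester)
    n = int(rng.poisson(config.offspring_mean))
    if dead_straight:
        straight = 1 if (n > 0 and rng.random() < config.miss_probability) else 0
    else:
        straight = int(rng.binomial(n, 1.0 / 3.0)) if n else 0
    if tester == "balancer_sibling":
        kind, tid = "balancer_sibling", "sibling"
    elif tester[0] == "deficiency":
        kind, tid = "deficiency", tester[1]
    elif tester[0] == "knockout":
        kind, tid = "knockout", f"ko:{tester[1]}"
    else:
        kind, tid = "allelism", tester[1].chrom_id
    return CrossResult(
        line_id=line_id or line_chromosome.chrom_id,
        tester_id=str(tid),
        tester_kind=kind,
        curly_n=n - straight,
        straight_n=straight,
    )


def _cross_table(
    line_ids: Sequence[str],
    mut_line_idx: np.ndarray,
    mut_pos: np.ndarray,
    panel: DeficiencyPanel,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Vectorized line-by-deficiency cross table from flat mutation arrays."""
    n_lines, n_def = len(line_ids), len(panel.deficiencies)
    uncomp = np.zeros((n_lines, n_def), dtype=bool)
    for d, (s, e) in enumerate(panel.intervals()):
        if len(mut_pos):
            uncomp[mut_line_idx[(mut_pos >= s) & (mut_pos <= e)], d] = True

    totals = rng.poisson(config.offspring_mean, size=(n_lines, n_def))
    straight = np.where(uncomp, 0, rng.binomial(totals, 1.0 / 3.0))
    if config.miss_probability > 0:
        esc = uncomp & (totals > 0) & (rng.random(uncomp.shape) < config.miss_probability)
        straight = np.where(esc, 1, straight)
    df_ids = panel.deficiencies["deficiency_id"].values
    return pd.DataFrame(
        {
            "line_id": np.repeat(list(line_ids), n_def),
            "tester_id": np.tile(df_ids, n_lines),
            "curly_n": (totals - straight).ravel(),
            "straight_n": straight.ravel(),
        }
    )


def simulate_screen_crosses(
    lines: Mapping[str, WildChromosome],
    panel: DeficiencyPanel,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Cross every line to every panel deficiency (vectorized).

    Returns a tidy table with columns ``line_id, tester_id, curly_n,
    straight_n`` — one row per cross, identical in law to repeated
    :func:`simulate_cross` calls but fast enough for thousands of lines.
    """
    line_ids = list(lines)
    pos_list, idx_list = [], []
    for i, lid in enumerate(line_ids):
        for m in lines[lid].lethal_mutations:
            pos_list.append(m.position)
            idx_list.append(i)
    return _cross_table(
        line_ids,
        np.asarray(idx_list, dtype=np.int64),
        np.asarray(pos_list, dtype=np.int64),
        panel,
        config,
        rng,
    )


@dataclass
class ChromosomeScreen:
    """A chromosome-level screen replicate (no fly/subline structure).

    Used for calibration studies where thousands of chromosomes are tested
    directly: each chromosome is its own line, lethal ones are crossed to
    the whole panel.
    """

    n_chromosomes: int
    lethal_mask: np.ndarray
    mutation_positions: np.ndarray  # all lethal-mutation positions, flat
    panel: DeficiencyPanel
    crosses: pd.DataFrame  # lethal lines x panel

    @property
    def x1(self) -> int:
        return int(self.lethal_mask.sum())

    def mutations_in_coverage(self) -> int:
        """True number of lethal mutations inside the panel's union —
        the quantity the null model predicts, before the conservative
        overlap de-duplication the mapping pipeline applies."""
        from .intervals import merge_intervals

        pos = np.sort(self.mutation_positions)
        total = 0
        for s, e in merge_intervals(self.panel.intervals()):
            total += int(
                np.searchsorted(pos, e, side="right")
                - np.searchsorted(pos, s, side="left")
            )
        return total


def simulate_chromosome_screen(
    config: SimConfig, n_chromosomes: int, rng: np.random.Generator
) -> ChromosomeScreen:
    """Draw ``n_chromosomes`` chromosomes and cross the lethal ones to a
    fresh deficiency panel, all vectorized.

    Identical in law to building the population object-by-object; intended
    for replicate-heavy calibration of the null model.
    """
    catalog = build_gene_catalog(config)
    k = rng.poisson(config.lambda_true, n_chromosomes)
    total = int(k.sum())
    genes = rng.choice(len(catalog), size=total, p=catalog.fragility)
    span = catalog.ends[genes] - catalog.starts[genes] + 1
    pos = catalog.starts[genes] + rng.integers(0, span)
    idx = np.repeat(np.arange(n_chromosomes), k)

    panel = _draw_panel(config, rng)

    lethal_mask = k > 0
    lethal_idx = np.flatnonzero(lethal_mask)
    remap = -np.ones(n_chromosomes, dtype=np.int64)
    remap[lethal_idx] = np.arange(len(lethal_idx))
    line_ids = [f"L{i}" for i in lethal_idx]
    crosses = _cross_table(
        line_ids, remap[idx], pos.astype(np.int64), panel, config, rng
    )
    return ChromosomeScreen(
        n_chromosomes=n_chromosomes,
        lethal_mask=lethal_mask,
        mutation_positions=pos.astype(np.int64),
        panel=panel,
        crosses=crosses,
    )


def simulate_allelism_crosses(
    lines: Mapping[str, WildChromosome],
    pairs: Iterable[tuple[str, str]],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[CrossResult]:
    """Pairwise allelism crosses between lethal lines, keyed by line ids."""
    out = []
    for a, b in pairs:
        counts = _offspring_counts(
            bool(lines[a].genes_hit() & lines[b].genes_hit()), config, rng
        )
        out.append(
            CrossResult(line_id=a, tester_id=b, tester_kind="allelism", **counts)
        )
    return out


def _offspring_counts(dead_straight: bool, config: SimConfig, rng) -> dict:
    n = int(rng.poisson(config.offspring_mean))
    if dead_straight:
        straight = 1 if (n > 0 and rng.random() < config.miss_probability) else 0
    else:
        straight = int(rng.binomial(n, 1.0 / 3.0)) if n else 0
    return {"curly_n": n - straight, "straight_n": straight}


#: Impact mix for background (non-causal) variants.
_BG_IMPACTS = ("MODIFIER", "LOW", "MODERATE", "HIGH")
_BG_IMPACT_WEIGHTS = (0.80, 0.18, 0.015, 0.005)
_BASES = ("A", "C", "G", "T")

_CAUSAL_CLASS_MAP = {
    # mutation class -> (variant class, SV length range or None)
    "TE_insertion": ("TE_insertion", (3000, 8000)),
    "deletion": ("deletion", (100, 2000)),
    "premature_stop": ("SNV", None),
    "splice_site": ("SNV", None),
}


def _background_records(
    n: int, config: SimConfig, rng: np.random.Generator
) -> list[VariantRecord]:
    recs = []
    for _ in range(n):
        pos = int(rng.integers(1, config.chromosome_length + 1))
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        impact = str(rng.choice(_BG_IMPACTS, p=_BG_IMPACT_WEIGHTS))
        recs.append(
            VariantRecord(
                chrom="2",
                pos=pos,
                ref=str(ref),
                alt=str(alt),
                var_class="SNV",
                impact=impact,
                source_callers=frozenset({"sim"}),
            )
        )
    return recs


def _causal_record(m: Mutation, rng: np.random.Generator) -> VariantRecord:
    var_class, len_range = _CAUSAL_CLASS_MAP[m.mutation_class]
    if var_class == "SNV":
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        return VariantRecord(
            chrom="2", pos=m.position, ref=str(ref), alt=str(alt),
            var_class="SNV", impact="HIGH", source_callers=frozenset({"sim"}),
        )
    length = int(rng.integers(*len_range))
    return VariantRecord(
        chrom="2", pos=m.position, ref="N", alt=f"<{var_class.upper()}>",
        var_class=var_class, impact="HIGH", length=length,
        source_callers=frozenset({"sim"}),
    )


def simulate_variant_tables(
    population: PopulationSample | Sequence[SublineRecord],
    causal_classes: tuple[str, ...] = MUTATION_CLASSES,
    background_rate: float = 50.0,
    seed: int = 0,
    config: SimConfig | None = None,
) -> dict[str, list[VariantRecord]]:
    """Per-line variant tables for sequenced (lethal) sublines.

    Each table contains the line's causal lethal mutations as HIGH-impact
    records (positions and classes taken from the simulated chromosome),
    one shared background set per identity-by-descent group, and
    Poisson(``background_rate``) private mostly-low-impact noise records.
    Lines in different allelic sets never share a causal record, because
    causal records are derived from each line's own mutation events.

    Accepts a :class:`PopulationSample` (after :func:`sample_sublines`) or a
    plain sequence of sublines together with an explicit ``config``.
    """
    if isinstance(population, PopulationSample):
        sublines, config = population.sublines, population.config
    else:
        sublines = list(population)
        if config is None:
            raise ValueError("config is required when passing bare sublines")
    rng = stage_rng(seed, "variants")
    lethal = [s for s in sublines if s.lethal]

    # Identical causal records for identical (IBD-copied) mutations: key the
    # record by the mutation event so copies share ref/alt and SV length.
    causal_cache: dict[Mutation, VariantRecord] = {}
    ibd_shared: dict[str, list[VariantRecord]] = {}
    tables: dict[str, list[VariantRecord]] = {}
    for s in sorted(lethal, key=lambda x: x.subline_id):
        recs = []
        for m in s.chromosome.lethal_mutations:
            if m.mutation_class not in causal_classes:
                continue
            if m not in causal_cache:
                causal_cache[m] = _causal_record(m, rng)
            recs.append(causal_cache[m])
        group = s.chromosome.ibd_group
        if group is not None:
            if group not in ibd_shared:
                n_shared = int(rng.poisson(background_rate))
                ibd_shared[group] = _background_records(n_shared, config, rng)
            recs.extend(ibd_shared[group])
        recs.extend(_background_records(int(rng.poisson(background_rate)), config, rng))
        tables[s.subline_id] = sorted(recs, key=lambda r: (r.chrom, r.pos))
    return tables


def simulate_read_depths(
    mean_depth: float,
    window: int = 100,
    heterozygous_deletion: bool = False,
    seed: int = 0,
    target_region: tuple[str, int, int] = ("2L", 5_000, 11_000),
    control_region: tuple[str, int, int] = ("2L", 10_000_000, 12_000_000),
    control_window: int = 1000,
) -> pd.DataFrame:
    """Windowed depth table over a peri-telomeric target and mid-arm control.

    Per-base depths are Poisson(``mean_depth``); a heterozygous terminal
    deletion halves the rate across the target region. Rows:
    ``chrom, start, end, depth`` with depth in mean reads per base.
    """
    if mean_depth <= 0:
        raise ValueError(f"mean_depth must be > 0, got {mean_depth!r}")
    rng = stage_rng(seed, "depths")
    rows = []
    for (chrom, start, end), w, deleted in (
        (target_region, window, heterozygous_deletion),
        (control_region, control_window, False),
    ):
        rate = mean_depth / 2.0 if deleted else mean_depth
        edges = np.arange(start, end + 2, w)
        for s, e in zip(edges[:-1], edges[1:] - 1):
            width = int(e - s + 1)
            depth = rng.poisson(rate * width) / width
            rows.append({"chrom": chrom, "start": int(s), "end": int(e), "depth": depth})
    return pd.DataFrame(rows)


@dataclass
class ScreenBundle:
    """Everything one simulated screen produces."""

    population: PopulationSample
    sublines: list[SublineRecord]
    panel: DeficiencyPanel
    deficiency_crosses: pd.DataFrame  # lethal lines x panel
    allelism_results: dict[frozenset, bool]  # same-fly lethal pairs (rule d)


def simulate_screen(config: SimConfig) -> ScreenBundle:
    """Run population, subline sampling, panel, and crossing stages."""
    population = simulate_population(config)
    sublines = sample_sublines(population, config)
    panel = simulate_deficiency_panel(config)
    rng = stage_rng(config.seed, "crosses")

    lethal_lines = {s.subline_id: s.chromosome for s in sublines if s.lethal}
    crosses = simulate_screen_crosses(lethal_lines, panel, config, rng)

    # Allelism crosses needed by counting rule (d): same-(male-)fly lethal pairs.
    by_fly: dict[str, list[SublineRecord]] = {}
    for s in sublines:
        if s.lethal and s.sex == "M":
            by_fly.setdefault(s.fly_id, []).append(s)
    allelism: dict[frozenset, bool] = {}
    min_curly = 35
    for fly_id, subs in sorted(by_fly.items()):
        for i in range(len(subs)):
            for j in range(i + 1, len(subs)):
                a, b = subs[i], subs[j]
                res = _offspring_counts(
                    bool(a.chromosome.genes_hit() & b.chromosome.genes_hit()),
                    config,
                    rng,
                )
                allelic = res["straight_n"] == 0 and res["curly_n"] >= min_curly
                allelism[frozenset((a.subline_id, b.subline_id))] = allelic
    return ScreenBundle(
        population=population,
        sublines=sublines,
        panel=panel,
        deficiency_crosses=crosses,
        allelism_results=allelism,
    )
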