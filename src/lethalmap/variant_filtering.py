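"""Candidate lethal-mutation filtering, depth-ratio deletion detection,
and kinship between balanced lines.

Once an allelic set is fine-mapped to a small interval, whole-genome variant
tables of its member lines are reduced to candidate lethal mutations by three
rules: the variant must be annotated HIGH or MODERATE impact, must fall
inside the fine-mapped interval, and must be absent from every sequenced
lethal line that did *not* map there (a variant shared with a non-allelic
line is either non-lethal or sits on the common balancer). A strict mode
additionally requires the candidate in every sequenced set member, which is
the right default for identical-by-descent sets; independently arising
mutations in the same fragile gene are distinct variants and are filtered
per line instead.

Heterozygous terminal deletions are detected from read depth: the mean
per-base depth over a peri-telomeric target window divided by that over a
mid-arm control window drops to ~0.5 in carriers.

Relatedness between lines uses the KING-robust kinship coefficient

    phi = (N_het,het - 2 * N_AA,aa) / (N_het(i) + N_het(j))

which stays valid when the sample is not a homogeneous population — all
lines share the same CyO balancer, so only relative coefficients are
interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "CandidateReport",
    "DepthRatioResult",
    "KinshipEstimate",
    "merge_variant_records",
    "filter_candidates",
    "depth_ratio",
    "classify_deletion_carrier",
    "king_kinship",
    "kinship_matrix",
    "genotypes_from_variant_tables",
]

SV_CLASSES = ("insertion", "deletion", "inversion", "tandem_repeat", "TE_insertion")
IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")

#: Breakpoint jitter tolerated when deduplicating the same SV across callers.
SV_POS_TOL = 10
SV_LEN_TOL = 0.10

#: Default windows for terminal-deletion detection (2L peri-telomere vs
#: mid-arm control), 1-based inclusive.
TARGET_WINDOW = ("2L", 5_000, 11_000)
CONTROL_WINDOW = ("2L", 10_000_000, 12_000_000)


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: str  # SNV or one of SV_CLASSES
    impact: str
    length: int = 0  # bases, for SVs
    carrier_lines: frozenset = frozenset()
    source_callers: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.impact not in IMPACTS:
            raise ValueError(f"unknown impact {self.impact!r}")

    def key(self) -> tuple:
        """Deduplication key: exact for SNVs, class/position/length for SVs."""
        if self.var_class == "SNV":
            return (self.chrom, self.pos, "SNV", self.alt)
        return (self.chrom, self.pos, self.var_class, self.length)


@dataclass
class CandidateReport:
    set_id: str
    fine_mapped_interval: tuple[str, int, int]
    candidates: list[VariantRecord]
    excluded: list[tuple[VariantRecord, str]] = field(default_factory=list)


@dataclass(frozen=True)
class DepthRatioResult:
    line_id: str
    target_window: tuple[str, int, int]
    control_window: tuple[str, int, int]
    target_depth: float
    control_depth: float
    ratio: float


@dataclass(frozen=True)
class KinshipEstimate:
    line_i: str
    line_j: str
    phi: float  # NaN when the heterozygosity denominator is zero
    n_snps_used: int


def merge_variant_records(
    per_caller: Iterable[Sequence[VariantRecord]],
) -> list[VariantRecord]:
    """Merge per-caller variant lists into one deduplicated list.

    SNVs deduplicate on (chrom, pos, alt); two callers disagreeing on the
    reference allele at the same site is a data error and raises. Structural
    variants of the same class whose positions agree within ±10 bp and
    lengths within ±10% are treated as the same event (caller breakpoint
    jitter); the earliest-position record is kept. Carrier lines and caller
    provenance are unioned across merged duplicates.
    """
    records = [r for lst in per_caller for r in lst]
    snvs: dict[tuple, VariantRecord] = {}
    svs: list[VariantRecord] = []
    for r in records:
        if r.var_class == "SNV":
            key = r.key()
            if key in snvs:
                prev = snvs[key]
                if prev.ref != r.ref:
                    raise ValueError(
                        f"conflicting ref alleles at {r.chrom}:{r.pos} "
                        f"({prev.ref!r} vs {r.ref!r})"
                    )
                snvs[key] = replace(
                    prev,
                    carrier_lines=prev.carrier_lines | r.carrier_lines,
                    source_callers=prev.source_callers | r.source_callers,
                )
            else:
                snvs[key] = r
        else:
            svs.append(r)

    merged_svs: list[VariantRecord] = []
    svs.sort(key=lambda r: (r.chrom, r.var_class, r.pos, r.length))
    for r in svs:
        prev = merged_svs[-1] if merged_svs else None
        if (
            prev is not None
            and prev.chrom == r.chrom
            and prev.var_class == r.var_class
            and abs(prev.pos - r.pos) <= SV_POS_TOL
            and _lengths_match(prev.length, r.length)
        ):
            merged_svs[-1] = replace(
                prev,
                carrier_lines=prev.carrier_lines | r.carrier_lines,
                source_callers=prev.source_callers | r.source_callers,
            )
        else:
            merged_svs.append(r)
    return sorted(
        list(snvs.values()) + merged_svs, key=lambda r: (r.chrom, r.pos, r.var_class)
    )


def _lengths_match(a: int, b: int) -> bool:
    if a == b:
        return True
    longer = max(abs(a), abs(b))
    return longer > 0 and abs(a - b) / longer <= SV_LEN_TOL


def filter_candidates(
    variants_by_line: Mapping[str, Sequence[VariantRecord]],
    set_lines: Iterable[str],
    fine_mapped_interval: tuple[str, int, int],
    nonallelic_variants: Mapping[str, Sequence[VariantRecord]] | None = None,
    strict_shared: bool = True,
    set_id: str = "",
) -> CandidateReport:
    """Reduce an allelic set's variant tables to candidate lethal mutations.

    Exclusion reasons, applied in order per distinct variant:
    ``outside_region``, ``low_impact``, ``present_in_nonallelic_line``, and
    (strict mode only) ``not_shared_in_set``. Every distinct input variant
    of the set appears exactly once, in candidates or in excluded.
    """
    chrom, start, end = fine_mapped_interval
    if start > end:
        raise ValueError(f"empty fine-mapped interval {fine_mapped_interval!r}")
    set_lines = sorted(set(set_lines))
    missing = [l for l in set_lines if l not in variants_by_line]
    if missing:
        raise KeyError(f"no variant table for set members: {missing}")

    # Union the set's tables, tracking which members carry each key.
    merged = merge_variant_records(
        [
            [replace(v, carrier_lines=v.carrier_lines | {line}) for v in variants_by_line[line]]
            for line in set_lines
        ]
    )
    nonallelic_keys = set()
    for recs in (nonallelic_variants or {}).values():
        nonallelic_keys.update(v.key() for v in recs)

    candidates, excluded = [], []
    for v in merged:
        if not (v.chrom == chrom and start <= v.pos <= end):
            excluded.append((v, "outside_region"))
        elif v.impact not in ("HIGH", "MODERATE"):
            excluded.append((v, "low_impact"))
        elif v.key() in nonallelic_keys:
            excluded.append((v, "present_in_nonallelic_line"))
        elif strict_shared and not set(set_lines) <= v.carrier_lines:
            excluded.append((v, "not_shared_in_set"))
        else:
            candidates.append(v)
    return CandidateReport(
        set_id=set_id,
        fine_mapped_interval=fine_mapped_interval,
        candidates=candidates,
        excluded=excluded,
    )


def _window_mean_depth(depth: pd.DataFrame, window: tuple[str, int, int]) -> float:
    chrom, start, end = window
    d = depth[depth["chrom"] == chrom] if "chrom" in depth.columns else depth
    ov = (
        np.minimum(d["end"].values, end) - np.maximum(d["start"].values, start) + 1
    ).clip(min=0)
    if ov.sum() == 0:
        raise ValueError(f"window {window!r} is not covered by the depth table")
    return float(np.average(d["depth"].values, weights=ov))


def depth_ratio(
    depth_table: pd.DataFrame,
    target_window: tuple[str, int, int] = TARGET_WINDOW,
    control_window: tuple[str, int, int] = CONTROL_WINDOW,
    line_id: str = "",
) -> DepthRatioResult:
    """Mean per-base depth in the target window over the control window.

    ``depth_table`` columns: ``chrom, start, end, depth`` (depth is mean
    reads per base in the window, 1-based inclusive coordinates). The ratio
    is scale-invariant, so libraries of different total depth are comparable.
    """
    target = _window_mean_depth(depth_table, target_window)
    control = _window_mean_depth(depth_table, control_window)
    if control <= 0:
        raise ValueError("control window has zero depth")
    return DepthRatioResult(
        line_id=line_id,
        target_window=target_window,
        control_window=control_window,
        target_depth=target,
        control_depth=control,
        ratio=target / control,
    )


def classify_deletion_carrier(
    result: DepthRatioResult | float, threshold: float = 0.75
) -> bool:
    """Call a heterozygous-deletion carrier from a depth ratio.

    Carrier iff ratio strictly below ``threshold``; the default midpoint
    separates the ~0.5 expected for a heterozygous deletion from the ~1.0 of
    non-carriers.
    """
    ratio = result.ratio if isinstance(result, DepthRatioResult) else float(result)
    return ratio < threshold


def king_kinship(
    genotypes_i: np.ndarray,
    genotypes_j: np.ndarray,
    line_i: str = "i",
    line_j: str = "j",
) -> KinshipEstimate:
    """KING-robust kinship from genotype vectors coded 0/1/2 (NaN = missing).

    phi = (N_het,het - 2 * N_AA,aa) / (N_het(i) + N_het(j)); sites missing in
    either sample are dropped pairwise. A zero denominator (no heterozygous
    site in either sample) yields phi = NaN rather than a silent 0.
    """
    gi = np.asarray(genotypes_i, dtype=float)
    gj = np.asarray(genotypes_j, dtype=float)
    if gi.shape != gj.shape:
        raise ValueError("genotype vectors differ in length")
    ok = ~(np.isnan(gi) | np.isnan(gj))
    gi, gj = gi[ok], gj[ok]
    het_i = gi == 1
    het_j = gj == 1
    n_hh = int(np.sum(het_i & het_j))
    n_opp = int(np.sum(((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))))
    denom = int(het_i.sum() + het_j.sum())
    phi = (n_hh - 2.0 * n_opp) / denom if denom > 0 else float("nan")
    return KinshipEstimate(line_i=line_i, line_j=line_j, phi=phi, n_snps_used=int(ok.sum()))


def kinship_matrix(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Pairwise KING-robust kinship matrix (lines x lines).

    ``genotypes`` is lines-by-sites, coded 0/1/2 with NaN missing. The
    result is symmetric with an NaN diagonal — self-kinship is not a
    meaningful between-line quantity and is left blank.
    """
    lines = list(genotypes.index)
    if len(lines) < 2:
        raise ValueError("need >= 2 lines")
    mat = pd.DataFrame(np.nan, index=lines, columns=lines)
    for a in range(len(lines)):
        for b in range(a + 1, len(lines)):
            est = king_kinship(
                genotypes.iloc[a].values, genotypes.iloc[b].values,
                lines[a], lines[b],
            )
            mat.iloc[a, b] = est.phi
            mat.iloc[b, a] = est.phi
    return mat


def genotypes_from_variant_tables(
    tables: Mapping[str, Sequence[VariantRecord]],
) -> pd.DataFrame:
    """Presence/absence genotypes over the union of variant keys.

    Balanced lines are heterozygous for every wild-chromosome variant, so a
    carried variant codes 1 (het) and an absent one 0; this feeds the
    kinship estimator for screens sequenced as balanced stocks.
    """
    keys = sorted({v.key() for recs in tables.values() for v in recs})
    idx = {k: i for i, k in enumerate(keys)}
    mat = np.zeros((len(tables), len(keys)))
    lines = sorted(tables)
    for row, line in enumerate(lines):
        for v in tables[line]:
            mat[row, idx[v.key()]] = 1
    return pd.DataFrame(mat, index=lines, columns=pd.RangeIndex(len(keys)))
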