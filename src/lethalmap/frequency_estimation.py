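"""Distinct-chromosome counting and lethal-fraction estimation.

A wild male fly carries two second chromosomes; each balanced subline derived
from him samples one of them, so two sublines from the same fly may or may
not represent distinct chromosomes. The screen resolves this with five
counting rules, applied per source fly:

(a) one subline assayed -> 1 chromosome tested;
(b) male, two sublines, one lethal + one non-lethal -> 2 (they must differ);
(c) male, two sublines, both non-lethal -> 1.5 (either one or both
    chromosomes were sampled, equally likely, so the expected value is used);
(d) male, two sublines, both lethal -> an allelism cross decides: allelic
    means one chromosome sampled twice (one subline discarded), otherwise 2;
(e) female-derived sublines are recombinants (females recombine), so one
    subline per female is retained uniformly at random and the rest are
    excluded from both numerator and denominator.

The lethal fraction is the distinct lethal count over the distinct total,
with a normal-approximation standard error and 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ChromosomeCount",
    "ProportionEstimate",
    "count_distinct_chromosomes",
    "lethal_fraction",
    "nonlethal_proportion",
]

SUBLINE_COLUMNS = ["subline_id", "fly_id", "sex", "year", "lethal"]


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with binomial SE and clipped 95% normal CI."""

    p: float
    n: float
    se: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_counts(cls, k: float, n: float) -> "ProportionEstimate":
        if n <= 0:
            raise ValueError(f"sample size must be > 0, got {n!r}")
        p = k / n
        se = float(np.sqrt(p * (1.0 - p) / n))
        return cls(
            p=p,
            n=n,
            se=se,
            ci_low=max(0.0, p - 1.96 * se),
            ci_high=min(1.0, p + 1.96 * se),
        )


@dataclass
class ChromosomeCount:
    """Distinct-chromosome bookkeeping for one screen."""

    n_lethal: float
    n_total: float
    excluded_sublines: list[str] = field(default_factory=list)
    rule_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.n_lethal <= self.n_total:
            raise ValueError(
                f"need 0 <= n_lethal <= n_total, got {self.n_lethal}/{self.n_total}"
            )


def _as_frame(sublines) -> pd.DataFrame:
    if isinstance(sublines, pd.DataFrame):
        df = sublines
    else:  # iterable of SublineRecord-like objects
        df = pd.DataFrame(
            [
                {
                    "subline_id": s.subline_id,
                    "fly_id": s.fly_id,
                    "sex": s.sex,
                    "year": s.year,
                    "lethal": s.lethal,
                }
                for s in sublines
            ]
        )
    missing = set(SUBLINE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"subline table is missing columns: {sorted(missing)}")
    if df["lethal"].isna().any():
        bad = df.loc[df["lethal"].isna(), "subline_id"].tolist()
        raise ValueError(f"missing lethality call for sublines: {bad}")
    return df


def _allelic(allelism: Mapping, a: str, b: str, fly_id: str) -> bool:
    for key in ((a, b), (b, a), frozenset((a, b))):
        if key in allelism:
            return bool(allelism[key])
    raise ValueError(
        f"fly {fly_id!r} has two lethal sublines ({a!r}, {b!r}) but no "
        "allelism result was supplied for the pair"
    )


def _count_male_fly(
    fly_id: str,
    subs: pd.DataFrame,
    allelism: Mapping,
    rng: np.random.Generator,
) -> tuple[float, float, list[str], str]:
    """Apply rules (a)-(d) to one male fly; returns (total, lethal, excluded, rule).

    Flies with more than two sublines (rare in practice) are handled by the
    same logic generalized: the number of distinct lethal chromosomes is the
    number of allelic components among lethal sublines (a male carries only
    two chromosomes, so this is capped at 2), and any non-lethal subline
    pins down the remaining homologue.
    """
    ids = subs["subline_id"].tolist()
    lethal_ids = subs.loc[subs["lethal"], "subline_id"].tolist()
    k, n_lethal_subs = len(ids), len(lethal_ids)

    if k == 1:
        return 1.0, float(subs["lethal"].iloc[0]), [], "a"
    if k == 2 and n_lethal_subs == 1:
        return 2.0, 1.0, [], "b"
    if k == 2 and n_lethal_subs == 0:
        return 1.5, 0.0, [], "c"
    if k == 2 and n_lethal_subs == 2:
        if _allelic(allelism, lethal_ids[0], lethal_ids[1], fly_id):
            drop = lethal_ids[int(rng.integers(2))]
            return 1.0, 1.0, [drop], "d"
        return 2.0, 2.0, [], "d"

    # >2 sublines: allelic components among the lethal ones, capped at 2.
    comps = _allelic_components(lethal_ids, allelism, fly_id)
    excluded: list[str] = []
    for comp in comps:
        keep = comp[int(rng.integers(len(comp)))]
        excluded.extend(s for s in comp if s != keep)
    n_lethal = float(min(2, len(comps)))
    has_nonlethal = n_lethal_subs < k
    if n_lethal >= 2:
        total = 2.0
    elif n_lethal == 1:
        total = 2.0 if has_nonlethal else 1.0
    else:
        total = 1.5  # all non-lethal: one or both chromosomes, average
    return total, n_lethal, excluded, "d*" if n_lethal_subs >= 2 else "a*"


def _allelic_components(
    lethal_ids: list[str], allelism: Mapping, fly_id: str
) -> list[list[str]]:
    parent = {s: s for s in lethal_ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(lethal_ids):
        for b in lethal_ids[i + 1 :]:
            if _allelic(allelism, a, b, fly_id):
                parent[find(a)] = find(b)
    comps: dict[str, list[str]] = {}
    for s in lethal_ids:
        comps.setdefault(find(s), []).append(s)
    return list(comps.values())


def count_distinct_chromosomes(
    sublines,
    allelism_results: Mapping | None = None,
    seed: int = 0,
) -> ChromosomeCount:
    """Count distinct wild chromosomes from a subline table.

    Parameters
    ----------
    sublines
        DataFrame with columns ``subline_id, fly_id, sex, year, lethal``
        (or an iterable of objects with those attributes). ``sex`` is
        ``"M"``/``"F"`` for the *source fly*.
    allelism_results
        Mapping from subline-id pairs (tuples in either order, or
        frozensets) to a bool: True if the pair failed to complement.
        Required for any male fly contributing two or more lethal sublines.
    seed
        Seeds the stream used for rule-(e) female retention and rule-(d)
        discard choices only, so counting is reproducible and independent
        of any other randomness.
    """
    df = _as_frame(sublines)
    allelism = allelism_results or {}
    rng = np.random.default_rng(seed)

    n_total = 0.0
    n_lethal = 0.0
    excluded: list[str] = []
    rule_log: list[tuple[str, str]] = []

    # Iterate flies in a canonical order so counting is permutation-invariant.
    for fly_id, subs in df.sort_values("subline_id").groupby("fly_id", sort=True):
        sex = subs["sex"].iloc[0]
        if sex == "F" and len(subs) > 1:
            keep_pos = int(rng.integers(len(subs)))
            kept = subs.iloc[[keep_pos]]
            excluded.extend(s for s in subs["subline_id"] if s != kept["subline_id"].iloc[0])
            n_total += 1.0
            n_lethal += float(kept["lethal"].iloc[0])
            rule_log.append((str(fly_id), "e"))
            continue
        total, lethal, drop, rule = _count_male_fly(str(fly_id), subs, allelism, rng)
        n_total += total
        n_lethal += lethal
        excluded.extend(drop)
        rule_log.append((str(fly_id), rule))

    return ChromosomeCount(
        n_lethal=n_lethal,
        n_total=n_total,
        excluded_sublines=excluded,
        rule_log=rule_log,
    )


def lethal_fraction(count: ChromosomeCount) -> ProportionEstimate:
    """Proportion of distinct chromosomes that are homozygous lethal."""
    return ProportionEstimate.from_counts(count.n_lethal, count.n_total)


def nonlethal_proportion(count: ChromosomeCount) -> ProportionEstimate:
    """Proportion of distinct chromosomes that are non-lethal (P0).

    This is the zero-class proportion consumed by the null model; if every
    chromosome is lethal the downstream Poisson mean is undefined, which the
    null model reports by refusing p0 = 0.
    """
    return ProportionEstimate.from_counts(
        count.n_total - count.n_lethal, count.n_total
    )
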