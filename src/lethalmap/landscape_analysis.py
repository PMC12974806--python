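"""Genomic-landscape context for per-deficiency mapping frequencies.

Each deficiency interrogates a window of the chromosome; normalizing the
number of lethal mutations mapped to it by the deficiency's size and by the
number of lethal lines crossed gives a mapping frequency comparable across
deficiencies. Averaging annotation tracks (recombination rate in cM/Mb,
coding-base density, GC content) over the same windows lets the mapping
frequency be correlated with landscape features.

Intervals are 1-based inclusive, matching the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import merge_intervals, overlap_length

__all__ = [
    "GenomeTrack",
    "interval_weighted_mean",
    "coding_density",
    "mapping_frequency",
    "summarize_deficiencies",
    "correlate_tracks",
]

TRACK_KINDS = ("recombination_rate", "coding_flag", "gc_content")


@dataclass
class GenomeTrack:
    """Windowed values over a chromosome arm.

    ``windows`` columns: ``start, end, value`` (optionally ``chrom``);
    windows must not overlap within an arm.
    """

    windows: pd.DataFrame
    kind: str = "recombination_rate"

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        w = self.windows.sort_values("start")
        if not np.isfinite(w["value"]).all():
            raise ValueError("track values must be finite")
        if (w["start"].values[1:] <= w["end"].values[:-1]).any():
            raise ValueError("track windows overlap")
        self.windows = w.reset_index(drop=True)


def interval_weighted_mean(track: GenomeTrack, interval: tuple[int, int]) -> float:
    """Overlap-length-weighted mean of track values inside ``interval``.

    Where the track does not cover the whole interval (recombination maps
    have gaps near telomeres and centromeres) the mean is taken over covered
    bases only. Zero overlap is an error rather than a silent NaN.
    """
    start, end = interval
    if start > end:
        raise ValueError(f"empty interval {interval!r}")
    w = track.windows
    ov = np.minimum(w["end"].values, end) - np.maximum(w["start"].values, start) + 1
    ov = np.clip(ov, 0, None).astype(float)
    if ov.sum() == 0:
        raise ValueError(f"interval {interval!r} has no overlap with the track")
    return float(np.average(w["value"].values, weights=ov))


def covered_fraction(track: GenomeTrack, interval: tuple[int, int]) -> float:
    """Fraction of the interval's bases the track covers."""
    start, end = interval
    w = track.windows
    ov = np.minimum(w["end"].values, end) - np.maximum(w["start"].values, start) + 1
    return float(np.clip(ov, 0, None).sum() / (end - start + 1))


def coding_density(
    coding_intervals: list[tuple[int, int]] | pd.DataFrame,
    interval: tuple[int, int],
) -> float:
    """Proportion of the interval's bases that are coding.

    Coding annotations are merged first, so duplicated or overlapping exon
    entries are not double-counted.
    """
    start, end = interval
    if start > end:
        raise ValueError(f"empty interval {interval!r}")
    if isinstance(coding_intervals, pd.DataFrame):
        coding_intervals = list(zip(coding_intervals["start"], coding_intervals["end"]))
    merged = merge_intervals(list(coding_intervals))
    covered = sum(overlap_length(iv, interval) for iv in merged)
    return covered / (end - start + 1)


def mapping_frequency(n_mapped: float, size: float, n_crosses: float) -> float:
    """Mapped lethal mutations per base per cross for one deficiency."""
    if size <= 0:
        raise ValueError(f"deficiency size must be > 0, got {size!r}")
    if n_crosses <= 0:
        raise ValueError(f"number of crosses must be > 0, got {n_crosses!r}")
    return n_mapped / (size * n_crosses)


def summarize_deficiencies(
    panel,
    calls: pd.DataFrame,
    coding_intervals=None,
    recombination: GenomeTrack | None = None,
    gc: GenomeTrack | None = None,
) -> pd.DataFrame:
    """Per-deficiency summary table (mapping frequency plus track means).

    ``calls`` is a mapping-call table (``tester_id``, ``call`` columns);
    crosses per deficiency are taken from the panel's ``n_crosses`` column
    when present, otherwise from the number of scoreable calls.
    """
    df = panel.deficiencies.copy()
    n_mapped = (
        calls[calls["call"] == "mapped"].groupby("tester_id").size()
        .reindex(df["deficiency_id"], fill_value=0).values
    )
    if "n_crosses" in df.columns:
        n_crosses = df["n_crosses"].values
    else:
        n_crosses = (
            calls.groupby("tester_id").size()
            .reindex(df["deficiency_id"], fill_value=0).values
        )
    out = pd.DataFrame(
        {
            "deficiency_id": df["deficiency_id"],
            "start": df["start"],
            "end": df["end"],
            "size": df["end"] - df["start"] + 1,
            "n_mapped": n_mapped,
            "n_crosses": n_crosses,
        }
    )
    out["mapping_frequency"] = [
        mapping_frequency(m, s, c) if c > 0 else np.nan
        for m, s, c in zip(out["n_mapped"], out["size"], out["n_crosses"])
    ]
    ivs = list(zip(df["start"], df["end"]))
    if coding_intervals is not None:
        out["coding_density"] = [coding_density(coding_intervals, iv) for iv in ivs]
    if recombination is not None:
        out["mean_recombination"] = [
            interval_weighted_mean(recombination, iv) for iv in ivs
        ]
    if gc is not None:
        out["mean_gc"] = [interval_weighted_mean(gc, iv) for iv in ivs]
    return out


def correlate_tracks(
    summaries: pd.DataFrame,
    x_field: str,
    y_field: str,
    method: str = "pearson",
) -> tuple[float, float, int]:
    """Correlate two per-deficiency fields; returns (r, p, n).

    Pearson product-moment with a two-sided t p-value by default (Spearman
    available); rows with a NaN in either field are dropped first, so
    terminal deficiencies of unknown size can be excluded by setting their
    fields to NaN upstream.
    """
    sub = summaries[[x_field, y_field]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 complete observations, got {n}")
    x, y = sub[x_field].values, sub[y_field].values
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the fields")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), n
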