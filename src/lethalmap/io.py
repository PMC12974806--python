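"""Readers and writers for the screen's on-disk formats.

Tabular data travels as TSV; deficiency panels as BED (coordinates are
converted between the package's 1-based inclusive convention and BED's
0-based half-open at this boundary only); per-line variant tables as minimal
VCF 4.2 with ``IMPACT``, ``VCLASS``, ``SVLEN`` and ``SRC`` INFO keys
(written and read through pysam).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import pysam

from .complementation_mapping import DeficiencyPanel
from .variant_filtering import VariantRecord

__all__ = [
    "write_subline_table",
    "read_subline_table",
    "write_cross_table",
    "read_cross_table",
    "write_deficiency_bed",
    "read_deficiency_bed",
    "write_depth_table",
    "read_depth_table",
    "write_variant_vcf",
    "read_variant_vcf",
    "write_allelism_table",
    "read_allelism_table",
]


def write_subline_table(sublines, path) -> None:
    df = sublines if isinstance(sublines, pd.DataFrame) else pd.DataFrame(
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
    df.to_csv(path, sep="\t", index=False)


def read_subline_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["lethal"] = df["lethal"].astype(bool)
    return df


def write_cross_table(crosses, path) -> None:
    df = crosses if isinstance(crosses, pd.DataFrame) else pd.DataFrame(
        [
            {
                "line_id": c.line_id,
                "tester_id": c.tester_id,
                "tester_kind": c.tester_kind,
                "curly_n": c.curly_n,
                "straight_n": c.straight_n,
            }
            for c in crosses
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_cross_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_allelism_table(allelism: dict, path) -> None:
    rows = [
        {"line_a": sorted(pair)[0], "line_b": sorted(pair)[1], "allelic": flag}
        for pair, flag in sorted(allelism.items(), key=lambda kv: sorted(kv[0]))
    ]
    pd.DataFrame(rows, columns=["line_a", "line_b", "allelic"]).to_csv(
        path, sep="\t", index=False
    )


def read_allelism_table(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {
        frozenset((r.line_a, r.line_b)): bool(r.allelic) for r in df.itertuples()
    }


def write_deficiency_bed(panel: DeficiencyPanel, path, chrom: str = "2") -> None:
    """1-based inclusive panel -> 0-based half-open BED."""
    df = panel.deficiencies
    bed = pd.DataFrame(
        {
            "chrom": chrom,
            "start": df["start"] - 1,
            "end": df["end"],
            "name": df["deficiency_id"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_deficiency_bed(path, chromosome_length: int) -> DeficiencyPanel:
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name"]
    )
    df = pd.DataFrame(
        {
            "deficiency_id": bed["name"],
            "start": bed["start"] + 1,
            "end": bed["end"],
        }
    )
    return DeficiencyPanel(deficiencies=df, chromosome_length=chromosome_length)


def write_depth_table(depth: pd.DataFrame, path) -> None:
    depth.to_csv(path, sep="\t", index=False)


def read_depth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


_VCF_HEADER_INFO = [
    ('##INFO=<ID=IMPACT,Number=1,Type=String,'
     'Description="Predicted functional impact">'),
    ('##INFO=<ID=VCLASS,Number=1,Type=String,Description="Variant class">'),
    ('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">'),
    ('##INFO=<ID=SRC,Number=.,Type=String,Description="Source callers">'),
    ('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">'),
]


def write_variant_vcf(
    records: Sequence[VariantRecord], path, contigs: dict[str, int] | None = None
) -> None:
    """Write one line's variant records as an uncompressed VCF 4.2."""
    header = pysam.VariantHeader()
    for line in _VCF_HEADER_INFO:
        header.add_line(line)
    names = sorted({r.chrom for r in records}) or ["2"]
    contigs = contigs or {}
    for name in set(names) | set(contigs):
        header.contigs.add(name, length=contigs.get(name))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in sorted(records, key=lambda x: (x.chrom, x.pos)):
            rec = vcf.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                stop=r.pos - 1 + max(1, len(r.ref)),
                alleles=(r.ref, r.alt),
            )
            rec.info["IMPACT"] = r.impact
            rec.info["VCLASS"] = r.var_class
            if r.length:
                rec.info["SVLEN"] = r.length
            if r.source_callers:
                rec.info["SRC"] = tuple(sorted(r.source_callers))
            vcf.write(rec)


def read_variant_vcf(path, carrier_line: str | None = None) -> list[VariantRecord]:
    """Read a minimal VCF back into variant records.

    ``carrier_line`` stamps every record's carrier set (each per-line VCF
    holds exactly one line's variants).
    """
    carriers = frozenset({carrier_line}) if carrier_line else frozenset()
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else ".",
                    var_class=str(info.get("VCLASS", "SNV")),
                    impact=str(info.get("IMPACT", "MODIFIER")),
                    length=int(info.get("SVLEN", 0) or 0),
                    carrier_lines=carriers,
                    source_callers=frozenset(info.get("SRC", ())),
                )
            )
    return out
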