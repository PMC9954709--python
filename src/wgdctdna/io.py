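"""Tabular I/O: segment TSVs, cohort CSVs, plasma count TSVs, panel files.

The segment dialect follows ASCAT output: columns ``sample, chr, startpos,
endpos, nMajor, nMinor`` with 1-based inclusive coordinates, converted to
0-based half-open internally and restored on write.  Lines starting with
``#`` are treated as comments in all formats.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cn_profile import CNProfile, CNSegment
from .ctdna_caller import SiteCounts

__all__ = [
    "read_segments",
    "write_segments",
    "read_cohort",
    "write_cohort",
    "read_counts",
    "write_counts",
    "read_panel",
    "load_reference_counts",
]

SEGMENT_COLUMNS = ["sample", "chr", "startpos", "endpos", "nMajor", "nMinor"]
COUNT_COLUMNS = ["sample", "mutation_id", "fwd_alt", "fwd_total", "rev_alt", "rev_total"]


class ParseError(ValueError):
    """Malformed input row; the message carries the offending line number."""


def read_segments(path: str | Path) -> list[CNProfile]:
    """Read an ASCAT-dialect segment TSV into per-sample profiles.

    1-based inclusive input coordinates become 0-based half-open; rows are
    validated (``nMajor >= nMinor >= 0``, integer copy numbers, no overlap
    within a chromosome) with errors naming the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    by_sample: dict[str, list[CNSegment]] = {}
    header_offset = 2  # 1-based line number of the first data row (after header)
    for idx, row in df.iterrows():
        line = int(idx) + header_offset
        try:
            start1 = int(row["startpos"])
            end1 = int(row["endpos"])
            major = int(row["nMajor"])
            minor = int(row["nMinor"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{line}: non-integer field ({exc})") from None
        try:
            seg = CNSegment(str(row["chr"]), start1 - 1, end1, major, minor)
        except ValueError as exc:
            raise ParseError(f"{path}:{line}: {exc}") from None
        by_sample.setdefault(str(row["sample"]), []).append(seg)
    profiles = []
    for sample, segs in by_sample.items():
        try:
            profiles.append(CNProfile(sample_id=sample, segments=segs))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from None
    return profiles


def write_segments(profiles: Iterable[CNProfile], path: str | Path,
                   header_comments: Sequence[str] = ()) -> None:
    """Write profiles back to the 1-based inclusive ASCAT TSV dialect."""
    rows = []
    for p in profiles:
        for s in p.segments:
            rows.append((p.sample_id, s.chromosome, s.start + 1, s.end, s.major_cn, s.minor_cn))
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "ctdna_detected" in df.columns:
        df["ctdna_detected"] = df["ctdna_detected"].astype(bool)
    if "wgd" in df.columns:
        df["wgd"] = df["wgd"].astype(bool)
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path,
                 header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        cohort.to_csv(fh, index=False, float_format="%.6g")


def read_counts(path: str | Path) -> dict[str, list[SiteCounts]]:
    """Read a plasma (or panel-of-normals) counts TSV, grouped by sample."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    out: dict[str, list[SiteCounts]] = {}
    for idx, row in df.iterrows():
        try:
            sc = SiteCounts(
                str(row["mutation_id"]),
                int(row["fwd_alt"]), int(row["fwd_total"]),
                int(row["rev_alt"]), int(row["rev_total"]),
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{int(idx) + 2}: {exc}") from None
        out.setdefault(str(row["sample"]), []).append(sc)
    return out


def write_counts(counts: Mapping[str, Sequence[SiteCounts]], path: str | Path,
                 header_comments: Sequence[str] = ()) -> None:
    rows = [
        (sample, c.mutation_id, c.fwd_alt, c.fwd_total, c.rev_alt, c.rev_total)
        for sample, site_list in counts.items()
        for c in site_list
    ]
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_panel(path: str | Path) -> set[str]:
    """Read a ddPCR assay panel file: one mutation identifier per line."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def load_reference_counts() -> pd.DataFrame:
    """Stratum-level counts from a published colorectal-cancer ctDNA cohort
    (n=701), packaged for exact reproduction of its reported odds ratios.

    Columns: stratum (overall or UICC stage), characteristic, level,
    is_reference (1 for the reference level), ctdna_pos, ctdna_neg.
    """
    data_path = Path(__file__).parent / "data" / "reference_counts.tsv"
    return pd.read_csv(data_path, sep="\t", comment="#")
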