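"""Readers and writers for STR profile tables, frequency tables and results.

Profile files follow the genetic-analyzer CSV export dialect: a header row
with a sample column ("Sample File" or "Sample Name", case-insensitive), a
"Marker" column, numbered "Allele 1..k" columns and optional "Height 1..k"
columns.  Both comma- and tab-delimited files are accepted (delimiter is
sniffed), column order does not matter, and a UTF-8 byte-order mark from
Excel is tolerated.

Frequency tables use a long CSV format with header ``Marker,Allele,Frequency``
and one row per (marker, allele).  Wide NIST-style tables (one column per
population) can be converted with :func:`convert_wide_frequency_table`.
"""

from __future__ import annotations

import csv
import io
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

from .datamodel import (
    FrequencyTable,
    Genotype,
    LocusEvidence,
    LRResult,
    ReferenceProfile,
    clean_allele,
)

PathOrStream = Union[str, Path, TextIO]

_SAMPLE_HEADERS = ("sample file", "sample name")
_ALLELE_RE = re.compile(r"^allele\s*(\d+)$")
_HEIGHT_RE = re.compile(r"^height\s*(\d+)$")


@dataclass
class ProfileRow:
    sample_name: str
    marker: str
    alleles: list[str]
    heights: Optional[list[float]]


@dataclass
class ProfileTable:
    """Parsed rows of a profile export; one row per (sample, marker)."""

    rows: list[ProfileRow]

    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.sample_name)
        return list(seen)


def _open_text(source: PathOrStream) -> tuple[str, bool]:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8-sig")
    else:
        text = source.read()
        if text.startswith("﻿"):
            text = text.lstrip("﻿")
    return text, True


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def read_profiles(source: PathOrStream) -> ProfileTable:
    """Parse a genetic-analyzer style profile export (CSV or tab-delimited)."""
    text, _ = _open_text(source)
    first_line = text.splitlines()[0] if text.splitlines() else ""
    delim = _sniff_delimiter(first_line)
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    try:
        header = next(reader)
    except StopIteration:
        raise ValueError("empty profile file") from None

    norm = [h.strip().lower() for h in header]
    sample_col = marker_col = None
    allele_cols: list[tuple[int, int]] = []  # (allele number, column index)
    height_cols: dict[int, int] = {}
    for idx, h in enumerate(norm):
        if h in _SAMPLE_HEADERS and sample_col is None:
            sample_col = idx
        elif h == "marker":
            marker_col = idx
        else:
            m = _ALLELE_RE.match(h)
            if m:
                allele_cols.append((int(m.group(1)), idx))
                continue
            m = _HEIGHT_RE.match(h)
            if m:
                height_cols[int(m.group(1))] = idx
    if sample_col is None:
        raise ValueError('missing mandatory "Sample File"/"Sample Name" column')
    if marker_col is None:
        raise ValueError('missing mandatory "Marker" column')
    if not allele_cols:
        raise ValueError('no "Allele <k>" columns found')
    allele_cols.sort()

    rows: list[ProfileRow] = []
    seen: set[tuple[str, str]] = set()
    for lineno, record in enumerate(reader, start=2):
        if not record or all(not c.strip() for c in record):
            continue
        sample = record[sample_col].strip()
        marker = record[marker_col].strip()
        if not sample or not marker:
            raise ValueError(f"line {lineno}: blank sample or marker")
        key = (sample, marker)
        if key in seen:
            raise ValueError(f"line {lineno}: duplicate row for sample {sample!r} "
                             f"marker {marker!r}")
        seen.add(key)
        alleles: list[str] = []
        heights: list[float] = []
        any_height = False
        for k, col in allele_cols:
            cell = record[col].strip() if col < len(record) else ""
            if not cell:
                continue
            alleles.append(clean_allele(cell))
            hcol = height_cols.get(k)
            hcell = (
                record[hcol].strip() if hcol is not None and hcol < len(record) else ""
            )
            if hcell:
                any_height = True
                heights.append(float(hcell))
            else:
                heights.append(math.nan)
        if any_height:
            if any(math.isnan(h) for h in heights):
                raise ValueError(
                    f"line {lineno}: heights present but not aligned 1:1 with alleles"
                )
            rows.append(ProfileRow(sample, marker, alleles, heights))
        else:
            rows.append(ProfileRow(sample, marker, alleles, None))
    return ProfileTable(rows)


def write_profiles(table: ProfileTable, dest: PathOrStream) -> None:
    """Write a ProfileTable in the canonical comma-delimited export dialect."""
    max_alleles = max((len(r.alleles) for r in table.rows), default=1)
    any_heights = any(r.heights is not None for r in table.rows)
    header = ["Sample Name", "Marker"]
    header += [f"Allele {k}" for k in range(1, max_alleles + 1)]
    if any_heights:
        header += [f"Height {k}" for k in range(1, max_alleles + 1)]

    def emit(fh: TextIO) -> None:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(header)
        for r in table.rows:
            row = [r.sample_name, r.marker]
            row += list(r.alleles) + [""] * (max_alleles - len(r.alleles))
            if any_heights:
                hs = r.heights or []
                row += [repr(h) for h in hs] + [""] * (max_alleles - len(hs))
            w.writerow(row)

    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            emit(fh)
    else:
        emit(dest)


def to_evidence(table: ProfileTable, sample_name: str) -> dict[str, LocusEvidence]:
    """Build per-marker evidence from one sample's rows.

    Duplicate alleles within a row collapse to one detected allele; a marker
    row with no alleles is kept as an empty detected set (complete locus
    drop-out).
    """
    rows = [r for r in table.rows if r.sample_name == sample_name]
    if not rows:
        raise KeyError(f"sample {sample_name!r} not found in profile table")
    out: dict[str, LocusEvidence] = {}
    for r in rows:
        heights: Optional[dict[str, float]] = None
        if r.heights is not None:
            heights = {}
            for a, h in zip(r.alleles, r.heights):
                heights[a] = h  # last occurrence wins for duplicates
        out[r.marker] = LocusEvidence(
            marker=r.marker, detected=frozenset(r.alleles), heights=heights
        )
    return out


def to_reference(table: ProfileTable, sample_name: str) -> ReferenceProfile:
    """Build a reference profile; one allele means homozygous."""
    rows = [r for r in table.rows if r.sample_name == sample_name]
    if not rows:
        raise KeyError(f"sample {sample_name!r} not found in profile table")
    genotypes: dict[str, Genotype] = {}
    for r in rows:
        uniq = list(dict.fromkeys(r.alleles))
        if len(uniq) == 1:
            genotypes[r.marker] = Genotype(uniq[0], uniq[0])
        elif len(uniq) == 2:
            genotypes[r.marker] = Genotype(uniq[0], uniq[1])
        else:
            raise ValueError(
                f"reference sample {sample_name!r} has {len(uniq)} alleles at "
                f"{r.marker}; expected 1 or 2"
            )
    return ReferenceProfile(sample_name=sample_name, genotypes=genotypes)


def read_frequency_table(
    source: PathOrStream, population: str, n_individuals: int
) -> FrequencyTable:
    """Read a long-format ``Marker,Allele,Frequency`` CSV."""
    text, _ = _open_text(source)
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        raise ValueError("empty frequency file")
    fields = {f.strip().lower(): f for f in reader.fieldnames}
    for required in ("marker", "allele", "frequency"):
        if required not in fields:
            raise ValueError(f'frequency file missing "{required.title()}" column')
    freqs: dict[str, dict[str, float]] = {}
    for lineno, row in enumerate(reader, start=2):
        marker = row[fields["marker"]].strip()
        allele = clean_allele(row[fields["allele"]])
        f = float(row[fields["frequency"]])
        if not (0.0 < f <= 1.0):
            raise ValueError(f"line {lineno}: frequency {f} outside (0, 1]")
        locus = freqs.setdefault(marker, {})
        if allele in locus:
            raise ValueError(f"line {lineno}: duplicate entry for {marker}/{allele}")
        locus[allele] = f
    return FrequencyTable(population=population, n_individuals=n_individuals, freqs=freqs)


def convert_wide_frequency_table(
    source: PathOrStream,
    population_column: str,
    population: str,
    n_individuals: int,
    marker_column: str = "Marker",
    allele_column: str = "Allele",
) -> FrequencyTable:
    """Convert a wide table (one frequency column per population) to a
    FrequencyTable; blank cells mean the allele is unobserved there."""
    text, _ = _open_text(source)
    reader = csv.DictReader(io.StringIO(text))
    freqs: dict[str, dict[str, float]] = {}
    for row in reader:
        cell = (row.get(population_column) or "").strip()
        if not cell:
            continue
        marker = row[marker_column].strip()
        allele = clean_allele(row[allele_column])
        freqs.setdefault(marker, {})[allele] = float(cell)
    return FrequencyTable(population=population, n_individuals=n_individuals, freqs=freqs)


def write_results(results: Sequence[LRResult], dest: PathOrStream) -> None:
    """Write results as CSV: a parameter-echo block, then one row per marker
    with an LR column per population and a final "Overall" row."""
    if not results:
        raise ValueError("no results to write")
    params = results[0].params
    markers = list(results[0].per_locus)

    def fmt(x: float) -> str:
        if math.isinf(x):
            return "inf"
        return repr(x)

    def emit(fh: TextIO) -> None:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["# P(D_O)", repr(params.p_dropout)])
        w.writerow(["# P(D_I)", repr(params.p_dropin)])
        w.writerow(["# theta", repr(params.theta)])
        w.writerow(["# alpha", repr(params.alpha)])
        w.writerow(["# hypotheses", results[0].hypothesis])
        w.writerow(["Marker"] + [f"LR ({r.population})" for r in results] + ["Warnings"])
        for m in markers:
            notes = "; ".join(
                f"{r.population}: {r.warnings[m]}" for r in results if m in r.warnings
            )
            w.writerow([m] + [fmt(r.per_locus[m]) for r in results] + [notes])
        w.writerow(["Overall"] + [fmt(r.overall) for r in results] + [""])

    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            emit(fh)
    else:
        emit(dest)
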