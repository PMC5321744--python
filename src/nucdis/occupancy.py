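"""Gene-level ChIP occupancy quantification and genomic file I/O.

All coordinates are 0-based, half-open internally.  GFF3 input (1-based,
closed) is converted at the boundary; BED input passes through unchanged.
Coverage lives in fixed-step :class:`CoverageTrack` bins tiling each
chromosome from position 0.

A gene's occupancy is the length-weighted mean signal over its annotated
interval (mean, not sum, so gene length does not confound the value),
reported as ``log2((IP + pseudocount) / (control + pseudocount))``.  Mutant
effects are expressed as ``log2(mutant/WT)`` differences of such values.
There is no depth or spike-in normalisation: all signals are relative.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]

#: allowed per-column metadata tags on gene tables
COLUMN_TAGS = ("log2_ip_over_input", "log2_mutant_over_wt", "linear")

_GFF3_ID_RE = re.compile(r"(?:^|;)\s*(?:ID|gene_id|Name)=([^;]+)")


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Fixed-step numeric signal per chromosome.

    ``data[chrom]`` holds one value per ``step_bp`` bin; bin *i* covers the
    half-open interval ``[i*step_bp, (i+1)*step_bp)``.  Raw coverage is
    non-negative; log-ratio tracks may hold any real value.
    """

    step_bp: int
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.step_bp <= 0:
            raise ValidationError(f"step_bp must be positive, got {self.step_bp}")
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom]) * self.step_bp

    @property
    def chromosomes(self) -> list[str]:
        return list(self.data)


@dataclass
class GeneOccupancyTable:
    """Genes x samples matrix of occupancy values with per-column scale tags.

    ``values`` is indexed by gene_id; ``tags`` maps every column to one of
    ``log2_ip_over_input``, ``log2_mutant_over_wt`` or ``linear``.
    """

    values: pd.DataFrame
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()][:3].tolist()
            raise ValidationError(f"duplicated gene_ids in table: {dupes}")
        for col in self.values.columns:
            tag = self.tags.setdefault(col, "linear")
            if tag not in COLUMN_TAGS:
                raise ValidationError(f"unknown tag {tag!r} for column {col!r}")

    def column(self, name: str) -> pd.Series:
        return self.values[name]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

def _validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return df
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "gene_id"].iloc[0]
        raise ValidationError(f"gene {bad!r} has start >= end")
    if df["gene_id"].duplicated().any():
        bad = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene_id {bad!r} in annotation")
    if not df["strand"].isin(["+", "-"]).all():
        bad = df.loc[~df["strand"].isin(["+", "-"]), "strand"].iloc[0]
        raise ValidationError(f"invalid strand {bad!r}; expected '+' or '-'")
    return df.reset_index(drop=True)


def read_gene_annotation(
    path: str | Path,
    format: str = "gff3",
    feature_type: str = "gene",
) -> pd.DataFrame:
    """Read a gene annotation into internal 0-based half-open coordinates.

    Parameters
    ----------
    path
        GFF3 or BED6 file.
    format
        ``gff3`` (1-based closed, converted; only ``feature_type`` records
        kept) or ``bed`` (already 0-based half-open).
    feature_type
        GFF3 feature column filter, default ``gene``.

    Returns
    -------
    DataFrame with columns gene_id, chrom, start, end, strand.
    """
    path = Path(path)
    if format not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation format {format!r}")
    records: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "gff3":
                if len(fields) != 9:
                    raise FormatError(
                        f"{path.name}:{lineno}: expected 9 GFF3 fields, got {len(fields)}"
                    )
                if fields[2] != feature_type:
                    continue
                try:
                    start1, end1 = int(fields[3]), int(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path.name}:{lineno}: non-integer coordinate") from exc
                m = _GFF3_ID_RE.search(fields[8])
                if m is None:
                    raise FormatError(f"{path.name}:{lineno}: no ID in attributes column")
                records.append((m.group(1), fields[0], start1 - 1, end1, fields[6]))
            else:  # bed
                if len(fields) < 6:
                    raise FormatError(
                        f"{path.name}:{lineno}: expected >= 6 BED fields, got {len(fields)}"
                    )
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise FormatError(f"{path.name}:{lineno}: non-integer coordinate") from exc
                records.append((fields[3], fields[0], start, end, fields[5]))
    if not records:
        logger.warning("annotation %s yielded no gene records", path)
    df = pd.DataFrame(records, columns=ANNOTATION_COLUMNS)
    return _validate_annotation(df)


def write_gene_annotation_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write the internal annotation as GFF3 (coordinates converted back)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tnucdis\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom.sizes`` TSV."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(f"chrom.sizes line {lineno}: expected 2 fields")
            sizes[fields[0]] = int(fields[1])
    return sizes


# ---------------------------------------------------------------------------
# coverage I/O and rasterization
# ---------------------------------------------------------------------------

def read_coverage_bedgraph(
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    step_bp: int,
) -> CoverageTrack:
    """Rasterize a bedGraph onto fixed ``step_bp`` bins.

    Interval values are spread by length-weighted averaging into the bins
    they overlap; uncovered positions contribute 0.  Intervals must be
    non-overlapping and lie within the declared chromosome sizes.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep=r"\s+", comment="#", header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
            skip_blank_lines=True,
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse bedGraph {path.name}: {exc}") from exc

    tracks: dict[str, np.ndarray] = {
        chrom: np.zeros(-(-size // step_bp), dtype=float)
        for chrom, size in chrom_sizes.items()
    }
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in chrom_sizes:
            raise ValidationError(f"bedGraph chromosome {chrom!r} not in chrom sizes")
        size = chrom_sizes[chrom]
        if (sub["end"] > size).any() or (sub["start"] < 0).any():
            raise ValidationError(f"bedGraph interval outside chromosome {chrom!r} [0, {size})")
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValidationError(f"overlapping bedGraph intervals on {chrom!r}")
        acc = tracks[chrom]
        for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
            _deposit(acc, step_bp, int(start), int(end), float(value))
    for chrom in tracks:
        tracks[chrom] /= step_bp
    return CoverageTrack(step_bp=step_bp, data=tracks)


def _deposit(acc: np.ndarray, step: int, start: int, end: int, value: float) -> None:
    """Add value*overlap_length of [start, end) into bin accumulator."""
    i0, i1 = start // step, -(-end // step)
    w = np.full(i1 - i0, float(step))
    w[0] -= start - i0 * step
    w[-1] -= i1 * step - end
    if i1 - i0 == 1:
        w[0] = end - start
    acc[i0:i1] += value * w


def write_coverage_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph, merging runs of equal adjacent bins."""
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            values = track.data[chrom]
            if len(values) == 0:
                continue
            breaks = np.flatnonzero(np.diff(values) != 0) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [len(values)]))
            for s, e in zip(starts, ends):
                fh.write(
                    f"{chrom}\t{s * track.step_bp}\t{e * track.step_bp}\t{float(values[s])!r}\n"
                )


def interval_mean(
    values: np.ndarray,
    step: float,
    start: float,
    end: float,
    oob: str = "error",
) -> float:
    """Length-weighted mean of a piecewise-constant binned signal on [start, end).

    ``oob`` controls positions outside the track: ``error`` raises,
    ``zero`` treats them as signal 0 (denominator stays end - start),
    ``nan`` returns NaN for any out-of-range window.
    """
    if end <= start:
        raise ValidationError(f"empty interval [{start}, {end})")
    extent = len(values) * step
    if start < 0 or end > extent:
        if oob == "error":
            raise ValidationError(
                f"interval [{start}, {end}) outside track extent [0, {extent})"
            )
        if oob == "nan":
            return float("nan")
    lo, hi = max(start, 0.0), min(end, extent)
    if lo >= hi:
        return 0.0  # oob == "zero": fully outside
    i0, i1 = int(np.floor(lo / step)), int(np.ceil(hi / step))
    w = np.full(i1 - i0, float(step))
    w[0] -= lo - i0 * step
    w[-1] -= i1 * step - hi
    if i1 - i0 == 1:
        w[0] = hi - lo
    return float(np.dot(values[i0:i1], w)) / (end - start)


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def gene_level_occupancy(
    ip: CoverageTrack,
    control: CoverageTrack,
    genes: pd.DataFrame,
    pseudocount: float = 0.01,
    column: str = "occupancy",
) -> tuple[GeneOccupancyTable, pd.DataFrame]:
    """Per-gene ``log2((mean IP + pc) / (mean control + pc))`` over the ORF.

    Genes whose control mean is exactly 0 before the pseudocount, or that
    fall outside the track extent, are excluded and listed (with a reason)
    in the returned exclusions frame rather than raising.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if ip.step_bp != control.step_bp:
        raise ValidationError(
            f"IP and control step mismatch: {ip.step_bp} vs {control.step_bp}"
        )
    rows: dict[str, float] = {}
    excluded: list[tuple[str, str]] = []
    for row in genes.itertuples(index=False):
        try:
            ip_mean = interval_mean(ip.data[row.chrom], ip.step_bp, row.start, row.end)
            ctrl_mean = interval_mean(
                control.data[row.chrom], control.step_bp, row.start, row.end
            )
        except (KeyError, ValidationError) as exc:
            excluded.append((row.gene_id, f"outside track extent: {exc}"))
            continue
        if ctrl_mean == 0.0:
            excluded.append((row.gene_id, "zero control coverage"))
            continue
        rows[row.gene_id] = float(
            np.log2((ip_mean + pseudocount) / (ctrl_mean + pseudocount))
        )
    if excluded:
        logger.info("gene_level_occupancy excluded %d genes", len(excluded))
    table = GeneOccupancyTable(
        values=pd.DataFrame({column: pd.Series(rows, dtype=float)}),
        tags={column: "log2_ip_over_input"},
    )
    exclusions = pd.DataFrame(excluded, columns=["gene_id", "reason"])
    return table, exclusions


def occupancy_change(mutant: pd.Series, wildtype: pd.Series) -> pd.Series:
    """log2(mutant/WT) change as the difference of two log2 occupancy columns.

    Gene universes are inner-joined; disjoint sets are an error.
    """
    shared = mutant.index.intersection(wildtype.index)
    if len(shared) == 0:
        raise ValidationError("mutant and wildtype columns share no genes")
    dropped = max(len(mutant), len(wildtype)) - len(shared)
    if dropped:
        logger.info("occupancy_change: %d genes outside the shared universe", dropped)
    return (mutant.loc[shared] - wildtype.loc[shared]).rename(
        f"{mutant.name or 'mutant'}_minus_{wildtype.name or 'wt'}"
    )


# ---------------------------------------------------------------------------
# gene table I/O
# ---------------------------------------------------------------------------

_TAG_HEADER = "# tags:"


def write_gene_table(table: GeneOccupancyTable, path: str | Path) -> None:
    """Write a gene table as TSV, ``gene_id`` first; float repr round-trips."""
    with open(path, "w") as fh:
        tags = " ".join(f"{c}={table.tags[c]}" for c in table.values.columns)
        fh.write(f"{_TAG_HEADER} {tags}\n")
        out = table.values.copy()
        out.index.name = "gene_id"
        out.to_csv(fh, sep="\t", na_rep="")


def read_gene_table(path: str | Path) -> GeneOccupancyTable:
    """Read a TSV gene table; first column must be ``gene_id``."""
    path = Path(path)
    tags: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith(_TAG_HEADER):
            skip = 1
            for item in first[len(_TAG_HEADER):].split():
                col, _, tag = item.partition("=")
                tags[col] = tag
    try:
        df = pd.read_csv(path, sep="\t", skiprows=skip)
    except pd.errors.ParserError as exc:
        raise FormatError(f"cannot parse gene table {path.name}: {exc}") from exc
    if df.columns[0] != "gene_id":
        raise FormatError(
            f"gene table {path.name}: first column must be 'gene_id', got {df.columns[0]!r}"
        )
    df = df.set_index("gene_id")
    return GeneOccupancyTable(values=df, tags={c: tags.get(c, "linear") for c in df.columns})
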