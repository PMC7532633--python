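"""Reading and writing per-CpG methylation tables and interval outputs.

The on-disk format is the methcounts-style 6-column text used throughout
the MethPipe ecosystem::

    chrom  position  strand  context  level  coverage

with ``level`` the fraction of reads reporting methylation and ``coverage``
the read count at the site. Positions are treated as 0-based single-base
coordinates; all intervals (BED output included) are 0-based half-open.

The number of methylated reads at a site is recovered once, at read time,
as ``round(level * coverage)`` and carried alongside the raw fields; no
later step re-derives it.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .domains import PmdSet
from .errors import ChromosomeNotFoundError, ConsistencyError, OrderingError, ParseError

METHCOUNTS_COLUMNS = ["chrom", "pos", "strand", "context", "level", "coverage"]

_SITE_DTYPES = {
    "pos": np.int64,
    "strand": object,
    "context": object,
    "level": np.float64,
    "coverage": np.int64,
    "meth": np.int64,
}


@dataclass(frozen=True)
class CpGSite:
    """One symmetric-CpG observation: position, strand, context, level, coverage."""

    chrom: str
    pos: int
    strand: str
    context: str
    level: float
    coverage: int

    @property
    def meth(self) -> int:
        """Methylated-read count recovered as round(level * coverage)."""
        return int(round(self.level * self.coverage))


@dataclass
class Methylome:
    """Per-chromosome ordered site tables plus chromosome lengths.

    ``sites[chrom]`` is a DataFrame with columns pos, strand, context,
    level, coverage, meth; positions strictly increase within a chromosome
    and are below the chromosome length.
    """

    chrom_sizes: dict[str, int]
    sites: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, df in self.sites.items():
            if chrom not in self.chrom_sizes:
                raise ChromosomeNotFoundError(f"no length for chromosome {chrom!r}")
            pos = df["pos"].to_numpy()
            if pos.size and np.any(np.diff(pos) <= 0):
                raise OrderingError(f"{chrom}: positions not strictly increasing")
            if pos.size and pos[-1] >= self.chrom_sizes[chrom]:
                raise ConsistencyError(
                    f"{chrom}: position {pos[-1]} beyond chromosome length "
                    f"{self.chrom_sizes[chrom]}"
                )

    @property
    def chroms(self) -> list[str]:
        return list(self.sites)

    @property
    def n_sites(self) -> int:
        return sum(len(df) for df in self.sites.values())

    @property
    def total_coverage(self) -> int:
        return int(sum(df["coverage"].sum() for df in self.sites.values()))

    @property
    def genome_size(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def iter_sites(self) -> Iterator[CpGSite]:
        for chrom, df in self.sites.items():
            for row in df.itertuples(index=False):
                yield CpGSite(chrom, int(row.pos), row.strand, row.context,
                              float(row.level), int(row.coverage))


def _finalize_site_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Recover methylated counts and normalise zero-coverage levels to 0."""
    df = df.copy()
    zero = df["coverage"].to_numpy() == 0
    if zero.any():
        df.loc[zero, "level"] = 0.0
    df["meth"] = np.rint(df["level"].to_numpy() * df["coverage"].to_numpy()).astype(np.int64)
    return df.astype({k: v for k, v in _SITE_DTYPES.items() if k in df.columns})


def make_methylome(
    chrom_sizes: Mapping[str, int],
    records: Mapping[str, Mapping[str, np.ndarray]],
) -> Methylome:
    """Assemble a Methylome from per-chromosome arrays (pos, level, coverage...)."""
    sites = {}
    for chrom, arrays in records.items():
        n = len(arrays["pos"])
        df = pd.DataFrame(
            {
                "pos": np.asarray(arrays["pos"], dtype=np.int64),
                "strand": arrays.get("strand", np.full(n, "+", dtype=object)),
                "context": arrays.get("context", np.full(n, "CpG", dtype=object)),
                "level": np.asarray(arrays["level"], dtype=float),
                "coverage": np.asarray(arrays["coverage"], dtype=np.int64),
            }
        )
        sites[chrom] = _finalize_site_frame(df)
    return Methylome(dict(chrom_sizes), sites)


def read_methcounts(path: str | Path, chrom_sizes: Mapping[str, int]) -> Methylome:
    """Read a methcounts 6-column table into a validated :class:`Methylome`.

    Raises :class:`ParseError` (with line number) on malformed lines,
    :class:`OrderingError` on unsorted positions and
    :class:`ChromosomeNotFoundError` when a chromosome is missing from
    ``chrom_sizes``.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(
            path, sep=r"\s+", header=None, names=METHCOUNTS_COLUMNS, dtype=str,
            comment="#", skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return Methylome(dict(chrom_sizes), {})
    if raw.isna().any(axis=None):
        bad = int(raw.isna().any(axis=1).to_numpy().argmax()) + 1
        raise ParseError(f"{path}:{bad}: expected 6 whitespace-delimited columns")

    def _numeric(col: str, caster, what: str) -> np.ndarray:
        converted = pd.to_numeric(raw[col], errors="coerce")
        if converted.isna().any():
            bad = int(converted.isna().to_numpy().argmax()) + 1
            raise ParseError(f"{path}:{bad}: {what} is not numeric: {raw[col].iloc[bad-1]!r}")
        return converted.to_numpy(caster)

    pos = _numeric("pos", np.int64, "position")
    level = _numeric("level", np.float64, "methylation level")
    coverage = _numeric("coverage", np.int64, "coverage")
    if np.any((level < 0) | (level > 1)):
        bad = int(np.argmax((level < 0) | (level > 1))) + 1
        raise ParseError(f"{path}:{bad}: methylation level {level[bad-1]} outside [0, 1]")
    if np.any(coverage < 0):
        bad = int(np.argmax(coverage < 0)) + 1
        raise ParseError(f"{path}:{bad}: negative coverage {coverage[bad-1]}")
    if np.any(pos < 0):
        bad = int(np.argmax(pos < 0)) + 1
        raise ParseError(f"{path}:{bad}: negative position {pos[bad-1]}")

    df = pd.DataFrame(
        {
            "chrom": raw["chrom"].to_numpy(object),
            "pos": pos,
            "strand": raw["strand"].to_numpy(object),
            "context": raw["context"].to_numpy(object),
            "level": level,
            "coverage": coverage,
        }
    )
    sites: dict[str, pd.DataFrame] = {}
    for chrom in df["chrom"].unique():
        sub = df[df["chrom"] == chrom].drop(columns="chrom").reset_index(drop=True)
        sites[str(chrom)] = _finalize_site_frame(sub)
    return Methylome(dict(chrom_sizes), sites)


def write_methcounts(meth: Methylome, path: str | Path) -> None:
    """Write a Methylome back to 6-column text, levels at 6 decimals."""
    with open(path, "w") as fh:
        for chrom, df in meth.sites.items():
            for row in df.itertuples(index=False):
                fh.write(
                    f"{chrom}\t{row.pos}\t{row.strand}\t{row.context}\t"
                    f"{row.level:.6f}\t{row.coverage}\n"
                )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom.sizes file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: length {parts[1]!r} not an integer")
    return sizes


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def write_pmds_bed(pmds: PmdSet, path: str | Path) -> None:
    """Serialize a PmdSet as BED6; the score column holds the mean posterior
    scaled to an integer in [0, 1000]."""
    pmds.validate()
    with open(path, "w") as fh:
        for i, row in enumerate(pmds.df.itertuples(index=False), 1):
            score = int(round(min(max(float(row.score), 0.0), 1.0) * 1000))
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tPMD_{i}\t{score}\t.\n")


def read_pmds_bed(path: str | Path, sample_id: str = "") -> PmdSet:
    """Read a BED file of domains back into a PmdSet (score rescaled to [0,1])."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED line needs >=3 columns")
            score = float(parts[4]) / 1000.0 if len(parts) >= 5 else 1.0
            rows.append((parts[0], int(parts[1]), int(parts[2]), score, 0))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "n_bins"])
    return PmdSet(df, sample_id=sample_id)


def read_bed_features(path: str | Path) -> pd.DataFrame:
    """Read BED3+ into a frame with chrom, start, end, name, strand."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED line needs >=3 columns")
            name = parts[3] if len(parts) >= 4 else f"feature_{lineno}"
            strand = parts[5] if len(parts) >= 6 else "."
            rows.append((parts[0], int(parts[1]), int(parts[2]), name, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
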