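"""Percent-methylation calling, locus QC, and coverage-file I/O.

The count container holds methylated/unmethylated read counts per
(sample, locus); an absent cell is a missing datum, never an implicit zero.
QC drops a locus if it is missing in any sample or if any sample's coverage
at it falls below ``min_reads`` (default 10); the retained matrix therefore
has no missing cells.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical 5'->3' order of the rDNA regions used for locus sorting
REGION_ORDER = ("18S", "ITS1", "ITS2", "28S")


class CoverageParseError(ValueError):
    """Raised for a malformed coverage-file row; carries the line number."""


class EmptyMatrixError(ValueError):
    """Raised when QC removes every locus."""


def _region_rank(region: str) -> tuple[int, str]:
    try:
        return (REGION_ORDER.index(region), region)
    except ValueError:
        return (len(REGION_ORDER), region)


def locus_sort_key(locus_id: str) -> tuple[int, str, int]:
    region, _, pos = locus_id.rpartition("_")
    return (*_region_rank(region), int(pos))


def percent_methylation(count_meth: int, count_unmeth: int) -> float:
    """Percent of informative reads reporting methylation.

    Returns ``nan`` (a missing datum, not 0%) when both counts are zero.
    """
    if count_meth < 0 or count_unmeth < 0:
        raise ValueError(f"counts must be non-negative, got ({count_meth}, {count_unmeth})")
    total = count_meth + count_unmeth
    if total == 0:
        return math.nan
    return 100.0 * count_meth / total


def conversion_rate(count_c: int, count_t: int, threshold: float = 99.0) -> tuple[float, bool]:
    """Bisulphite conversion rate from non-CpG cytosine counts.

    Returns ``(percent_converted, flagged)`` where ``flagged`` is True when
    the rate falls below ``threshold``. Zero total reads yields ``nan``
    (missing) and no flag.
    """
    if count_c < 0 or count_t < 0:
        raise ValueError("counts must be non-negative")
    total = count_c + count_t
    if total == 0:
        return math.nan, False
    rate = 100.0 * count_t / total
    return rate, rate < threshold


@dataclass
class MethylCountTable:
    """Methylated/unmethylated read counts per (sample, locus).

    ``meth`` and ``unmeth`` are aligned samples x loci frames of float counts
    with NaN marking a missing cell (both frames share the NaN mask).
    ``loci`` maps locus_id -> (region, position).
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    loci: pd.DataFrame  # index locus_id, columns: region, position

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.unmeth.index) or not self.meth.columns.equals(
            self.unmeth.columns
        ):
            raise ValueError("meth and unmeth frames must be aligned")
        for frame in (self.meth, self.unmeth):
            vals = frame.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0) < 0:
                raise ValueError("read counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.meth.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.meth.columns)

    def coverage(self) -> pd.DataFrame:
        return self.meth + self.unmeth

    def missing_mask(self) -> pd.DataFrame:
        return self.meth.isna() | self.unmeth.isna()

    @classmethod
    def from_records(
        cls, records: dict[tuple[str, str], tuple[int, int]], loci: pd.DataFrame | None = None
    ) -> "MethylCountTable":
        """Build from a {(sample_id, locus_id): (meth, unmeth)} mapping."""
        samples = sorted({s for s, _ in records})
        locus_ids = sorted({l for _, l in records}, key=locus_sort_key)
        meth = pd.DataFrame(np.nan, index=samples, columns=locus_ids)
        unmeth = pd.DataFrame(np.nan, index=samples, columns=locus_ids)
        for (s, l), (m, u) in records.items():
            meth.at[s, l] = m
            unmeth.at[s, l] = u
        if loci is None:
            parsed = [locus_id.rpartition("_") for locus_id in locus_ids]
            loci = pd.DataFrame(
                {"region": [p[0] for p in parsed], "position": [int(p[2]) for p in parsed]},
                index=pd.Index(locus_ids, name="locus_id"),
            )
        return cls(meth=meth, unmeth=unmeth, loci=loci)


@dataclass
class MethylationMatrix:
    """Samples x loci percent-methylation values after QC (no missing cells)."""

    values: pd.DataFrame
    loci: pd.DataFrame  # index locus_id, columns region, position

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "sample_id"
        out.to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MethylationMatrix":
        values = pd.read_csv(path, index_col="sample_id")
        parsed = [c.rpartition("_") for c in values.columns]
        loci = pd.DataFrame(
            {"region": [p[0] for p in parsed], "position": [int(p[2]) for p in parsed]},
            index=pd.Index(values.columns, name="locus_id"),
        )
        return cls(values=values, loci=loci)


@dataclass
class QCReport:
    n_loci_input: int
    n_loci_retained: int
    drop_reasons: dict[str, str] = field(default_factory=dict)  # locus_id -> reason
    min_coverage_per_sample: dict[str, float] = field(default_factory=dict)
    mean_coverage_per_sample: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_loci_input": self.n_loci_input,
                    "n_loci_retained": self.n_loci_retained,
                    "drop_reasons": self.drop_reasons,
                    "min_coverage_per_sample": self.min_coverage_per_sample,
                    "mean_coverage_per_sample": self.mean_coverage_per_sample,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )


def apply_qc(
    table: MethylCountTable, samples: list[str] | None = None, min_reads: int = 10
) -> tuple[MethylationMatrix, QCReport]:
    """Drop loci missing in any sample or under-covered in any sample.

    A locus is removed iff (a) it is missing in >=1 sample, or (b) any
    sample's coverage (meth + unmeth reads) at it is < ``min_reads``.
    The recorded drop reason is the first failing rule: missing before
    low_coverage. Retained loci are ordered by (region, position).
    """
    if samples is None:
        samples = table.samples
    if len(samples) == 0:
        raise ValueError("at least one sample is required")
    missing_samples = [s for s in samples if s not in table.meth.index]
    if missing_samples:
        raise ValueError(f"samples absent from count table: {missing_samples}")

    meth = table.meth.loc[samples]
    unmeth = table.unmeth.loc[samples]
    cov = meth + unmeth

    drop_reasons: dict[str, str] = {}
    for locus in table.locus_ids:
        col_missing = meth[locus].isna() | unmeth[locus].isna()
        if col_missing.any():
            drop_reasons[locus] = "missing"
        elif (cov[locus] < min_reads).any():
            drop_reasons[locus] = "low_coverage"

    retained = [l for l in table.locus_ids if l not in drop_reasons]
    retained.sort(key=lambda l: (_region_rank(table.loci.at[l, "region"]), table.loci.at[l, "position"]))
    if not retained:
        raise EmptyMatrixError(
            f"QC removed all {len(table.locus_ids)} loci (min_reads={min_reads})"
        )

    with np.errstate(invalid="ignore"):
        pct = 100.0 * meth[retained] / cov[retained]
    matrix = MethylationMatrix(values=pct, loci=table.loci.loc[retained].copy())
    report = QCReport(
        n_loci_input=len(table.locus_ids),
        n_loci_retained=len(retained),
        drop_reasons=drop_reasons,
        min_coverage_per_sample={s: float(np.nanmin(cov.loc[s])) for s in samples},
        mean_coverage_per_sample={s: float(np.nanmean(cov.loc[s])) for s in samples},
    )
    return matrix, report


# ---------------------------------------------------------------------------
# Bismark-style coverage files: one per sample, tab-separated
#   chromosome  start  end  percent_methylation  count_methylated  count_unmethylated
# with 1-based inclusive coordinates and the rDNA region name as chromosome.
# ---------------------------------------------------------------------------

def read_coverage_file(path: str | Path) -> pd.DataFrame:
    """Read one sample's coverage file.

    Returns a frame with columns (locus_id, region, position, count_meth,
    count_unmeth). Emits a warning for an empty file or when the percent
    column disagrees with the counts by more than 0.01.
    """
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise CoverageParseError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, got {len(parts)}"
                )
            region, start_s, end_s, pct_s, meth_s, unmeth_s = parts
            try:
                start, end = int(start_s), int(end_s)
                pct = float(pct_s)
                meth, unmeth = int(meth_s), int(unmeth_s)
            except ValueError as exc:
                raise CoverageParseError(f"{path}:{lineno}: {exc}") from exc
            if meth < 0 or unmeth < 0:
                raise CoverageParseError(f"{path}:{lineno}: negative read count")
            if start < 1 or end < start:
                raise CoverageParseError(f"{path}:{lineno}: bad coordinates {start}-{end}")
            expected = percent_methylation(meth, unmeth)
            if not math.isnan(expected) and abs(expected - pct) > 0.01:
                warnings.warn(
                    f"{path}:{lineno}: percent column {pct} inconsistent with counts "
                    f"({expected:.4f})",
                    stacklevel=2,
                )
            rows.append((f"{region}_{start}", region, start, meth, unmeth))
    if not rows:
        warnings.warn(f"{path}: empty coverage file", stacklevel=2)
    return pd.DataFrame(
        rows, columns=["locus_id", "region", "position", "count_meth", "count_unmeth"]
    )


def write_coverage_file(counts: pd.DataFrame, path: str | Path) -> None:
    """Write one sample's counts in the 6-column coverage dialect.

    ``counts`` needs columns (region, position, count_meth, count_unmeth);
    the percent column is recomputed from the counts and rounded to six
    decimals. Sites are written in (region, position) order.
    """
    path = Path(path)
    ordered = counts.sort_values(
        by=["region", "position"], key=lambda col: col.map(_region_rank) if col.name == "region" else col
    )
    with path.open("w") as fh:
        for row in ordered.itertuples(index=False):
            meth, unmeth = int(row.count_meth), int(row.count_unmeth)
            if meth < 0 or unmeth < 0:
                raise ValueError("negative read count")
            pct = percent_methylation(meth, unmeth)
            pct_s = "NA" if math.isnan(pct) else f"{round(pct, 6):g}"
            fh.write(f"{row.region}\t{row.position}\t{row.position}\t{pct_s}\t{meth}\t{unmeth}\n")


def read_count_dir(
    counts_dir: str | Path, sample_ids: list[str] | None = None, suffix: str = ".cov"
) -> MethylCountTable:
    """Assemble a count table from per-sample coverage files in a directory.

    Files are named ``<sample_id><suffix>``. When ``sample_ids`` is given only
    those files are read (and all must exist); otherwise every ``*<suffix>``
    file is used.
    """
    counts_dir = Path(counts_dir)
    if sample_ids is None:
        paths = sorted(counts_dir.glob(f"*{suffix}"))
        sample_ids = [p.name[: -len(suffix)] for p in paths]
    else:
        paths = [counts_dir / f"{s}{suffix}" for s in sample_ids]
        for p in paths:
            if not p.exists():
                raise FileNotFoundError(p)
    records: dict[tuple[str, str], tuple[int, int]] = {}
    loci_rows: dict[str, tuple[str, int]] = {}
    for sample_id, p in zip(sample_ids, paths):
        frame = read_coverage_file(p)
        for row in frame.itertuples(index=False):
            records[(sample_id, row.locus_id)] = (row.count_meth, row.count_unmeth)
            loci_rows[row.locus_id] = (row.region, row.position)
    if not records:
        raise ValueError(f"no count data found in {counts_dir}")
    loci = pd.DataFrame(
        {
            "region": [loci_rows[l][0] for l in sorted(loci_rows, key=locus_sort_key)],
            "position": [loci_rows[l][1] for l in sorted(loci_rows, key=locus_sort_key)],
        },
        index=pd.Index(sorted(loci_rows, key=locus_sort_key), name="locus_id"),
    )
    table = MethylCountTable.from_records(records, loci=loci)
    # ensure every requested sample has a row even if its file was empty
    absent = [s for s in sample_ids if s not in table.meth.index]
    if absent:
        pad = pd.DataFrame(np.nan, index=absent, columns=table.meth.columns)
        table = MethylCountTable(
            meth=pd.concat([table.meth, pad]).loc[sample_ids],
            unmeth=pd.concat([table.unmeth, pad]).loc[sample_ids],
            loci=table.loci,
        )
    return table
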