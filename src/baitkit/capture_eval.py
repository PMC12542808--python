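"""Per-sample capture recovery statistics and their summaries.

Mirrors the per-sample assembly summary a capture experiment reports: raw
and on-target read counts, how many panel loci received reads / yielded a
sequence / were recovered beyond 50% and 75% of the target length, paralog
warnings, and total recovered bases — plus column-wise Average/Sum/min/max
summaries and sample x locus recovery matrices for heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_away
from .config import DesignConfig
from .errors import DataError, DegenerateFitError, EmptyInputError

#: Numeric columns of a sample-statistics table, in report order.
STATS_COLUMNS = [
    "n_reads", "n_on_target", "pct_on_target", "n_loci_with_reads",
    "n_loci_with_seq", "n_loci_50", "n_loci_75",
    "n_paralog_len", "n_paralog_depth", "total_bases",
]


@dataclass
class LocusRecovery:
    """Recovery of one locus in one sample."""

    recovered_len: int
    target_len: float
    has_reads: bool = True
    has_seq: bool | None = None  # default: recovered_len > 0
    paralog_len: bool = False
    paralog_depth: bool = False

    def __post_init__(self) -> None:
        if self.has_seq is None:
            self.has_seq = self.recovered_len > 0


@dataclass
class SampleRecoveryRecord:
    """All per-locus recovery data for one sample."""

    sample_id: str
    total_reads: int
    mapped_reads: int
    loci: dict[str, LocusRecovery] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mapped_reads > self.total_reads:
            raise DataError(
                f"{self.sample_id}: mapped_reads {self.mapped_reads} > "
                f"total_reads {self.total_reads}"
            )


@dataclass
class SampleStatsRow:
    """One row of the per-sample summary table."""

    sample_id: str
    n_reads: int
    n_on_target: int
    pct_on_target: float
    n_loci_with_reads: int
    n_loci_with_seq: int
    n_loci_50: int
    n_loci_75: int
    n_paralog_len: int
    n_paralog_depth: int
    total_bases: int


@dataclass
class SummaryRow:
    """Column-wise Average / Sum / min / max over sample rows.

    ``min``/``max`` map each column to ``(value, [sample ids attaining it])``.
    """

    mean: dict[str, float]
    sum: dict[str, float]
    min: dict[str, tuple[float, list[str]]]
    max: dict[str, tuple[float, list[str]]]


def build_sample_stats(
    record: SampleRecoveryRecord,
    config: DesignConfig | None = None,
    strict_greater: bool = True,
) -> SampleStatsRow:
    """Reduce one sample's per-locus recoveries to a summary row.

    Recovery-threshold counts use strict ">" ("more than 50%/75% of the
    target length"); ``strict_greater=False`` switches to ">=" for
    sensitivity analysis.  The on-target percentage is reported to 1 decimal.
    """
    config = config or DesignConfig()
    thresholds = sorted(config.recovery_thresholds)
    counts = dict.fromkeys(thresholds, 0)
    n_reads_loci = n_seq_loci = n_para_len = n_para_depth = total_bases = 0
    for locus, rec in record.loci.items():
        if rec.target_len <= 0:
            raise DataError(
                f"{record.sample_id}/{locus}: target length {rec.target_len}"
            )
        n_reads_loci += rec.has_reads
        n_seq_loci += rec.has_seq
        n_para_len += rec.paralog_len
        n_para_depth += rec.paralog_depth
        total_bases += rec.recovered_len
        for thr in thresholds:
            cut = thr * rec.target_len
            if (rec.recovered_len > cut) if strict_greater else (
                rec.recovered_len >= cut
            ):
                counts[thr] += 1
    pct = round_half_away(100.0 * record.mapped_reads / record.total_reads, 1)

    def _count_at(frac: float) -> int:
        for thr in thresholds:
            if abs(thr - frac) < 1e-9:
                return counts[thr]
        return 0

    return SampleStatsRow(
        sample_id=record.sample_id,
        n_reads=record.total_reads,
        n_on_target=record.mapped_reads,
        pct_on_target=pct,
        n_loci_with_reads=n_reads_loci,
        n_loci_with_seq=n_seq_loci,
        n_loci_50=_count_at(0.50),
        n_loci_75=_count_at(0.75),
        n_paralog_len=n_para_len,
        n_paralog_depth=n_para_depth,
        total_bases=total_bases,
    )


def stats_frame(rows: list[SampleStatsRow]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in rows]).set_index("sample_id")
    return df[STATS_COLUMNS]


def summarize_stats(rows: list[SampleStatsRow]) -> SummaryRow:
    """Column means (1 decimal, half away from zero), sums, and extremes.

    Sums are exact; min/max carry the sample ids attaining them.
    """
    if not rows:
        raise EmptyInputError("summarize_stats needs >= 1 row")
    df = stats_frame(rows)
    mean = {
        col: round_half_away(float(df[col].mean()), 1) for col in df.columns
    }
    # The summary on-target percentage follows the convention of published
    # assembly-statistics tables: it is the ratio of the averaged counts
    # (equivalently of the column sums), not the mean of per-row percentages.
    mean["pct_on_target"] = round_half_away(
        100.0 * float(df["n_on_target"].sum()) / float(df["n_reads"].sum()), 1
    )
    total = {col: float(df[col].sum()) for col in df.columns}
    lo, hi = {}, {}
    for col in df.columns:
        vmin, vmax = df[col].min(), df[col].max()
        lo[col] = (float(vmin), sorted(df.index[df[col] == vmin]))
        hi[col] = (float(vmax), sorted(df.index[df[col] == vmax]))
    return SummaryRow(mean=mean, sum=total, min=lo, max=hi)


def recovery_matrix(
    records: list[SampleRecoveryRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample x locus matrices for heatmaps.

    The first matrix holds recovered/target fractions capped at 1.0 (missing
    loci are 0.0); the second holds paralog-warning counts per cell (0-2,
    one point each for the length- and depth-based flags).  Rows follow the
    input sample order; columns are locus ids ascending.
    """
    all_loci = sorted({loc for rec in records for loc in rec.loci})
    samples = [rec.sample_id for rec in records]
    frac = np.zeros((len(records), len(all_loci)))
    para = np.zeros((len(records), len(all_loci)), dtype=int)
    for i, rec in enumerate(records):
        for j, locus in enumerate(all_loci):
            lr = rec.loci.get(locus)
            if lr is None:
                continue
            frac[i, j] = min(1.0, lr.recovered_len / lr.target_len)
            para[i, j] = int(lr.paralog_len) + int(lr.paralog_depth)
    return (
        pd.DataFrame(frac, index=samples, columns=all_loci),
        pd.DataFrame(para, index=samples, columns=all_loci),
    )


def linear_r2(x, y) -> float:
    """Ordinary least squares R-squared, reported to 3 decimals.

    Constant ``y`` returns 0.0 by convention (no variance to explain);
    constant ``x`` is a degenerate fit and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise DataError("linear_r2 needs >= 3 paired points")
    if np.ptp(x) == 0:
        raise DegenerateFitError("x is constant")
    if np.ptp(y) == 0:
        return 0.0
    fit = stats.linregress(x, y)
    return float(round_half_away(fit.rvalue ** 2, 3))


# ---------------------------------------------------------------------------
# long-format TSV <-> records, and the Table-1-style stats table on disk

def read_recovery_records(path: str | Path) -> list[SampleRecoveryRecord]:
    """Read long-format recovery records.

    Expected columns: sample, locus, recovered_len, target_len, reads,
    mapped, paralog_len, paralog_depth (flags as 0/1).
    """
    df = pd.read_csv(path, sep="\t")
    records = []
    for sample, group in df.groupby("sample", sort=False):
        loci = {}
        for _, row in group.iterrows():
            loci[str(row["locus"])] = LocusRecovery(
                recovered_len=int(row["recovered_len"]),
                target_len=float(row["target_len"]),
                paralog_len=bool(row["paralog_len"]),
                paralog_depth=bool(row["paralog_depth"]),
            )
        first = group.iloc[0]
        records.append(
            SampleRecoveryRecord(
                sample_id=str(sample),
                total_reads=int(first["reads"]),
                mapped_reads=int(first["mapped"]),
                loci=loci,
            )
        )
    return records


def write_recovery_records(
    records: list[SampleRecoveryRecord], path: str | Path
) -> None:
    rows = []
    for rec in records:
        for locus in sorted(rec.loci):
            lr = rec.loci[locus]
            rows.append({
                "sample": rec.sample_id, "locus": locus,
                "recovered_len": lr.recovered_len,
                "target_len": lr.target_len,
                "reads": rec.total_reads, "mapped": rec.mapped_reads,
                "paralog_len": int(lr.paralog_len),
                "paralog_depth": int(lr.paralog_depth),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_stats_table(path: str | Path) -> list[SampleStatsRow]:
    """Read a per-sample statistics table (TSV with STATS_COLUMNS schema)."""
    df = pd.read_csv(path, sep="\t")
    rows = []
    for _, row in df.iterrows():
        rows.append(
            SampleStatsRow(
                sample_id=str(row["sample_id"]),
                **{col: row[col] for col in STATS_COLUMNS},
            )
        )
    return rows


def write_stats_table(rows: list[SampleStatsRow], path: str | Path) -> None:
    stats_frame(rows).to_csv(path, sep="\t")
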