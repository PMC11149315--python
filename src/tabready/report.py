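"""Persist search artifacts: per-run readiness CSVs, the best-per-run CSV,
the cleansed sub-table CSV, and a plain-text global summary.

All indices are 0-based positions in the master table; floats in the score
tables are serialized at 6 decimals; index sets are stored as compact range
strings (``"0-4,7,9"``) so large tables stay diff-able.
"""

from __future__ import annotations

import datetime as _dt
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import MasterTable, write_master
from .search import RunRecord, SearchResult

#: Column order of the per-run and best-per-run CSVs.
REPORT_COLUMNS = (
    "run", "record", "n_rows", "n_cols",
    "pc_q", "spearman_q", "missing_q", "outlier_q", "overlap_q",
    "clf_acc", "clu_acc", "combined_acc", "f_tilde", "rows", "cols",
)


@dataclass(frozen=True)
class ReportBundle:
    """Paths of everything :func:`write_reports` wrote."""

    outdir: Path
    per_run_tables: list[Path]
    best_per_run: Path
    cleansed_csv: Path
    summary_txt: Path

    def all_files(self) -> list[Path]:
        return [*self.per_run_tables, self.best_per_run,
                self.cleansed_csv, self.summary_txt]


def compact_ranges(indices: Sequence[int]) -> str:
    """Compress a strictly increasing index list to ``"0-4,7,9"`` form."""
    indices = list(indices)
    if not indices:
        return ""
    parts: list[str] = []
    start = prev = indices[0]
    for value in indices[1:]:
        if value == prev + 1:
            prev = value
            continue
        parts.append(str(start) if start == prev else f"{start}-{prev}")
        start = prev = value
    parts.append(str(start) if start == prev else f"{start}-{prev}")
    return ",".join(parts)


def expand_ranges(text: str) -> list[int]:
    """Inverse of :func:`compact_ranges`."""
    if not text:
        return []
    out: list[int] = []
    for part in text.split(","):
        if "-" in part:
            lo, hi = part.split("-")
            out.extend(range(int(lo), int(hi) + 1))
        else:
            out.append(int(part))
    return out


def _record_row(run_id: int, record_id: int, record: RunRecord) -> dict:
    q = record.quality
    a = record.accuracy
    return {
        "run": run_id,
        "record": record_id,
        "n_rows": record.index.n_rows,
        "n_cols": record.index.n_columns,
        "pc_q": round(q.pc_quality, 6),
        "spearman_q": round(q.spearman_quality, 6),
        "missing_q": round(q.missing_quality, 6),
        "outlier_q": round(q.outlier_quality, 6),
        "overlap_q": round(q.overlap_quality, 6),
        "clf_acc": round(a.classification_accuracy, 6),
        "clu_acc": round(a.clustering_accuracy, 6),
        "combined_acc": round(a.combined_accuracy, 6),
        "f_tilde": round(record.f_tilde, 6) if record.f_tilde is not None else "",
        "rows": compact_ranges(record.index.row_indices),
        "cols": compact_ranges(record.index.column_indices),
    }


def _records_frame(rows: Iterable[dict]) -> pd.DataFrame:
    frame = pd.DataFrame(list(rows), columns=list(REPORT_COLUMNS))
    return frame


def _resolve_outdir(outdir: str | os.PathLike) -> Path:
    """Use ``outdir`` directly, or a timestamped subdirectory on collision."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if (outdir / "summary.txt").exists():
        stamp = _dt.datetime.now().strftime("%Y%m%d-%H%M%S")
        outdir = outdir / stamp
        outdir.mkdir(exist_ok=True)
    return outdir


def _float6(value: float) -> str:
    return f"{value:.6f}"


def _summary_text(result: SearchResult, master: MasterTable) -> str:
    best = result.global_best
    lines = [
        "readiness search summary",
        "(all row/column indices are 0-based positions in the master table)",
        "",
        f"master shape: {master.n_rows} rows x {master.n_features} features "
        f"(+ label '{master.label_name}')",
        f"runs: {len(result.run_records)}; "
        f"sub-tables per run: {len(result.run_records[0])}",
        "",
        f"global best run: {result.global_best_run}",
        f"global best f_tilde: {_float6(best.f_tilde)}",
        f"global best shape: {best.index.n_rows} rows x "
        f"{best.index.n_columns} features",
        "mean weights (pc, spearman, missing, outlier, overlap): "
        + ", ".join(_float6(w) for w in result.mean_weights.w),
        "",
        "best quality (pc, spearman, missing, outlier, overlap): "
        + ", ".join(_float6(v) for v in best.quality.as_array()),
        f"best accuracy (clf, clu, combined): "
        + ", ".join(
            _float6(v)
            for v in (
                best.accuracy.classification_accuracy,
                best.accuracy.clustering_accuracy,
                best.accuracy.combined_accuracy,
            )
        ),
        "",
        "master baseline f_tilde: " + _float6(result.baseline.f_tilde),
        "master baseline quality: "
        + ", ".join(_float6(v) for v in result.baseline.quality.as_array()),
        "master baseline accuracy (clf, clu, combined): "
        + ", ".join(
            _float6(v)
            for v in (
                result.baseline.accuracy.classification_accuracy,
                result.baseline.accuracy.clustering_accuracy,
                result.baseline.accuracy.combined_accuracy,
            )
        ),
        "",
        "selected column indices: " + compact_ranges(best.index.column_indices),
        "selected column names: "
        + ",".join(master.feature_names[c] for c in best.index.column_indices),
        "selected row indices: " + compact_ranges(best.index.row_indices),
        "",
    ]
    return "\n".join(lines)


def write_reports(
    result: SearchResult, master: MasterTable, outdir: str | os.PathLike
) -> ReportBundle:
    """Write the full report bundle and return the paths."""
    outdir = _resolve_outdir(outdir)

    per_run_paths: list[Path] = []
    for run_id, records in enumerate(result.run_records, start=1):
        path = outdir / f"run_{run_id:03d}.csv"
        frame = _records_frame(
            _record_row(run_id, i, rec) for i, rec in enumerate(records)
        )
        frame.to_csv(path, index=False)
        per_run_paths.append(path)

    best_path = outdir / "best_per_run.csv"
    _records_frame(
        _record_row(
            run_id,
            next(
                i for i, r in enumerate(result.run_records[run_id - 1])
                if r is rec
            ),
            rec,
        )
        for run_id, rec, _ in result.per_run_best
    ).to_csv(best_path, index=False)

    cleansed_path = outdir / "cleansed.csv"
    write_master(result.global_best.index.materialize(master), cleansed_path)

    summary_path = outdir / "summary.txt"
    summary_path.write_text(_summary_text(result, master), encoding="utf-8")

    return ReportBundle(
        outdir=outdir,
        per_run_tables=per_run_paths,
        best_per_run=best_path,
        cleansed_csv=cleansed_path,
        summary_txt=summary_path,
    )
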