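"""Study-style report assembly: factor tables, source comparisons, segments.

The report mirrors the output structure of the study this package emulates:
a per-factor table of Kruskal-Wallis p-values for acceleration and time
shift, the paired first-vs-last morphometry table, per-source group
comparisons, and per-subject line-segment data (follow-up age span, time
shift, acceleration) for trajectory plots.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import ALPHA, GroupComparison, compare_factor


def factor_table(
    params: pd.DataFrame, covariates: pd.DataFrame, factors: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, dict[str, GroupComparison]]]:
    """Kruskal-Wallis comparisons of acceleration and time shift per factor.

    ``params`` must carry subject_id, alpha, tau; ``covariates`` one binary
    (or categorical) column per factor.  Returns the tidy table and the full
    comparison objects keyed by factor and parameter.
    """
    merged = params.merge(covariates, on="subject_id")
    if factors is None:
        factors = [c for c in covariates.columns if c != "subject_id"]
    rows = []
    details: dict[str, dict[str, GroupComparison]] = {}
    for fac in factors:
        labels = merged[fac].to_numpy()
        if len(pd.unique(labels)) < 2:
            continue
        comp_a = compare_factor(merged["alpha"].to_numpy(), labels, factor=fac)
        comp_t = compare_factor(merged["tau"].to_numpy(), labels, factor=fac)
        details[fac] = {"acceleration": comp_a, "time_shift": comp_t}
        rows.append(
            {
                "factor": fac,
                "group_sizes": json.dumps(comp_a.group_sizes, sort_keys=True),
                "acceleration_p": comp_a.pvalue,
                "time_shift_p": comp_t.pvalue,
                "acceleration_significant": comp_a.pvalue < ALPHA,
                "time_shift_significant": comp_t.pvalue < ALPHA,
            }
        )
    return pd.DataFrame(rows), details


def source_table(params: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-source, per-factor Kruskal-Wallis comparisons of loadings."""
    merged = params.merge(covariates, on="subject_id")
    src_cols = [c for c in params.columns if c.startswith("s_")]
    rows = []
    for fac in (c for c in covariates.columns if c != "subject_id"):
        labels = merged[fac].to_numpy()
        if len(pd.unique(labels)) < 2:
            continue
        for col in src_cols:
            comp = compare_factor(merged[col].to_numpy(), labels, factor=fac)
            rows.append(
                {
                    "factor": fac,
                    "source": col,
                    "p": comp.pvalue,
                    "significant": comp.pvalue < ALPHA,
                    **{f"median_{k}": v for k, v in comp.medians.items()},
                }
            )
    return pd.DataFrame(rows)


def subject_segments(params: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject follow-up segment: age span, time shift, acceleration."""
    spans = records.groupby("subject_id")["age"].agg(["min", "max"]).reset_index()
    spans.columns = ["subject_id", "age_start", "age_end"]
    return params.merge(spans, on="subject_id")[
        ["subject_id", "age_start", "age_end", "tau", "alpha", "xi"]
    ]


@dataclass
class StudyReport:
    """Serializable bundle of the group-comparison outputs."""

    factor_table: pd.DataFrame
    morphometry_table: pd.DataFrame
    source_table: pd.DataFrame
    subject_segments: pd.DataFrame
    meta: dict = field(default_factory=dict)

    _TABLES = ("factor_table", "morphometry_table", "source_table", "subject_segments")

    def to_json(self) -> str:
        payload = {"meta": self.meta}
        for name in self._TABLES:
            df: pd.DataFrame = getattr(self, name)
            payload[name] = json.loads(df.to_json(orient="split", index=False))
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        payload = json.loads(text)
        tables = {
            name: pd.DataFrame(
                payload[name]["data"], columns=payload[name]["columns"]
            )
            for name in cls._TABLES
        }
        return cls(meta=payload.get("meta", {}), **tables)

    def write(self, out_dir: str | Path, plots: bool = False) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(out / f"{name}.csv", index=False, float_format="%.9g")
        (out / "report.json").write_text(self.to_json())
        if plots:
            self._plot(out)
        return out / "report.json"

    def _plot(self, out: Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        seg = self.subject_segments
        if len(seg):
            fig, ax = plt.subplots(figsize=(7, 5))
            for _, r in seg.iterrows():
                mid = (r.age_start + r.age_end) / 2
                half = (r.age_end - r.age_start) / 2
                y_mid = mid - r.tau
                ax.plot(
                    [r.age_start, r.age_end],
                    [y_mid - r.alpha * half, y_mid + r.alpha * half],
                    lw=0.8,
                )
            ax.set_xlabel("chronological age (y)")
            ax.set_ylabel("position on population trajectory (y)")
            fig.savefig(out / "subject_segments.png", dpi=120)
            plt.close(fig)


def build_report(
    params: pd.DataFrame,
    covariates: pd.DataFrame,
    records: pd.DataFrame,
    morphometry_table: pd.DataFrame,
    meta: dict | None = None,
) -> StudyReport:
    ft, _ = factor_table(params, covariates)
    return StudyReport(
        factor_table=ft,
        morphometry_table=morphometry_table,
        source_table=source_table(params, covariates),
        subject_segments=subject_segments(params, records),
        meta=meta or {},
    )
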