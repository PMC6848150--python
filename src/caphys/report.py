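"""Report bundles: per-condition tables, comparisons and a text summary."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from caphys.imaging.summary import SliceSummary
from caphys.stats import GroupComparison


def format_p(p: float) -> str:
    """Two significant figures; very small p rendered as a threshold."""
    if not p == p:  # NaN
        return "undefined"
    if p < 1e-4:
        return "p < 0.0001"
    return f"p = {p:.2g}"


@dataclass
class ReportBundle:
    summary_table: pd.DataFrame
    comparison_table: pd.DataFrame
    text: str

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary_table.to_csv(out / "summaries.csv", index=False)
        self.comparison_table.to_csv(out / "comparisons.csv", index=False)
        (out / "report.txt").write_text(self.text)
        return out


def build_report(
    summaries: Sequence[SliceSummary],
    comparisons: Sequence[GroupComparison] = (),
) -> ReportBundle:
    """Assemble a deterministic report bundle.

    Summaries are ordered by condition label and comparisons by
    (measure, group labels).  A measure reported with two different units
    across comparisons is rejected.
    """
    if not summaries:
        raise ValueError("at least one slice summary required")
    units_by_measure: dict[str, str] = {}
    for c in comparisons:
        if c.measure in units_by_measure and units_by_measure[c.measure] != c.units:
            raise ValueError(
                f"mixed units for measure '{c.measure}': "
                f"{units_by_measure[c.measure]!r} vs {c.units!r}"
            )
        units_by_measure[c.measure] = c.units

    srows = [
        {
            "condition": s.condition_label,
            "n_total_cells": s.n_total_cells,
            "n_responders": s.n_vdrn,
            "responding_percent": s.responding_percent,
            "responding_percent_txneg_denominator": s.responding_percent_txneg,
            "excluded_out_of_focus": s.excluded_cells.get("out_of_focus", 0),
            "excluded_unresponsive": s.excluded_cells.get("electrically_unresponsive", 0),
            "session_qc_pass": s.session_qc_pass,
            "percent_defined": s.percent_defined,
        }
        for s in sorted(summaries, key=lambda s: s.condition_label)
    ]
    crows = [
        {
            "measure": c.measure,
            "units": c.units,
            "group_a": c.group_a_label,
            "group_b": c.group_b_label,
            "n_a": c.n_a,
            "n_b": c.n_b,
            "mean_a": c.mean_a,
            "mean_b": c.mean_b,
            "sem_a": c.sem_a,
            "sem_b": c.sem_b,
            "t_stat": c.t_stat,
            "df_welch": c.df_welch,
            "p_two_tailed": c.p_two_tailed,
        }
        for c in sorted(
            comparisons, key=lambda c: (c.measure, c.group_a_label, c.group_b_label)
        )
    ]

    lines = ["Responder screening report", "=" * 26, ""]
    for r in srows:
        pct = (
            f"{r['responding_percent']:.1f}%"
            if r["percent_defined"]
            else "undefined (no eligible cells)"
        )
        lines.append(
            f"[{r['condition']}] {r['n_responders']}/{r['n_total_cells']} responding cells"
            f" ({pct}); QC pass: {r['session_qc_pass']}"
        )
    if crows:
        lines.append("")
        lines.append("Group comparisons (unpaired two-tailed t test, Welch's correction):")
        for c in crows:
            lines.append(
                f"  {c['measure']} [{c['units']}]: {c['group_a']} "
                f"{c['mean_a']:.3g} +/- {c['sem_a']:.2g} (n={c['n_a']}) vs "
                f"{c['group_b']} {c['mean_b']:.3g} +/- {c['sem_b']:.2g} (n={c['n_b']}), "
                f"t = {c['t_stat']:.3g}, df = {c['df_welch']:.3g}, "
                f"{format_p(c['p_two_tailed'])}"
            )
    lines += ["", "Data = mean +/- SEM. No multiple-comparison correction applied.", ""]

    return ReportBundle(
        summary_table=pd.DataFrame(srows),
        comparison_table=pd.DataFrame(crows),
        text="\n".join(lines),
    )
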