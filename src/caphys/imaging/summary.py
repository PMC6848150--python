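"""Per-slice summaries with the denominator rule.

The responding percentage divides responders (electrically responsive,
counterstain-negative cells only) by the total in-focus cell count across
both counterstain labels, so imperfect counterstaining can only make the
reported proportion an underestimate.  A counterstain-negative-only tally is
also emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from caphys.imaging.qc import QCReport
from caphys.imaging.responders import ResponderCall
from caphys.imaging.rois import RoiSet
from caphys.stats import proportion_responding, round_half_up


@dataclass
class SliceSummary:
    condition_label: str
    n_total_cells: int  # in-focus, electrically responsive, both labels
    n_vdrn: int  # responders among eligible (counterstain-negative) cells
    responding_percent: float  # 100 * n_vdrn / n_total_cells, 1 decimal
    responding_percent_txneg: float  # counterstain-negative denominator tally
    excluded_cells: dict[str, int] = field(default_factory=dict)
    session_qc_pass: bool = True
    percent_defined: bool = True

    def __post_init__(self) -> None:
        if self.percent_defined:
            if not 0.0 <= self.responding_percent <= 100.0:
                raise ValueError("responding_percent must be in [0, 100]")
            if self.n_vdrn > self.n_total_cells:
                raise ValueError("n_vdrn cannot exceed n_total_cells")


def summarize_slice(
    calls: list[ResponderCall],
    rois: RoiSet,
    qc: QCReport,
    condition_label: str = "",
) -> SliceSummary:
    """Apply eligibility and exclusion rules and compute the responding %."""
    if not qc.evaluable:
        raise ValueError("session QC unevaluable: cannot summarise")
    n = rois.n_cells
    if len(calls) != n:
        raise ValueError("one responder call per ROI required")
    responsive = (
        qc.electrically_responsive
        if qc.electrically_responsive is not None
        else np.ones(n, dtype=bool)
    )
    in_focus = rois.in_focus
    counted = in_focus & responsive  # both labels
    eligible = counted & ~rois.txred_positive
    is_resp = np.array([c.is_responder for c in calls], dtype=bool)
    vdrn = eligible & is_resp

    n_total = int(counted.sum())
    n_vdrn = int(vdrn.sum())
    n_txneg = int(eligible.sum())
    excluded = {
        "out_of_focus": int((~in_focus).sum()),
        "electrically_unresponsive": int((in_focus & ~responsive).sum()),
    }
    if n_total == 0:
        return SliceSummary(
            condition_label=condition_label,
            n_total_cells=0,
            n_vdrn=0,
            responding_percent=float("nan"),
            responding_percent_txneg=float("nan"),
            excluded_cells=excluded,
            session_qc_pass=qc.session_pass,
            percent_defined=False,
        )
    pct = proportion_responding(n_vdrn, n_total)
    pct_neg = (
        proportion_responding(n_vdrn, n_txneg) if n_txneg else float("nan")
    )
    return SliceSummary(
        condition_label=condition_label,
        n_total_cells=n_total,
        n_vdrn=n_vdrn,
        responding_percent=round_half_up(pct, 1),
        responding_percent_txneg=pct_neg,
        excluded_cells=excluded,
        session_qc_pass=qc.session_pass,
    )
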