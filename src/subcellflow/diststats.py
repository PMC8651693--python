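"""Distribution statistics for protein groups across fractions.

For a defined set of proteins (e.g. the large ribosomal subunit members),
the summed intensity per fraction is expressed as a percentage of the
group's total signal, separately for every replicate and condition, and
changes of the percentage in a given fraction between two conditions are
tested with a two-sided paired t-test across replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import QuantTable, SampleDesign

__all__ = ["GroupDistribution", "PairedTestResult",
           "group_fraction_percentages", "paired_fraction_test"]

log = logging.getLogger(__name__)


@dataclass
class GroupDistribution:
    """Per replicate x condition, the percentage of the group's summed
    intensity recovered in each fraction (rows sum to 100)."""

    group: str
    table: pd.DataFrame  # long: condition, replicate, fraction, percentage

    def percentages(self, condition: str, fraction: int) -> pd.Series:
        sub = self.table[
            (self.table["condition"] == condition)
            & (self.table["fraction"] == fraction)
        ]
        return sub.set_index("replicate")["percentage"].sort_index()


class PairedTestResult(NamedTuple):
    t: float
    df: int
    p: float
    zero_variance: bool


def group_fraction_percentages(
    table: QuantTable,
    members: Sequence[str],
    design: SampleDesign | None = None,
    group: str = "group",
) -> GroupDistribution:
    """Percentage of the group's total intensity found in each fraction,
    per replicate and condition.

    percentage_f = 100 x sum_members intensity_f / sum_members sum_f intensity_f

    Intensities are de-logged; members missing in a fraction contribute 0
    there (absence post-filter means below detection in that compartment).
    """
    design = design or table.design
    present = [m for m in members if m in table.features]
    if not present:
        raise ValueError("no group member is quantified in the table")
    if len(present) < len(members):
        log.info("group %r: %d/%d members quantified",
                 group, len(present), len(members))
    linear = np.exp2(table.values.loc[present]).fillna(0.0)
    rows = []
    for condition in design.conditions:
        for rep in design.replicates:
            per_fraction = {}
            for f in design.fractions:
                cols = [
                    s for s in design.samples_for(
                        fraction=f, condition=condition, replicate=rep
                    ) if s in linear.columns
                ]
                per_fraction[f] = float(linear[cols].to_numpy().sum()) if cols else 0.0
            total = sum(per_fraction.values())
            if total <= 0:
                raise ValueError(
                    f"group {group!r} has no signal for condition {condition!r} "
                    f"replicate {rep}"
                )
            for f, v in per_fraction.items():
                rows.append((condition, rep, f, 100.0 * v / total))
    frame = pd.DataFrame(
        rows, columns=["condition", "replicate", "fraction", "percentage"]
    )
    return GroupDistribution(group=group, table=frame)


def paired_fraction_test(
    dist_a: GroupDistribution,
    dist_b: GroupDistribution,
    fraction: int,
    condition_a: str | None = None,
    condition_b: str | None = None,
) -> PairedTestResult:
    """Two-sided paired t-test on per-replicate percentages in one fraction.

    ``dist_a`` and ``dist_b`` may be the same distribution evaluated at two
    conditions (pass ``condition_a``/``condition_b``) or two distributions
    (e.g. resting vs stimulated muscle) paired by replicate id. df equals
    the number of pairs minus 1; all-equal nonzero differences are flagged
    as zero-variance with an undefined p.
    """
    cond_a = condition_a or dist_a.table["condition"].iloc[0]
    cond_b = condition_b or dist_b.table["condition"].iloc[0]
    a = dist_a.percentages(cond_a, fraction)
    b = dist_b.percentages(cond_b, fraction)
    shared = a.index.intersection(b.index)
    if len(shared) < 2:
        raise ValueError("paired test needs at least 2 replicate pairs")
    diffs = (a[shared] - b[shared]).to_numpy(dtype=float)
    df = len(diffs) - 1
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            return PairedTestResult(0.0, df, 1.0, True)
        log.warning("paired_fraction_test: zero-variance nonzero differences")
        return PairedTestResult(np.inf if diffs[0] > 0 else -np.inf, df,
                                np.nan, True)
    t, p = stats.ttest_rel(a[shared].to_numpy(), b[shared].to_numpy())
    return PairedTestResult(float(t), df, float(p), False)
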