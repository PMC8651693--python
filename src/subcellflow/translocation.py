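"""Movement-score detection of protein translocation between fractions.

For each feature the per-fraction intensities at a time point are scaled
to the feature's total abundance, giving a length-F profile of fraction
proportions. Against the reference (control) profile, the fraction with
the largest gain is the acceptor and the fraction with the largest loss
the donor; the movement score is the mean of the gained and lost mass,

    M = (Δ[acceptor] + |Δ[donor]|) / 2,

which equals the moved proportion for a clean two-fraction move. A real
translocation must change abundance in *both* fractions, so the
per-fraction moderated-t p-values of donor and acceptor are combined with
Fisher's method (chi-square, 4 df) and corrected across features by
Benjamini-Hochberg within each time point. Candidates require a movement
score above ``score_min`` (default 0.1, i.e. 10% of the profile moved)
and a corrected combined p below ``fdr_max`` (default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import QuantTable, SampleDesign
from .diffstats import ModeratedStats, bh_adjust, fit_moderated

__all__ = [
    "ScaledProfileSet",
    "scale_profiles",
    "movement_score",
    "classify_neighborhood",
    "fisher_combine",
    "call_translocations",
    "per_fraction_pvalues",
    "DEFAULT_NEIGHBORHOODS",
]

log = logging.getLogger(__name__)

_P_FLOOR = 1e-300

#: fraction -> neighborhood for the six-fraction protocol: the first two
#: fractions enrich the cytosol, the middle two membrane-bound organelles,
#: the last two the nuclear compartment.
DEFAULT_NEIGHBORHOODS: dict[int, str] = {
    1: "cytosol", 2: "cytosol",
    3: "membrane", 4: "membrane",
    5: "nuclear", 6: "nuclear",
}


@dataclass
class ScaledProfileSet:
    """Per-condition fraction-proportion profiles (replicate means).

    ``profiles[condition]`` is a DataFrame (features x fractions) whose
    rows sum to 1 for features quantified in at least one fraction;
    fractions where the feature was filtered out contribute 0.
    ``undefined[condition]`` lists features with no signal anywhere in
    that condition (profile undefined).
    """

    profiles: dict[str, pd.DataFrame]
    fractions: list[int]
    undefined: dict[str, list[str]] = field(default_factory=dict)

    @property
    def conditions(self) -> list[str]:
        return list(self.profiles)


def scale_profiles(table: QuantTable, design: SampleDesign | None = None) -> ScaledProfileSet:
    """Scale per-fraction intensities to the feature total, per condition.

    Intensities are de-logged, missing fractions contribute 0; each
    replicate's fraction vector is normalized to sum 1 and the replicate
    vectors are averaged per condition.
    """
    design = design or table.design
    fractions = design.fractions
    linear = np.exp2(table.values).fillna(0.0)
    profiles: dict[str, pd.DataFrame] = {}
    undefined: dict[str, list[str]] = {}
    for condition in design.conditions:
        acc = pd.DataFrame(0.0, index=table.features, columns=fractions)
        n_reps = pd.Series(0, index=table.features, dtype=int)
        for rep in design.replicates:
            cols, order = [], []
            for f in fractions:
                s = design.samples_for(fraction=f, condition=condition, replicate=rep)
                if len(s) == 1 and s[0] in linear.columns:
                    cols.append(s[0])
                    order.append(f)
            if len(cols) != len(fractions):
                continue
            block = linear[cols]
            block.columns = order
            totals = block.sum(axis=1)
            has_signal = totals > 0
            scaled = block.loc[has_signal].div(totals[has_signal], axis=0)
            acc.loc[has_signal, order] += scaled[order]
            n_reps[has_signal] += 1
        defined = n_reps > 0
        acc.loc[defined] = acc.loc[defined].div(n_reps[defined], axis=0)
        acc.loc[~defined] = np.nan
        profiles[condition] = acc
        missing = table.features[~defined].tolist()
        if missing:
            undefined[condition] = missing
            log.info(
                "scale_profiles: %d features without signal in condition %r",
                len(missing), condition,
            )
    return ScaledProfileSet(profiles=profiles, fractions=fractions, undefined=undefined)


def movement_score(
    profile_t: np.ndarray, profile_ref: np.ndarray, variant: str = "top2"
) -> tuple[float, int | None, int | None]:
    """Movement score and directed (donor, acceptor) fraction pair.

    Returns ``(M, donor, acceptor)`` with 1-based fraction indices;
    ``donor``/``acceptor`` are None when the profiles are identical
    (M = 0). ``variant="total"`` uses half the total absolute profile
    change instead of the mean of the two extreme changes.
    """
    pt = np.asarray(profile_t, dtype=float)
    pr = np.asarray(profile_ref, dtype=float)
    if pt.shape != pr.shape:
        raise ValueError("profiles must have equal length")
    delta = pt - pr
    if np.allclose(delta, 0.0, atol=1e-12):
        return 0.0, None, None
    acceptor = int(np.argmax(delta))
    donor = int(np.argmin(delta))
    if variant == "top2":
        m = (delta[acceptor] + abs(delta[donor])) / 2.0
    elif variant == "total":
        m = float(np.abs(delta).sum() / 2.0)
    else:
        raise ValueError(f"unknown score variant {variant!r}")
    return float(m), donor + 1, acceptor + 1


def classify_neighborhood(
    donor: int | None,
    acceptor: int | None,
    grouping: dict[int, str] | None = None,
) -> str:
    """Neighborhood category of a donor→acceptor move.

    Categories follow the three-neighborhood grouping of the six-fraction
    protocol: moves between cytosol and nuclear, cytosol and membrane, or
    membrane and nuclear neighborhoods, moves within one neighborhood, and
    "none" when no move occurred.
    """
    if donor is None or acceptor is None:
        return "none"
    grouping = grouping or DEFAULT_NEIGHBORHOODS
    try:
        a, b = grouping[donor], grouping[acceptor]
    except KeyError as exc:
        raise ValueError(f"fraction {exc.args[0]} missing from grouping") from exc
    if a == b:
        return "within-neighborhood"
    return "-".join(sorted((a, b)))


def fisher_combine(p_donor: float, p_acceptor: float) -> tuple[float, float]:
    """Fisher's method over the donor- and acceptor-fraction p-values.

    X² = −2(ln p_donor + ln p_acceptor) is referred to the upper tail of a
    chi-square with 4 degrees of freedom. Zero p-values are floored at
    1e-300 before taking logs.
    """
    pd_, pa_ = max(float(p_donor), _P_FLOOR), max(float(p_acceptor), _P_FLOOR)
    if not (0 < pd_ <= 1 and 0 < pa_ <= 1):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = -2.0 * (np.log(pd_) + np.log(pa_))
    return float(x2), float(stats.chi2.sf(x2, df=4))


def per_fraction_pvalues(
    table: QuantTable,
    reference: str,
    min_valid: int = 3,
    prior_df: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Moderated-t p-values of every condition versus the reference, per
    fraction. Returns ``{condition: DataFrame(features x fractions)}``."""
    design = table.design
    out: dict[str, pd.DataFrame] = {}
    for condition in design.conditions:
        if condition == reference:
            continue
        pmat = pd.DataFrame(np.nan, index=table.features, columns=design.fractions)
        for fraction in design.fractions:
            fit: ModeratedStats = fit_moderated(
                table, condition, reference, fraction,
                min_valid=min_valid, prior_df=prior_df,
            )
            pmat.loc[fit.table.index, fraction] = fit.table["p"]
        out[condition] = pmat
    return out


def call_translocations(
    profiles: ScaledProfileSet,
    reference: str,
    pvalues: dict[str, pd.DataFrame],
    score_min: float = 0.1,
    fdr_max: float = 0.05,
    grouping: dict[int, str] | None = None,
    variant: str = "top2",
) -> dict[str, pd.DataFrame]:
    """Score and test every feature at every non-reference time point.

    Per time point: movement score, donor/acceptor pair and neighborhood
    category from the scaled profiles; Fisher-combined donor/acceptor
    p-values, BH-corrected across features; a feature is called when
    M > score_min and q < fdr_max. Features whose donor or acceptor
    p-value is unavailable are excluded from calling (never imputed).
    Results are sorted by q then by descending M.
    """
    if reference not in profiles.profiles:
        raise ValueError(f"reference condition {reference!r} has no profiles")
    ref = profiles.profiles[reference]
    results: dict[str, pd.DataFrame] = {}
    for condition, prof in profiles.profiles.items():
        if condition == reference:
            continue
        rows = []
        for feature in prof.index:
            pt = prof.loc[feature].to_numpy()
            pr = ref.loc[feature].to_numpy()
            if np.isnan(pt).any() or np.isnan(pr).any():
                continue
            m, donor, acceptor = movement_score(pt, pr, variant=variant)
            category = classify_neighborhood(donor, acceptor, grouping)
            p_comb, x2 = np.nan, np.nan
            if donor is not None and condition in pvalues:
                p_d = pvalues[condition].at[feature, donor]
                p_a = pvalues[condition].at[feature, acceptor]
                if np.isfinite(p_d) and np.isfinite(p_a):
                    x2, p_comb = fisher_combine(p_d, p_a)
            rows.append((feature, m, donor, acceptor, category, x2, p_comb))
        res = pd.DataFrame(
            rows,
            columns=["feature", "movement_score", "donor", "acceptor",
                     "category", "X2", "p_combined"],
        ).set_index("feature")
        res["donor"] = res["donor"].astype("Int64")
        res["acceptor"] = res["acceptor"].astype("Int64")
        res["q"] = bh_adjust(res["p_combined"].to_numpy())
        res["called"] = (
            (res["movement_score"] > score_min) & (res["q"] < fdr_max)
        ).fillna(False)
        n_unscored = int(res["p_combined"].isna().sum())
        if n_unscored:
            log.info(
                "call_translocations: %d features lacked donor/acceptor "
                "p-values at %r", n_unscored, condition,
            )
        res = res.sort_values(["q", "movement_score"], ascending=[True, False])
        results[condition] = res
    return results
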