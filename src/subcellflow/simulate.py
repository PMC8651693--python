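"""Synthetic subcellular fractionation data with known ground truth.

Generates feature-by-sample log2 intensity matrices that emulate the key
properties of DIA fractionation proteomics: compartment-specific enrichment
profiles over F fractions, log-normal abundance and measurement noise,
replicate structure, injected time-course translocation events (a stated
proportion of profile mass moved from a donor to an acceptor fraction), and
two missingness regimes — completely-at-random dropout plus an
intensity-dependent (left-censoring) logistic dropout curve.

Every downstream stage of the pipeline can therefore be scored against
exact ground truth: which features translocate, from where to where, by how
much, and which cells were dropped by which regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import QuantTable, SampleDesign

__all__ = [
    "CompartmentTemplate",
    "TranslocationSpec",
    "SyntheticTruth",
    "default_templates",
    "generate_truth",
    "simulate_intensities",
    "apply_missingness",
]


@dataclass(frozen=True)
class CompartmentTemplate:
    """A compartment's fractionation fingerprint.

    ``profile`` holds the proportion of a resident protein's total signal
    recovered in each fraction; proportions are nonnegative and sum to 1.
    """

    name: str
    profile: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.profile, dtype=float)
        if p.size < 2:
            raise ValueError("a template needs at least 2 fractions")
        if (p < 0).any():
            raise ValueError("profile proportions must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"profile of {self.name!r} must sum to 1, got {p.sum()}")

    @property
    def n_fractions(self) -> int:
        return len(self.profile)

    @property
    def dominant_fraction(self) -> int:
        """1-based index of the fraction holding the largest proportion."""
        return int(np.argmax(self.profile)) + 1


@dataclass(frozen=True)
class TranslocationSpec:
    """Ground-truth movement of one feature: move ``delta`` of its profile
    mass from the donor to the acceptor fraction, from ``onset`` onwards."""

    feature: str
    donor: int       # 1-based fraction index
    acceptor: int    # 1-based fraction index
    delta: float     # proportion of mass moved, in (0, 1]
    onset: str       # condition label at which the move first appears

    def __post_init__(self) -> None:
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor fractions must differ")
        if not 0 < self.delta <= 1:
            raise ValueError("delta must lie in (0, 1]")


@dataclass
class SyntheticTruth:
    """Everything the simulator decided, for test assertions downstream."""

    features: list[str]
    compartment: pd.Series            # feature -> compartment label
    abundance: pd.Series              # feature -> base abundance (log2)
    specs: list[TranslocationSpec]
    templates: dict[str, CompartmentTemplate]
    mcar_rate: float
    mnar_midpoint: float
    mnar_slope: float
    dropout: pd.DataFrame | None = field(default=None)
    # dropout: cell-level record written by apply_missingness; values are
    # "" (kept), "mcar" or "mnar".

    def __post_init__(self) -> None:
        if not 0 <= self.mcar_rate < 1:
            raise ValueError("mcar_rate must lie in [0, 1)")
        if self.mnar_slope < 0:
            raise ValueError(
                "mnar_slope must be >= 0 so dropout never increases with intensity"
            )

    @property
    def translocating_features(self) -> set[str]:
        return {s.feature for s in self.specs}

    def spec_for(self, feature: str) -> TranslocationSpec | None:
        for s in self.specs:
            if s.feature == feature:
                return s
        return None


def default_templates(
    n_fractions: int = 6, spillover: float = 0.15
) -> list[CompartmentTemplate]:
    """One template per fraction: dominant proportion ``1 - spillover`` with
    the remainder spilling into the adjacent fraction (the last spills
    backwards), mimicking the single-niche-dominant marker profiles that
    chemical fractionation produces."""
    templates = []
    for i in range(n_fractions):
        profile = [0.0] * n_fractions
        profile[i] = 1.0 - spillover
        j = i + 1 if i + 1 < n_fractions else i - 1
        profile[j] = spillover
        templates.append(CompartmentTemplate(name=f"C{i + 1}", profile=tuple(profile)))
    return templates


def generate_truth(
    n_features: int,
    templates: list[CompartmentTemplate] | None = None,
    frac_translocating: float = 0.05,
    delta_range: tuple[float, float] = (0.2, 0.4),
    seed: int = 0,
    onset: str = "stimulated",
    mcar_rate: float = 0.02,
    mnar_midpoint: float = 18.0,
    mnar_slope: float = 1.0,
    abundance_range: tuple[float, float] = (20.0, 30.0),
) -> SyntheticTruth:
    """Draw per-feature compartments, abundances and translocation events.

    Exactly ``round(n_features * frac_translocating)`` features receive a
    :class:`TranslocationSpec`; the donor is the dominant fraction of the
    feature's compartment template, the acceptor a uniformly drawn other
    fraction, and ``delta`` is uniform over ``delta_range``. Deterministic
    for a fixed seed.
    """
    if templates is None:
        templates = default_templates()
    if not templates:
        raise ValueError("templates must be non-empty")
    if not 0 <= frac_translocating < 1:
        raise ValueError("frac_translocating must lie in [0, 1)")
    lo, hi = delta_range
    if not 0 < lo <= hi:
        raise ValueError("delta_range must satisfy 0 < lo <= hi")
    min_dominant = min(t.profile[t.dominant_fraction - 1] for t in templates)
    if hi > min_dominant:
        raise ValueError(
            f"delta_range upper bound {hi} exceeds the smallest template donor "
            f"proportion {min_dominant}"
        )
    n_frac = {t.n_fractions for t in templates}
    if len(n_frac) != 1:
        raise ValueError("all templates must cover the same number of fractions")

    rng = np.random.default_rng(seed)
    features = [f"P{i + 1:05d}" for i in range(n_features)]
    tmpl_idx = rng.integers(0, len(templates), size=n_features)
    compartment = pd.Series(
        [templates[i].name for i in tmpl_idx], index=features, name="compartment"
    )
    abundance = pd.Series(
        rng.uniform(*abundance_range, size=n_features), index=features, name="abundance"
    )

    n_moving = int(round(n_features * frac_translocating))
    moving = rng.choice(n_features, size=n_moving, replace=False)
    specs = []
    F = templates[0].n_fractions
    for fi in sorted(moving):
        template = templates[tmpl_idx[fi]]
        donor = template.dominant_fraction
        others = [f for f in range(1, F + 1) if f != donor]
        acceptor = int(rng.choice(others))
        delta = float(rng.uniform(lo, hi))
        specs.append(
            TranslocationSpec(features[fi], donor, acceptor, delta, onset=onset)
        )

    return SyntheticTruth(
        features=features,
        compartment=compartment,
        abundance=abundance,
        specs=specs,
        templates={t.name: t for t in templates},
        mcar_rate=mcar_rate,
        mnar_midpoint=mnar_midpoint,
        mnar_slope=mnar_slope,
    )


def _profile_for(
    truth: SyntheticTruth, feature: str, condition: str, condition_order: list[str]
) -> np.ndarray:
    template = truth.templates[truth.compartment[feature]]
    profile = np.asarray(template.profile, dtype=float).copy()
    spec = truth.spec_for(feature)
    if spec is not None and spec.onset in condition_order:
        if condition_order.index(condition) >= condition_order.index(spec.onset):
            if spec.delta > profile[spec.donor - 1] + 1e-12:
                raise ValueError(
                    f"delta {spec.delta} exceeds donor proportion of {feature}"
                )
            profile[spec.donor - 1] -= spec.delta
            profile[spec.acceptor - 1] += spec.delta
    return profile


def simulate_intensities(
    truth: SyntheticTruth,
    design: SampleDesign,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> QuantTable:
    """Expected linear intensity of feature i in fraction f is
    ``2**abundance_i * profile_i[f]`` (profile shifted by delta for
    translocators at/after onset); Gaussian noise of sd ``noise_sd`` is
    added on the log2 scale. Fractions with a true proportion of zero are
    emitted as missing — search engines report non-detection, not zero.
    """
    conditions = design.conditions
    for spec in truth.specs:
        if spec.onset not in conditions:
            raise ValueError(
                f"design lacks onset condition {spec.onset!r} referenced by "
                f"translocation of {spec.feature}"
            )
    rng = np.random.default_rng(seed)
    n, m = len(truth.features), len(design.samples)
    values = np.full((n, m), np.nan)
    frac_of = design.frame["fraction"]
    cond_of = design.frame["condition"]

    # per (feature, condition) profile, expanded over replicate samples
    for ci, condition in enumerate(conditions):
        cols = np.flatnonzero((cond_of == condition).to_numpy())
        fr = frac_of.iloc[cols].to_numpy() - 1
        for i, feature in enumerate(truth.features):
            profile = _profile_for(truth, feature, condition, conditions)
            p = profile[fr]
            with np.errstate(divide="ignore"):
                mu = truth.abundance[feature] + np.log2(p)
            values[i, cols] = np.where(p > 0, mu, np.nan)
    noise = rng.normal(0.0, noise_sd, size=(n, m)) if noise_sd > 0 else 0.0
    values = values + noise

    frame = pd.DataFrame(values, index=truth.features, columns=design.samples)
    return QuantTable(frame, design)


def apply_missingness(
    table: QuantTable, truth: SyntheticTruth, seed: int = 0
) -> QuantTable:
    """Drop observed cells stochastically under both regimes.

    Each observed cell of log2 intensity x is removed with probability
    ``mcar_rate + (1 - mcar_rate) * logistic(-slope * (x - midpoint))``:
    a flat completely-at-random floor plus a left-censoring term that
    decreases monotonically with intensity. The per-cell regime
    ("mcar"/"mnar"/"") is recorded on ``truth.dropout``.
    """
    rng = np.random.default_rng(seed)
    x = table.values.to_numpy(dtype=float)
    observed = ~np.isnan(x)
    p_mnar = expit(-truth.mnar_slope * (x - truth.mnar_midpoint))
    u = rng.uniform(size=x.shape)
    is_mcar = observed & (u < truth.mcar_rate)
    p_total = truth.mcar_rate + (1 - truth.mcar_rate) * p_mnar
    is_mnar = observed & ~is_mcar & (u < p_total)

    dropped = x.copy()
    dropped[is_mcar | is_mnar] = np.nan
    regime = np.where(is_mcar, "mcar", np.where(is_mnar, "mnar", ""))
    truth.dropout = pd.DataFrame(
        regime, index=table.values.index, columns=table.values.columns
    )
    frame = pd.DataFrame(
        dropped, index=table.values.index, columns=table.values.columns
    )
    return QuantTable(frame, table.design)
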