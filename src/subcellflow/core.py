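"""Core containers: sample layout and quantification matrices.

A fractionation experiment measures each protein (or phospho-site) across
F sequential subcellular fractions, under one or more conditions (time
points), with replicates. Samples are therefore identified by the triple
(fraction, condition, replicate). Intensities are stored on the log2 scale
with ``NaN`` marking missing values, the convention of search-engine output
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = ["SampleDesign", "QuantTable"]


@dataclass
class SampleDesign:
    """Maps sample ids to (fraction, condition, replicate).

    Parameters
    ----------
    frame
        DataFrame indexed by sample id with columns ``fraction`` (int,
        1-based), ``condition`` (str) and ``replicate`` (int). The order of
        first appearance of condition labels defines the time-course order.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"fraction", "condition", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"design is missing columns: {sorted(missing)}")
        if self.frame.index.duplicated().any():
            dup = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in design: {dup}")
        triples = self.frame[["fraction", "condition", "replicate"]]
        if triples.duplicated().any():
            raise ValueError("(fraction, condition, replicate) triples must be unique")
        self.frame = self.frame.copy()
        self.frame["fraction"] = self.frame["fraction"].astype(int)
        self.frame["replicate"] = self.frame["replicate"].astype(int)

    @classmethod
    def from_layout(
        cls,
        n_fractions: int = 6,
        conditions: Sequence[str] = ("control",),
        n_replicates: int = 4,
    ) -> "SampleDesign":
        """Full-factorial design with samples named ``<cond>_FR<f>_R<r>``."""
        rows = []
        for cond in conditions:
            for f in range(1, n_fractions + 1):
                for r in range(1, n_replicates + 1):
                    rows.append((f"{cond}_FR{f}_R{r}", f, cond, r))
        frame = pd.DataFrame(
            rows, columns=["sample", "fraction", "condition", "replicate"]
        ).set_index("sample")
        return cls(frame)

    @property
    def samples(self) -> pd.Index:
        return self.frame.index

    @property
    def fractions(self) -> list[int]:
        return sorted(self.frame["fraction"].unique().tolist())

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance (time-course order)."""
        seen: dict[str, None] = {}
        for c in self.frame["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def replicates(self) -> list[int]:
        return sorted(self.frame["replicate"].unique().tolist())

    def samples_for(
        self, fraction: int | None = None, condition: str | None = None,
        replicate: int | None = None,
    ) -> pd.Index:
        mask = pd.Series(True, index=self.frame.index)
        if fraction is not None:
            mask &= self.frame["fraction"] == fraction
        if condition is not None:
            mask &= self.frame["condition"] == condition
        if replicate is not None:
            mask &= self.frame["replicate"] == replicate
        return self.frame.index[mask]

    def groups(self) -> Iterator[tuple[int, str, pd.Index]]:
        """Iterate over (fraction, condition) cells — the experimental groups."""
        for fraction in self.fractions:
            for condition in self.conditions:
                samples = self.samples_for(fraction=fraction, condition=condition)
                if len(samples):
                    yield fraction, condition, samples


@dataclass
class QuantTable:
    """Feature-by-sample log2 intensity matrix bound to a :class:`SampleDesign`.

    Attributes
    ----------
    values
        DataFrame (features x samples), log2 intensities, NaN = missing.
    design
        Sample annotation; ``values.columns`` must all be design samples.
    observed
        Boolean mask of originally *measured* cells. Imputation fills
        ``values`` but never touches this mask, so downstream stages can
        distinguish measured from imputed numbers.
    retained
        Boolean (features x fractions) mask set by the min-valid filter:
        which (feature, fraction) blocks survived filtering. ``None`` means
        no filtering has been applied yet.
    """

    values: pd.DataFrame
    design: SampleDesign
    observed: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    retained: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        unknown = [c for c in self.values.columns if c not in self.design.samples]
        if unknown:
            raise ValueError(f"samples not present in design: {unknown}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dup}")
        with np.errstate(invalid="ignore"):
            if np.isinf(self.values.to_numpy(dtype=float)).any():
                raise ValueError("intensity values must be finite or missing")
        if self.observed is None:
            self.observed = self.values.notna()

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def copy(self) -> "QuantTable":
        return QuantTable(
            self.values.copy(),
            self.design,
            self.observed.copy(),
            None if self.retained is None else self.retained.copy(),
        )

    def retained_mask_cells(self) -> pd.DataFrame:
        """Expand the per-(feature, fraction) retention mask to cell level."""
        if self.retained is None:
            return pd.DataFrame(True, index=self.values.index, columns=self.values.columns)
        frac_of = self.design.frame.loc[self.values.columns, "fraction"]
        cells = pd.DataFrame(
            {s: self.retained[frac_of[s]] for s in self.values.columns},
            index=self.values.index,
        )
        return cells

    def is_complete(self) -> bool:
        """True when every retained cell holds a value."""
        cells = self.retained_mask_cells()
        return not (self.values.isna() & cells).any().any()
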