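"""Tab-separated readers and writers plus YAML configuration.

Quantification matrices are plain TSV: a ``feature`` id column followed by
one column per sample; missing values are empty fields ("NA" is accepted
on read). Sample annotation, marker lists and group membership files are
TSV as well, so every output the pipeline writes is re-parseable by the
readers here.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import QuantTable, SampleDesign

__all__ = [
    "read_design", "write_design",
    "read_quant_table", "write_quant_table",
    "read_markers", "write_markers",
    "read_group_members",
    "PipelineConfig", "load_config",
]

_NA_VALUES = ["", "NA", "NaN", "nan"]


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def read_design(path: str | Path) -> SampleDesign:
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str})
    if "sample" not in frame.columns:
        raise ValueError(f"{path}: design needs a 'sample' column")
    return SampleDesign(frame.set_index("sample"))


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.frame.rename_axis("sample").to_csv(path, sep="\t")


def read_quant_table(
    path: str | Path,
    design: SampleDesign | str | Path,
    linear: bool = False,
) -> QuantTable:
    """Read a feature-by-sample matrix and bind it to a design.

    ``linear=True`` log2-transforms the values on read (zeros become
    missing). Unmatched sample columns, duplicate feature ids and
    non-numeric cells raise with the offending names/locations.
    """
    if not isinstance(design, SampleDesign):
        design = read_design(design)
    raw = pd.read_csv(
        path, sep="\t", index_col=0, na_values=_NA_VALUES,
        keep_default_na=False, dtype=str,
    )
    unmatched = [c for c in raw.columns if c not in design.samples]
    if unmatched:
        raise ValueError(f"{path}: columns not in design: {unmatched}")
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids: {dup}")
    values = pd.DataFrame(index=raw.index.rename("feature"), columns=raw.columns,
                          dtype=float)
    for col in raw.columns:
        try:
            # Python's float() round-trips the writer's %.17g exactly
            converted = raw[col].map(lambda v: np.nan if pd.isna(v) else float(v))
        except (TypeError, ValueError):
            bad = raw[col].map(
                lambda v: not pd.isna(v) and not _is_number(v))
            row = raw.index[bad][0]
            raise ValueError(
                f"{path}: non-numeric value {raw.at[row, col]!r} at "
                f"feature {row!r}, sample {col!r}"
            ) from None
        values[col] = converted
    if linear:
        with np.errstate(divide="ignore"):
            values = np.log2(values.where(values > 0))
    return QuantTable(values, design)


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    # %.17g round-trips IEEE doubles exactly through text
    table.values.rename_axis("feature").to_csv(
        path, sep="\t", na_rep="", float_format="%.17g"
    )


def read_markers(path: str | Path) -> dict[str, str]:
    """Two-column TSV (feature, compartment) -> MarkerMap."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: marker file needs two tab-separated columns")
    if frame[0].duplicated().any():
        dup = frame[0][frame[0].duplicated()].tolist()
        raise ValueError(f"{path}: markers listed twice: {dup}")
    return dict(zip(frame[0], frame[1]))


def write_markers(markers: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for feat, comp in markers.items():
            fh.write(f"{feat}\t{comp}\n")


def read_group_members(path: str | Path) -> list[str]:
    """One feature id per line."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


@dataclass
class PipelineConfig:
    """Every knob that changes a numeric output of the pipeline."""

    # inputs (optional; simulation is used when matrix is None)
    matrix: str | None = None
    design: str | None = None
    markers: str | None = None
    groups: str | None = None
    values_are_linear: bool = False

    # simulation
    sim_n_features: int = 1000
    sim_n_fractions: int = 6
    sim_n_replicates: int = 4
    sim_conditions: tuple[str, ...] = ("control", "stimulated")
    sim_frac_translocating: float = 0.05
    sim_delta_min: float = 0.2
    sim_delta_max: float = 0.4
    sim_noise_sd: float = 0.3
    sim_spillover: float = 0.15
    sim_mcar_rate: float = 0.02
    sim_mnar_midpoint: float = 18.0
    sim_mnar_slope: float = 1.0
    seed: int = 0

    # preprocessing
    min_valid: int = 3
    loess_span: float = 0.7
    loess_iterations: int = 3
    k_neighbors: int = 10
    quantile: float = 0.025

    # translocation
    reference_condition: str = "control"
    score_min: float = 0.1
    fdr_max: float = 0.05
    score_variant: str = "top2"

    # compartment assignment
    kmeans_k: int | None = None        # default: 2 x number of compartments
    kmeans_restarts: int = 25

    def validate(self) -> None:
        for name in ("sim_frac_translocating", "sim_mcar_rate", "quantile",
                     "score_min", "fdr_max", "sim_spillover"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in ("matrix", "design", "markers", "groups"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Load a flat YAML config; keyword overrides win."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "sim_conditions" in data:
        data["sim_conditions"] = tuple(data["sim_conditions"])
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["sim_conditions"] = list(d["sim_conditions"])
    return d


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
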