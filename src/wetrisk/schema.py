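"""Feature schema for the wetland-antibiotics experiment table.

The modelling matrix has 16 numeric and 3 categorical features describing a
single wetland treatment trial, grouped into four mechanistic categories
(water quality properties, artificial configuration parameters, hydraulic
conditions and temperature, wetland construction characteristics).  The
schema is data, not code: the default below can be replaced wholesale when
real experiment tables with a different column set are substituted for the
synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "Feature",
    "FeatureSchema",
    "GROUPS",
    "default_schema",
    "TARGET",
]

TARGET = "are"

GROUPS = (
    "water quality properties",
    "artificial configuration parameters",
    "hydraulic conditions and temperature",
    "wetland construction characteristics",
)


@dataclass(frozen=True)
class Feature:
    """One input variable: its name, kind, category group and domain.

    ``low``/``high`` bound numeric features (``log=True`` marks features
    sampled and interpreted on a log10 scale); ``levels`` enumerates the
    vocabulary of categorical features.
    """

    name: str
    kind: str  # "numeric" | "categorical"
    group: str
    low: float | None = None
    high: float | None = None
    log: bool = False
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown feature group {self.group!r}")


@dataclass(frozen=True)
class FeatureSchema:
    features: tuple[Feature, ...]

    @property
    def numeric(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features if f.kind == "numeric")

    @property
    def categorical(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features if f.kind == "categorical")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    def __getitem__(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def group_of(self, name: str) -> str:
        return self[name].group

    def validate_table(self, columns: Sequence[str]) -> None:
        missing = [n for n in self.names if n not in columns]
        if missing:
            raise ValueError(f"table is missing feature columns: {missing}")


def default_schema() -> FeatureSchema:
    """The default 16-numeric + 3-categorical trial schema.

    Ranges are the plausible spans of lab- to field-scale treatment-wetland
    trials; they bound both the synthetic generator and the feature
    attributes attached to regional wetland units.
    """
    wq = GROUPS[0]
    cfg = GROUPS[1]
    hyd = GROUPS[2]
    con = GROUPS[3]
    feats = (
        # water quality properties
        Feature("antibiotic_conc", "numeric", wq, 0.1, 1000.0, log=True),  # ug/L
        Feature("tetracycline_frac", "numeric", wq, 0.0, 1.0),
        Feature("nh4_n", "numeric", wq, 0.1, 60.0, log=True),  # mg/L
        Feature("cod", "numeric", wq, 5.0, 500.0, log=True),  # mg/L
        Feature("ph", "numeric", wq, 5.5, 9.5),
        Feature("dissolved_oxygen", "numeric", wq, 0.5, 10.0),  # mg/L
        Feature("total_n", "numeric", wq, 1.0, 50.0),  # mg/L
        Feature("total_p", "numeric", wq, 0.1, 10.0),  # mg/L
        # artificial configuration parameters
        Feature("planting_density", "numeric", cfg, 0.0, 300.0),  # plants/m2
        # hydraulic conditions and temperature
        Feature("hrt", "numeric", hyd, 0.5, 15.0),  # d
        Feature("hlr", "numeric", hyd, 0.01, 1.0, log=True),  # m/d
        Feature("influent_flow", "numeric", hyd, 0.01, 100.0, log=True),  # m3/d
        Feature("temperature", "numeric", hyd, 5.0, 40.0),  # degC
        # wetland construction characteristics
        Feature("wetland_area", "numeric", con, 0.1, 5000.0, log=True),  # m2
        Feature("depth", "numeric", con, 0.2, 2.0),  # m
        Feature("aspect_ratio", "numeric", con, 1.0, 10.0),
        # categoricals
        Feature("structural_type", "categorical", con,
                levels=("surface_flow", "subsurface_flow", "hybrid")),
        Feature("modified_substrate", "categorical", cfg, levels=("no", "yes")),
        Feature("aeration", "categorical", cfg, levels=("no", "yes")),
    )
    schema = FeatureSchema(feats)
    assert len(schema.numeric) == 16 and len(schema.categorical) == 3
    return schema
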