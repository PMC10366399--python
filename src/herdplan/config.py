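"""Run configuration: one YAML/JSON document with full defaults.

The configuration covers the synthetic herd and demand generators, the
growth-model constants, the economics of the planning instance, the
facility/product roster and solver settings.  ``config_hash`` gives the
short provenance digest embedded in every artifact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field

from .growth import GrowthParameters
from .instance import Economics, Facility, Product
from .synthetic import HerdSpec


class FacilityConfig(BaseModel):
    id: str
    slaughter_cost: float = 50.0


class ProductConfig(BaseModel):
    id: str
    price: float
    meat_per_unit: float = 1.0
    production_cost: float = 0.0
    holding_cost: float = 0.05
    inventory_cap: float = 5000.0


class HerdConfig(BaseModel):
    cohort_size: int = 90
    horizon_months: int = 22
    sex_ratio: float = 0.5


class DemandConfig(BaseModel):
    mean: float = 50_000.0
    sd: float = 2_000.0


class SolverConfig(BaseModel):
    mip_gap: float = 1e-4
    time_limit: Optional[float] = None
    backend: str = "highs"


class PathsConfig(BaseModel):
    herd_csv: str = "herd.csv"
    demand_csv: str = "demand.csv"
    out_dir: str = "."


class RunConfig(BaseModel):
    """Everything a run needs, with case-study defaults.

    growth/economics hold keyword overrides of the library defaults so a
    config file only states what it changes.
    """

    seed: int = 0
    n_periods: int = 7
    herd: HerdConfig = Field(default_factory=HerdConfig)
    demand: DemandConfig = Field(default_factory=DemandConfig)
    growth: dict = Field(default_factory=dict)
    economics: dict = Field(default_factory=dict)
    facilities: list[FacilityConfig] = Field(
        default_factory=lambda: [
            FacilityConfig(id="F1", slaughter_cost=50.0),
            FacilityConfig(id="F2", slaughter_cost=52.0),
        ]
    )
    products: list[ProductConfig] = Field(
        default_factory=lambda: [
            ProductConfig(id="P1", price=3.0, meat_per_unit=0.5, production_cost=0.1),
            ProductConfig(id="P2", price=3.0, meat_per_unit=1.0, production_cost=0.8),
            ProductConfig(id="P3", price=3.2, meat_per_unit=1.0, production_cost=0.2),
        ]
    )
    paths: PathsConfig = Field(default_factory=PathsConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)

    # -- factories --------------------------------------------------------
    def growth_params(self) -> GrowthParameters:
        return GrowthParameters(**self.growth)

    def economics_params(self) -> Economics:
        return Economics(**self.economics)

    def herd_spec(self) -> HerdSpec:
        return HerdSpec(
            cohort_size=self.herd.cohort_size,
            horizon_months=self.herd.horizon_months,
            sex_ratio=self.herd.sex_ratio,
            seed=self.seed,
        )

    def facility_objects(self) -> list[Facility]:
        return [Facility(f.id, f.slaughter_cost) for f in self.facilities]

    def product_objects(self) -> list[Product]:
        return [
            Product(
                p.id,
                price=p.price,
                meat_per_unit=p.meat_per_unit,
                production_cost=p.production_cost,
                holding_cost=p.holding_cost,
                inventory_cap=p.inventory_cap,
            )
            for p in self.products
        ]

    def config_hash(self) -> str:
        """Digest of the scientific configuration (paths excluded, so the
        same scenario hashes identically wherever its artifacts live)."""
        payload = self.model_dump()
        payload.pop("paths", None)
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
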