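"""Model parameter set: values, sensitivity bounds, and sampling distributions.

The package ships a complete built-in parameter table (unit costs,
adverse-event incidences, utilities, the average patient profile, fitted
survival parameters, the willingness-to-pay context, and the published
base-case/price-simulation figures that anchor the socazolimab calibration).
Users can load their own table from a YAML file with the same schema.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .costing import AEProfile, CostTable, PatientProfile, calibrate_socazolimab
from .psm import UtilitySet
from .survival import ParametricSurvival

__all__ = [
    "ParameterValue",
    "WTPContext",
    "ReportedBaseCase",
    "ParameterSet",
    "load_parameters",
    "default_parameters",
]

_SCHEMA = "pscea-parameters-v1"

_REQUIRED = (
    "cost_socazolimab_per_mg", "cost_etoposide_per_mg", "cost_carboplatin_per_mg",
    "cost_laboratory", "cost_radiology", "cost_anemia", "cost_leukocytopenia",
    "cost_neutropenia", "cost_thrombocytopenia", "cost_bsc",
    "ae_neutropenia_treatment", "ae_leukocytopenia_treatment",
    "ae_anemia_treatment", "ae_thrombocytopenia_treatment",
    "ae_neutropenia_control", "ae_leukocytopenia_control",
    "ae_anemia_control", "ae_thrombocytopenia_control",
    "utility_pfs", "utility_pd", "discount_rate", "weight", "bsa", "ccr",
)


@dataclass(frozen=True)
class ParameterValue:
    """One row of the parameter table."""

    base: float
    low: float
    high: float
    dist: str            # gamma | beta | normal | fixed
    group: str           # cost | incidence | utility | profile | setting
    repaired: bool = False

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"require low <= base <= high, got ({self.low}, {self.base}, {self.high})"
            )
        if self.dist not in ("gamma", "beta", "normal", "fixed"):
            raise ValueError(f"unknown distribution tag {self.dist!r}")


@dataclass(frozen=True)
class WTPContext:
    """Willingness-to-pay: a GDP-per-capita anchor times a multiplier."""

    gdp_per_capita: float = 95797.0
    multiplier: float = 3.0

    @property
    def wtp(self) -> float:
        return self.gdp_per_capita * self.multiplier


@dataclass(frozen=True)
class ReportedBaseCase:
    """Published base-case decomposition (inputs to the identity/price layer)."""

    cost_treatment: float
    cost_control: float
    delta_cost: float
    qaly_treatment: float
    qaly_control: float
    delta_qaly: float
    icer: float


class ParameterSet:
    """Everything the pipeline needs, addressable by parameter name.

    ``with_value(name, x)`` returns a copy with one parameter moved — the
    primitive both the one-way and probabilistic sensitivity analyses build on.
    """

    def __init__(
        self,
        values: dict[str, ParameterValue],
        survival: dict[str, dict[str, ParametricSurvival]],
        wtp: WTPContext,
        reported: ReportedBaseCase,
        price_rows: list[tuple[float, float]],
    ) -> None:
        missing = [n for n in _REQUIRED if n not in values]
        if missing:
            raise ValueError(f"parameter table is missing: {missing}")
        self.values = values
        self.survival = survival
        self.wtp = wtp
        self.reported = reported
        self.price_rows = price_rows

    # -- scalar access ---------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self.values[name].base

    def names(self) -> list[str]:
        return list(self.values)

    def with_value(self, name: str, value: float) -> "ParameterSet":
        if name not in self.values:
            raise KeyError(name)
        new = copy.copy(self)
        new.values = dict(self.values)
        old = self.values[name]
        lo, hi = min(old.low, value), max(old.high, value)
        new.values[name] = ParameterValue(value, lo, hi, old.dist, old.group, old.repaired)
        return new

    def with_values(self, updates: dict[str, float]) -> "ParameterSet":
        out = self
        for k, v in updates.items():
            out = out.with_value(k, v)
        return out

    # -- typed views -----------------------------------------------------
    def costs(self) -> CostTable:
        g = self.__getitem__
        return CostTable(
            socazolimab_per_mg=g("cost_socazolimab_per_mg"),
            etoposide_per_mg=g("cost_etoposide_per_mg"),
            carboplatin_per_mg=g("cost_carboplatin_per_mg"),
            laboratory_per_cycle=g("cost_laboratory"),
            radiology_per_cycle=g("cost_radiology"),
            anemia=g("cost_anemia"),
            leukocytopenia=g("cost_leukocytopenia"),
            neutropenia=g("cost_neutropenia"),
            thrombocytopenia=g("cost_thrombocytopenia"),
            bsc_per_cycle=g("cost_bsc"),
        )

    def profile(self) -> PatientProfile:
        return PatientProfile(
            weight=self["weight"], bsa=self["bsa"], ccr=self["ccr"]
        )

    def utilities(self) -> UtilitySet:
        return UtilitySet(u_pfs=self["utility_pfs"], u_pd=self["utility_pd"])

    def ae_profile(self, arm: str) -> AEProfile:
        if arm not in ("treatment", "control"):
            raise ValueError(f"arm must be 'treatment' or 'control', got {arm!r}")
        return AEProfile(
            neutropenia=self[f"ae_neutropenia_{arm}"],
            leukocytopenia=self[f"ae_leukocytopenia_{arm}"],
            anemia=self[f"ae_anemia_{arm}"],
            thrombocytopenia=self[f"ae_thrombocytopenia_{arm}"],
        )

    def survival_model(self, arm: str, endpoint: str) -> ParametricSurvival:
        return self.survival[arm][endpoint]

    def soca_calibrated_total(self) -> float:
        """Total discounted socazolimab spend from the published price rows."""
        return calibrate_socazolimab(self.price_rows)

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema": _SCHEMA,
            "currency": "CNY",
            "parameters": {
                name: {
                    "base": v.base, "low": v.low, "high": v.high,
                    "dist": v.dist, "group": v.group,
                    **({"repaired": True} if v.repaired else {}),
                }
                for name, v in self.values.items()
            },
            "survival": {
                arm: {
                    ep: {"family": m.family, "params": list(m.params)}
                    for ep, m in eps.items()
                }
                for arm, eps in self.survival.items()
            },
            "wtp": {
                "gdp_per_capita": self.wtp.gdp_per_capita,
                "multiplier": self.wtp.multiplier,
            },
            "reported": {
                "base_case": dict(self.reported.__dict__),
                "price_rows": [
                    {"fraction": f, "delta_cost": dc} for f, dc in self.price_rows
                ],
            },
        }

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def digest(self) -> str:
        """Stable content hash, recorded in run manifests."""
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def frame(self) -> pd.DataFrame:
        rows = [
            {"name": n, "base": v.base, "low": v.low, "high": v.high,
             "dist": v.dist, "group": v.group}
            for n, v in self.values.items()
        ]
        return pd.DataFrame(rows)


def _from_dict(doc: dict) -> ParameterSet:
    if doc.get("schema") != _SCHEMA:
        raise ValueError(
            f"unsupported parameter schema {doc.get('schema')!r}; expected {_SCHEMA!r}"
        )
    values = {
        name: ParameterValue(
            base=float(row["base"]), low=float(row["low"]), high=float(row["high"]),
            dist=str(row["dist"]), group=str(row["group"]),
            repaired=bool(row.get("repaired", False)),
        )
        for name, row in doc["parameters"].items()
    }
    survival = {
        arm: {
            ep: ParametricSurvival(spec["family"], tuple(spec["params"]))
            for ep, spec in eps.items()
        }
        for arm, eps in doc["survival"].items()
    }
    wtp = WTPContext(
        gdp_per_capita=float(doc["wtp"]["gdp_per_capita"]),
        multiplier=float(doc["wtp"]["multiplier"]),
    )
    bc = doc["reported"]["base_case"]
    reported = ReportedBaseCase(**{k: float(v) for k, v in bc.items()})
    price_rows = [
        (float(r["fraction"]), float(r["delta_cost"]))
        for r in doc["reported"]["price_rows"]
    ]
    return ParameterSet(values, survival, wtp, reported, price_rows)


def load_parameters(path: str | Path) -> ParameterSet:
    """Read a parameter table from a YAML file and validate it."""
    doc = yaml.safe_load(Path(path).read_text())
    return _from_dict(doc)


def default_parameters() -> ParameterSet:
    """The built-in parameter table shipped with the package."""
    text = (
        importlib.resources.files("pscea").joinpath("data/parameters.yaml").read_text()
    )
    return _from_dict(yaml.safe_load(text))
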