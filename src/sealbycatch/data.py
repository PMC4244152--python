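"""Survey–effort data structures and the 2012 Baltic grey-seal study dataset.

The study aggregates interview-survey data from professional coastal
fisheries into nine sub-areas (E1–E3 Estonia, F1–F3 Finland, S1–S3 Sweden).
For each sub-area and gear type (trap nets measured in gear-days, gill nets
in km-days) it records the by-catch reported by interviewed fishermen, the
fishing effort of the interviewed sample, and the total effort of the whole
fleet, together with the expected/spring/fall share of the grey-seal
population present in the sub-area.  Gill nets contribute to by-catch only
in the Swedish sub-areas S1 and S2.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

GEARS: tuple[str, str] = ("trap", "gill")
AREA_IDS: tuple[str, ...] = ("E1", "E2", "E3", "F1", "F2", "F3", "S1", "S2", "S3")
RESIDUAL_LABEL = "outside"

_COUNTRY_BY_PREFIX = {"E": "Estonia", "F": "Finland", "S": "Sweden"}


class SchemaError(ValueError):
    """A dataset file does not match the documented tabular schema."""


class ValidationError(ValueError):
    """A dataset violates a structural invariant (e.g. sampled > total effort)."""


@dataclass(frozen=True)
class GearData:
    """Survey and effort numbers for one gear in one sub-area."""

    sampled_bycatch: int = 0
    sampled_effort: float = 0.0
    total_effort: float = 0.0
    active: bool = True

    def __post_init__(self) -> None:
        if self.sampled_bycatch < 0:
            raise ValidationError("sampled_bycatch must be >= 0")
        if self.sampled_effort < 0 or self.total_effort < 0:
            raise ValidationError("efforts must be >= 0")
        if self.active and self.sampled_effort > self.total_effort:
            raise ValidationError(
                f"sampled_effort {self.sampled_effort} exceeds total_effort "
                f"{self.total_effort}"
            )
        if self.sampled_effort == 0 and self.sampled_bycatch != 0:
            raise ValidationError("non-zero by-catch with zero sampled effort")
        if not self.active and (
            self.sampled_bycatch or self.sampled_effort or self.total_effort
        ):
            raise ValidationError("inactive gear must carry zero effort and by-catch")


@dataclass(frozen=True)
class SubAreaRecord:
    """One sub-area: both gears, interview count and population proportions.

    ``prop_*`` are fractions of the total population (not percent).
    """

    area_id: str
    country: str
    trap: GearData
    gill: GearData
    n_interviews: int
    prop_expected: float
    prop_spring: float
    prop_fall: float

    def __post_init__(self) -> None:
        for name in ("prop_expected", "prop_spring", "prop_fall"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1] for {self.area_id}")
        if self.n_interviews < 0:
            raise ValidationError("n_interviews must be >= 0")

    def gear(self, name: str) -> GearData:
        if name not in GEARS:
            raise KeyError(name)
        return getattr(self, name)

    @property
    def sampled_bycatch_total(self) -> int:
        return self.trap.sampled_bycatch + self.gill.sampled_bycatch


@dataclass(frozen=True)
class StudyDataset:
    """The full survey: sub-area records plus population-count scalars.

    ``counted_seals`` is the 2012 moult count; the count is believed to see
    between ``count_efficiency_low`` and ``count_efficiency_high`` of the
    true population.  The expected proportions over the nine sub-areas need
    not sum to one; ``residual_proportion`` is the share of the population
    outside the study area.
    """

    records: tuple[SubAreaRecord, ...]
    counted_seals: int = 28255
    count_efficiency_low: float = 0.70
    count_efficiency_high: float = 0.85

    def __post_init__(self) -> None:
        ids = [r.area_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate area_id")
        total = sum(r.prop_expected for r in self.records)
        if total > 1.0 + 1e-9:
            raise ValidationError("expected proportions sum above 1")

    # -- basic access ------------------------------------------------------

    @property
    def area_ids(self) -> list[str]:
        return [r.area_id for r in self.records]

    @property
    def countries(self) -> list[str]:
        return [r.country for r in self.records]

    @property
    def n_areas(self) -> int:
        return len(self.records)

    def by_area(self, area_id: str) -> SubAreaRecord:
        for r in self.records:
            if r.area_id == area_id:
                return r
        raise KeyError(area_id)

    @property
    def residual_proportion(self) -> float:
        return round(1.0 - sum(r.prop_expected for r in self.records), 12)

    # -- array views used by the model layer -------------------------------

    def bycatch_sampled(self) -> np.ndarray:
        """(n_areas, 2) integer array of sampled by-catch [trap, gill]."""
        return np.array(
            [[r.trap.sampled_bycatch, r.gill.sampled_bycatch] for r in self.records],
            dtype=np.int64,
        )

    def efforts_sampled(self) -> np.ndarray:
        return np.array(
            [[r.trap.sampled_effort, r.gill.sampled_effort] for r in self.records],
            dtype=float,
        )

    def efforts_total(self) -> np.ndarray:
        return np.array(
            [[r.trap.total_effort, r.gill.total_effort] for r in self.records],
            dtype=float,
        )

    def active_mask(self) -> np.ndarray:
        return np.array(
            [[r.trap.active, r.gill.active] for r in self.records], dtype=bool
        )

    def sampled_mask(self) -> np.ndarray:
        """(gear, area) pairs that carry survey information."""
        return self.active_mask() & (self.efforts_sampled() > 0)

    def prop_expected_vector(self, include_residual: bool = True) -> np.ndarray:
        props = [r.prop_expected for r in self.records]
        if include_residual:
            props.append(self.residual_proportion)
        return np.asarray(props, dtype=float)

    @property
    def composition_labels(self) -> list[str]:
        return self.area_ids + [RESIDUAL_LABEL]


@dataclass
class RunConfig:
    """MCMC run settings (seed, lengths, adaptation and reporting levels)."""

    seed: int = 0
    n_chains: int = 4
    n_iterations: int = 50_000
    n_burnin: int = 20_000
    thinning: int = 10
    adapt: bool = True
    target_acceptance: float = 0.3
    n_area_transfers: int = 10
    quantile_levels: tuple[float, ...] = (0.05, 0.5, 0.8, 0.95)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")
        if self.n_burnin > self.n_iterations:
            raise ValidationError("n_burnin must not exceed n_iterations")
        if self.thinning < 1:
            raise ValidationError("thinning must be >= 1")
        if not 0 < self.target_acceptance < 1:
            raise ValidationError("target_acceptance must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown RunConfig fields: {sorted(unknown)}")
        if "quantile_levels" in d:
            d = {**d, "quantile_levels": tuple(d["quantile_levels"])}
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["quantile_levels"] = list(self.quantile_levels)
        return d

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(path.read_text()))
        return cls.from_dict(json.loads(path.read_text()))


# ---------------------------------------------------------------------------
# The printed study table (per-cent proportions converted to fractions).
# Row layout: trap (y, E_sample, E_total), gill (y, E_sample, E_total),
# interviews, expected %, spring %, fall %.
_TABLE1 = {
    "E1": ((104, 2458, 11772), None, 34, 6.25, 7.5, 5.0),
    "E2": ((59, 1542, 8722), None, 25, 6.25, 7.5, 5.0),
    "E3": ((10, 1096, 3135), None, 13, 1.75, 0.5, 3.0),
    "F1": ((45, 23533, 36636), None, 25, 1.75, 0.5, 3.0),
    "F2": ((5, 3823, 58863), None, 10, 30.0, 35.0, 25.0),
    "F3": ((0, 0, 5057), None, 0, 2.0, 0.0, 4.0),
    "S1": ((0, 0, 8515), (20, 1402, 7904), 13, 22.5, 25.0, 20.0),
    "S2": ((61, 2450, 2563), (35, 1540, 1611), 41, 16.5, 15.0, 18.0),
    "S3": ((0, 0, 4806), None, 0, 2.0, 0.0, 4.0),
}


def load_table1_fixture() -> StudyDataset:
    """The 2012 survey dataset exactly as published.

    Trap nets are active in every sub-area (S1's trap row has zero sampled
    effort because no trap-net fishermen from S1 were interviewed); gill
    nets are active only in S1 and S2.
    """
    records = []
    for area_id, (trap, gill, n_int, e, sp, fa) in _TABLE1.items():
        records.append(
            SubAreaRecord(
                area_id=area_id,
                country=_COUNTRY_BY_PREFIX[area_id[0]],
                trap=GearData(*[float(x) if i else int(x) for i, x in enumerate(trap)]),
                gill=GearData(*[float(x) if i else int(x) for i, x in enumerate(gill)])
                if gill is not None
                else GearData(active=False),
                n_interviews=n_int,
                prop_expected=e / 100.0,
                prop_spring=sp / 100.0,
                prop_fall=fa / 100.0,
            )
        )
    return StudyDataset(records=tuple(records))


# ---------------------------------------------------------------------------
# Tabular IO.  CSV schema: one row per (area, gear) with columns
#   area_id, country, gear, sampled_bycatch, sampled_effort, total_effort,
#   n_interviews, prop_expected, prop_spring, prop_fall
# Areas with no gill row have the gill gear marked inactive.  JSON mirrors
# the same content and additionally carries the dataset-level scalars; the
# CSV reader uses the published scalar defaults.

_CSV_COLUMNS = [
    "area_id",
    "country",
    "gear",
    "sampled_bycatch",
    "sampled_effort",
    "total_effort",
    "n_interviews",
    "prop_expected",
    "prop_spring",
    "prop_fall",
]


def dataset_to_frame(data: StudyDataset) -> pd.DataFrame:
    rows = []
    for r in data.records:
        for gear in GEARS:
            g = r.gear(gear)
            if not g.active:
                continue
            rows.append(
                {
                    "area_id": r.area_id,
                    "country": r.country,
                    "gear": gear,
                    "sampled_bycatch": g.sampled_bycatch,
                    "sampled_effort": g.sampled_effort,
                    "total_effort": g.total_effort,
                    "n_interviews": r.n_interviews,
                    "prop_expected": r.prop_expected,
                    "prop_spring": r.prop_spring,
                    "prop_fall": r.prop_fall,
                }
            )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def _records_from_frame(df: pd.DataFrame) -> tuple[SubAreaRecord, ...]:
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing dataset columns: {sorted(missing)}")
    records = []
    for area_id in df["area_id"].drop_duplicates():
        sub = df[df["area_id"] == area_id]
        gears: dict[str, GearData] = {}
        for _, row in sub.iterrows():
            gear = row["gear"]
            if gear not in GEARS:
                raise SchemaError(f"unknown gear {gear!r} for area {area_id}")
            if gear in gears:
                raise SchemaError(f"duplicate {gear} row for area {area_id}")
            try:
                gears[gear] = GearData(
                    sampled_bycatch=int(row["sampled_bycatch"]),
                    sampled_effort=float(row["sampled_effort"]),
                    total_effort=float(row["total_effort"]),
                )
            except (TypeError, ValueError) as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise SchemaError(
                    f"malformed numeric value in area {area_id}, gear {gear}: {exc}"
                ) from exc
        first = sub.iloc[0]
        records.append(
            SubAreaRecord(
                area_id=str(area_id),
                country=str(first["country"]),
                trap=gears.get("trap", GearData(active=False)),
                gill=gears.get("gill", GearData(active=False)),
                n_interviews=int(first["n_interviews"]),
                prop_expected=float(first["prop_expected"]),
                prop_spring=float(first["prop_spring"]),
                prop_fall=float(first["prop_fall"]),
            )
        )
    return tuple(records)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise SchemaError(f"cannot infer dataset format from {path.name!r}")


def write_dataset(data: StudyDataset, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        # shortest full-precision repr keeps round-trips lossless
        dataset_to_frame(data).to_csv(
            path, index=False, float_format=lambda x: repr(float(x))
        )
    elif fmt == "json":
        payload = {
            "counted_seals": data.counted_seals,
            "count_efficiency_low": data.count_efficiency_low,
            "count_efficiency_high": data.count_efficiency_high,
            "records": dataset_to_frame(data).to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise SchemaError(f"unsupported dataset format {fmt!r}")


def read_dataset(path: str | Path, fmt: str | None = None) -> StudyDataset:
    """Read a survey dataset from CSV or JSON, enforcing all invariants."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:  # malformed CSV
            raise SchemaError(f"cannot parse {path}: {exc}") from exc
        return StudyDataset(records=_records_from_frame(df))
    if fmt == "json":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(f"cannot parse {path}: {exc}") from exc
        if "records" not in payload:
            raise SchemaError("JSON dataset missing 'records'")
        df = pd.DataFrame(payload["records"])
        return StudyDataset(
            records=_records_from_frame(df),
            counted_seals=int(payload.get("counted_seals", 28255)),
            count_efficiency_low=float(payload.get("count_efficiency_low", 0.70)),
            count_efficiency_high=float(payload.get("count_efficiency_high", 0.85)),
        )
    raise SchemaError(f"unsupported dataset format {fmt!r}")
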