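"""Reading and writing landmark configurations and specimen metadata.

Two interchange formats are supported:

* the canonical long-format landmark table — CSV with columns
  ``specimen_id,point_index,x,y,z`` (``point_index`` 1-based), which
  round-trips coordinates at full precision;
* the ``tps`` landmark dialect (``LM3=<k>`` header, k lines of 3 floats,
  ``ID=<id>`` per specimen block) for interchange with standard
  morphometrics software.

Specimen metadata is a CSV with columns
``specimen_id,subspecies,habitat,mobility,sex,limb[,side]``.  Enum tokens
are matched case- and space-insensitively.  When a ``side`` column is
present, left-side configurations are mirrored (x negated) to the right
side at dataset assembly, so that reflection never enters the Procrustes
fit.

Units are millimetres throughout; no conversion is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .templates import LandmarkTemplate, Limb, template_for_limb

logger = logging.getLogger(__name__)

__all__ = [
    "Subspecies",
    "Habitat",
    "Mobility",
    "Sex",
    "LandmarkConfiguration",
    "SpecimenRecord",
    "Dataset",
    "read_landmark_table",
    "write_landmark_table",
    "read_tps_file",
    "write_tps_file",
    "load_metadata",
    "write_metadata",
    "load_study_metadata",
    "build_dataset",
]


class Subspecies(str, Enum):
    CARIBOU = "caribou"
    GRANTI = "granti"
    GROENLANDICUS = "groenlandicus"
    PEARYI = "pearyi"


class Habitat(str, Enum):
    MOUNTAIN = "mountain"
    TUNDRA = "tundra"
    BOREAL_FOREST = "boreal_forest"


class Mobility(str, Enum):
    ALTITUDINAL = "altitudinal"
    PLANARLY = "planarly"
    SEDENTARY = "sedentary"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


#: Group-label vocabulary of the 7 subspecies+habitat+mobility combinations.
_SUBSPECIES_LABEL = {
    Subspecies.CARIBOU: "Rtcaribou",
    Subspecies.GRANTI: "Rtgranti",
    Subspecies.GROENLANDICUS: "Rtgroenlandicus",
    Subspecies.PEARYI: "Rtpeary",
}
_HABITAT_LABEL = {
    Habitat.MOUNTAIN: "Mountain",
    Habitat.TUNDRA: "Tundra",
    Habitat.BOREAL_FOREST: "BorealForest",
}
_MOBILITY_LABEL = {
    Mobility.ALTITUDINAL: "Altitudinal",
    Mobility.PLANARLY: "Planarly",
    Mobility.SEDENTARY: "Sedentary",
}

VALID_GROUPS = frozenset(
    {
        "Rtcaribou_BorealForest_Sedentary",
        "Rtcaribou_Mountain_Altitudinal",
        "Rtcaribou_Mountain_Sedentary",
        "Rtcaribou_Tundra_Planarly",
        "Rtgranti_Tundra_Planarly",
        "Rtgroenlandicus_Tundra_Planarly",
        "Rtpeary_Tundra_Planarly",
    }
)


def _parse_enum(enum_cls, token: str, column: str):
    norm = str(token).strip().lower().replace(" ", "_").replace("-", "_")
    for member in enum_cls:
        if member.value == norm:
            return member
    valid = ", ".join(m.value for m in enum_cls)
    raise ValueError(
        f"unknown {column} value {token!r}; expected one of: {valid}"
    )


@dataclass
class LandmarkConfiguration:
    """One specimen's k x 3 landmark coordinates, in millimetres."""

    specimen_id: str
    limb: Limb
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.limb = Limb(self.limb)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(
                f"specimen {self.specimen_id!r}: coordinates must be k x 3, "
                f"got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"specimen {self.specimen_id!r}: non-finite coordinates")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class SpecimenRecord:
    specimen_id: str
    subspecies: Subspecies
    habitat: Habitat
    mobility: Mobility
    sex: Sex = Sex.UNKNOWN
    limb: Limb = Limb.FORE
    side: str | None = None

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(
                f"specimen {self.specimen_id!r}: subspecies/habitat/mobility "
                f"combination {self.group!r} is not one of the sampled groups"
            )

    @property
    def group(self) -> str:
        """Composite subspecies+habitat+mobility label, e.g. Rtcaribou_Tundra_Planarly."""
        return "_".join(
            (
                _SUBSPECIES_LABEL[self.subspecies],
                _HABITAT_LABEL[self.habitat],
                _MOBILITY_LABEL[self.mobility],
            )
        )

    def factor(self, name: str) -> str:
        """Value of a (possibly composite) grouping factor for this specimen."""
        parts = name.replace("*", "+").split("+")
        vals = []
        for part in parts:
            part = part.strip().lower()
            if part in ("subspecies", "ssp"):
                vals.append(self.subspecies.value)
            elif part == "habitat":
                vals.append(self.habitat.value)
            elif part == "mobility":
                vals.append(self.mobility.value)
            elif part in ("composite", "group"):
                vals.append(self.group)
            elif part == "sex":
                vals.append(self.sex.value)
            else:
                raise KeyError(f"unknown factor {part!r}")
        return "+".join(vals)


@dataclass
class Dataset:
    """A template, one landmark configuration per specimen, and its metadata."""

    template: LandmarkTemplate
    configurations: list[LandmarkConfiguration]
    records: list[SpecimenRecord]

    def __post_init__(self) -> None:
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate specimen ids among configurations")
        rec_ids = [r.specimen_id for r in self.records]
        if sorted(ids) != sorted(rec_ids):
            raise ValueError("configurations and metadata records do not match 1:1")
        by_id = {r.specimen_id: r for r in self.records}
        self.records = [by_id[i] for i in ids]
        for cfg in self.configurations:
            self.template.validate_coords(cfg.coords, cfg.specimen_id)

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def coords_array(self) -> np.ndarray:
        """All configurations stacked as an (n, k, 3) array."""
        return np.stack([c.coords for c in self.configurations])

    def labels(self, factor: str) -> np.ndarray:
        return np.array([r.factor(factor) for r in self.records])

    def subset(self, mask: Sequence[bool]) -> "Dataset":
        mask = np.asarray(mask, dtype=bool)
        return Dataset(
            template=self.template,
            configurations=[c for c, m in zip(self.configurations, mask) if m],
            records=[r for r, m in zip(self.records, mask) if m],
        )

    def with_coords(self, coords: np.ndarray) -> "Dataset":
        """Copy of the dataset with replaced coordinates (same order)."""
        coords = np.asarray(coords, dtype=float)
        cfgs = [
            LandmarkConfiguration(c.specimen_id, c.limb, x)
            for c, x in zip(self.configurations, coords)
        ]
        return Dataset(self.template, cfgs, list(self.records))


# ---------------------------------------------------------------------------
# canonical long-format landmark table


def read_landmark_table(
    path: str | Path, template: LandmarkTemplate
) -> list[LandmarkConfiguration]:
    """Read the canonical CSV landmark table, one configuration per specimen."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"specimen_id", "point_index", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("x", "y", "z"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad.index[0]) + 2  # header + 1-based
            raise ValueError(f"{path}: non-numeric {col!r} value at line {line}")
    configs = []
    for sid, block in df.groupby("specimen_id", sort=False):
        block = block.sort_values("point_index")
        if len(block) != template.n_points:
            raise ValueError(
                f"specimen {sid!r}: {len(block)} points in file but the "
                f"{template.limb.value} template defines {template.n_points}"
            )
        expected = np.arange(1, template.n_points + 1)
        if not np.array_equal(block["point_index"].to_numpy(), expected):
            raise ValueError(f"specimen {sid!r}: point_index is not 1..{template.n_points}")
        configs.append(
            LandmarkConfiguration(
                str(sid), template.limb, block[["x", "y", "z"]].to_numpy(float)
            )
        )
    return configs


def write_landmark_table(
    configs: Iterable[LandmarkConfiguration], path: str | Path
) -> None:
    frames = []
    for cfg in configs:
        k = cfg.n_points
        frames.append(
            pd.DataFrame(
                {
                    "specimen_id": cfg.specimen_id,
                    "point_index": np.arange(1, k + 1),
                    "x": cfg.coords[:, 0],
                    "y": cfg.coords[:, 1],
                    "z": cfg.coords[:, 2],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    # repr-roundtrip float formatting: read_csv restores the exact doubles
    out.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# tps dialect


def read_tps_file(path: str | Path, limb: Limb | str = Limb.FORE) -> list[LandmarkConfiguration]:
    """Parse a tps landmark file (LM3= blocks) into configurations."""
    limb = Limb(limb)
    configs: list[LandmarkConfiguration] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    block = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.upper().startswith("LM3="):
            raise ValueError(
                f"{path}: expected 'LM3=' header at line {i}, got {line!r}"
            )
        block += 1
        k = int(line.split("=", 1)[1])
        coords = np.empty((k, 3))
        for j in range(k):
            try:
                coords[j] = [float(v) for v in lines[i].split()]
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: bad coordinate line {i + 1}") from exc
            i += 1
        specimen_id = f"specimen_{block}"
        while i < len(lines) and lines[i].strip() and "=" in lines[i] and not lines[
            i
        ].strip().upper().startswith("LM3="):
            key, _, value = lines[i].strip().partition("=")
            if key.upper() == "ID":
                specimen_id = value.strip()
            else:
                logger.warning("%s: ignoring unsupported tps field %r", path, key)
            i += 1
        configs.append(LandmarkConfiguration(specimen_id, limb, coords))
    return configs


def write_tps_file(configs: Iterable[LandmarkConfiguration], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"LM3={cfg.n_points}\n")
            for x, y, z in cfg.coords:
                fh.write(f"{x:.10f} {y:.10f} {z:.10f}\n")
            fh.write(f"ID={cfg.specimen_id}\n")


# ---------------------------------------------------------------------------
# metadata


def load_metadata(path: str | Path) -> list[SpecimenRecord]:
    """Read a specimen metadata CSV into validated records."""
    df = pd.read_csv(path, dtype=str)
    required = {"specimen_id", "subspecies", "habitat", "mobility", "limb"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        sex = row.get("sex")
        side = row.get("side")
        records.append(
            SpecimenRecord(
                specimen_id=str(row["specimen_id"]).strip(),
                subspecies=_parse_enum(Subspecies, row["subspecies"], "subspecies"),
                habitat=_parse_enum(Habitat, row["habitat"], "habitat"),
                mobility=_parse_enum(Mobility, row["mobility"], "mobility"),
                sex=_parse_enum(Sex, sex, "sex") if pd.notna(sex) else Sex.UNKNOWN,
                limb=Limb(str(row["limb"]).strip().lower()),
                side=str(side).strip().lower() if pd.notna(side) else None,
            )
        )
    return records


def write_metadata(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    rows = [
        {
            "specimen_id": r.specimen_id,
            "subspecies": r.subspecies.value,
            "habitat": r.habitat.value,
            "mobility": r.mobility.value,
            "sex": r.sex.value,
            "limb": r.limb.value,
            **({"side": r.side} if r.side else {}),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_study_metadata(limb: Limb | str) -> list[SpecimenRecord]:
    """Packaged study-design metadata fixture for one limb (34 fore / 44 hind)."""
    limb = Limb(limb)
    name = f"study_metadata_{limb.value}.csv"
    with resources.as_file(resources.files("phalanxgmm.data") / name) as p:
        return load_metadata(p)


def build_dataset(
    configs: Sequence[LandmarkConfiguration],
    records: Sequence[SpecimenRecord],
    template: LandmarkTemplate | None = None,
) -> Dataset:
    """Assemble a Dataset, mirroring left-side configurations to the right.

    If a record carries ``side == 'left'`` the configuration's x coordinates
    are negated, standardizing all specimens to one side before analysis.
    Without a side column, input is assumed pre-standardized.
    """
    if template is None:
        if not configs:
            raise ValueError("cannot infer template from an empty configuration list")
        template = template_for_limb(configs[0].limb)
    by_id = {r.specimen_id: r for r in records}
    mirrored = []
    for cfg in configs:
        rec = by_id.get(cfg.specimen_id)
        if rec is not None and rec.side == "left":
            coords = cfg.coords.copy()
            coords[:, 0] *= -1.0
            cfg = LandmarkConfiguration(cfg.specimen_id, cfg.limb, coords)
        mirrored.append(cfg)
    return Dataset(template, mirrored, list(records))
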