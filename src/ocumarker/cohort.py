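"""Cohort table container: samples x variables with per-variable metadata.

The table is a thin wrapper around a :class:`pandas.DataFrame` (rows = eyes /
participants, columns = variables) plus a sidecar of per-variable metadata
(role, measurement scale, compartment, detection limit).  Analyte
concentrations below their detection limit are stored as 0 with the detected
flag cleared; missing cells are ``NaN`` and are distinct from censored zeros.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ROLES = ("dependent-candidate", "independent", "identifier")
SCALES = ("continuous", "dichotomous", "nominal")
COMPARTMENTS = ("plasma", "AqH", None)

GROUP_COLUMN = "group"
CONTROL = "control"
GLAUCOMA = "glaucoma"


@dataclass
class VariableMeta:
    """Metadata for one cohort variable.

    Parameters
    ----------
    role : str
        One of ``dependent-candidate``, ``independent`` or ``identifier``.
    scale : str
        Measurement scale: ``continuous``, ``dichotomous`` or ``nominal``.
    compartment : str or None
        ``plasma`` or ``AqH`` for analyte columns, ``None`` otherwise.
    lod : float
        Assay detection limit (same units as the column); 0 means none.
    """

    role: str = "independent"
    scale: str = "continuous"
    compartment: str | None = None
    lod: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.lod < 0:
            raise ValueError("lod must be >= 0")

    @property
    def is_analyte(self) -> bool:
        return self.compartment is not None


class CohortTable:
    """Samples x variables matrix with per-variable metadata.

    ``data`` holds one row per sample; the index carries unique sample
    identifiers and a ``group`` column the two-group labels.  ``meta`` maps
    every non-group column name to its :class:`VariableMeta`.
    """

    def __init__(self, data: pd.DataFrame, meta: Mapping[str, VariableMeta]):
        if data.index.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        missing_meta = [c for c in data.columns if c != GROUP_COLUMN and c not in meta]
        if missing_meta:
            raise ValueError(f"columns without metadata: {missing_meta}")
        self.data = data
        self.meta = dict(meta)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def groups(self) -> pd.Series:
        return self.data[GROUP_COLUMN]

    def columns_by(self, *, role: str | None = None, scale: str | None = None,
                   compartment: str | None = "__any__") -> list[str]:
        out = []
        for name, m in self.meta.items():
            if name not in self.data.columns:
                continue
            if role is not None and m.role != role:
                continue
            if scale is not None and m.scale != scale:
                continue
            if compartment != "__any__" and m.compartment != compartment:
                continue
            out.append(name)
        return out

    def analyte_columns(self, compartment: str | None = None) -> list[str]:
        return [n for n, m in self.meta.items()
                if m.is_analyte and n in self.data.columns
                and (compartment is None or m.compartment == compartment)]

    def detected(self, column: str) -> pd.Series:
        """Detected flags for an analyte column.

        Censored cells are stored as 0, so a cell is detected iff it is
        observed and strictly positive.
        """
        m = self.meta.get(column)
        if m is None or not m.is_analyte:
            raise KeyError(f"{column!r} is not an analyte column")
        vals = self.data[column]
        return vals.notna() & (vals > 0)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), {k: VariableMeta(**asdict(v))
                                              for k, v in self.meta.items()})

    # -- round-trippable serialization ----------------------------------------

    def write(self, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write the table as CSV (empty cell = missing) + JSON metadata sidecar."""
        csv_path = Path(csv_path)
        self.data.to_csv(csv_path, index_label="sample_id")
        if sidecar_path is None:
            sidecar_path = csv_path.with_suffix(".meta.json")
        sidecar = {name: asdict(m) for name, m in self.meta.items()}
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read(cls, csv_path: str | Path, sidecar_path: str | Path | None = None) -> "CohortTable":
        csv_path = Path(csv_path)
        if sidecar_path is None:
            sidecar_path = csv_path.with_suffix(".meta.json")
        sidecar = json.loads(Path(sidecar_path).read_text())
        meta = {name: VariableMeta(**m) for name, m in sidecar.items()}
        nominal = [n for n, m in meta.items() if m.scale == "nominal"]
        data = pd.read_csv(csv_path, index_col="sample_id",
                           dtype={c: "object" for c in nominal + [GROUP_COLUMN]})
        return cls(data, meta)


def split_groups(table: CohortTable, column: str) -> tuple[pd.Series, pd.Series]:
    """Return the (control, glaucoma) values of one column, missing dropped."""
    g = table.groups
    vals = table.data[column]
    return (vals[g == CONTROL].dropna(), vals[g == GLAUCOMA].dropna())
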