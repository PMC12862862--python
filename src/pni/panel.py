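"""Longitudinal athlete panel container.

The in-memory representation is a wide :class:`pandas.DataFrame` with one row
per (athlete, time point): metadata columns ``athlete_id, group, tertile,
age, time_index`` followed by the feature columns.  The on-disk dialect is a
long-format CSV (``athlete_id,group,tertile,time_index,feature,value``) with
a JSON sidecar carrying the generating spec, seed and ground-truth
degradation mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

META_COLUMNS = ("athlete_id", "group", "tertile", "age", "time_index")


class PanelError(ValueError):
    """Raised on malformed panel input."""


@dataclass
class AthletePanel:
    """Wide-format longitudinal panel plus optional degradation ground truth.

    ``mask`` (if present) is a tidy frame of injected degradations:
    columns ``athlete_id, time_index, feature, kind, true_value`` with
    ``kind`` in {"missing", "outlier"}.
    """

    data: pd.DataFrame
    mask: pd.DataFrame | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("athlete_id", "time_index") if c not in self.data.columns]
        if missing:
            raise PanelError(f"panel is missing required columns {missing}")
        dup = self.data.duplicated(["athlete_id", "time_index"])
        if dup.any():
            raise PanelError("duplicate (athlete_id, time_index) rows in panel")
        self.data = self.data.sort_values(["athlete_id", "time_index"]).reset_index(drop=True)

    # -- views ----------------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def athlete_ids(self) -> np.ndarray:
        return self.data["athlete_id"].unique()

    @property
    def n_athletes(self) -> int:
        return int(self.data["athlete_id"].nunique())

    @property
    def n_timepoints(self) -> int:
        return int(self.data["time_index"].nunique())

    @property
    def time_indices(self) -> np.ndarray:
        return np.sort(self.data["time_index"].unique())

    def meta(self) -> pd.DataFrame:
        """One row of static metadata per athlete."""
        cols = [c for c in META_COLUMNS if c in self.data.columns and c != "time_index"]
        return self.data[cols].drop_duplicates("athlete_id").set_index("athlete_id")

    def at_time(self, t: int) -> pd.DataFrame:
        return self.data[self.data["time_index"] == t]

    def tensor(self, features: list[str] | None = None) -> np.ndarray:
        """(n_athletes, T, D) array, athletes and times sorted."""
        feats = features if features is not None else self.feature_names
        wide = self.data.pivot_table(index="athlete_id", columns="time_index",
                                     values=feats, sort=True)
        n, t = self.n_athletes, self.n_timepoints
        out = np.empty((n, t, len(feats)))
        for j, f in enumerate(feats):
            out[:, :, j] = wide[f].to_numpy()
        return out

    def series(self, feature: str) -> pd.DataFrame:
        """athletes x time matrix of one feature."""
        return self.data.pivot(index="athlete_id", columns="time_index", values=feature)

    def copy(self) -> "AthletePanel":
        return AthletePanel(self.data.copy(),
                            None if self.mask is None else self.mask.copy(),
                            dict(self.attrs))

    def missing_fraction_per_athlete(self) -> pd.Series:
        feats = self.feature_names
        return self.data.groupby("athlete_id")[feats].apply(
            lambda g: float(g.isna().to_numpy().mean())
        )

    # -- long-format I/O -------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        id_vars = [c for c in META_COLUMNS if c in self.data.columns]
        return self.data.melt(id_vars=id_vars, var_name="feature", value_name="value")

    @classmethod
    def from_long(cls, long: pd.DataFrame, mask: pd.DataFrame | None = None,
                  attrs: dict | None = None) -> "AthletePanel":
        for col in ("athlete_id", "time_index", "feature", "value"):
            if col not in long.columns:
                raise PanelError(f"long-format panel is missing column {col!r}")
        wide = long.pivot(index=["athlete_id", "time_index"], columns="feature",
                          values="value").reset_index()
        wide.columns.name = None
        meta_cols = [c for c in META_COLUMNS
                     if c in long.columns and c not in ("athlete_id", "time_index")]
        if meta_cols:
            meta = long.drop_duplicates("athlete_id")[["athlete_id", *meta_cols]]
            wide = wide.merge(meta, on="athlete_id", how="left")
            wide = wide[["athlete_id", *meta_cols, "time_index",
                         *[c for c in wide.columns
                           if c not in META_COLUMNS]]]
        return cls(wide, mask, attrs or {})

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        self.to_long().to_csv(path, index=False, float_format="%.10g")
        if sidecar:
            payload = {"attrs": _jsonable(self.attrs)}
            if self.mask is not None:
                payload["mask"] = self.mask.to_dict(orient="list")
            path.with_suffix(".json").write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "AthletePanel":
        path = Path(path)
        long = pd.read_csv(path)
        mask, attrs = None, {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            payload = json.loads(sidecar.read_text())
            attrs = payload.get("attrs", {})
            if "mask" in payload:
                mask = pd.DataFrame(payload["mask"])
        return cls.from_long(long, mask, attrs)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
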