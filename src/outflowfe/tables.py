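"""Fitted-parameter tables: fixture loading and the ParamTable container.

The four CSV fixtures shipped under ``outflowfe/data`` hold the calibrated
viscoelastic parameter sets for the TM-patch models (tables 1-2) and the
per-eye TM/JCT/SC-wall complex models in healthy and glaucoma eyes
(tables 3-4).  Rows carry ``(model_id, condition, flow, group, G0_MPa,
Ginf_MPa, beta_per_s)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .material import ViscoelasticParams
from .meshing import TissueTag

__all__ = ["ParamTable", "load_table", "ground_truth_set", "GROUP_TO_TAG"]

#: tissue/beam group names as used in the fixtures mapped to mesh tags;
#: beam groups are keyed by their host tissue tag.
GROUP_TO_TAG = {
    "TM": TissueTag.TM,
    "JCT": TissueTag.JCT,
    "SC_wall": TissueTag.SC_WALL,
    "TM_beam": TissueTag.TM,
    "JCT_beam": TissueTag.JCT,
}

ECM_GROUPS = ("TM", "JCT", "SC_wall")
BEAM_GROUPS = ("TM_beam", "JCT_beam")

BETA_ECM = 109.0
BETA_BEAM = 450.0


@dataclass
class ParamTable:
    """A fitted-parameter table (thin wrapper around a DataFrame)."""

    df: pd.DataFrame

    def __post_init__(self):
        required = {"group", "G0_MPa", "Ginf_MPa", "beta_per_s"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"parameter table lacks columns {sorted(missing)}")
        if (self.df["G0_MPa"] <= 0).any() or (self.df["Ginf_MPa"] <= 0).any():
            raise ValueError("moduli must be positive")

    @classmethod
    def from_csv(cls, path) -> "ParamTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path):
        self.df.to_csv(path, index=False)

    def select(self, group=None, condition=None, flow=None) -> pd.DataFrame:
        d = self.df
        if group is not None:
            d = d[d["group"] == group]
        if condition is not None and "condition" in d.columns:
            d = d[d["condition"] == condition]
        if flow is not None and "flow" in d.columns:
            d = d[d["flow"] == flow]
        return d

    def params(self, group: str, model_id=None) -> ViscoelasticParams:
        d = self.select(group=group)
        if model_id is not None:
            d = d[d["model_id"] == model_id]
        if d.empty:
            raise KeyError(f"no rows for group={group!r} model_id={model_id!r}")
        row = d.iloc[0]
        return ViscoelasticParams(
            g0=float(row["G0_MPa"]),
            ginf=float(row["Ginf_MPa"]),
            beta=float(row["beta_per_s"]),
        )


def load_table(n: int) -> ParamTable:
    """Load fixture table 1-4."""
    if n not in (1, 2, 3, 4):
        raise ValueError("table number must be 1..4")
    with resources.files("outflowfe.data").joinpath(f"table{n}.csv").open() as fh:
        return ParamTable(pd.read_csv(fh))


def ground_truth_set(model_id: str = "115LF") -> dict:
    """Ground-truth parameter map for one eye model from tables 3/4.

    Returns ``{group_name: ViscoelasticParams}`` for the five calibrated
    groups (three ECM tissues + two beam groups).
    """
    table = load_table(3)
    if model_id not in set(table.df.get("model_id", [])):
        table = load_table(4)
    if model_id not in set(table.df.get("model_id", [])):
        raise KeyError(f"unknown model id {model_id!r}")
    out = {}
    for group in ECM_GROUPS + BEAM_GROUPS:
        out[group] = table.params(group, model_id=model_id)
    return out
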