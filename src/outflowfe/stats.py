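"""One-way ANOVA, Scheffe post hoc comparisons and fold-change reporting."""

from __future__ import annotations

from typing import Dict, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import ParamTable

__all__ = [
    "AnovaResult",
    "one_way_anova",
    "scheffe_posthoc",
    "fold_change",
    "write_report",
]


class AnovaResult(NamedTuple):
    f: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    flag: str = ""


def _check_groups(groups):
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    return gs


def one_way_anova(groups: Sequence) -> AnovaResult:
    """Classical between/within mean-square F test with (k-1, N-k) dof.

    Degenerate inputs are flagged: identical groups give F = 0, p = 1; zero
    within-group variance with unequal means gives p = 0 with a flag.
    """
    gs = _check_groups(groups)
    k = len(gs)
    n_tot = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    dfb, dfw = k - 1, n_tot - k
    msb = ssb / dfb
    msw = ssw / dfw
    if msw == 0.0:
        if msb == 0.0:
            return AnovaResult(0.0, 1.0, dfb, dfw, 0.0, "all values identical")
        return AnovaResult(np.inf, 0.0, dfb, dfw, 0.0,
                           "zero within-group variance with unequal means")
    f = msb / msw
    p = float(sps.f.sf(f, dfb, dfw))
    return AnovaResult(float(f), p, dfb, dfw, float(msw))


def scheffe_posthoc(groups: Sequence, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise contrasts with the Scheffe criterion.

    A pair (i, j) is significant when the contrast statistic
    ``(mean_i - mean_j)^2 / (MSW (1/n_i + 1/n_j))`` exceeds
    ``(k - 1) F_crit(alpha; k-1, N-k)``.
    """
    gs = _check_groups(groups)
    an = one_way_anova(gs)
    k = len(gs)
    f_crit = float(sps.f.isf(alpha, an.df_between, an.df_within))
    crit = (k - 1) * f_crit
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = gs[i].mean() - gs[j].mean()
            denom = an.ms_within * (1.0 / gs[i].size + 1.0 / gs[j].size)
            stat = np.inf if denom == 0 and diff != 0 else (
                0.0 if denom == 0 else diff**2 / denom
            )
            rows.append(
                {
                    "group_i": i,
                    "group_j": j,
                    "mean_diff": diff,
                    "statistic": stat,
                    "critical": crit,
                    "significant": bool(stat > crit),
                }
            )
    return pd.DataFrame(rows)


def fold_change(table_a: ParamTable, table_b: ParamTable, group: str,
                modulus: str = "G0") -> float:
    """Mean-ratio fold change (table_a over table_b), one-decimal rounding.

    ``modulus`` is ``"G0"`` or ``"Ginf"``.
    """
    col = {"G0": "G0_MPa", "Ginf": "Ginf_MPa"}[modulus]
    a = table_a.select(group=group)[col]
    b = table_b.select(group=group)[col]
    if a.empty or b.empty:
        raise ValueError(f"group {group!r} missing from one of the tables")
    return round(float(a.mean() / b.mean()), 1)


def write_report(tables: Dict[str, ParamTable], out_dir,
                 fold_specs=None, alpha: float = 0.05) -> dict:
    """CSV tables plus a deterministic text summary of the statistics.

    Runs three prespecified comparisons: condition on ECM moduli, condition
    on beam moduli, and flow (LF vs HF) within condition; then the requested
    fold changes (default: the four beam-modulus ratios).
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    for name, tab in sorted(tables.items()):
        tab.to_csv(os.path.join(out_dir, f"{name}.csv"))

    t3 = tables.get("table3")
    t4 = tables.get("table4")
    lines = []
    results = {"anova": {}, "fold_changes": {}}
    if t3 is not None and t4 is not None:
        ecm_groups = ("TM", "JCT", "SC_wall")
        beam_groups = ("TM_beam", "JCT_beam")

        def pooled(tab, groups):
            d = tab.df[tab.df["group"].isin(groups)]
            return np.concatenate([d["G0_MPa"].to_numpy(), d["Ginf_MPa"].to_numpy()])

        comparisons = {
            "condition_ecm": (pooled(t3, ecm_groups), pooled(t4, ecm_groups)),
            "condition_beam": (pooled(t3, beam_groups), pooled(t4, beam_groups)),
        }
        for cond, tab in (("healthy", t3), ("glaucoma", t4)):
            lf = tab.df[tab.df["flow"] == "LF"]
            hf = tab.df[tab.df["flow"] == "HF"]
            comparisons[f"flow_within_{cond}"] = (
                np.concatenate([lf["G0_MPa"], lf["Ginf_MPa"]]),
                np.concatenate([hf["G0_MPa"], hf["Ginf_MPa"]]),
            )
        for name, (a, b) in comparisons.items():
            an = one_way_anova([a, b])
            results["anova"][name] = an
            lines.append(
                f"ANOVA [{name}]: F({an.df_between},{an.df_within}) = "
                f"{an.f:.3f}, p = {an.p:.4g}"
                + (f" [{an.flag}]" if an.flag else "")
            )
            sch = scheffe_posthoc([a, b], alpha=alpha)
            sig = sch["significant"].any()
            lines.append(f"  Scheffe significant pairs: {int(sch['significant'].sum())}"
                         f" ({'yes' if sig else 'no'})")

        if fold_specs is None:
            fold_specs = [
                ("TM_beam", "G0"), ("JCT_beam", "G0"),
                ("TM_beam", "Ginf"), ("JCT_beam", "Ginf"),
            ]
        for group, modulus in fold_specs:
            fc = fold_change(t4, t3, group, modulus)
            results["fold_changes"][(group, modulus)] = fc
            lines.append(f"Fold change {group} {modulus} (glaucoma/healthy): {fc}")

    with open(os.path.join(out_dir, "summary.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return results
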