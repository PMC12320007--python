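"""Interhemispheric transfer statistics and the a-priori power analysis.

The headline quantities are computed on the homotopic modulatory
parameters b(L→R) and b(R→L) of the OFA–OFA and FFA–FFA connections,
separately for the three face modulators (left / central / right
stimulation):

* transfer difference  D = b_LR - b_RL  (signed asymmetry of transfer)
* transfer strength    S = (|b_LR| + |b_RL|) / 2

A 2 x 3 within-subject ANOVA (factors: region pair OFA/FFA, stimulus
location left/central/right) tests whether stimulus location shifts these
measures, with pairwise paired-t post-hoc contrasts between locations.

`power_sample_size` reproduces the study-design computation: the smallest
n for which a two-sided paired t-test at a Bonferroni-corrected alpha
reaches the target power for a given Cohen's d, using the exact
noncentral-t power function.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import json
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .network_model import MODULATORY_INPUTS

__all__ = [
    "TransferMeasures",
    "AnovaResult",
    "transfer_difference",
    "transfer_strength",
    "extract_measures",
    "rm_anova_2x3",
    "power_paired_t",
    "power_sample_size",
]

#: modulator -> stimulus location
MODULATOR_LOCATION = {"LF": "left", "CF": "central", "RF": "right"}

#: region pair -> (left-to-right edge, right-to-left edge) as (source, target)
HOMOTOPIC_EDGES = {
    "OFA": (("lOFA", "rOFA"), ("rOFA", "lOFA")),
    "FFA": (("lFFA", "rFFA"), ("rFFA", "lFFA")),
}


def transfer_difference(b_lr: float, b_rl: float) -> float:
    """Left-to-right minus right-to-left modulatory coupling (Hz)."""
    if not (np.isfinite(b_lr) and np.isfinite(b_rl)):
        raise ValueError("coupling parameters must be finite")
    return float(b_lr) - float(b_rl)


def transfer_strength(b_lr: float, b_rl: float) -> float:
    """Mean absolute homotopic coupling, (|b_LR| + |b_RL|) / 2 (Hz)."""
    if not (np.isfinite(b_lr) and np.isfinite(b_rl)):
        raise ValueError("coupling parameters must be finite")
    return (abs(float(b_lr)) + abs(float(b_rl))) / 2.0


@dataclass
class TransferMeasures:
    """Tidy per-subject transfer table.

    One row per subject x region pair (OFA, FFA) x location (left,
    central, right) with columns b_lr, b_rl, difference, strength.
    """

    table: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TransferMeasures":
        return cls(table=pd.read_csv(path, sep="\t"))


def extract_measures(per_subject_params: list[dict[str, float]]) -> TransferMeasures:
    """Build the transfer table from per-subject BMA parameter maps.

    Each subject's parameters are given as a mapping from labels of the
    form ``"B[CF] lOFA->rOFA"`` (as produced by the model-averaging step)
    to posterior means.  Missing keys are reported by name.
    """
    from .model_comparison import entry_label  # local to avoid cycle

    from .network_model import region_index

    rows = []
    missing: list[str] = []
    for s, params in enumerate(per_subject_params):
        for pair, (edge_lr, edge_rl) in HOMOTOPIC_EDGES.items():
            for m, mod in enumerate(MODULATORY_INPUTS):
                keys = []
                for src, tgt in (edge_lr, edge_rl):
                    keys.append(
                        entry_label(("B", m, region_index(tgt), region_index(src)))
                    )
                vals = []
                for key in keys:
                    if key not in params:
                        missing.append(f"subject {s}: {key}")
                        vals.append(np.nan)
                    else:
                        vals.append(float(params[key]))
                b_lr, b_rl = vals
                rows.append(
                    {
                        "subject": s,
                        "region_pair": pair,
                        "location": MODULATOR_LOCATION[mod],
                        "b_lr": b_lr,
                        "b_rl": b_rl,
                        "difference": b_lr - b_rl,
                        "strength": (abs(b_lr) + abs(b_rl)) / 2.0,
                    }
                )
    if missing:
        raise KeyError(
            "missing homotopic modulatory parameters: " + "; ".join(missing)
        )
    return TransferMeasures(table=pd.DataFrame(rows))


@dataclass
class AnovaResult:
    """Within-subject 2 x 3 ANOVA summary plus post-hoc location contrasts."""

    effects: pd.DataFrame       # rows: region, location, interaction
    posthoc: pd.DataFrame       # pairwise location paired t-tests
    response: str

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "response": self.response,
            "effects": self.effects.reset_index().to_dict(orient="records"),
            "posthoc": self.posthoc.to_dict(orient="records"),
            "note": "two-factor within-subject ANOVA, no sphericity correction",
        }
        text = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        lines = [f"2x3 within-subject ANOVA on '{self.response}'"]
        for name, row in self.effects.iterrows():
            lines.append(
                f"  {name}: F({row['df_num']:.0f}, {row['df_den']:.0f}) = "
                f"{row['F']:.2f}, p = {row['p']:.4g}"
            )
        lines.append("post-hoc paired t-tests between locations:")
        for _, row in self.posthoc.iterrows():
            lines.append(
                f"  {row['a']} vs {row['b']}: t({row['df']:.0f}) = "
                f"{row['t']:.2f}, p = {row['p']:.4g}"
            )
        return "\n".join(lines)


def rm_anova_2x3(
    measures: TransferMeasures,
    response: str = "difference",
    posthoc_correction: str | None = None,
) -> AnovaResult:
    """Two-factor within-subject ANOVA (region x location).

    Subjects are the random blocking factor; each subject must contribute
    exactly one observation per (region pair, location) cell.  Post-hoc
    pairwise location contrasts are paired t-tests on the per-subject
    location means (collapsed over region), optionally Bonferroni
    corrected.
    """
    df = measures.table
    if response not in df.columns:
        raise ValueError(f"unknown response {response!r}")
    counts = df.groupby(["subject", "region_pair", "location"]).size()
    if (counts != 1).any():
        raise ValueError("incomplete or unbalanced design: need exactly one "
                         "observation per subject x region x location cell")
    n_sub = df["subject"].nunique()
    if n_sub < 3:
        raise ValueError("need at least 3 subjects")

    res = AnovaRM(
        data=df,
        depvar=response,
        subject="subject",
        within=["region_pair", "location"],
    ).fit()
    tbl = res.anova_table  # F Value, Num DF, Den DF, Pr > F
    effects = pd.DataFrame(
        {
            "F": tbl["F Value"].to_numpy(),
            "df_num": tbl["Num DF"].to_numpy(),
            "df_den": tbl["Den DF"].to_numpy(),
            "p": tbl["Pr > F"].to_numpy(),
        },
        index=["region", "location", "region x location"],
    )

    loc_means = (
        df.groupby(["subject", "location"])[response].mean().unstack("location")
    )
    rows = []
    pairs = list(combinations(sorted(loc_means.columns), 2))
    for a, b in pairs:
        t, p = stats.ttest_rel(loc_means[a], loc_means[b])
        if posthoc_correction == "bonferroni":
            p = min(1.0, p * len(pairs))
        rows.append({"a": a, "b": b, "t": float(t), "df": n_sub - 1,
                     "p": float(p)})
    return AnovaResult(effects=effects, posthoc=pd.DataFrame(rows),
                       response=response)


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------


def power_paired_t(
    effect_size_d: float, alpha: float, n: int, two_sided: bool = True
) -> float:
    """Exact power of a one-sample / paired t-test at sample size n.

    Uses the noncentral-t distribution with noncentrality d * sqrt(n) and
    n - 1 degrees of freedom.
    """
    if n < 2:
        return 0.0
    df = n - 1
    nc = effect_size_d * np.sqrt(n)
    if two_sided:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(
            1.0 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        )
    tcrit = stats.t.ppf(1.0 - alpha, df)
    return float(1.0 - stats.nct.cdf(tcrit, df, nc))


def power_sample_size(
    effect_size_d: float,
    alpha: float,
    power: float,
    two_sided: bool = True,
    n_max: int = 10_000,
) -> int:
    """Smallest n at which the paired t-test reaches the target power."""
    if effect_size_d <= 0:
        raise ValueError("effect size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if power_paired_t(effect_size_d, alpha, n, two_sided=two_sided) >= power:
            return n
    raise ValueError(f"target power not reached by n = {n_max}")
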