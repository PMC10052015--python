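"""UV dose–response survival curves and genotype–phenotype correlation.

Colony counts from spot titers are turned into percent survival relative to
the unirradiated control, separately for plates exposed to photoreactivating
light and plates kept dark.  Survival is summarised by a log-linear kill
slope (log10 survival per J/m²), and photoreactivation benefit is the
per-dose difference log10(S_light) − log10(S_dark).  Strains are ranked and
the ranking is correlated (Spearman, permutation p-value) with the
photolyase-integrity score from the variant analysis.

Replicates are averaged on the linear CFU scale after dilution correction;
zero-colony observations are floored at half a colony at the deepest plated
dilution and flagged censored, keeping log survival finite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "DoseResponseSummary",
    "percent_survival",
    "summarize_strain",
    "photoreactivation_benefit",
    "rank_strains",
    "spearman_rho",
    "genotype_phenotype_correlation",
]

CONDITIONS = ("light", "dark")

REQUIRED_COLUMNS = ["strain", "condition", "dose_J_per_m2", "replicate", "dilution", "cfu"]


@dataclass
class SurvivalDataset:
    """Raw records plus derived percent survival per (strain, condition, dose)."""

    records: pd.DataFrame
    survival: pd.DataFrame  # columns: strain, condition, dose, percent_survival, censored

    def strains(self) -> list[str]:
        return sorted(self.survival.strain.unique())

    def curve(self, strain: str, condition: str) -> pd.DataFrame:
        sub = self.survival[(self.survival.strain == strain) & (self.survival.condition == condition)]
        if not len(sub):
            raise KeyError(f"missing condition {condition!r} for strain {strain!r}")
        return sub.sort_values("dose").reset_index(drop=True)


@dataclass
class DoseResponseSummary:
    strain: str
    condition: str
    doses: list[float]
    log10_survival: list[float]
    slope: float  # log10 survival per J/m² (negative = killing)
    d10: float  # dose for 10% survival (extrapolated when flagged)
    d10_extrapolated: bool
    max_dose_log_kill: float  # −log10 S(max dose)/100
    increasing_flag: bool = False
    censored_any: bool = False


def percent_survival(records: pd.DataFrame) -> SurvivalDataset:
    """Dilution-corrected, replicate-averaged percent survival.

    ``records`` columns: strain, condition, dose_J_per_m2, replicate,
    dilution (fold dilution of the plated sample; counts are multiplied by
    it), cfu.  Requires a dose-0 control per (strain, condition).
    """
    df = records.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if (df.cfu < 0).any():
        raise ValueError("negative CFU counts")
    if (df.dose_J_per_m2 < 0).any():
        raise ValueError("negative doses")
    df["titer"] = df.cfu * df.dilution

    rows = []
    for (strain, cond), grp in df.groupby(["strain", "condition"], sort=True):
        doses = sorted(grp.dose_J_per_m2.unique())
        if 0 not in doses and 0.0 not in doses:
            raise ValueError(f"no dose-0 control for ({strain}, {cond})")
        n0 = grp[grp.dose_J_per_m2 == 0].titer.mean()
        if n0 <= 0:
            raise ValueError(f"dose-0 titer is zero for ({strain}, {cond})")
        for d in doses:
            sub = grp[grp.dose_J_per_m2 == d]
            titer = sub.titer.mean()
            censored = False
            if titer <= 0:
                # detection floor: half a colony at the deepest plated dilution
                titer = 0.5 * sub.dilution.min()
                censored = True
            s = 100.0 * titer / n0 if d != 0 else 100.0
            rows.append({"strain": strain, "condition": cond, "dose": float(d), "percent_survival": s, "censored": censored})
    surv = pd.DataFrame(rows)
    return SurvivalDataset(records=df, survival=surv)


def summarize_strain(sd: SurvivalDataset, strain: str, condition: str) -> DoseResponseSummary:
    """Log-linear dose-response summary for one strain and condition."""
    curve = sd.curve(strain, condition)
    doses = curve.dose.to_numpy(float)
    logs = np.log10(curve.percent_survival.to_numpy(float))
    if len(doses) >= 2:
        slope = float(np.polyfit(doses, logs, 1)[0])
    else:
        slope = 0.0
    increasing = slope > 0
    if slope < 0:
        d10 = float((1.0 - 2.0) / slope)  # log10(10) - log10(100) = -1
        extrap = d10 > doses.max()
    else:
        d10, extrap = math.inf, True
    return DoseResponseSummary(
        strain=strain,
        condition=condition,
        doses=list(doses),
        log10_survival=list(logs),
        slope=slope,
        d10=d10,
        d10_extrapolated=bool(extrap),
        max_dose_log_kill=float(2.0 - logs[-1]),
        increasing_flag=bool(increasing),
        censored_any=bool(curve.censored.any()),
    )


def photoreactivation_benefit(sd: SurvivalDataset, strain: str) -> tuple[pd.DataFrame, float]:
    """Per-dose light-vs-dark benefit and its mean over positive doses.

    benefit(d) = log10 S_light(d) − log10 S_dark(d); positive values mean
    photoreactivating light rescued survival.
    """
    light = sd.curve(strain, "light")
    dark = sd.curve(strain, "dark")
    merged = light.merge(dark, on="dose", suffixes=("_light", "_dark"))
    merged["benefit"] = np.log10(merged.percent_survival_light) - np.log10(merged.percent_survival_dark)
    merged["censored"] = merged.censored_light | merged.censored_dark
    out = merged[["dose", "benefit", "censored"]]
    positive = out[out.dose > 0]
    mean_benefit = float(positive.benefit.mean()) if len(positive) else 0.0
    return out, mean_benefit


def rank_strains(
    sd: SurvivalDataset,
    metric: str = "light_survival_at_max_common_dose",
    condition: str = "light",
) -> pd.DataFrame:
    """Deterministic strain ranking, best survivor first.

    Default metric: percent survival under the chosen condition at the
    highest dose shared by all strains; ties broken by mean
    photoreactivation benefit, then strain id.  Returns a DataFrame with
    rank, metric value and a tie flag.
    """
    strains = sd.strains()
    if len(strains) < 2:
        raise ValueError("need at least two strains to rank")
    common = None
    for s in strains:
        doses = set(sd.curve(s, condition).dose)
        common = doses if common is None else (common & doses)
    common = sorted(d for d in common if d > 0)
    if not common:
        raise ValueError("no common positive dose across strains")
    dmax = common[-1]

    rows = []
    for s in strains:
        curve = sd.curve(s, condition)
        if metric == "light_survival_at_max_common_dose":
            value = float(curve[curve.dose == dmax].percent_survival.iloc[0])
        elif metric == "slope":
            value = summarize_strain(sd, s, condition).slope
        else:
            raise ValueError(f"unknown metric {metric!r}")
        try:
            _, benefit = photoreactivation_benefit(sd, s)
        except KeyError:
            benefit = 0.0
        rows.append({"strain": s, "metric": value, "mean_benefit": benefit})
    df = pd.DataFrame(rows)
    df = df.sort_values(["metric", "mean_benefit", "strain"], ascending=[False, False, True], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["tied"] = df.metric.duplicated(keep=False)
    return df


def _rankdata(x: np.ndarray) -> np.ndarray:
    # average ranks (ties shared), 1-based
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), float)
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of average ranks)."""
    rx, ry = _rankdata(np.asarray(x, float)), _rankdata(np.asarray(y, float))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("constant ranks: correlation undefined")
    return float(rx @ ry / denom)


def genotype_phenotype_correlation(
    scores: Mapping[str, float],
    phenotype: Mapping[str, float],
    n_permutations: int = 100_000,
    seed: int | None = 0,
) -> dict:
    """Spearman correlation of integrity score vs survival metric, permutation p.

    Two-sided p-value: probability under random relabelling that |rho| is at
    least the observed |rho|.  Exhaustive over all n! permutations for
    n <= 8; seeded Monte Carlo above.
    """
    strains = sorted(set(scores) & set(phenotype))
    if len(strains) < 4:
        raise ValueError(f"need >= 4 strains with both values, got {len(strains)}")
    x = np.array([scores[s] for s in strains], float)
    y = np.array([phenotype[s] for s in strains], float)
    rho = spearman_rho(x, y)

    n = len(strains)
    count = 0
    if n <= 8:
        total = 0
        for perm in itertools.permutations(range(n)):
            r = spearman_rho(x, y[list(perm)])
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
        exact = True
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_permutations):
            r = spearman_rho(x, rng.permutation(y))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        exact = False
    return {"rho": rho, "p_value": p, "n": n, "exact": exact, "strains": strains}
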