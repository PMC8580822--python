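"""Mutant potency/efficacy shifts and the exact Wilcoxon rank-sum test.

Potency shifts are computed per G protein as
``dlogEC50 = logEC50(mutant) - logEC50(wild type)`` (replicates averaged
first); efficacy shifts analogously on Emax.  The predicted state-changing
and nonstate-changing mutant groups are compared with a two-sided Wilcoxon
rank-sum test: mid-ranks for ties, exact enumeration of the permutation
distribution for small groups, and a tie-corrected normal approximation
beyond.  The two-sided p doubles the smaller exact tail (including the
observed rank-sum) and caps at 1, a convention that stays well defined
when ties make the permutation distribution asymmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "MutantRecord",
    "GroupComparison",
    "load_mutant_table",
    "delta_from_wt",
    "wilcoxon_rank_sum_exact",
    "compare_groups",
]

GROUPS = ("state_changing", "nonstate_changing", "wt")
EXACT_MAX_PER_GROUP = 10


@dataclass(frozen=True)
class MutantRecord:
    mutant: str
    group: str
    g_protein: str
    log_ec50: float
    emax: float
    replicate: int = 1

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not math.isfinite(self.log_ec50):
            raise ValueError("log_ec50 must be finite")


def load_mutant_table(path) -> list:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"mutant", "group", "g_protein", "log_ec50", "emax"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mutant table missing column(s): {sorted(missing)}")
    return [MutantRecord(
        mutant=str(r.mutant), group=str(r.group), g_protein=str(r.g_protein),
        log_ec50=float(r.log_ec50), emax=float(r.emax),
        replicate=int(getattr(r, "replicate", 1)))
        for r in df.itertuples(index=False)]


def delta_from_wt(records) -> pd.DataFrame:
    """Per-mutant shifts from wild type, one row per mutant per G protein.

    Replicates are averaged before differencing, so the test below runs on
    mutant-level values.
    """
    df = pd.DataFrame([{
        "mutant": r.mutant, "group": r.group, "g_protein": r.g_protein,
        "log_ec50": r.log_ec50, "emax": r.emax} for r in records])
    if df.empty:
        raise ValueError("no mutant records")
    mean = (df.groupby(["g_protein", "group", "mutant"], as_index=False)
              [["log_ec50", "emax"]].mean())
    out_rows = []
    for gprot, sub in mean.groupby("g_protein"):
        wt = sub[sub["group"] == "wt"]
        if wt.empty:
            raise ValueError(f"no wild-type record for G protein {gprot}")
        wt_ec50 = float(wt["log_ec50"].mean())
        wt_emax = float(wt["emax"].mean())
        for r in sub[sub["group"] != "wt"].itertuples(index=False):
            out_rows.append({
                "g_protein": gprot, "group": r.group, "mutant": r.mutant,
                "delta_log_ec50": r.log_ec50 - wt_ec50,
                "delta_emax": r.emax - wt_emax,
            })
    return pd.DataFrame(out_rows).sort_values(
        ["g_protein", "group", "mutant"]).reset_index(drop=True)


def wilcoxon_rank_sum_exact(a, b, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum p-value with mid-ranks for ties.

    Exact permutation enumeration when both groups have at most
    ``EXACT_MAX_PER_GROUP`` observations; otherwise a tie-corrected normal
    approximation with continuity correction.  Identical pooled values in
    both groups give p = 1 by construction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n, N = len(a), len(pooled)
    w_obs = float(ranks[:n].sum())

    if max(len(a), len(b)) <= EXACT_MAX_PER_GROUP:
        total = math.comb(N, n)
        le = ge = 0
        eps = 1e-9
        for comb in combinations(range(N), n):
            w = float(ranks[list(comb)].sum())
            if w <= w_obs + eps:
                le += 1
            if w >= w_obs - eps:
                ge += 1
        p_less = le / total
        p_greater = ge / total
        if alternative == "less":
            return p_less
        if alternative == "greater":
            return p_greater
        return min(1.0, 2.0 * min(p_less, p_greater))

    # tie-corrected normal approximation with continuity correction
    mu = n * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    var = n * len(b) / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return 1.0
    from scipy.stats import norm
    if alternative == "two-sided":
        z = (abs(w_obs - mu) - 0.5) / math.sqrt(var)
        return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))
    if alternative == "greater":
        z = (w_obs - mu - 0.5) / math.sqrt(var)
    else:
        z = -(w_obs - mu + 0.5) / math.sqrt(var)
    return float(norm.sf(z))


@dataclass
class GroupComparison:
    g_protein: str
    mean_delta_log_ec50: dict
    mean_delta_emax: dict
    p_potency: float
    p_efficacy: float
    n_per_group: dict

    def __post_init__(self):
        for p in (self.p_potency, self.p_efficacy):
            if not 0 < p <= 1:
                raise ValueError(f"p-value {p} outside (0, 1]")


def compare_groups(records) -> dict:
    """State-changing vs nonstate-changing comparison per G protein."""
    deltas = delta_from_wt(records)
    out = {}
    for gprot, sub in deltas.groupby("g_protein"):
        sc = sub[sub["group"] == "state_changing"]
        nsc = sub[sub["group"] == "nonstate_changing"]
        if sc.empty or nsc.empty:
            raise ValueError(f"both mutant groups required for {gprot}")
        out[gprot] = GroupComparison(
            g_protein=gprot,
            mean_delta_log_ec50={
                "state_changing": float(sc["delta_log_ec50"].mean()),
                "nonstate_changing": float(nsc["delta_log_ec50"].mean())},
            mean_delta_emax={
                "state_changing": float(sc["delta_emax"].mean()),
                "nonstate_changing": float(nsc["delta_emax"].mean())},
            p_potency=wilcoxon_rank_sum_exact(
                sc["delta_log_ec50"], nsc["delta_log_ec50"]),
            p_efficacy=wilcoxon_rank_sum_exact(
                sc["delta_emax"], nsc["delta_emax"]),
            n_per_group={"state_changing": len(sc),
                         "nonstate_changing": len(nsc)},
        )
    return out


def comparison_to_frame(comparisons: dict) -> pd.DataFrame:
    rows = []
    for gprot, c in sorted(comparisons.items()):
        rows.append({
            "g_protein": gprot,
            "mean_dlogEC50_state_changing":
                round(c.mean_delta_log_ec50["state_changing"], 3),
            "mean_dlogEC50_nonstate_changing":
                round(c.mean_delta_log_ec50["nonstate_changing"], 3),
            "mean_dEmax_state_changing":
                round(c.mean_delta_emax["state_changing"], 3),
            "mean_dEmax_nonstate_changing":
                round(c.mean_delta_emax["nonstate_changing"], 3),
            "p_potency": round(c.p_potency, 4),
            "p_efficacy": round(c.p_efficacy, 4),
            "n_state_changing": c.n_per_group["state_changing"],
            "n_nonstate_changing": c.n_per_group["nonstate_changing"],
        })
    return pd.DataFrame(rows)
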