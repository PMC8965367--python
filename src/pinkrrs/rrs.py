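"""Reproductive-success tabulation and the headline fitness statistics.

From a pedigree-assignment table this module computes per-parent
reproductive success (RS; zero for sampled parents with no assigned
offspring), the proportion of hatchery-origin spawners (pHOS), unweighted
relative reproductive success (RRS = mean hatchery RS / mean natural RS)
with profile-likelihood confidence intervals and permutation p-values,
cross-type analysis of parent-pair matings, and Welch-t / Wilcoxon
contrasts of spawner covariates between origins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .records import ValidationError

__all__ = [
    "RRSResult",
    "tabulate_rs",
    "compute_phos",
    "unweighted_rrs",
    "kt_profile_ci",
    "permutation_test_rs",
    "cross_type_rs",
    "covariate_contrasts",
]

EXHAUSTIVE_LIMIT = 100_000


@dataclass
class RRSResult:
    """Ratio-of-means RRS for one stratum with CI and permutation p."""

    mean_rs_h: float
    mean_rs_n: float
    rrs: float
    ci_low: float
    ci_high: float
    p_value: float
    n_h: int
    n_n: int
    t_h: int
    t_n: int
    status: str = "ok"


def tabulate_rs(assignments: pd.DataFrame, parents: pd.DataFrame) -> pd.DataFrame:
    """Per-parent RS table: count of distinct assigned offspring, zero for
    parents never assigned. A triad offspring credits both parents."""
    ids = parents["sample_id"]
    if ids.duplicated().any():
        raise ValidationError("duplicate parent ids")
    known = set(ids)
    counts = {pid: 0 for pid in ids}
    for col in ("dam_id", "sire_id"):
        for pid in assignments[col].dropna():
            if pid not in known:
                raise ValidationError(f"assignment references unknown parent {pid!r}")
            counts[pid] += 1
    out = parents[["sample_id", "stream", "year", "lineage", "origin", "sex",
                   "length_mm", "sample_day", "distance_m", "intertidal"]].copy()
    out = out.rename(columns={"sample_id": "parent_id"})
    out["rs"] = out["parent_id"].map(counts).astype(int)
    return out


def compute_phos(samples: pd.DataFrame, strata: Optional[list[str]] = None) -> pd.DataFrame:
    """pHOS = hatchery / (hatchery + natural) per stratum, unknown-origin
    fish excluded; empty strata reported with pHOS missing."""
    df = samples.copy()
    if strata:
        groups = df.groupby(strata, dropna=False)
    else:
        df["_all"] = "all"
        groups = df.groupby("_all")
    rows = []
    for key, grp in groups:
        n_h = int((grp["origin"] == "hatchery").sum())
        n_n = int((grp["origin"] == "natural").sum())
        phos = n_h / (n_h + n_n) if (n_h + n_n) > 0 else np.nan
        row = dict(zip(strata, key if isinstance(key, tuple) else (key,))) if strata else {}
        row.update({"n_hatchery": n_h, "n_natural": n_n, "phos": phos})
        rows.append(row)
    return pd.DataFrame(rows)


def kt_profile_ci(
    n_h: int, n_n: int, t_h: int, t_n: int, level: float = 0.95
) -> tuple[float, float]:
    """Profile-likelihood CI for the RS ratio w = (T_H/n_H)/(T_N/n_N).

    The profile treats the split of the T_H + T_N assigned offspring
    between origins as binomial with success probability
    p(w) = w*n_H / (w*n_H + n_N); the interval is the set of w where twice
    the log-likelihood drop from the MLE stays below the chi-square(1)
    quantile. T_H = 0 pins the lower bound at 0; T_N = 0 leaves the upper
    bound open (inf).
    """
    if n_h < 1 or n_n < 1:
        raise ValueError("n_h and n_n must be >= 1")
    t = t_h + t_n
    if t < 1:
        raise ValueError("needs at least one assigned offspring")
    crit = stats.chi2.ppf(level, df=1)

    def loglik(w: float) -> float:
        p = w * n_h / (w * n_h + n_n)
        # binomial kernel; constants cancel in the likelihood ratio
        with np.errstate(divide="ignore", invalid="ignore"):
            return t_h * np.log(p) + t_n * np.log1p(-p) if 0 < p < 1 else (
                0.0 if (p == 0 and t_h == 0) or (p == 1 and t_n == 0) else -np.inf
            )

    if t_n == 0:
        w_hat = np.inf
    else:
        w_hat = (t_h / n_h) / (t_n / n_n)
    ll_hat = (loglik(w_hat) if np.isfinite(w_hat) and w_hat > 0
              else (0.0 if t_h == 0 or t_n == 0 else loglik(w_hat)))

    def drop(w: float) -> float:
        return 2.0 * (ll_hat - loglik(w)) - crit

    if t_h == 0:
        lo = 0.0
    elif t_n == 0:
        # profile is monotone: invert t_h*log p(w) = -crit/2 in closed form
        p_star = np.exp(-crit / (2.0 * t_h))
        lo = p_star * n_n / ((1.0 - p_star) * n_h)
    else:
        w_lo = w_hat
        while drop(w_lo) < 0:
            w_lo /= 4.0
            if w_lo < 1e-12:
                break
        lo = brentq(drop, w_lo, w_hat, xtol=1e-12, rtol=1e-12) if drop(w_lo) > 0 else 0.0
    if t_n == 0:
        hi = np.inf
    else:
        w0 = w_hat if w_hat > 0 else 1e-9
        w_hi = max(w0, 1e-9)
        while drop(w_hi) < 0 and w_hi < 1e12:
            w_hi *= 4.0
        hi = brentq(drop, w0, w_hi, xtol=1e-12, rtol=1e-12) if drop(w_hi) > 0 else np.inf
    return lo, hi


def permutation_test_rs(
    rs_h: np.ndarray,
    rs_n: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Two-sided permutation test of mean RS difference between origins.

    Origin labels are permuted on the pooled RS vector; exhaustive
    enumeration (exact p, no +1 correction) when the number of
    arrangements is at most 1e5, otherwise Monte-Carlo with the add-one
    correction.
    """
    x_h = np.asarray(rs_h, dtype=float)
    x_n = np.asarray(rs_n, dtype=float)
    if len(x_h) == 0 or len(x_n) == 0:
        raise ValueError("both RS vectors must be nonempty")
    pooled = np.concatenate([x_h, x_n])
    n, n_h = len(pooled), len(x_h)
    d_obs = abs(x_h.mean() - x_n.mean())
    total = pooled.sum()
    if comb(n, n_h) <= EXHAUSTIVE_LIMIT:
        hits = 0
        count = 0
        for idx in itertools.combinations(range(n), n_h):
            s = pooled[list(idx)].sum()
            d = abs(s / n_h - (total - s) / (n - n_h))
            hits += d >= d_obs - 1e-12
            count += 1
        return hits / count
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.random((n_perm, n))
    idx = np.argpartition(u, n_h - 1, axis=1)[:, :n_h]
    s = pooled[idx].sum(axis=1)
    d = np.abs(s / n_h - (total - s) / (n - n_h))
    return (1 + int((d >= d_obs - 1e-12).sum())) / (1 + n_perm)


def unweighted_rrs(
    rs_table: pd.DataFrame,
    by_sex: bool = True,
    level: float = 0.95,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Unweighted RRS per stratum: mean hatchery RS / mean natural RS with
    Kalinowski-Taper profile CI and permutation p-value."""
    strata = ["sex"] if by_sex else [None]
    rows = []
    for stratum in strata:
        if stratum is None:
            groups = [("all", rs_table)]
        else:
            groups = [(k, g) for k, g in rs_table.groupby(stratum) if k in ("F", "M")]
        for key, grp in groups:
            h = grp.loc[grp["origin"] == "hatchery", "rs"].to_numpy()
            nn = grp.loc[grp["origin"] == "natural", "rs"].to_numpy()
            row = {"stratum": key, "n_h": len(h), "n_n": len(nn),
                   "t_h": int(h.sum()) if len(h) else 0,
                   "t_n": int(nn.sum()) if len(nn) else 0}
            if len(h) == 0 or len(nn) == 0:
                row.update(mean_rs_h=np.nan, mean_rs_n=np.nan, rrs=np.nan,
                           ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                           status="missing origin group")
            elif nn.sum() == 0:
                row.update(mean_rs_h=h.mean(), mean_rs_n=0.0, rrs=np.nan,
                           ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                           status="undefined: natural mean RS is 0")
            else:
                ci = (0.0, np.inf)
                if h.sum() + nn.sum() >= 1:
                    ci = kt_profile_ci(len(h), len(nn), int(h.sum()),
                                       int(nn.sum()), level)
                p = permutation_test_rs(h, nn, n_perm=n_perm, seed=seed)
                row.update(mean_rs_h=h.mean(), mean_rs_n=nn.mean(),
                           rrs=h.mean() / nn.mean(), ci_low=ci[0],
                           ci_high=ci[1], p_value=p, status="ok")
            rows.append(row)
    cols = ["stratum", "mean_rs_h", "mean_rs_n", "rrs", "ci_low", "ci_high",
            "p_value", "n_h", "n_n", "t_h", "t_n", "status"]
    return pd.DataFrame(rows)[cols]


def cross_type_rs(
    assignments: pd.DataFrame,
    parents: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean RS per mating cross type from triads with RS >= 1.

    Cross types are keyed female origin first (HH, HN, NH, NN). Returns
    (per-type summary, pairwise permutation p-values).
    """
    triads = assignments[assignments["kind"] == "triad"]
    if len(triads) == 0:
        raise ValidationError("no triads in assignments")
    origin = parents.set_index("sample_id")["origin"]
    matings = triads.groupby(["dam_id", "sire_id"]).size().reset_index(name="rs")
    code = {"hatchery": "H", "natural": "N"}
    matings["cross"] = [
        code.get(origin.get(d, "unknown"), "?") + code.get(origin.get(s, "unknown"), "?")
        for d, s in zip(matings["dam_id"], matings["sire_id"])
    ]
    summary = (
        matings.groupby("cross")["rs"]
        .agg(n_matings="size", mean_rs="mean")
        .reindex(["HH", "HN", "NH", "NN"])
        .reset_index()
    )
    pair_rows = []
    present = [c for c in ("HH", "HN", "NH", "NN")
               if (matings["cross"] == c).any()]
    for a, b in itertools.combinations(present, 2):
        xa = matings.loc[matings["cross"] == a, "rs"].to_numpy()
        xb = matings.loc[matings["cross"] == b, "rs"].to_numpy()
        p = permutation_test_rs(xa, xb, n_perm=n_perm, seed=seed)
        pair_rows.append({"cross_a": a, "cross_b": b, "p_value": p})
    return summary, pd.DataFrame(pair_rows, columns=["cross_a", "cross_b", "p_value"])


def covariate_contrasts(parents: pd.DataFrame) -> pd.DataFrame:
    """Origin contrasts of length, sample day and distance per
    stream/sex/year stratum: Welch two-sided t for length, Wilcoxon
    rank-sum for day and distance; means and SDs reported per origin."""
    rows = []
    for (stream, year, sex), grp in parents.groupby(["stream", "year", "sex"]):
        if sex not in ("F", "M"):
            continue
        h = grp[grp["origin"] == "hatchery"]
        n = grp[grp["origin"] == "natural"]
        if len(h) < 2 or len(n) < 2:
            continue
        row = {"stream": stream, "year": year, "sex": sex,
               "n_h": len(h), "n_n": len(n)}
        for var, test in (("length_mm", "t"), ("sample_day", "wilcoxon"),
                          ("distance_m", "wilcoxon")):
            xh, xn = h[var].to_numpy(float), n[var].to_numpy(float)
            row[f"{var}_mean_h"] = xh.mean()
            row[f"{var}_sd_h"] = xh.std(ddof=1)
            row[f"{var}_mean_n"] = xn.mean()
            row[f"{var}_sd_n"] = xn.std(ddof=1)
            if xh.std() == 0 and xn.std() == 0 and xh.mean() == xn.mean():
                row[f"{var}_p"] = 1.0
                row[f"{var}_degenerate"] = True
                continue
            row[f"{var}_degenerate"] = False
            if test == "t":
                row[f"{var}_p"] = float(
                    stats.ttest_ind(xh, xn, equal_var=False).pvalue
                )
            else:
                row[f"{var}_p"] = float(
                    stats.mannwhitneyu(xh, xn, alternative="two-sided").pvalue
                )
        rows.append(row)
    return pd.DataFrame(rows)
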