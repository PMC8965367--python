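import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import pinkrrs as pk
from pinkrrs.records import ValidationError
from pinkrrs.rrs import covariate_contrasts, cross_type_rs, kt_profile_ci


def _parents_frame(rows):
    base = {"stream": "Hogan", "year": 2014, "lineage": "even",
            "length_mm": 430.0, "sample_day": 243, "distance_m": 300.0,
            "intertidal": True, "hatchery_code": None, "genotyped": True}
    out = []
    for r in rows:
        d = dict(base)
        d.update(r)
        if d["origin"] == "hatchery":
            d["hatchery_code"] = "AFK"
        out.append(d)
    return pd.DataFrame(out)


# -------------------------------------------------------------- tabulate


def test_tabulate_rs_zero_and_triad_credit():
    parents = _parents_frame([
        {"sample_id": "p1", "origin": "hatchery", "sex": "F"},
        {"sample_id": "p2", "origin": "natural", "sex": "M"},
    ])
    empty = pd.DataFrame(columns=["offspring_id", "dam_id", "sire_id",
                                  "posterior", "kind"])
    rs = pk.tabulate_rs(empty, parents)
    assert rs["rs"].tolist() == [0, 0]
    triad = pd.DataFrame([{"offspring_id": "o1", "dam_id": "p1",
                           "sire_id": "p2", "posterior": 1.0, "kind": "triad"}])
    rs = pk.tabulate_rs(triad, parents)
    assert rs["rs"].tolist() == [1, 1]


def test_tabulate_rs_unknown_parent_is_integrity_error():
    parents = _parents_frame([
        {"sample_id": "p1", "origin": "natural", "sex": "F"}])
    bad = pd.DataFrame([{"offspring_id": "o1", "dam_id": "zzz",
                         "sire_id": None, "posterior": 1.0, "kind": "dyad"}])
    with pytest.raises(ValidationError, match="zzz"):
        pk.tabulate_rs(bad, parents)


def test_tabulate_rs_matches_true_pedigree(assigned_cohort):
    rs = pk.tabulate_rs(assigned_cohort["assignments"],
                        assigned_cohort["parents"])
    truth = assigned_cohort["pedigree"].true_rs()
    merged = rs.set_index("parent_id")["rs"]
    expected = truth.reindex(merged.index).fillna(0).astype(int)
    assert (merged == expected).all()


def test_rs_sum_accounting(assigned_cohort):
    """Sum of RS equals dyads + 2 * triads."""
    a = assigned_cohort["assignments"]
    rs = pk.tabulate_rs(a, assigned_cohort["parents"])
    dyads = int((a["kind"] == "dyad").sum())
    triads = int((a["kind"] == "triad").sum())
    assert rs["rs"].sum() == dyads + 2 * triads


# ------------------------------------------------------------------ pHOS


def test_phos_values():
    df = _parents_frame(
        [{"sample_id": f"h{i}", "origin": "hatchery", "sex": "F"} for i in range(64)]
        + [{"sample_id": f"n{i}", "origin": "natural", "sex": "F"} for i in range(36)]
    )
    assert pk.compute_phos(df)["phos"].iloc[0] == pytest.approx(0.64)
    df_n = _parents_frame(
        [{"sample_id": f"n{i}", "origin": "natural", "sex": "F"} for i in range(5)])
    assert pk.compute_phos(df_n)["phos"].iloc[0] == 0.0


def test_phos_excludes_unknowns_and_recovers_simulated_rate():
    df = pk.simulate_spawners(10_000, 0.74, seed=70)
    df.loc[df.index[:100], "origin"] = "unknown"
    assert pk.compute_phos(df)["phos"].iloc[0] == pytest.approx(0.74, abs=0.01)


# --------------------------------------------------------------- KT CI


def test_kt_ci_symmetry_and_mle():
    lo, hi = kt_profile_ci(50, 50, 30, 30)
    assert lo * hi == pytest.approx(1.0, rel=1e-6)  # log-symmetric around 1
    lo, hi = kt_profile_ci(100, 100, 50, 100)
    assert lo < 0.5 < hi


def test_kt_ci_boundary_cases():
    lo, hi = kt_profile_ci(10, 10, 0, 5)
    assert lo == 0.0
    lo, hi = kt_profile_ci(10, 10, 5, 0)
    assert hi == np.inf and lo > 0


def test_kt_ci_matches_dense_grid_oracle():
    """Endpoints agree with a brute-force scan of the profile likelihood
    and sit exactly at the chi-square(1) drop."""
    n_h, n_n, t_h, t_n = 100, 100, 50, 100
    crit = stats.chi2.ppf(0.95, 1)

    def ll(w):
        p = w * n_h / (w * n_h + n_n)
        return t_h * np.log(p) + t_n * np.log(1 - p)

    w_hat = (t_h / n_h) / (t_n / n_n)
    grid = np.linspace(1e-4, 3.0, 2_000_001)
    inside = grid[2 * (ll(w_hat) - ll(grid)) <= crit]
    lo_oracle, hi_oracle = inside[0], inside[-1]
    lo, hi = kt_profile_ci(n_h, n_n, t_h, t_n)
    assert lo == pytest.approx(lo_oracle, abs=1e-5)
    assert hi == pytest.approx(hi_oracle, abs=1e-5)
    for b in (lo, hi):
        assert 2 * (ll(w_hat) - ll(b)) == pytest.approx(crit, abs=1e-6)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    n_h=st.integers(5, 300), n_n=st.integers(5, 300),
    t_h=st.integers(1, 400), t_n=st.integers(1, 400),
)
def test_kt_ci_brackets_the_mle(n_h, n_n, t_h, t_n):
    lo, hi = kt_profile_ci(n_h, n_n, t_h, t_n)
    w_hat = (t_h / n_h) / (t_n / n_n)
    assert lo <= w_hat <= hi
    assert lo >= 0


# ----------------------------------------------------------- permutation


def test_permutation_exhaustive_exact():
    assert pk.permutation_test_rs([0, 0, 0], [5, 5, 5]) == pytest.approx(0.1)
    assert pk.permutation_test_rs([2, 2, 2], [2, 2, 2]) == 1.0


def test_permutation_null_calibration():
    rng = np.random.default_rng(8)
    rejections = 0
    n_rep = 400
    for _ in range(n_rep):
        h = rng.negative_binomial(1, 1 / 3, 200)
        n = rng.negative_binomial(1, 1 / 3, 200)
        p = pk.permutation_test_rs(h, n, n_perm=500,
                                   rng=np.random.default_rng(rng.integers(2**31)))
        rejections += p <= 0.05
    rate = rejections / n_rep
    assert 0.02 <= rate <= 0.08


# ------------------------------------------------------- unweighted RRS


def test_unweighted_rrs_arithmetic():
    parents = _parents_frame(
        [{"sample_id": f"h{i}", "origin": "hatchery", "sex": "F"} for i in range(4)]
        + [{"sample_id": f"n{i}", "origin": "natural", "sex": "F"} for i in range(4)]
    )
    rs = pk.tabulate_rs(
        pd.DataFrame(columns=["offspring_id", "dam_id", "sire_id",
                              "posterior", "kind"]), parents)
    rs["rs"] = [0, 0, 2, 2, 1, 3, 0, 4]
    out = pk.unweighted_rrs(rs, by_sex=False, n_perm=200, seed=1)
    assert out["rrs"].iloc[0] == pytest.approx(0.5)
    rs["rs"] = [1, 2, 3, 4, 1, 2, 3, 4]
    out = pk.unweighted_rrs(rs, by_sex=False, n_perm=200, seed=1)
    assert out["rrs"].iloc[0] == pytest.approx(1.0)


def test_unweighted_rrs_undefined_when_natural_zero():
    parents = _parents_frame(
        [{"sample_id": "h1", "origin": "hatchery", "sex": "F"},
         {"sample_id": "n1", "origin": "natural", "sex": "F"}])
    rs = pk.tabulate_rs(
        pd.DataFrame([{"offspring_id": "o1", "dam_id": "h1", "sire_id": None,
                       "posterior": 1.0, "kind": "dyad"}]), parents)
    out = pk.unweighted_rrs(rs, by_sex=False)
    assert np.isnan(out["rrs"].iloc[0])
    assert "undefined" in out["status"].iloc[0]


# ------------------------------------------------------------ cross types


def test_cross_type_single_triad():
    parents = _parents_frame(
        [{"sample_id": "d", "origin": "hatchery", "sex": "F"},
         {"sample_id": "s", "origin": "hatchery", "sex": "M"}])
    triads = pd.DataFrame([
        {"offspring_id": f"o{i}", "dam_id": "d", "sire_id": "s",
         "posterior": 1.0, "kind": "triad"} for i in range(3)])
    summary, pvals = cross_type_rs(triads, parents, n_perm=100, seed=1)
    hh = summary.set_index("cross").loc["HH"]
    assert hh["n_matings"] == 1 and hh["mean_rs"] == 3
    assert summary.set_index("cross").loc["NN"].isna().any()
    assert len(pvals) == 0


def test_cross_type_identical_vectors_give_p_one():
    parents = _parents_frame(
        [{"sample_id": "d1", "origin": "hatchery", "sex": "F"},
         {"sample_id": "d2", "origin": "natural", "sex": "F"},
         {"sample_id": "s1", "origin": "hatchery", "sex": "M"},
         {"sample_id": "s2", "origin": "natural", "sex": "M"}])
    rows = []
    for i in range(2):
        rows.append({"offspring_id": f"a{i}", "dam_id": "d1", "sire_id": "s1",
                     "posterior": 1.0, "kind": "triad"})
        rows.append({"offspring_id": f"b{i}", "dam_id": "d2", "sire_id": "s2",
                     "posterior": 1.0, "kind": "triad"})
    summary, pvals = cross_type_rs(pd.DataFrame(rows), parents, seed=1)
    assert (pvals["p_value"] == 1.0).all()


def test_cross_type_additive_penalty_ordering():
    """With a multiplicative per-hatchery-parent penalty, mean RS orders
    NN > hybrids > HH in expectation."""
    rng = np.random.default_rng(9)
    parents_rows = []
    rows = []
    oid = 0
    for i in range(600):
        do = "hatchery" if rng.random() < 0.5 else "natural"
        so = "hatchery" if rng.random() < 0.5 else "natural"
        parents_rows.append({"sample_id": f"d{i}", "origin": do, "sex": "F"})
        parents_rows.append({"sample_id": f"s{i}", "origin": so, "sex": "M"})
        mu = 4.0 * (0.6 ** ((do == "hatchery") + (so == "hatchery")))
        n_off = rng.poisson(mu)
        for _ in range(n_off):
            rows.append({"offspring_id": f"o{oid}", "dam_id": f"d{i}",
                         "sire_id": f"s{i}", "posterior": 1.0, "kind": "triad"})
            oid += 1
    summary, _ = cross_type_rs(pd.DataFrame(rows),
                               _parents_frame(parents_rows), n_perm=100, seed=2)
    s = summary.set_index("cross")["mean_rs"]
    assert s["NN"] > s["HN"] > s["HH"]
    assert s["NN"] > s["NH"] > s["HH"]


# -------------------------------------------------------------- contrasts


def test_contrasts_identical_groups():
    rows = []
    for origin in ("hatchery", "natural"):
        for i in range(5):
            rows.append({"sample_id": f"{origin}{i}", "origin": origin,
                         "sex": "F"})
    df = _parents_frame(rows)
    out = covariate_contrasts(df)
    assert out["length_mm_p"].iloc[0] == 1.0
    assert bool(out["length_mm_degenerate"].iloc[0])


def test_contrasts_wilcoxon_exact_small_sample():
    rows = []
    for i, day in enumerate([1, 2, 3]):
        rows.append({"sample_id": f"h{i}", "origin": "hatchery", "sex": "F",
                     "sample_day": day, "length_mm": 400.0 + i})
    for i, day in enumerate([4, 5, 6]):
        rows.append({"sample_id": f"n{i}", "origin": "natural", "sex": "F",
                     "sample_day": day, "length_mm": 410.0 + i})
    out = covariate_contrasts(_parents_frame(rows))
    assert out["sample_day_p"].iloc[0] == pytest.approx(0.1)


def test_contrasts_detect_one_sd_shift():
    rng = np.random.default_rng(10)
    rows = []
    for i in range(200):
        rows.append({"sample_id": f"h{i}", "origin": "hatchery", "sex": "F",
                     "length_mm": rng.normal(440, 20)})
    for i in range(200):
        rows.append({"sample_id": f"n{i}", "origin": "natural", "sex": "F",
                     "length_mm": rng.normal(420, 20)})
    out = covariate_contrasts(_parents_frame(rows))
    assert out["length_mm_p"].iloc[0] < 0.001


# ------------------------------------------------- thinning invariance


def test_rrs_invariant_under_unbiased_offspring_thinning():
    """Binomial thinning of offspring counts leaves expected RRS unchanged
    (paired replicates, thinning 0.1 vs 1.0)."""
    rng = np.random.default_rng(11)
    diffs = []
    for rep in range(20):
        n = 400
        origin = np.where(rng.random(n) < 0.5, "hatchery", "natural")
        mu = np.where(origin == "hatchery", 1.5, 3.0)
        full = rng.negative_binomial(1, 1 / (1 + mu))
        thin = rng.binomial(full, 0.1)

        def ratio(x):
            return x[origin == "hatchery"].mean() / x[origin == "natural"].mean()

        if thin[origin == "natural"].sum() == 0:
            continue
        diffs.append(ratio(thin) - ratio(full))
    diffs = np.array(diffs)
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean()) < max(3 * se, 0.05)
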