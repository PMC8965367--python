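import itertools

import numpy as np
import pandas as pd
import pytest

import pinkrrs as pk
from pinkrrs.parentage import (LikelihoodTables, encode_states,
                               hypothesis_posteriors,
                               relationship_log_likelihoods)


# --------------------------------------------------------- allele freqs


def test_allele_freq_symmetry(snp_half):
    alleles = np.array([[[0, 0]], [[0, 1]], [[1, 1]]], dtype=np.int16)
    g = pk.GenotypeSet(["a", "b", "c"], alleles, snp_half)
    est = pk.estimate_allele_freqs(g, snp_half)
    assert est.loci[0].freqs == pytest.approx([0.5, 0.5])


def test_allele_freq_floor(snp_half):
    alleles = np.zeros((10, 1, 2), dtype=np.int16)  # all AA
    g = pk.GenotypeSet([f"s{i}" for i in range(10)], alleles, snp_half)
    est = pk.estimate_allele_freqs(g, snp_half)
    f = est.loci[0].freqs
    assert f[0] < 1.0 and f[1] > 0.0
    assert f[1] == pytest.approx(1 / 21 / (1 + 1 / 21))


def test_allele_freq_recovers_truth(snp_half):
    rng = np.random.default_rng(3)
    draws = rng.choice(2, size=(10_000, 1, 2), p=[0.3, 0.7]).astype(np.int16)
    g = pk.GenotypeSet([f"s{i}" for i in range(10_000)], np.sort(draws, axis=2),
                       snp_half)
    est = pk.estimate_allele_freqs(g, snp_half)
    assert est.loci[0].freqs[0] == pytest.approx(0.3, abs=0.01)


def test_all_missing_locus_is_an_error(snp_half):
    alleles = np.full((4, 1, 2), -1, dtype=np.int16)
    g = pk.GenotypeSet(list("abcd"), alleles, snp_half)
    with pytest.raises(Exception, match="snp"):
        pk.estimate_allele_freqs(g, snp_half)


# ------------------------------------------- per-genotype likelihoods


def test_po_likelihood_hand_enumeration(snp_half):
    """Parent AA, offspring AA at p(A)=0.5: L_PO = 0.5, L_U = 0.25,
    LOD10 = log10(2)."""
    out = relationship_log_likelihoods(
        np.array([[0, 0]]), np.array([[0, 0]]), None, snp_half, eps=0.0)
    assert np.exp(out["logL_PO"]) == pytest.approx(0.5)
    assert np.exp(out["logL_U"]) == pytest.approx(0.25)
    lod10 = (out["logL_PO"] - out["logL_U"]) / np.log(10)
    assert lod10 == pytest.approx(np.log10(2))


def test_mendelian_exclusion_and_error_floor(snp_half):
    out = relationship_log_likelihoods(
        np.array([[0, 0]]), np.array([[1, 1]]), None, snp_half, eps=0.0)
    assert out["logL_PO"] == -np.inf
    out = relationship_log_likelihoods(
        np.array([[0, 0]]), np.array([[1, 1]]), None, snp_half, eps=0.01)
    assert np.exp(out["logL_PO"]) == pytest.approx(0.01 * 0.25)


def test_trio_likelihood_certainty(snp_half):
    out = relationship_log_likelihoods(
        np.array([[0, 1]]), np.array([[0, 0]]), np.array([[1, 1]]),
        snp_half, eps=0.0)
    assert np.exp(out["logL_trio"]) == pytest.approx(1.0)


# ------------------------------------------------------------ assignment


def test_full_sampling_assignment_is_exact(assigned_cohort):
    """With complete parent sampling and no genotyping error every
    offspring is recovered as a correct triad with posterior ~1."""
    a = assigned_cohort["assignments"]
    truth = assigned_cohort["pedigree"].links.set_index("offspring_id")
    assert (a["kind"] == "triad").all()
    m = a.set_index("offspring_id").join(truth, rsuffix="_t")
    assert (m["dam_id"] == m["dam_id_t"]).all()
    assert (m["sire_id"] == m["sire_id_t"]).all()
    assert (a["posterior"] > 0.999).all()


def test_posteriors_sum_to_one(assigned_cohort):
    posts = hypothesis_posteriors(
        assigned_cohort["genotypes"].subset(
            assigned_cohort["offspring"]["sample_id"].tolist()[:10]),
        assigned_cohort["parents"],
        assigned_cohort["genotypes"].subset(
            assigned_cohort["parents"]["sample_id"].tolist()),
        pk.Config(genotyping_error_rate=0.0, n_fmax=500, n_mmax=500),
    )
    for p in posts:
        assert p.sum() == pytest.approx(1.0, abs=1e-9)


def test_unsampled_sire_yields_dam_dyads(full_panel):
    """When sires are unsampled but dams fully sampled, offspring resolve
    to dam dyads with no wrong-parent assignments."""
    parents = pk.simulate_spawners(160, 0.5, seed=31)
    ped, off = pk.simulate_reproduction(parents, pk.ReproConfig(mean_rs=3), seed=32)
    off = off.iloc[:120]
    links = ped.links[ped.links["offspring_id"].isin(set(off["sample_id"]))]
    ped = pk.TruePedigree(links.reset_index(drop=True))
    genos = pk.simulate_genotypes(
        ped, parents["sample_id"].tolist(), off["sample_id"].tolist(),
        full_panel, eps=0.0, miss=0.0, seed=33)
    females = parents[parents["sex"] == "F"]
    n_males_total = int((parents["sex"] == "M").sum())
    cfg = pk.Config(genotyping_error_rate=0.0, n_fmax=len(females),
                    n_mmax=2 * n_males_total)
    a = pk.assign_parentage(
        genos.subset(off["sample_id"].tolist()), females,
        genos.subset(females["sample_id"].tolist()), cfg)
    truth = ped.links.set_index("offspring_id")
    m = a.set_index("offspring_id").join(truth, rsuffix="_t")
    dyads = m[m["kind"] == "dyad"]
    assert len(dyads) / len(m) >= 0.95
    assert (dyads["dam_id"] == dyads["dam_id_t"]).all()
    wrong = m[(m["kind"] != "unassigned") & (m["dam_id"] != m["dam_id_t"])]
    assert len(wrong) == 0


def test_all_missing_offspring_unassigned(assigned_cohort, full_panel):
    off_ids = ["ghost"]
    alleles = np.full((1, full_panel.n_loci, 2), -1, dtype=np.int16)
    ghost = pk.GenotypeSet(off_ids, alleles, full_panel)
    a = pk.assign_parentage(
        ghost, assigned_cohort["parents"],
        assigned_cohort["genotypes"].subset(
            assigned_cohort["parents"]["sample_id"].tolist()),
        pk.Config(genotyping_error_rate=0.0, n_fmax=200, n_mmax=200))
    assert a["kind"].tolist() == ["unassigned"]


def test_doubling_error_rate_barely_changes_assignments(assigned_cohort):
    """Doubling the assumed genotyping error rate (the sensitivity
    analysis) changes at most 1% of assignments."""
    off = assigned_cohort["genotypes"].subset(
        assigned_cohort["offspring"]["sample_id"].tolist())
    cand = assigned_cohort["genotypes"].subset(
        assigned_cohort["parents"]["sample_id"].tolist())
    a1 = pk.assign_parentage(off, assigned_cohort["parents"], cand,
                             pk.Config(genotyping_error_rate=0.0054))
    a2 = pk.assign_parentage(off, assigned_cohort["parents"], cand,
                             pk.Config(genotyping_error_rate=0.0108))
    same = ((a1["dam_id"].fillna("-") == a2["dam_id"].fillna("-")) &
            (a1["sire_id"].fillna("-") == a2["sire_id"].fillna("-"))).mean()
    assert same >= 0.99


def test_unknown_sex_candidates_excluded_with_warning(assigned_cohort):
    parents = assigned_cohort["parents"].copy()
    parents.loc[parents.index[0], "sex"] = "unknown"
    off = assigned_cohort["genotypes"].subset(
        assigned_cohort["offspring"]["sample_id"].tolist()[:5])
    cand = assigned_cohort["genotypes"].subset(parents["sample_id"].tolist())
    with pytest.warns(UserWarning, match="unknown sex"):
        pk.assign_parentage(off, parents, cand,
                            pk.Config(genotyping_error_rate=0.0,
                                      n_fmax=200, n_mmax=200))


# -------------------------------------------------------------- exclusion


def _brute_force_exclusion(freqs):
    """Independent enumeration oracle over all genotype combinations."""
    A = len(freqs)
    genos = [(i, j) for i in range(A) for j in range(i, A)]

    def gp(g):
        i, j = g
        return freqs[i] ** 2 if i == j else 2 * freqs[i] * freqs[j]

    def offspring_dist(gd, gs):
        out = {}
        for a in gd:
            for b in gs:
                key = (min(a, b), max(a, b))
                out[key] = out.get(key, 0.0) + 0.25
        return out

    # q1: candidate shares no allele with a random (HWE) offspring
    q1 = 0.0
    for go in genos:
        for gc in genos:
            if not (set(go) & set(gc)):
                q1 += gp(go) * gp(gc)
    # q2: candidate cannot be the second parent given the true first parent
    q2 = 0.0
    for gd in genos:
        for gs in genos:
            dist = offspring_dist(gd, gs)
            for go, p_go in dist.items():
                for gc in genos:
                    if offspring_dist(gd, gc).get(go, 0.0) == 0.0:
                        q2 += gp(gd) * gp(gs) * p_go * gp(gc)
    return q1, q2


@pytest.mark.parametrize("freqs", [
    np.array([0.5, 0.5]),
    np.array([0.5, 0.3, 0.2]),
    np.array([0.4, 0.3, 0.2, 0.1]),
])
def test_exclusion_matches_brute_force(freqs):
    kind = "snp" if len(freqs) == 2 else "microhap"
    panel = pk.LocusPanel([pk.Locus("l", kind, [str(i) for i in range(len(freqs))],
                                    freqs)])
    df = pk.exclusion_probabilities(panel)
    q1, q2 = _brute_force_exclusion(freqs)
    assert df.loc[0, "q1"] == pytest.approx(q1, abs=1e-12)
    assert df.loc[0, "q2"] == pytest.approx(q2, abs=1e-12)


def test_combined_exclusion_near_one_for_full_panel(full_panel):
    df = pk.exclusion_probabilities(full_panel)
    comb = df[df["locus_id"] == "combined"].iloc[0]
    assert comb["q1"] >= 0.9999
    assert comb["q2"] >= 0.9999


def test_exclusion_monotone_in_loci():
    panel = pk.make_panel(30, 0, seed=9)
    prev = 0.0
    for n in (5, 10, 20, 30):
        sub = pk.LocusPanel(panel.loci[:n])
        q = pk.exclusion_probabilities(sub)
        comb = q[q["locus_id"] == "combined"]["q1"].iloc[0]
        assert comb >= prev - 1e-12
        prev = comb


def test_near_monomorphic_locus_is_uninformative():
    panel = pk.LocusPanel([pk.Locus("l", "snp", ["A", "B"],
                                    np.array([1 - 1e-6, 1e-6]))])
    df = pk.exclusion_probabilities(panel)
    assert df.loc[0, "q1"] < 1e-5
    assert df.loc[0, "q2"] < 1e-5


# ----------------------------------------- relationship discrimination


def test_full_panel_separates_po_from_unrelated(full_panel):
    rep = pk.relationship_discrimination_sim(full_panel, eps=0.005,
                                             n_sim=3000, seed=5)
    row = rep.table.set_index("comparison")
    assert row.loc["PO_vs_U", "fpr"] <= 1e-4 + 1e-12
    assert row.loc["PO_vs_U", "fnr"] <= 0.01
    assert row.loc["PO_vs_FS", "fnr"] <= 0.01


def test_single_locus_panel_cannot_discriminate(snp_half):
    rep = pk.relationship_discrimination_sim(snp_half, eps=0.0, n_sim=2000,
                                             seed=6)
    assert rep.table.set_index("comparison").loc["PO_vs_U", "fnr"] > 0.5


def test_discrimination_requires_minimum_sims(snp_half):
    with pytest.raises(ValueError):
        pk.relationship_discrimination_sim(snp_half, n_sim=50)
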