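import numpy as np
import pytest

import pinkrrs as pk


@pytest.fixture(scope="session")
def full_panel():
    """The default 298-locus amplicon panel (210 SNPs + 88 microhaps)."""
    return pk.make_panel(seed=11)


@pytest.fixture(scope="session")
def small_panel():
    """A reduced panel for fast likelihood tests."""
    return pk.make_panel(n_snp=40, n_microhap=10, seed=7)


@pytest.fixture(scope="session")
def snp_half():
    """Single biallelic locus with p(A) = 0.5."""
    return pk.LocusPanel([pk.Locus("snp", "snp", ["A", "B"], np.array([0.5, 0.5]))])


@pytest.fixture(scope="session")
def assigned_cohort(full_panel):
    """Fully sampled cohort with error-free genotypes and its assignments.

    200 offspring from 150 parents, both parents of every offspring
    genotyped, so the true pedigree is an exact oracle.
    """
    parents = pk.simulate_spawners(150, 0.5, seed=21)
    pedigree, offspring = pk.simulate_reproduction(
        parents, pk.ReproConfig(mean_rs=3.0), seed=22)
    offspring = offspring.iloc[:200]
    links = pedigree.links[
        pedigree.links["offspring_id"].isin(set(offspring["sample_id"]))]
    pedigree = pk.TruePedigree(links.reset_index(drop=True))
    genos = pk.simulate_genotypes(
        pedigree, parents["sample_id"].tolist(),
        offspring["sample_id"].tolist(), full_panel, eps=0.0, miss=0.0,
        seed=23)
    cfg = pk.Config(genotyping_error_rate=0.0)
    assignments = pk.assign_parentage(
        genos.subset(offspring["sample_id"].tolist()), parents,
        genos.subset(parents["sample_id"].tolist()), cfg)
    return {
        "parents": parents,
        "offspring": offspring,
        "pedigree": pedigree,
        "genotypes": genos,
        "assignments": assignments,
        "config": cfg,
    }
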