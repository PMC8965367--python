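"""Synthetic spawner cohorts, pedigrees, genotypes and carcass sampling.

The generator emulates the study system: a Pink Salmon stream with a
mixture of hatchery strays (identified by otolith thermal marks) and
natural-origin spawners, origin/sex-specific covariate shifts (body
length, sample day, distance upstream), negative-binomial reproductive
success with log-link covariate effects, polygamous mating, Mendelian
inheritance over a SNP + microhaplotype amplicon panel with genotyping
error and missingness, and incomplete (optionally date-biased) carcass
sampling. A fixed 2-year generation separates parents and offspring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io import substream
from .records import SAMPLE_COLUMNS, GenotypeSet, Locus, LocusPanel, ValidationError

__all__ = [
    "CovariateSpec",
    "ReproConfig",
    "TruePedigree",
    "make_panel",
    "simulate_spawners",
    "simulate_reproduction",
    "simulate_genotypes",
    "apply_carcass_sampling",
]

# Hogan Bay 2014 (even-year) covariate defaults, by (origin, sex):
# mean length mm, SD; mean sample day-of-year, SD; mean distance m, SD.
# Aug 31 = day 243; Aug 29 = 241; Aug 26 = 238 in a non-leap year.
_HOGAN_2014 = {
    ("hatchery", "F"): (441.9, 19.4, 243.0, 5.5, 368.4, 98.7),
    ("natural", "F"): (434.0, 20.4, 241.0, 6.4, 340.5, 96.7),
    ("hatchery", "M"): (435.7, 25.3, 243.0, 6.5, 353.0, 95.1),
    ("natural", "M"): (417.5, 31.6, 238.0, 6.2, 330.5, 85.4),
}

LENGTH_BOUNDS = (250.0, 600.0)
DAY_BOUNDS = (213, 273)  # Aug 1 .. Sep 30


@dataclass
class CovariateSpec:
    """Origin/sex-specific normal laws for length, day and distance.

    Defaults reproduce the Hogan Bay 2014 means/SDs; values are truncated
    to biological bounds (length 250-600 mm, day-of-year 213-273, distance
    within the stream).
    """

    table: dict = field(default_factory=lambda: dict(_HOGAN_2014))
    stream_length_m: float = 550.0

    def draw(self, rng: np.random.Generator, origin: str, sex: str, n: int):
        lm, ls, dm, ds, xm, xs = self.table[(origin, sex)]
        length = np.clip(rng.normal(lm, ls, n), *LENGTH_BOUNDS)
        day = np.clip(np.rint(rng.normal(dm, ds, n)), *DAY_BOUNDS).astype(int)
        dist = np.clip(rng.normal(xm, xs, n), 0.0, self.stream_length_m)
        return length, day, dist


@dataclass
class ReproConfig:
    """Negative-binomial reproductive-success model.

    Per female i, the number of surviving sampled-age adult offspring is
    NB with mean mu_i and dispersion (size) k, var = m + m^2/k, with
    log mu_i = log(mean_rs) + beta_origin*[hatchery] + beta_length*(L-430)
    + beta_date*(d-243) + beta_date2*(d-243)^2 + beta_distance*(x-350).
    Sires are drawn per offspring with probability proportional to the
    male's own mu times unit-mean gamma(k) noise (polygamy, overdispersed
    male RS).
    """

    mean_rs: float = 3.0
    dispersion_k: float = 1.0
    beta_origin: float = np.log(0.5)
    beta_length: float = 0.01
    beta_date: float = -0.03
    beta_date2: float = 0.0
    beta_distance: float = -0.002
    length_center: float = 430.0
    day_center: float = 243.0
    distance_center: float = 350.0

    def __post_init__(self) -> None:
        if self.mean_rs <= 0 or self.dispersion_k <= 0:
            raise ValueError("mean_rs and dispersion_k must be positive")

    def mu(self, df: pd.DataFrame) -> np.ndarray:
        eta = (
            np.log(self.mean_rs)
            + self.beta_origin * (df["origin"].to_numpy() == "hatchery")
            + self.beta_length * (df["length_mm"].to_numpy() - self.length_center)
            + self.beta_date * (df["sample_day"].to_numpy() - self.day_center)
            + self.beta_date2 * (df["sample_day"].to_numpy() - self.day_center) ** 2
            + self.beta_distance * (df["distance_m"].to_numpy() - self.distance_center)
        )
        return np.exp(eta)


@dataclass
class TruePedigree:
    """Ground-truth offspring -> (dam, sire) links of one generation."""

    links: pd.DataFrame  # columns offspring_id, dam_id, sire_id

    def __len__(self) -> int:
        return len(self.links)

    def parents_of(self, offspring_id: str) -> tuple[str, str]:
        row = self.links.loc[self.links["offspring_id"] == offspring_id].iloc[0]
        return row["dam_id"], row["sire_id"]

    def true_rs(self) -> pd.Series:
        """True offspring count per parent (dams and sires)."""
        counts = pd.concat(
            [self.links["dam_id"], self.links["sire_id"]]
        ).value_counts()
        counts.name = "rs"
        return counts


FreqLaw = Union[tuple, Callable[[np.random.Generator, int], np.ndarray]]


def make_panel(
    n_snp: int = 210,
    n_microhap: int = 88,
    freq_law: FreqLaw = ("uniform", 0.05, 0.5),
    seed: int = 0,
) -> LocusPanel:
    """Build a synthetic amplicon panel (default 210 SNPs + 88 microhaps).

    SNP minor-allele frequencies follow ``freq_law``: ``("uniform", lo,
    hi)``, ``("point", p)`` or a callable ``f(rng, n) -> array``. Microhap
    loci get 3-6 alleles with Dirichlet(1) frequencies floored at 0.01.
    """
    if n_snp < 0 or n_microhap < 0:
        raise ValueError("locus counts must be nonnegative")
    rng = np.random.default_rng(substream(seed, "panel"))
    if callable(freq_law):
        maf = np.asarray(freq_law(rng, n_snp), float)
    elif freq_law[0] == "uniform":
        maf = rng.uniform(freq_law[1], freq_law[2], n_snp)
    elif freq_law[0] == "point":
        maf = np.full(n_snp, float(freq_law[1]))
    else:
        raise ValueError(f"unknown freq law {freq_law!r}")
    loci = []
    for i in range(n_snp):
        p = float(maf[i])
        loci.append(Locus(f"snp_{i:04d}", "snp", ["A", "B"],
                          np.array([p, 1.0 - p])))
    for i in range(n_microhap):
        n_alleles = int(rng.integers(3, 7))
        f = rng.dirichlet(np.ones(n_alleles))
        f = np.clip(f, 0.01, None)
        f = f / f.sum()
        alleles = [f"h{j}" for j in range(n_alleles)]
        loci.append(Locus(f"mhap_{i:04d}", "microhap", alleles, f))
    return LocusPanel(loci)


def simulate_spawners(
    n_parents: int,
    phos: float,
    covariate_spec: Optional[CovariateSpec] = None,
    seed: int = 0,
    stream: str = "Hogan",
    year: int = 2014,
    id_prefix: str = "P",
    intertidal_boundary_m: float = 450.0,
) -> pd.DataFrame:
    """Simulate a spawner cohort: origin ~ Bernoulli(pHOS), sex ~
    Bernoulli(1/2), covariates from the origin/sex-specific laws."""
    if not 0.0 <= phos <= 1.0:
        raise ValueError("phos must lie in [0, 1]")
    spec = covariate_spec or CovariateSpec()
    rng = np.random.default_rng(substream(seed, "spawners"))
    origin = np.where(rng.random(n_parents) < phos, "hatchery", "natural")
    sex = np.where(rng.random(n_parents) < 0.5, "F", "M")
    length = np.empty(n_parents)
    day = np.empty(n_parents, dtype=int)
    dist = np.empty(n_parents)
    for o in ("hatchery", "natural"):
        for s in ("F", "M"):
            m = (origin == o) & (sex == s)
            if m.any():
                length[m], day[m], dist[m] = spec.draw(rng, o, s, int(m.sum()))
    lineage = "even" if year % 2 == 0 else "odd"
    df = pd.DataFrame({
        "sample_id": [f"{id_prefix}{i:06d}" for i in range(n_parents)],
        "stream": stream,
        "year": year,
        "lineage": lineage,
        "origin": origin,
        "hatchery_code": [("AFK" if o == "hatchery" else None) for o in origin],
        "sex": sex,
        "length_mm": length,
        "sample_day": day,
        "distance_m": dist,
        "intertidal": dist <= intertidal_boundary_m,
        "genotyped": True,
    })
    return df[SAMPLE_COLUMNS]


def simulate_reproduction(
    parents: pd.DataFrame,
    cfg: Optional[ReproConfig] = None,
    seed: int = 0,
    covariate_spec: Optional[CovariateSpec] = None,
    id_prefix: str = "O",
) -> tuple[TruePedigree, pd.DataFrame]:
    """Draw offspring counts per female and assign sires polygamously.

    Returns the true pedigree and the offspring cohort (fresh natural-
    origin covariates, sampled two years after the parents).
    """
    cfg = cfg or ReproConfig()
    rng = np.random.default_rng(substream(seed, "reproduction"))
    females = parents[parents["sex"] == "F"]
    males = parents[parents["sex"] == "M"]
    if len(females) == 0 or len(males) == 0:
        raise ValidationError("reproduction requires at least one parent of each sex")
    k = cfg.dispersion_k
    mu_f = cfg.mu(females)
    # NB(mean mu, size k): numpy parameterization n=k, p=k/(k+mu)
    counts = rng.negative_binomial(k, k / (k + mu_f))
    mu_m = cfg.mu(males)
    weights = mu_m * rng.gamma(k, 1.0 / k, len(males))
    w = weights / weights.sum()
    n_off = int(counts.sum())
    dam_idx = np.repeat(np.arange(len(females)), counts)
    sire_idx = rng.choice(len(males), size=n_off, p=w)
    offspring_ids = [f"{id_prefix}{i:06d}" for i in range(n_off)]
    pedigree = TruePedigree(pd.DataFrame({
        "offspring_id": offspring_ids,
        "dam_id": females["sample_id"].to_numpy()[dam_idx],
        "sire_id": males["sample_id"].to_numpy()[sire_idx],
    }))
    year = int(parents["year"].iloc[0]) + 2
    spec = covariate_spec or CovariateSpec()
    offspring = simulate_spawners(
        n_off, phos=0.0, covariate_spec=spec,
        seed=int(rng.integers(2**31)), stream=str(parents["stream"].iloc[0]),
        year=year, id_prefix=id_prefix,
    )
    # keep the pedigree's ids (simulate_spawners regenerates the prefix ids)
    offspring["sample_id"] = offspring_ids
    offspring["lineage"] = parents["lineage"].iloc[0]
    return pedigree, offspring


def _hwe_draw(rng: np.random.Generator, freqs: np.ndarray, n: int) -> np.ndarray:
    """(n, 2) allele indices from Hardy-Weinberg at the given frequencies."""
    cum = np.cumsum(freqs)
    u = rng.random((n, 2))
    return np.searchsorted(cum, u).astype(np.int16)


def simulate_genotypes(
    pedigree: TruePedigree,
    founder_ids: Sequence[str],
    offspring_ids: Sequence[str],
    panel: LocusPanel,
    eps: float = 0.0054,
    miss: float = 0.0,
    seed: int = 0,
) -> GenotypeSet:
    """Mendelian genotypes over the panel with genotyping error/missingness.

    Founders are drawn from Hardy-Weinberg; each offspring receives one
    uniformly chosen allele from each true parent per locus. With
    probability ``eps`` (per individual-locus) the observed genotype is
    replaced by a fresh HWE draw; with probability ``miss`` it is set
    missing.
    """
    if not (0.0 <= eps < 1.0 and 0.0 <= miss < 1.0):
        raise ValueError("eps and miss must lie in [0, 1)")
    rng = np.random.default_rng(substream(seed, "genotypes"))
    founder_ids = list(founder_ids)
    offspring_ids = list(offspring_ids)
    links = pedigree.links.set_index("offspring_id")
    f_index = {s: i for i, s in enumerate(founder_ids)}
    for oid in offspring_ids:
        dam, sire = links.loc[oid, "dam_id"], links.loc[oid, "sire_id"]
        if dam not in f_index or sire not in f_index:
            raise ValidationError(
                f"offspring {oid} has an ungenotyped parent ({dam}, {sire})"
            )
    dam_idx = np.array([f_index[links.loc[o, "dam_id"]] for o in offspring_ids], int)
    sire_idx = np.array([f_index[links.loc[o, "sire_id"]] for o in offspring_ids], int)
    n_f, n_o, L = len(founder_ids), len(offspring_ids), panel.n_loci
    n = n_f + n_o
    alleles = np.empty((n, L, 2), dtype=np.int16)
    for l, loc in enumerate(panel.loci):
        g_f = _hwe_draw(rng, loc.freqs, n_f)
        alleles[:n_f, l] = g_f
        if n_o:
            pick_d = rng.integers(0, 2, n_o)
            pick_s = rng.integers(0, 2, n_o)
            alleles[n_f:, l, 0] = g_f[dam_idx, pick_d]
            alleles[n_f:, l, 1] = g_f[sire_idx, pick_s]
        if eps > 0:
            err = rng.random(n) < eps
            n_err = int(err.sum())
            if n_err:
                alleles[err, l] = _hwe_draw(rng, loc.freqs, n_err)
    if miss > 0:
        missing = rng.random((n, L)) < miss
        alleles[missing] = -1
    return GenotypeSet(founder_ids + offspring_ids, alleles, panel)


def apply_carcass_sampling(
    cohort: pd.DataFrame,
    fraction: float,
    bias_spec: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Incomplete carcass sampling: each fish retained independently with
    probability ``fraction * w(day)/max(w)``; with no bias this is plain
    binomial thinning. Retained fish are marked genotyped."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(substream(seed, "carcass_sampling"))
    if bias_spec is None:
        p = np.full(len(cohort), fraction)
    else:
        w = np.asarray(bias_spec(cohort["sample_day"].to_numpy(float)), float)
        if np.any(w < 0):
            raise ValueError("bias weights must be nonnegative")
        p = fraction * w / w.max()
    keep = rng.random(len(cohort)) < p
    out = cohort.loc[keep].copy()
    out["genotyped"] = True
    return out
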