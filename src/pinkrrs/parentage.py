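"""Likelihood-based parentage assignment from incompletely sampled candidates.

Single-parent (dyad) and parent-pair (triad) hypotheses are scored per
offspring with Mendelian transmission likelihoods over the amplicon panel,
a genotype-replacement error model (each per-locus likelihood is floored
as ``(1-eps)*L_model + eps*L_HWE``), and escapement-based candidate priors
with an explicit "parent not sampled" hypothesis. Because the panel's
exclusion power is essentially complete, this prior-weighted likelihood
engine reproduces the decision surface of full Bayesian pedigree
reconstruction on this class of data (posteriors ~ 1 for true parents).

Genotypes are encoded per locus as unordered-pair state codes; an extra
state per locus stands for "missing" and contributes the marginal (HWE)
likelihood for a missing parent and nothing for a missing offspring
genotype, so hypotheses with different missingness remain comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .records import Config, GenotypeSet, Locus, LocusPanel, ValidationError

__all__ = [
    "PedigreeAssignment",
    "RelationshipPowerReport",
    "LikelihoodTables",
    "estimate_allele_freqs",
    "relationship_log_likelihoods",
    "assign_parentage",
    "exclusion_probabilities",
    "relationship_discrimination_sim",
]


@dataclass
class PedigreeAssignment:
    offspring_id: str
    dam_id: Optional[str]
    sire_id: Optional[str]
    posterior: float
    kind: str  # dyad | triad | unassigned


@dataclass
class RelationshipPowerReport:
    """False-positive/-negative rates for parent-offspring discrimination
    at a log-likelihood-ratio threshold calibrated on unrelated pairs."""

    table: pd.DataFrame  # rows PO_vs_U, PO_vs_FS, PO_vs_HS
    threshold: float
    n_sim: int


# ------------------------------------------------------------- state codes


def _pair_states(n_alleles: int) -> np.ndarray:
    """All unordered allele pairs (i <= j) for a locus, shape (S, 2)."""
    pairs = [(i, j) for i in range(n_alleles) for j in range(i, n_alleles)]
    return np.array(pairs, dtype=np.int64)


def _state_code(a: np.ndarray, b: np.ndarray, n_alleles: int) -> np.ndarray:
    """Triangular index of the unordered pair (a, b), a <= b."""
    return a * n_alleles - (a * (a - 1)) // 2 + (b - a)


def encode_states(genotypes: GenotypeSet) -> np.ndarray:
    """(n, L) int state codes; the per-locus missing state is S_l."""
    n_all = genotypes.panel.n_alleles()
    a = genotypes.alleles[:, :, 0].astype(np.int64)
    b = genotypes.alleles[:, :, 1].astype(np.int64)
    codes = _state_code(a, b, n_all[None, :])
    n_states = (n_all * (n_all + 1)) // 2
    missing = a < 0
    codes[missing] = np.broadcast_to(n_states[None, :], codes.shape)[missing]
    return codes


class LikelihoodTables:
    """Per-locus genotype probability tables with the error floor applied.

    For each locus with S genotype states the tables are padded to S+1
    (index S = missing):

    - ``log_hwe[go]``: Hardy-Weinberg probability of the offspring genotype.
    - ``log_po[gp, go]``: probability of the offspring genotype given one
      parent ``gp`` and the other parent drawn from the population.
    - ``log_trio[gp1, gp2, go]``: Mendelian probability given both parents.
    """

    def __init__(self, panel: LocusPanel, eps: float = 0.0):
        if not 0.0 <= eps < 1.0:
            raise ValueError("eps must lie in [0, 1)")
        self.panel = panel
        self.eps = eps
        self.log_hwe: list[np.ndarray] = []
        self.log_po: list[np.ndarray] = []
        self.log_trio: list[np.ndarray] = []
        self.hwe: list[np.ndarray] = []
        self.po: list[np.ndarray] = []
        self.trio: list[np.ndarray] = []
        for loc in panel.loci:
            hwe, po, trio = _locus_tables(loc)
            self.hwe.append(hwe)
            self.po.append(po)
            self.trio.append(trio)
            if eps > 0.0:
                po = (1.0 - eps) * po + eps * hwe[None, :]
                trio = (1.0 - eps) * trio + eps * hwe[None, None, :]
            S = len(hwe)
            lh = np.zeros(S + 1)
            lh[:S] = _safe_log(hwe)
            lp = np.zeros((S + 1, S + 1))
            lp[:S, :S] = _safe_log(po)
            lp[S, :S] = lh[:S]  # parent missing: marginal HWE
            lt = np.zeros((S + 1, S + 1, S + 1))
            lt[:S, :S, :S] = _safe_log(trio)
            lt[S, :S, :S] = lp[:S, :S]  # first parent missing -> PO on second
            lt[:S, S, :S] = lp[:S, :S]
            lt[S, S, :S] = lh[None, :S]
            self.log_hwe.append(lh)
            self.log_po.append(lp)
            self.log_trio.append(lt)


def _safe_log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


def _locus_tables(loc: Locus) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    A = len(loc.alleles)
    p = loc.freqs
    pairs = _pair_states(A)
    S = len(pairs)
    hwe = np.array([
        p[i] ** 2 if i == j else 2 * p[i] * p[j] for i, j in pairs
    ])
    code = {(i, j): s for s, (i, j) in enumerate(map(tuple, pairs))}

    def st(x, y):
        return code[(min(x, y), max(x, y))]

    po = np.zeros((S, S))
    for gp, (i, j) in enumerate(pairs):
        for t in (i, j):  # transmitted allele, 1/2 each
            for o in range(A):  # other parent's contribution from HWE
                po[gp, st(t, o)] += 0.5 * p[o]
    trio = np.zeros((S, S, S))
    for g1, (i, j) in enumerate(pairs):
        for g2, (k, m) in enumerate(pairs):
            for t1 in (i, j):
                for t2 in (k, m):
                    trio[g1, g2, st(t1, t2)] += 0.25
    return hwe, po, trio


# --------------------------------------------------------- allele freqs


def estimate_allele_freqs(genotypes: GenotypeSet, panel: LocusPanel) -> LocusPanel:
    """Empirical allele frequencies, floored at 1/(2N+1) and renormalized.

    Raises on a locus with no non-missing genotypes.
    """
    loci = []
    for l, loc in enumerate(panel.loci):
        g = genotypes.alleles[:, l, :]
        obs = g[g[:, 0] >= 0]
        if len(obs) == 0:
            raise ValidationError(f"no non-missing genotypes at locus {loc.locus_id}")
        counts = np.bincount(obs.ravel(), minlength=len(loc.alleles)).astype(float)
        freqs = counts / counts.sum()
        floor = 1.0 / (2 * len(obs) + 1)
        freqs = np.maximum(freqs, floor)
        freqs = freqs / freqs.sum()
        loci.append(Locus(loc.locus_id, loc.kind, list(loc.alleles), freqs))
    return LocusPanel(loci)


# ------------------------------------------- single-genotype likelihoods


def relationship_log_likelihoods(
    g_off: np.ndarray,
    g_p1: Optional[np.ndarray],
    g_p2: Optional[np.ndarray],
    freqs: LocusPanel,
    eps: float = 0.0,
) -> dict:
    """Total log-likelihoods of one offspring's genotype vector under the
    unrelated, single-parent and parent-pair hypotheses.

    Genotype vectors are (L, 2) allele-index arrays with (-1, -1) for
    missing loci; missing loci are skipped (contribute log 1).
    """
    tables = LikelihoodTables(freqs, eps)
    n_all = freqs.n_alleles()
    S = (n_all * (n_all + 1)) // 2

    def codes(g):
        if g is None:
            return S.copy()
        g = np.asarray(g, dtype=np.int64)
        c = _state_code(g[:, 0], g[:, 1], n_all)
        c[g[:, 0] < 0] = S[g[:, 0] < 0]
        return c

    co = codes(np.asarray(g_off))
    c1 = codes(g_p1)
    c2 = codes(g_p2)
    ll_u = ll_po1 = ll_po2 = ll_trio = 0.0
    for l in range(freqs.n_loci):
        ll_u += tables.log_hwe[l][co[l]]
        ll_po1 += tables.log_po[l][c1[l], co[l]]
        ll_po2 += tables.log_po[l][c2[l], co[l]]
        ll_trio += tables.log_trio[l][c1[l], c2[l], co[l]]
    out = {"logL_U": ll_u, "logL_trio": ll_trio}
    out["logL_PO"] = ll_po1
    out["logL_PO_p1"] = ll_po1
    out["logL_PO_p2"] = ll_po2
    return out


# ------------------------------------------------------------- assignment


def _pairwise_po_loglik(
    tables: LikelihoodTables, cand_codes: np.ndarray, off_codes: np.ndarray
) -> np.ndarray:
    """(n_cand, n_off) total log L_PO for every candidate x offspring."""
    n_c, n_o = len(cand_codes), len(off_codes)
    ll = np.zeros((n_c, n_o))
    for l in range(tables.panel.n_loci):
        ll += tables.log_po[l][cand_codes[:, l][:, None], off_codes[:, l][None, :]]
    return ll


def assign_parentage(
    offspring: GenotypeSet,
    candidates: pd.DataFrame,
    candidate_genotypes: GenotypeSet,
    cfg: Optional[Config] = None,
    freqs: Optional[LocusPanel] = None,
) -> pd.DataFrame:
    """Assign each offspring to a dam and/or sire, or leave it unassigned.

    Hypotheses per offspring: each sampled female as dam (sire unsampled),
    each sampled male as sire, the top-``pair_beam_width`` females crossed
    with the top males as parent pairs, and "no sampled parent". Priors
    factorize by sex: a specific sampled female has prior 1/N_fmax and the
    unsampled-dam hypothesis carries the remaining mass 1 - n_f/N_fmax
    (likewise for males). The best hypothesis is accepted iff its
    posterior reaches the configured threshold; ties at machine precision
    are left unassigned.
    """
    cfg = cfg or Config()
    panel = offspring.panel
    if freqs is None:
        pooled = GenotypeSet(
            list(candidate_genotypes.sample_ids) + list(offspring.sample_ids),
            np.concatenate([candidate_genotypes.alleles, offspring.alleles]),
            panel,
        )
        freqs = estimate_allele_freqs(pooled, panel)
    tables = LikelihoodTables(freqs, cfg.genotyping_error_rate)

    known_sex = candidates["sex"].isin(["F", "M"])
    if not known_sex.all():
        warnings.warn(
            f"excluding {(~known_sex).sum()} candidates with unknown sex",
            stacklevel=2,
        )
    fem_ids = candidates.loc[known_sex & (candidates["sex"] == "F"), "sample_id"].tolist()
    mal_ids = candidates.loc[known_sex & (candidates["sex"] == "M"), "sample_id"].tolist()
    fem_ids = [s for s in fem_ids if s in candidate_genotypes]
    mal_ids = [s for s in mal_ids if s in candidate_genotypes]
    n_f, n_m = len(fem_ids), len(mal_ids)
    n_fmax = cfg.n_fmax if cfg.n_fmax is not None else n_f
    n_mmax = cfg.n_mmax if cfg.n_mmax is not None else n_m
    if n_fmax < n_f or n_mmax < n_m:
        raise ValidationError("N_fmax/N_mmax below the number of sampled candidates")

    codes_f = encode_states(candidate_genotypes.subset(fem_ids)) if n_f else np.empty((0, panel.n_loci), int)
    codes_m = encode_states(candidate_genotypes.subset(mal_ids)) if n_m else np.empty((0, panel.n_loci), int)
    codes_o = encode_states(offspring)
    n_off = len(offspring)

    ll_f = _pairwise_po_loglik(tables, codes_f, codes_o)
    ll_m = _pairwise_po_loglik(tables, codes_m, codes_o)
    ll_u = np.zeros(n_off)
    for l in range(panel.n_loci):
        ll_u += tables.log_hwe[l][codes_o[:, l]]

    with np.errstate(divide="ignore"):
        lp_f = -np.log(n_fmax) if n_f else -np.inf
        lp_m = -np.log(n_mmax) if n_m else -np.inf
        lu_f = np.log(max(1.0 - n_f / n_fmax, 0.0)) if n_fmax > 0 else 0.0
        lu_m = np.log(max(1.0 - n_m / n_mmax, 0.0)) if n_mmax > 0 else 0.0

    B = min(cfg.pair_beam_width, max(n_f, 1), max(n_m, 1))
    pair_ok = n_f > 0 and n_m > 0
    if pair_ok:
        top_f = np.argpartition(-ll_f, min(B, n_f) - 1, axis=0)[:B]  # (B, n_off)
        top_m = np.argpartition(-ll_m, min(B, n_m) - 1, axis=0)[:B]
        n_states = ((panel.n_alleles() * (panel.n_alleles() + 1)) // 2)
        ll_pair = np.zeros((top_f.shape[0], top_m.shape[0], n_off))
        for l in range(panel.n_loci):
            S1 = n_states[l] + 1
            flat = tables.log_trio[l].reshape(S1 * S1, S1)
            gf = codes_f[top_f, l]  # (B, n_off)
            gm = codes_m[top_m, l]
            combo = gf[:, None, :] * S1 + gm[None, :, :]
            ll_pair += flat[combo, codes_o[:, l][None, None, :]]

    blocks = [ll_f + lp_f + lu_m, ll_m + lp_m + lu_f]
    if pair_ok:
        bf, bm = ll_pair.shape[0], ll_pair.shape[1]
        blocks.append(ll_pair.reshape(bf * bm, n_off) + lp_f + lp_m)
    else:
        bf = bm = 0
    blocks.append((ll_u + lu_f + lu_m)[None, :])
    nums = np.vstack(blocks)  # (H, n_off)
    with np.errstate(invalid="ignore"):
        total = logsumexp(nums, axis=0)
    best = np.argmax(nums, axis=0)
    top_vals = nums[best, np.arange(n_off)]
    if nums.shape[0] > 1:
        second_vals = np.partition(nums, -2, axis=0)[-2]
    else:
        second_vals = top_vals
    post = np.exp(top_vals - total)
    rows = []
    pair_base = n_f + n_m
    u_index = pair_base + bf * bm
    for o in range(n_off):
        oid = offspring.sample_ids[o]
        if not np.isfinite(total[o]):
            rows.append((oid, None, None, 0.0, "unassigned"))
            continue
        b = int(best[o])
        p = float(post[o])
        tied = (top_vals[o] - second_vals[o]) < 1e-9
        if b == u_index or p < cfg.posterior_threshold or tied:
            rows.append((oid, None, None, p, "unassigned"))
        elif b < n_f:
            rows.append((oid, fem_ids[b], None, p, "dyad"))
        elif b < pair_base:
            rows.append((oid, None, mal_ids[b - n_f], p, "dyad"))
        else:
            i, j = divmod(b - pair_base, bm)
            rows.append((oid, fem_ids[top_f[i, o]], mal_ids[top_m[j, o]], p, "triad"))
    return pd.DataFrame(
        rows, columns=["offspring_id", "dam_id", "sire_id", "posterior", "kind"]
    )


def hypothesis_posteriors(
    offspring: GenotypeSet,
    candidates: pd.DataFrame,
    candidate_genotypes: GenotypeSet,
    cfg: Optional[Config] = None,
    freqs: Optional[LocusPanel] = None,
) -> list[np.ndarray]:
    """Full normalized posterior vector per offspring (for diagnostics and
    the sum-to-one invariant)."""
    cfg = cfg or Config()
    panel = offspring.panel
    if freqs is None:
        pooled = GenotypeSet(
            list(candidate_genotypes.sample_ids) + list(offspring.sample_ids),
            np.concatenate([candidate_genotypes.alleles, offspring.alleles]),
            panel,
        )
        freqs = estimate_allele_freqs(pooled, panel)
    tables = LikelihoodTables(freqs, cfg.genotyping_error_rate)
    fem = candidates[candidates["sex"] == "F"]["sample_id"].tolist()
    mal = candidates[candidates["sex"] == "M"]["sample_id"].tolist()
    n_f, n_m = len(fem), len(mal)
    n_fmax = cfg.n_fmax if cfg.n_fmax is not None else n_f
    n_mmax = cfg.n_mmax if cfg.n_mmax is not None else n_m
    codes_f = encode_states(candidate_genotypes.subset(fem))
    codes_m = encode_states(candidate_genotypes.subset(mal))
    codes_o = encode_states(offspring)
    ll_f = _pairwise_po_loglik(tables, codes_f, codes_o)
    ll_m = _pairwise_po_loglik(tables, codes_m, codes_o)
    ll_u = np.zeros(len(offspring))
    for l in range(panel.n_loci):
        ll_u += tables.log_hwe[l][codes_o[:, l]]
    with np.errstate(divide="ignore"):
        lp_f, lp_m = -np.log(n_fmax), -np.log(n_mmax)
        lu_f = np.log(max(1.0 - n_f / n_fmax, 0.0))
        lu_m = np.log(max(1.0 - n_m / n_mmax, 0.0))
    out = []
    for o in range(len(offspring)):
        nums = np.concatenate([
            ll_f[:, o] + lp_f + lu_m,
            ll_m[:, o] + lp_m + lu_f,
            [ll_u[o] + lu_f + lu_m],
        ])
        out.append(np.exp(nums - logsumexp(nums)))
    return out


# -------------------------------------------------------------- exclusion


def exclusion_probabilities(panel: LocusPanel) -> pd.DataFrame:
    """Per-locus and combined exclusion probabilities.

    ``q1``: probability a random unrelated adult is excluded as the sole
    parent of a random offspring; ``q2``: excluded as the second parent
    given the true first parent is known. The combined row uses
    ``1 - prod(1 - q)``.
    """
    rows = []
    for loc in panel.loci:
        hwe, po, trio = _locus_tables(loc)
        excl1 = (po == 0.0)  # (gc, go)
        q1 = float(hwe @ excl1 @ hwe)
        # A[gd, go]: offspring distribution given dam, sire from HWE
        a = np.einsum("s,dsg->dg", hwe, trio)
        # E[gd, go]: P(random candidate incompatible as the second parent)
        e = np.einsum("c,dcg->dg", hwe, (trio == 0.0).astype(float))
        q2 = float(np.einsum("d,dg,dg->", hwe, a, e))
        rows.append({"locus_id": loc.locus_id, "q1": q1, "q2": q2})
    df = pd.DataFrame(rows)
    combined = {
        "locus_id": "combined",
        "q1": 1.0 - np.prod(1.0 - df["q1"].to_numpy()),
        "q2": 1.0 - np.prod(1.0 - df["q2"].to_numpy()),
    }
    return pd.concat([df, pd.DataFrame([combined])], ignore_index=True)


# --------------------------------------------- relationship discrimination


def _sample_conditional(
    rng: np.random.Generator, rows: np.ndarray
) -> np.ndarray:
    """Categorical draw per row of a (n, S) probability matrix."""
    cum = np.cumsum(rows, axis=1)
    u = rng.random(len(rows))
    return (cum < u[:, None]).sum(axis=1)


def relationship_discrimination_sim(
    panel: LocusPanel,
    eps: float = 0.0054,
    n_sim: int = 10_000,
    seed: int = 0,
    fpr_target: float = 1e-4,
) -> RelationshipPowerReport:
    """Monte-Carlo power of the panel to separate parent-offspring pairs
    from unrelated, full-sibling and half-sibling pairs.

    Pairs are simulated under each relationship (with genotyping error),
    scored with the parent-offspring vs unrelated log-likelihood ratio,
    and rates are reported at the threshold achieving an empirical false-
    positive rate <= ``fpr_target`` on the unrelated distribution.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    tables = LikelihoodTables(panel, eps)
    lam = {rel: np.zeros(n_sim) for rel in ("U", "PO", "FS", "HS")}
    for l in range(panel.n_loci):
        hwe, po, trio = tables.hwe[l], tables.po[l], tables.trio[l]
        S = len(hwe)
        cum_h = np.cumsum(hwe)

        def hdraw(n):
            return np.searchsorted(cum_h, rng.random(n))

        pairs = {}
        g1 = hdraw(n_sim)
        pairs["U"] = (g1, hdraw(n_sim))
        g1 = hdraw(n_sim)
        pairs["PO"] = (g1, _sample_conditional(rng, po[g1]))
        gd, gs = hdraw(n_sim), hdraw(n_sim)
        pairs["FS"] = (
            _sample_conditional(rng, trio[gd, gs]),
            _sample_conditional(rng, trio[gd, gs]),
        )
        gp, gm1, gm2 = hdraw(n_sim), hdraw(n_sim), hdraw(n_sim)
        pairs["HS"] = (
            _sample_conditional(rng, trio[gp, gm1]),
            _sample_conditional(rng, trio[gp, gm2]),
        )
        po_eps = (1.0 - eps) * po + eps * hwe[None, :] if eps > 0 else po
        with np.errstate(divide="ignore"):
            log_po, log_h = np.log(po_eps), np.log(hwe)
        for rel, (a, b) in pairs.items():
            if eps > 0:
                err = rng.random(n_sim) < eps
                a = np.where(err, hdraw(n_sim), a)
                err = rng.random(n_sim) < eps
                b = np.where(err, hdraw(n_sim), b)
            lam[rel] += log_po[a, b] - log_h[b]
    allowed = int(np.floor(fpr_target * n_sim))
    u_sorted = np.sort(lam["U"])[::-1]
    threshold = float(u_sorted[allowed])
    fnr_po = float(np.mean(lam["PO"] <= threshold))
    rows = [
        {"comparison": "PO_vs_U", "fpr": float(np.mean(lam["U"] > threshold)),
         "fnr": fnr_po},
        {"comparison": "PO_vs_FS", "fpr": float(np.mean(lam["FS"] > threshold)),
         "fnr": fnr_po},
        {"comparison": "PO_vs_HS", "fpr": float(np.mean(lam["HS"] > threshold)),
         "fnr": fnr_po},
    ]
    return RelationshipPowerReport(pd.DataFrame(rows), threshold, n_sim)
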