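"""Population differentiation: WC84 Fst, Nei (1978) Ds, AMOVA, Mantel test.

Fst uses Weir & Cockerham's (1984) variance-component estimator theta,
combined across loci as a ratio of sums, with significance by permuting
individuals between populations.  AMOVA partitions allele-level variance
into among-population, among-individual-within-population and
within-individual strata (codominant, diploid).  The Mantel test correlates
genetic and geographic distance matrices for isolation-by-distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "wc_fst_components",
    "multilocus_theta",
    "pairwise_wc_fst",
    "pairwise_matrices",
    "nei_ds",
    "amova_three_level",
    "AMOVAResult",
    "mantel_test",
    "great_circle_matrix",
]

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _group_stats(calls: np.ndarray, groups: list[np.ndarray]):
    """Per-locus (n_i, p_i, h_i) stacked over groups; NaN where untyped."""
    ns, ps, hs = [], [], []
    for idx in groups:
        sub = calls[idx]
        typed = sub != MISSING
        n = typed.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(typed, sub, 0).sum(axis=0) / (2 * n), np.nan)
            h = np.where(n > 0, (sub == 1).sum(axis=0) / n, np.nan)
        ns.append(n), ps.append(p), hs.append(h)
    return np.vstack(ns), np.vstack(ps), np.vstack(hs)


def wc_fst_components(calls: np.ndarray, groups: list[np.ndarray]):
    """Per-locus WC84 variance components (a, b, c) for r groups.

    a: among populations; b: among individuals within populations;
    c: within individuals.  Loci with fewer than two groups typed or with
    degenerate sample sizes yield NaN components.
    """
    ns, ps, hs = _group_stats(calls, groups)
    valid = ns > 0
    r_eff = valid.sum(axis=0).astype(float)
    n_tot = np.where(valid, ns, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_tot / r_eff
        sum_n2 = np.where(valid, ns**2, 0).sum(axis=0)
        nc = (n_tot - sum_n2 / n_tot) / (r_eff - 1)
        pbar = np.where(valid, ns * np.nan_to_num(ps), 0).sum(axis=0) / n_tot
        s2 = np.where(valid, ns * (np.nan_to_num(ps) - pbar) ** 2, 0).sum(axis=0) / ((r_eff - 1) * nbar)
        hbar = np.where(valid, ns * np.nan_to_num(hs), 0).sum(axis=0) / n_tot
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r_eff - 1) / r_eff) * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r_eff - 1) / r_eff) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
    bad = (r_eff < 2) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def multilocus_theta(calls: np.ndarray, groups: list[np.ndarray]) -> float:
    """Ratio-of-sums theta = sum(a) / sum(a + b + c) across loci."""
    a, b, c = wc_fst_components(calls, groups)
    denom = np.nansum(a + b + c)
    if not denom > 0:
        raise ValueError("total variance is zero at every locus; theta undefined")
    return float(np.nansum(a) / denom)


def pairwise_wc_fst(
    matrix: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-population multilocus theta and its permutation p-value.

    Individuals are shuffled between the two groups (sizes fixed); p is the
    +1-smoothed fraction of permutations with theta at least the observed.
    """
    pops = matrix.pop_indices()
    ia, ib = pops[pop_a], pops[pop_b]
    if ia.size < 2 or ib.size < 2:
        raise ValueError("both populations need at least two individuals")
    both = np.concatenate([ia, ib])
    calls = matrix.calls[both]
    na = ia.size
    theta = multilocus_theta(calls, [np.arange(na), np.arange(na, both.size)])
    if n_perm <= 0:
        return theta, np.nan
    rng = np.random.default_rng(seed)
    hits = 0
    order = np.arange(both.size)
    for _ in range(n_perm):
        rng.shuffle(order)
        try:
            tp = multilocus_theta(calls, [order[:na], order[na:]])
        except ValueError:
            continue
        if tp >= theta:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return theta, p


# ---------------------------------------------------------------------------
# Nei (1978) unbiased standard genetic distance
# ---------------------------------------------------------------------------

def nei_ds(matrix: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Nei's (1978) Ds from unbiased gene identities averaged across loci.

    Per locus Jx_hat = (2n (p^2 + q^2) - 1)/(2n - 1), Jxy = p_x p_y +
    q_x q_y; identities are averaged across loci first, then
    Ds = -ln(Jxy_bar / sqrt(Jx_bar * Jy_bar)).  Fixed opposite alleles give
    +inf; negative underflow is clipped to 0.
    """
    import warnings

    stats = {}
    for pop in (pop_a, pop_b):
        idx = matrix.pop_indices()[pop]
        sub = matrix.calls[idx]
        typed = sub != MISSING
        n = typed.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(typed, sub, 0).sum(axis=0) / (2 * n), np.nan)
        stats[pop] = (n, p)
    na, pa = stats[pop_a]
    nb, pb = stats[pop_b]
    shared = (na > 0) & (nb > 0)
    if not shared.any():
        raise ValueError("populations share no typed loci")
    with np.errstate(invalid="ignore", divide="ignore"):
        jx = (2 * na * (pa**2 + (1 - pa) ** 2) - 1) / (2 * na - 1)
        jy = (2 * nb * (pb**2 + (1 - pb) ** 2) - 1) / (2 * nb - 1)
    jxy = pa * pb + (1 - pa) * (1 - pb)
    use = shared & (jx > 0) & (jy > 0)
    if (shared & ~use).any():
        warnings.warn(
            f"{int((shared & ~use).sum())} loci skipped in Nei Ds (non-positive identity)",
            UserWarning,
            stacklevel=2,
        )
    jx_bar, jy_bar, jxy_bar = (float(np.nanmean(v[use])) for v in (jx, jy, jxy))
    if jxy_bar <= 0:
        return np.inf
    ds = -np.log(jxy_bar / np.sqrt(jx_bar * jy_bar))
    return max(0.0, float(ds))


def pairwise_matrices(
    matrix: GenotypeMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """All pairwise theta (+ permutation p) and Nei Ds matrices."""
    pops = matrix.pop_labels
    k = len(pops)
    fst = np.zeros((k, k))
    pmat = np.zeros((k, k))
    ds = np.zeros((k, k))
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            th, p = pairwise_wc_fst(matrix, pops[i], pops[j], n_perm=n_perm,
                                    seed=int(rng.integers(2**31)))
            d = nei_ds(matrix, pops[i], pops[j])
            fst[i, j] = fst[j, i] = th
            pmat[i, j] = pmat[j, i] = p
            ds[i, j] = ds[j, i] = d
    return {
        "fst": pd.DataFrame(fst, index=pops, columns=pops),
        "fst_p": pd.DataFrame(pmat, index=pops, columns=pops),
        "ds": pd.DataFrame(ds, index=pops, columns=pops),
    }


# ---------------------------------------------------------------------------
# AMOVA (three levels, codominant diploid)
# ---------------------------------------------------------------------------

@dataclass
class AMOVAResult:
    components: dict[str, float]
    percentages: dict[str, float]
    f_statistics: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)


def _amova_components(calls: np.ndarray, groups: list[np.ndarray]) -> tuple[float, float, float]:
    """Summed-over-loci variance components (among pops, among ind, within ind).

    Allele-level sums of squares per locus with per-locus sample sizes and
    coefficients (Arlequin-style), components summed across loci.
    """
    L = calls.shape[1]
    typed = calls != MISSING
    half = np.where(typed, calls / 2.0, np.nan)  # individual allele mean
    het = np.where(typed, calls == 1, np.nan)
    # per-pop per-locus
    Ns = np.vstack([typed[g].sum(axis=0) for g in groups]).astype(float)
    Ps = np.vstack([np.nanmean(half[g], axis=0) if len(g) else np.full(L, np.nan) for g in groups])
    with np.errstate(invalid="ignore", divide="ignore"):
        Ntot = Ns.sum(axis=0)
        Ptot = np.nansum(Ns * np.nan_to_num(Ps), axis=0) / Ntot
        ss_wi = 0.5 * np.nansum(het, axis=0)  # each heterozygote contributes 2*(1/2)^2
        ss_ai = np.zeros(L)
        for gi, g in enumerate(groups):
            dev = (half[g] - Ps[gi]) ** 2
            ss_ai += 2.0 * np.nansum(dev, axis=0)
        ss_ap = np.nansum(2.0 * Ns * (np.nan_to_num(Ps) - Ptot) ** 2 * (Ns > 0), axis=0)
        r_eff = (Ns > 0).sum(axis=0).astype(float)
        df_ap = r_eff - 1
        df_ai = Ntot - r_eff
        df_wi = Ntot
        nc = (Ntot - np.where(Ns > 0, Ns**2, 0).sum(axis=0) / Ntot) / df_ap
        ms_ap = ss_ap / df_ap
        ms_ai = ss_ai / df_ai
        ms_wi = ss_wi / df_wi
        sig_wi = ms_wi
        sig_ai = (ms_ai - ms_wi) / 2.0
        sig_ap = (ms_ap - ms_ai) / (2.0 * nc)
    ok = (df_ap > 0) & (df_ai > 0) & np.isfinite(sig_ap) & np.isfinite(sig_ai) & np.isfinite(sig_wi)
    return (
        float(np.nansum(sig_ap[ok])),
        float(np.nansum(sig_ai[ok])),
        float(np.nansum(sig_wi[ok])),
    )


def amova_three_level(
    matrix: GenotypeMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> AMOVAResult:
    """Three-level AMOVA on diploid dosage data.

    Strata: among populations / among individuals within populations /
    within individuals.  Percentages are of the summed variance components;
    F-statistics are the Fst/Fis/Fit analogues.  P-values: among-population
    component by permuting individuals among populations; among-individual
    component by re-pairing alleles among individuals within populations.
    """
    groups = list(matrix.pop_indices().values())
    if len(groups) < 2:
        raise ValueError("AMOVA needs at least two populations")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every population needs at least two individuals")
    calls = matrix.calls
    sAP, sAI, sWI = _amova_components(calls, groups)
    total = sAP + sAI + sWI
    if total <= 0:
        raise ValueError("total variance is zero; AMOVA undefined")
    comp = {"among_populations": sAP, "among_individuals": sAI, "within_individuals": sWI}
    pct = {k: 100.0 * v / total for k, v in comp.items()}
    fst = sAP / total
    fis = sAI / (sAI + sWI) if (sAI + sWI) > 0 else np.nan
    fit = (sAP + sAI) / total
    pvals: dict[str, float] = {}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        sizes = np.cumsum([len(g) for g in groups])[:-1]
        order = np.concatenate(groups)
        hits_ap = 0
        for _ in range(n_perm):
            perm = rng.permutation(order)
            pg = np.split(perm, sizes)
            s_ap, _, _ = _amova_components(calls, pg)
            if s_ap >= sAP:
                hits_ap += 1
        pvals["among_populations"] = (hits_ap + 1) / (n_perm + 1)
        # within-population allele shuffle for the among-individual component
        hits_ai = 0
        for _ in range(n_perm):
            shuffled = _shuffle_alleles_within_pops(calls, groups, rng)
            _, s_ai, _ = _amova_components(shuffled, groups)
            if s_ai >= sAI:
                hits_ai += 1
        pvals["among_individuals"] = (hits_ai + 1) / (n_perm + 1)
    return AMOVAResult(comp, pct, {"fst": fst, "fis": fis, "fit": fit}, pvals)


def _shuffle_alleles_within_pops(
    calls: np.ndarray, groups: list[np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    """Randomly re-pair alleles among individuals within each population."""
    out = calls.copy()
    for g in groups:
        sub = calls[g]
        for j in range(sub.shape[1]):
            col = sub[:, j]
            typed = col != MISSING
            k = int(typed.sum())
            if k < 2:
                continue
            n_snp = int(col[typed].sum())
            pool = np.zeros(2 * k, dtype=np.int16)
            pool[:n_snp] = 1
            rng.shuffle(pool)
            new = pool[:k] + pool[k:]
            tmp = col.copy()
            tmp[typed] = new
            out[g, j] = tmp
    return out


# ---------------------------------------------------------------------------
# Mantel test and geographic distances
# ---------------------------------------------------------------------------

def mantel_test(
    mat_a: pd.DataFrame | np.ndarray,
    mat_b: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the off-diagonal elements; p is the
    +1-smoothed upper-tail fraction under joint row/column permutation of
    the second matrix.
    """
    A = np.asarray(mat_a, dtype=float)
    B = np.asarray(mat_b, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and congruent")
    if not (np.allclose(A, A.T) and np.allclose(B, B.T)):
        raise ValueError("matrices must be symmetric")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    va, vb = A[iu], B[iu]
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = np.corrcoef(va, B[np.ix_(perm, perm)][iu])[0, 1]
        if r_p >= r_obs:
            hits += 1
    return r_obs, (hits + 1) / (n_perm + 1)


def great_circle_matrix(sites: pd.DataFrame) -> pd.DataFrame:
    """Haversine great-circle distance matrix (km) from a site table."""
    lat = np.radians(sites["latitude"].to_numpy(dtype=float))
    lon = np.radians(sites["longitude"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    labels = sites["population"].tolist()
    return pd.DataFrame(d, index=labels, columns=labels)
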