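"""Maximum-likelihood pairwise kinship classification.

Every within-population pair is scored under four relationship models
defined by their k-coefficients (probabilities of sharing 0/1/2 alleles
identical by descent): Unrelated (1,0,0), Half-sib (0.5,0.5,0), Full-sib
(0.25,0.5,0.25), Parent-Offspring (0,1,0).  Per locus,

    P(g1, g2 | model) = k0 P(g1) P(g2) + k1 P1(g1, g2) + k2 P(g1) [g1 = g2]

with HWE genotype probabilities from the pair's own population and the
standard one-IBD transition terms.  Log-likelihoods are summed over
mutually typed polymorphic loci; the best model is the argmax, with ties
broken toward the less related model.  No genotyping-error model is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = ["RELATIONSHIP_MODELS", "pair_loglik", "classify_pairs"]

# model name -> (k0, k1, k2), ordered least related first (tie-break order)
RELATIONSHIP_MODELS: dict[str, tuple[float, float, float]] = {
    "U": (1.0, 0.0, 0.0),
    "HS": (0.5, 0.5, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "PO": (0.0, 1.0, 0.0),
}


def _genotype_prob(g: np.ndarray, p: np.ndarray) -> np.ndarray:
    """HWE genotype probability for dosage g at SNP-allele frequency p."""
    q = 1.0 - p
    return np.where(g == 2, p**2, np.where(g == 1, 2 * p * q, q**2))


def _one_ibd_prob(g1: np.ndarray, g2: np.ndarray, p: np.ndarray) -> np.ndarray:
    """P(g1, g2 | exactly one allele IBD) = P(g1) T(g2 | g1).

    T: from a homozygote the shared allele is fixed, the partner's second
    allele is a population draw; from a heterozygote the shared allele is
    either with probability 1/2.
    """
    q = 1.0 - p
    t = np.zeros_like(p, dtype=float)
    # g1 == 2 (AA): g2=2 -> p, g2=1 -> q, g2=0 -> 0
    t = np.where((g1 == 2) & (g2 == 2), p, t)
    t = np.where((g1 == 2) & (g2 == 1), q, t)
    # g1 == 0 (aa): g2=0 -> q, g2=1 -> p
    t = np.where((g1 == 0) & (g2 == 0), q, t)
    t = np.where((g1 == 0) & (g2 == 1), p, t)
    # g1 == 1 (Aa): g2=2 -> p/2, g2=1 -> 1/2, g2=0 -> q/2
    t = np.where((g1 == 1) & (g2 == 2), p / 2, t)
    t = np.where((g1 == 1) & (g2 == 1), 0.5, t)
    t = np.where((g1 == 1) & (g2 == 0), q / 2, t)
    return _genotype_prob(g1, p) * t


def pair_loglik(
    g1: np.ndarray,
    g2: np.ndarray,
    freqs: np.ndarray,
    model: str | tuple[float, float, float],
) -> float:
    """Log-likelihood of a genotype pair under a relationship model.

    ``freqs`` are SNP-allele frequencies from the pair's population.
    Monomorphic and mutually missing loci are skipped; a structurally
    impossible configuration (e.g. opposite homozygotes under PO) gives
    -inf.  Raises if no locus is mutually typed.
    """
    k0, k1, k2 = RELATIONSHIP_MODELS[model] if isinstance(model, str) else model
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    p = np.asarray(freqs, dtype=float)
    use = (g1 != MISSING) & (g2 != MISSING) & (p > 0) & (p < 1)
    if not use.any():
        raise ValueError("no mutually typed polymorphic loci for this pair")
    g1, g2, p = g1[use], g2[use], p[use]
    lik = (
        k0 * _genotype_prob(g1, p) * _genotype_prob(g2, p)
        + k1 * _one_ibd_prob(g1, g2, p)
        + k2 * _genotype_prob(g1, p) * (g1 == g2)
    )
    if (lik <= 0).any():
        return -np.inf
    return float(np.log(lik).sum())


@dataclass
class PairClassification:
    table: pd.DataFrame
    counts: dict[str, int]

    def summary(self) -> pd.DataFrame:
        """Counts and mean +- SD log-likelihood of the best model per category."""
        rows = []
        for m in RELATIONSHIP_MODELS:
            sub = self.table[self.table["best"] == m]
            ll = sub[f"ll_{m}"].replace(-np.inf, np.nan)
            rows.append({
                "relationship": m,
                "count": len(sub),
                "ll_mean": float(ll.mean()) if len(sub) else np.nan,
                "ll_sd": float(ll.std()) if len(sub) > 1 else np.nan,
            })
        return pd.DataFrame(rows).set_index("relationship")


def classify_pairs(matrix: GenotypeMatrix, population: str) -> PairClassification:
    """Score every within-population pair under U/HS/FS/PO and pick the best.

    Allele frequencies are estimated from the focal population including
    the pair itself.  Ties go to the less related model (U > HS > FS > PO).
    """
    sub = matrix.for_population(population)
    if sub.n_individuals < 2:
        raise ValueError("population needs at least two individuals")
    calls = sub.calls
    typed = calls != MISSING
    n = typed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(typed, calls, 0).sum(axis=0) / (2.0 * n), 0.0)
    rows = []
    counts = {m: 0 for m in RELATIONSHIP_MODELS}
    ids = sub.individual_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            lls = {m: pair_loglik(calls[i], calls[j], p, m) for m in RELATIONSHIP_MODELS}
            best, best_ll = None, -np.inf
            for m, ll in lls.items():  # insertion order = least related first
                if ll > best_ll:
                    best, best_ll = m, ll
            counts[best] += 1
            n_loci = int(((calls[i] != MISSING) & (calls[j] != MISSING)).sum())
            rows.append({
                "id1": ids[i], "id2": ids[j], "best": best, "loci_used": n_loci,
                **{f"ll_{m}": ll for m, ll in lls.items()},
            })
    return PairClassification(pd.DataFrame(rows), counts)
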