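"""Post-calling SNP filter cascade and Hardy-Weinberg screening.

The cascade mirrors standard DArTseq panel curation: collapse clone
duplicates to one SNP per genomic locus (best call rate, ties by PIC), then
filter on call rate, read depth, PIC, per-population MAF and repeatability,
and finally screen the surviving loci for Hardy-Weinberg departures with an
exact test.

For biallelic loci the Guo-Thompson MCMC exact test reduces to full
enumeration of the Levene distribution over heterozygote counts conditional
on the allele counts; enumeration is used here for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import lgamma, log

import numpy as np
from scipy.stats import false_discovery_control

from .genotype_io import MISSING, GenotypeMatrix, LocusMetadata

__all__ = [
    "FilterThresholds",
    "FilterReport",
    "compute_pic",
    "pooled_allele_frequencies",
    "deduplicate_clone_snps",
    "apply_quality_filters",
    "hwe_exact_test",
    "hwe_het_probabilities",
    "hwe_screen",
]


@dataclass
class FilterThresholds:
    """Thresholds of the quality-filter cascade (fractions in [0, 1]).

    ``min_mean_depth`` is exclusive (a locus must exceed it); the others are
    inclusive floors.  ``maf_mode`` selects whether a locus survives the MAF
    stage when it is common in at least one population (``"any"``, default)
    or must be common in every population (``"all"``).
    """

    min_call_rate: float = 0.95
    min_mean_depth: float = 8.0
    min_avg_pic: float = 0.01
    min_pop_maf: float = 0.02
    min_repeatability: float = 0.95
    hwe_alpha: float = 0.05
    hwe_correction: str = "fdr"  # "fdr" (Benjamini-Hochberg) or "none"
    maf_mode: str = "any"

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_avg_pic", "min_pop_maf",
                     "min_repeatability", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.maf_mode not in ("any", "all"):
            raise ValueError("maf_mode must be 'any' or 'all'")
        if self.hwe_correction not in ("fdr", "none"):
            raise ValueError("hwe_correction must be 'fdr' or 'none'")


@dataclass
class FilterReport:
    """Ordered per-stage accounting: (stage, loci in, loci out, removed)."""

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int) -> None:
        if self.stages and self.stages[-1][2] != n_in:
            raise ValueError("stage input does not telescope from previous output")
        self.stages.append((stage, n_in, n_out, n_in - n_out))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.stages, columns=["stage", "loci_in", "loci_out", "removed"])


def compute_pic(p: float | np.ndarray) -> float | np.ndarray:
    """Biallelic polymorphic information content, 1 - (p^2 + q^2) - 2 p^2 q^2.

    Symmetric in p <-> q with maximum 0.375 at p = 0.5.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    q = 1.0 - p
    out = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2
    return float(out) if out.ndim == 0 else out


def pooled_allele_frequencies(matrix: GenotypeMatrix) -> np.ndarray:
    """Global SNP-allele frequency per locus over all typed individuals (NaN if untyped)."""
    typed = matrix.typed_mask()
    dose = np.where(typed, matrix.calls, 0)
    n = typed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, dose.sum(axis=0) / (2.0 * n), np.nan)


def deduplicate_clone_snps(
    matrix: GenotypeMatrix, metadata: LocusMetadata
) -> tuple[GenotypeMatrix, tuple[str, int, int, int]]:
    """Keep one SNP per clone (genomic locus): highest call rate, then
    highest PIC on pooled frequencies, then lexicographically first locus ID.
    """
    meta = metadata.for_loci(matrix.loci)
    pic = compute_pic(np.nan_to_num(pooled_allele_frequencies(matrix)))
    call = meta["call_rate"].to_numpy(dtype=float)
    clones = meta["clone_id"].to_numpy()
    best: dict[object, tuple] = {}
    for j, locus in enumerate(matrix.loci):
        key = (-call[j], -pic[j], locus)
        c = clones[j]
        if c not in best or key < best[c][0]:
            best[c] = (key, j)
    keep = sorted(j for _, j in best.values())
    out = matrix.subset_loci(np.asarray(keep))
    entry = ("clone_dedup", matrix.n_loci, out.n_loci, matrix.n_loci - out.n_loci)
    return out, entry


def _population_maf(matrix: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency per (population, locus); NaN where untyped."""
    rows = []
    for idx in matrix.pop_indices().values():
        sub = matrix.calls[idx]
        typed = sub != MISSING
        n = typed.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(typed, sub, 0).sum(axis=0) / (2.0 * n), np.nan)
        rows.append(np.minimum(p, 1.0 - p))
    return np.vstack(rows)


def apply_quality_filters(
    matrix: GenotypeMatrix,
    metadata: LocusMetadata,
    thresholds: FilterThresholds = FilterThresholds(),
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the cascade: call rate -> depth -> PIC -> per-pop MAF -> repeatability."""
    report = report if report is not None else FilterReport()
    cur = matrix

    def stage(name: str, keep: np.ndarray) -> None:
        nonlocal cur
        n_in = cur.n_loci
        cur = cur.subset_loci(keep)
        report.add(name, n_in, cur.n_loci)

    meta = metadata.for_loci(cur.loci)
    stage("call_rate", meta["call_rate"].to_numpy(dtype=float) >= thresholds.min_call_rate)

    meta = metadata.for_loci(cur.loci)
    stage("read_depth", meta["mean_read_depth"].to_numpy(dtype=float) > thresholds.min_mean_depth)

    pic = compute_pic(np.nan_to_num(pooled_allele_frequencies(cur)))
    stage("pic", pic >= thresholds.min_avg_pic)

    maf = _population_maf(cur)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        if thresholds.maf_mode == "any":
            keep = np.nanmax(maf, axis=0) >= thresholds.min_pop_maf
        else:
            keep = np.nanmin(maf, axis=0) >= thresholds.min_pop_maf
    stage("pop_maf", np.nan_to_num(keep))

    meta = metadata.for_loci(cur.loci)
    stage("repeatability", meta["repeatability"].to_numpy(dtype=float) >= thresholds.min_repeatability)

    if cur.n_loci == 0:
        warnings.warn("filter cascade removed every locus", UserWarning, stacklevel=2)
    return cur, report


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Levene/Haldane enumeration)
# ---------------------------------------------------------------------------

def hwe_het_probabilities(n_a: int, n: int) -> dict[int, float]:
    """Levene distribution of the heterozygote count given allele counts.

    ``n`` diploids carry ``n_a`` copies of one allele (and ``2n - n_a`` of
    the other).  Returns P(heterozygotes = h) for every admissible h; the
    probabilities sum to 1.
    """
    if n_a < 0 or n < 0 or n_a > 2 * n:
        raise ValueError("inadmissible allele/genotype counts")
    n_b = 2 * n - n_a
    # log constant: n! * n_a! * n_b! / (2n)!
    logc = lgamma(n + 1) + lgamma(n_a + 1) + lgamma(n_b + 1) - lgamma(2 * n + 1)
    probs: dict[int, float] = {}
    hmin = n_a % 2
    for h in range(hmin, min(n_a, n_b) + 1, 2):
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        if naa < 0 or nbb < 0 or naa + nbb + h != n:
            continue
        lp = logc + h * log(2.0) - lgamma(naa + 1) - lgamma(h + 1) - lgamma(nbb + 1)
        probs[h] = float(np.exp(lp))
    total = sum(probs.values())
    return {h: p / total for h, p in probs.items()}


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value by full enumeration.

    The p-value is the total probability, under the Levene distribution
    conditional on the observed allele counts, of all heterozygote counts no
    more probable than the observed one.  Monomorphic samples return 1.
    Raises on an all-missing locus (no genotypes at all).
    """
    for c in (n_aa, n_ab, n_bb):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotyped individuals: HWE test undefined")
    n_a = 2 * n_aa + n_ab
    probs = hwe_het_probabilities(n_a, n)
    p_obs = probs[n_ab]
    tol = 1e-12
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + tol)))


def hwe_screen(
    matrix: GenotypeMatrix,
    alpha: float = 0.05,
    correction: str = "fdr",
):
    """Exact HWE test per locus per population, corrected across loci within
    each population.  Returns (p-value DataFrame, list of deviating loci).
    """
    import pandas as pd

    pvals = {}
    flagged: set[str] = set()
    for pop, idx in matrix.pop_indices().items():
        sub = matrix.calls[idx]
        col = np.full(matrix.n_loci, np.nan)
        for j in range(matrix.n_loci):
            g = sub[:, j]
            g = g[g != MISSING]
            if g.size == 0:
                continue
            col[j] = hwe_exact_test(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
        ok = ~np.isnan(col)
        adj = col.copy()
        if correction == "fdr" and ok.any():
            adj[ok] = false_discovery_control(col[ok], method="bh")
        pvals[pop] = col
        flagged.update(np.asarray(matrix.loci)[ok & (adj < alpha)])
    frame = pd.DataFrame(pvals, index=matrix.loci)
    return frame, sorted(flagged)
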