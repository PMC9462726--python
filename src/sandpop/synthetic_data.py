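"""Synthetic genotype generators with the statistical structure the
analysis assumes.

Three generators cover every genetic module's testing needs without any
external data:

* :func:`simulate_island_model` — Balding-Nichols demes: per locus an
  ancestral frequency p is drawn uniformly and each deme's frequency from
  Beta(p (1-F)/F, (1-p) (1-F)/F), so the expected Wright fixation index is
  F by construction.  Deme-specific F values allow one outlier deme, the
  pattern seen in geographically isolated populations.
* :func:`simulate_family_pairs` — labelled Unrelated / Half-sib /
  Full-sib / Parent-Offspring pairs built from HWE founders by Mendelian
  transmission.
* :func:`simulate_wright_fisher` — discrete-generation random-union-of-
  gametes drift at unlinked loci, the forward oracle for the LD effective
  population size estimator.

All generators are pure functions of their seed.  The default
:func:`study_conditions_spec` freezes the sampled-population layout used
throughout tests: six demes (KA/LA/MA/RA/SA/YA) of 22/45/25/46/42/31
diploids, background F = 0.034 with LA elevated to 0.06.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "IslandModelSpec",
    "FamilySpec",
    "study_conditions_spec",
    "simulate_island_model",
    "simulate_family_pairs",
    "simulate_wright_fisher",
]


@dataclass
class IslandModelSpec:
    """Balding-Nichols island-model parameters."""

    n_pops: int = 6
    n_per_pop: tuple[int, ...] = (40, 40, 40, 40, 40, 40)
    n_loci: int = 2000
    fst: float = 0.05
    fst_per_pop: tuple[float, ...] | None = None  # overrides fst per deme
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    pop_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_pop, int):
            self.n_per_pop = (self.n_per_pop,) * self.n_pops
        if len(self.n_per_pop) != self.n_pops:
            raise ValueError("n_per_pop length must equal n_pops")
        fs = self.fst_per_pop if self.fst_per_pop is not None else (self.fst,)
        for f in fs:
            if not 0.0 < f < 1.0:
                raise ValueError("Fst must lie strictly in (0, 1)")
        lo, hi = self.ancestral_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral frequency range must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing rate must lie in [0, 1)")


def study_conditions_spec(n_loci: int = 2000, missing_rate: float = 0.02, seed: int = 0) -> IslandModelSpec:
    """The sampled-population layout of the Fijian sandfish survey.

    Six demes with the field sample sizes, shallow differentiation
    (F = 0.034) and one elevated outlier deme (LA, F = 0.06).
    """
    return IslandModelSpec(
        n_pops=6,
        n_per_pop=(22, 45, 25, 46, 42, 31),
        pop_labels=("KA", "LA", "MA", "RA", "SA", "YA"),
        n_loci=n_loci,
        fst=0.034,
        fst_per_pop=(0.034, 0.06, 0.034, 0.034, 0.034, 0.034),
        missing_rate=missing_rate,
        seed=seed,
    )


def simulate_island_model(spec: IslandModelSpec) -> GenotypeMatrix:
    """Draw a dosage matrix under the Balding-Nichols island model."""
    rng = np.random.default_rng(spec.seed)
    L = spec.n_loci
    labels = list(spec.pop_labels) if spec.pop_labels else [f"P{k + 1}" for k in range(spec.n_pops)]
    fs = list(spec.fst_per_pop) if spec.fst_per_pop is not None else [spec.fst] * spec.n_pops
    p_anc = rng.uniform(*spec.ancestral_range, size=L)
    blocks, ids, pops = [], [], []
    for k in range(spec.n_pops):
        F = fs[k]
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_deme = rng.beta(a, b)
        n = spec.n_per_pop[k]
        calls = rng.binomial(2, p_deme, size=(n, L)).astype(np.int16)
        if spec.missing_rate > 0:
            mask = rng.random((n, L)) < spec.missing_rate
            calls[mask] = MISSING
        blocks.append(calls)
        ids.extend(f"{labels[k]}_{i + 1:03d}" for i in range(n))
        pops.extend([labels[k]] * n)
    loci = [f"L{j + 1:05d}" for j in range(L)]
    return GenotypeMatrix(ids, pops, loci, np.vstack(blocks))


@dataclass
class FamilySpec:
    """Counts of labelled relationship pairs to simulate."""

    n_loci: int = 2000
    n_unrelated: int = 20
    n_half_sib: int = 10
    n_full_sib: int = 10
    n_parent_offspring: int = 10
    freq_range: tuple[float, float] = (0.1, 0.9)
    base_freqs: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("n_unrelated", "n_half_sib", "n_full_sib", "n_parent_offspring"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


def _hwe_individual(p: np.ndarray, rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """(n, L, 2) founder allele array under HWE at frequencies p."""
    return (rng.random((n, p.size, 2)) < p[None, :, None]).astype(np.int8)


def _gamete(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One allele per locus, chosen independently (unlinked loci)."""
    pick = rng.integers(0, 2, size=parent.shape[0])
    return parent[np.arange(parent.shape[0]), pick]


def simulate_family_pairs(spec: FamilySpec) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate labelled U/HS/FS/PO pairs; returns (matrix, truth table).

    Each pair is built from its own founders so pairs are unrelated to one
    another; the truth table lists (id1, id2, relationship).
    """
    rng = np.random.default_rng(spec.seed)
    p = (np.asarray(spec.base_freqs, dtype=float) if spec.base_freqs is not None
         else rng.uniform(*spec.freq_range, size=spec.n_loci))
    L = p.size
    genomes: list[np.ndarray] = []
    ids: list[str] = []
    truth = []

    def add(ind: np.ndarray, label: str) -> str:
        genomes.append(ind)
        ids.append(label)
        return label

    c = 0
    for _ in range(spec.n_unrelated):
        c += 1
        a = _hwe_individual(p, rng)[0]
        b = _hwe_individual(p, rng)[0]
        truth.append((add(a, f"U{c}a"), add(b, f"U{c}b"), "U"))
    for _ in range(spec.n_half_sib):
        c += 1
        shared = _hwe_individual(p, rng)[0]
        other1 = _hwe_individual(p, rng)[0]
        other2 = _hwe_individual(p, rng)[0]
        s1 = np.stack([_gamete(shared, rng), _gamete(other1, rng)], axis=1)
        s2 = np.stack([_gamete(shared, rng), _gamete(other2, rng)], axis=1)
        truth.append((add(s1, f"H{c}a"), add(s2, f"H{c}b"), "HS"))
    for _ in range(spec.n_full_sib):
        c += 1
        mum = _hwe_individual(p, rng)[0]
        dad = _hwe_individual(p, rng)[0]
        s1 = np.stack([_gamete(mum, rng), _gamete(dad, rng)], axis=1)
        s2 = np.stack([_gamete(mum, rng), _gamete(dad, rng)], axis=1)
        truth.append((add(s1, f"F{c}a"), add(s2, f"F{c}b"), "FS"))
    for _ in range(spec.n_parent_offspring):
        c += 1
        parent = _hwe_individual(p, rng)[0]
        mate = _hwe_individual(p, rng)[0]
        child = np.stack([_gamete(parent, rng), _gamete(mate, rng)], axis=1)
        truth.append((add(parent, f"P{c}a"), add(child, f"P{c}b"), "PO"))
    calls = np.array([g.sum(axis=1) for g in genomes], dtype=np.int16)
    loci = [f"L{j + 1:05d}" for j in range(L)]
    matrix = GenotypeMatrix(ids, ["FAM"] * len(ids), loci, calls)
    return matrix, pd.DataFrame(truth, columns=["id1", "id2", "relationship"])


def simulate_wright_fisher(
    n_diploid: int,
    n_loci: int,
    generations: int,
    sample_size: int,
    seed: int = 0,
) -> GenotypeMatrix:
    """Forward Wright-Fisher drift at unlinked loci, all starting at p = 0.5.

    Each generation every offspring draws two distinct parents uniformly and
    receives one Mendelian gamete from each, loci assorting independently.
    Returns a dosage matrix for ``sample_size`` sampled individuals.
    """
    if sample_size > n_diploid:
        raise ValueError("sample_size cannot exceed the population size")
    rng = np.random.default_rng(seed)
    pop = (rng.random((n_diploid, n_loci, 2)) < 0.5).astype(np.int8)
    for _ in range(generations):
        mothers = rng.integers(0, n_diploid, size=n_diploid)
        fathers = (mothers + 1 + rng.integers(0, n_diploid - 1, size=n_diploid)) % n_diploid
        pick_m = rng.integers(0, 2, size=(n_diploid, n_loci))
        pick_f = rng.integers(0, 2, size=(n_diploid, n_loci))
        rows = np.arange(n_loci)[None, :]
        egg = pop[mothers[:, None], rows, pick_m]
        sperm = pop[fathers[:, None], rows, pick_f]
        pop = np.stack([egg, sperm], axis=2)
    sample = rng.choice(n_diploid, size=sample_size, replace=False)
    calls = pop[sample].sum(axis=2).astype(np.int16)
    ids = [f"WF_{i + 1:03d}" for i in range(sample_size)]
    loci = [f"L{j + 1:05d}" for j in range(n_loci)]
    return GenotypeMatrix(ids, ["WF"] * sample_size, loci, calls)
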