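"""Synthetic annotated cohorts with known ground truth, plus simulator presets.

Generates polarized variant tables (optionally written as VCF) whose
per-class derived-frequency laws, per-population inbreeding levels and
burden multipliers are chosen by configuration, so every empirical-side
statistic can be tested against a constructed truth without any data
download.  Sites are independent across loci; linkage-aware data comes from
the simulator module.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

from .core import MutationModelConfig
from .popgen import AnnotatedVariantTable
from .simulate import SimulationConfig

__all__ = [
    "PopulationSpec",
    "SyntheticCohortConfig",
    "generate_cohort",
    "expected_rxy",
    "expected_rxy_prime",
    "make_sim_fixture",
    "SIM_PRESETS",
]


@dataclasses.dataclass(frozen=True)
class PopulationSpec:
    """One cohort population: sample size, inbreeding coefficient F in
    [0, 1], per-class derived-frequency burden multipliers (default 1) and
    an optional derived-call thinning factor emulating reference bias /
    branch shortening (applies to every class alike, so Rxy' cancels it)."""

    name: str
    n_individuals: int
    f_inbreeding: float = 0.0
    burden: Mapping[str, float] = dataclasses.field(default_factory=dict)
    thinning: float = 1.0

    def burden_for(self, effect_class: str) -> float:
        return float(self.burden.get(effect_class, 1.0))


def _default_sites() -> dict:
    # scaled ~30x down from a typical annotated resequencing cohort
    # (order 10^5 deleterious, 10^3 LoF sites): large enough for a
    # 100-block jackknife, small enough for seconds-scale tests
    return {"neutral": 10_000, "deleterious": 5_000, "lof": 500}


def _default_spectrum() -> dict:
    # density proportional to 1/q on [qmin, qmax], the neutral-SFS-like law
    return {
        "neutral": (0.005, 0.5),
        "deleterious": (0.005, 0.5),
        "lof": (0.005, 0.3),
    }


@dataclasses.dataclass(frozen=True)
class SyntheticCohortConfig:
    populations: tuple[PopulationSpec, ...]
    sites_per_class: Mapping[str, int] = dataclasses.field(default_factory=_default_sites)
    spectrum: Mapping[str, tuple[float, float]] = dataclasses.field(default_factory=_default_spectrum)
    n_chromosomes: int = 8
    chromosome_length: int = 10_000_000
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for p in self.populations:
            if not 0.0 <= p.f_inbreeding <= 1.0:
                raise ValueError("F must lie in [0, 1]")
            if any(b <= 0 for b in p.burden.values()):
                raise ValueError("burden multipliers must be positive")
            if not 0.0 < p.thinning <= 1.0:
                raise ValueError("thinning must lie in (0, 1]")
        if any(n < 0 for n in self.sites_per_class.values()):
            raise ValueError("site counts must be non-negative")
        total = sum(self.sites_per_class.values())
        if total > self.n_chromosomes * self.chromosome_length:
            raise ValueError("more sites requested than genome positions")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def _base_frequency(qmin: float, qmax: float, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw from the density proportional to 1/q on [qmin, qmax]."""
    return qmin * (qmax / qmin) ** u


def generate_cohort(cfg: SyntheticCohortConfig) -> AnnotatedVariantTable:
    """Generate a polarized, annotated cohort with per-sample genotypes.

    Per site, a base derived frequency q is drawn from the class's spectrum;
    each population uses q_p = min(q * burden, 1) and samples genotypes under
    the inbreeding law P(hom-derived) = q^2 + pqF, P(het) = 2pq(1-F),
    P(hom-ancestral) = p^2 + pqF.  Derived alleles are then thinned per
    population (each derived allele kept with probability ``thinning``) and
    genotypes masked at the missingness rate.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    classes = [c for c in ("neutral", "deleterious", "lof") if cfg.sites_per_class.get(c, 0) > 0]
    n_sites = sum(cfg.sites_per_class[c] for c in classes)
    # deterministic layout: sites spread over chromosomes in genomic order,
    # class labels interleaved at random
    per_chrom = np.bincount(rng.integers(0, cfg.n_chromosomes, n_sites), minlength=cfg.n_chromosomes)
    chrom_list, pos_list = [], []
    for ci, k in enumerate(per_chrom):
        pos = np.sort(rng.choice(cfg.chromosome_length, size=int(k), replace=False)) + 1
        chrom_list.append(np.full(int(k), f"chr{ci + 1}", dtype=object))
        pos_list.append(pos.astype(np.int64))
    chrom = np.concatenate(chrom_list)
    pos = np.concatenate(pos_list)
    labels = np.concatenate([np.full(cfg.sites_per_class[c], c, dtype=object) for c in classes])
    rng.shuffle(labels)

    q_base = np.empty(n_sites)
    for c in classes:
        m = labels == c
        qmin, qmax = cfg.spectrum[c]
        q_base[m] = _base_frequency(qmin, qmax, rng.random(int(m.sum())))

    samples, sample_pop, geno_cols = [], [], []
    for spec in cfg.populations:
        q = np.minimum(q_base * np.array([spec.burden_for(c) for c in labels]), 1.0)
        p = 1.0 - q
        F = spec.f_inbreeding
        p_hom = q * q + p * q * F
        p_het = 2.0 * p * q * (1.0 - F)
        u = rng.random((n_sites, spec.n_individuals))
        g = np.zeros((n_sites, spec.n_individuals), np.int8)
        g[u < (p_hom + p_het)[:, None]] = 1
        g[u < p_hom[:, None]] = 2
        if spec.thinning < 1.0:
            kept = rng.binomial(g.astype(np.int64), spec.thinning).astype(np.int8)
            g = kept
        if cfg.missing_rate > 0.0:
            g[rng.random(g.shape) < cfg.missing_rate] = -1
        geno_cols.append(g)
        samples.extend(f"{spec.name}_{i:03d}" for i in range(spec.n_individuals))
        sample_pop.extend([spec.name] * spec.n_individuals)

    genotypes = np.concatenate(geno_cols, axis=1)
    return AnnotatedVariantTable.from_genotypes(chrom, pos, labels, genotypes, samples, np.array(sample_pop, dtype=object))


def _spec_by_name(cfg: SyntheticCohortConfig, name: str) -> PopulationSpec:
    for p in cfg.populations:
        if p.name == name:
            return p
    raise KeyError(f"population {name!r} not in config")


def expected_rxy(cfg: SyntheticCohortConfig, popX: str, popY: str, category: str, n_mc: int = 1_000_000) -> float:
    """Ground-truth burden ratio implied by the configured frequency laws:
    E[L_{X not Y}] / E[L_{Y not X}] by Monte-Carlo over the per-site law
    (burden multipliers, clamping and thinning included)."""
    cfg.validate()
    sx, sy = _spec_by_name(cfg, popX), _spec_by_name(cfg, popY)
    qmin, qmax = cfg.spectrum[category]
    rng = np.random.default_rng(cfg.seed + 986_533)
    q = _base_frequency(qmin, qmax, rng.random(n_mc))
    qx = np.minimum(q * sx.burden_for(category), 1.0) * sx.thinning
    qy = np.minimum(q * sy.burden_for(category), 1.0) * sy.thinning
    return float(np.sum(qx * (1.0 - qy)) / np.sum(qy * (1.0 - qx)))


def expected_rxy_prime(cfg: SyntheticCohortConfig, popX: str, popY: str, category: str, n_mc: int = 1_000_000) -> float:
    """Ground-truth Rxy' = expected_rxy(category) / expected_rxy(neutral)."""
    return expected_rxy(cfg, popX, popY, category, n_mc) / expected_rxy(cfg, popX, popY, "neutral", n_mc)


# ---------------------------------------------------------------------------
# simulator presets

SIM_PRESETS = ("desk", "neutral-only", "full-scale")


def make_sim_fixture(preset_name: str, sigma: float = 0.0, seed: int = 0, replicate_id: int = 0) -> SimulationConfig:
    """Frozen simulator presets.

    ``full-scale``: the full study conditions (50 demes, K_core 5000,
    K 200, G 1e7, burn-in 4*K_core, shift at deme 25).  ``desk``: the scaled
    preset used by the test suite (10 demes, K_core 500, K 100, G 1e6,
    shift at deme 5, all per-bp rates unchanged).  ``neutral-only``: a small
    single-class configuration for neutral-equilibrium oracles (K_core 200,
    G 1e6, burn-in 8*K_core, every mutation neutral).
    """
    if preset_name == "full-scale":
        return SimulationConfig(sigma=sigma, seed=seed, replicate_id=replicate_id)
    if preset_name == "desk":
        return SimulationConfig(
            n_demes=10,
            K_core=500,
            K_deme=100,
            shift_deme=5,
            sigma=sigma,
            mutation_model=MutationModelConfig(G=1_000_000),
            seed=seed,
            replicate_id=replicate_id,
        )
    if preset_name == "neutral-only":
        return SimulationConfig(
            n_demes=1,
            K_core=200,
            K_deme=200,
            shift_deme=1,
            sigma=sigma,
            burn_in_generations=8 * 200,
            mutation_model=MutationModelConfig(G=1_000_000, class_proportions=(1.0, 0.0, 0.0, 0.0)),
            seed=seed,
            replicate_id=replicate_id,
        )
    raise KeyError(f"unknown preset {preset_name!r}; choose from {SIM_PRESETS}")
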