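"""Load and purging statistics on polarized, effect-annotated variant tables.

Operates on cohorts of populations genotyped at sites classified as
``neutral`` (synonymous-like), ``deleterious`` (missense/nonsense-like) or
``lof`` (loss-of-function), with the derived allele identified by an
ancestral-state annotation.  Implements the derived-allele burden ratio
Rxy and its neutral-normalized form Rxy', the contiguous-block jackknife,
per-individual additive/recessive load counts, per-class fixation
proportions and windowed nucleotide diversity with invariant sites in the
denominator.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "EFFECT_CLASSES",
    "AnnotatedVariantTable",
    "RxyResult",
    "rxy_raw",
    "rxy_prime",
    "block_jackknife",
    "empirical_load_counts",
    "fixation_proportion_by_class",
    "windowed_pi",
]

EFFECT_CLASSES = ("neutral", "deleterious", "lof")


@dataclasses.dataclass
class AnnotatedVariantTable:
    """Polarized per-site records with effect class and per-population
    genotype counts.

    ``derived``, ``called``, ``hom`` and ``het`` are (n_sites, n_pops)
    arrays of derived-allele counts, called genotypes, homozygous-derived
    genotypes and heterozygous genotypes.  ``genotypes`` (optional) is an
    (n_sites, n_samples) matrix of derived-allele dosages 0/1/2 with -1 for
    missing, needed only for the per-individual load counts.
    Sites are stored in genomic order (chromosomes in input order, then
    position); only polarized sites are admitted.
    """

    chrom: np.ndarray
    pos: np.ndarray
    effect_class: np.ndarray
    populations: list[str]
    derived: np.ndarray
    called: np.ndarray
    hom: np.ndarray
    het: np.ndarray
    genotypes: Optional[np.ndarray] = None
    samples: Optional[list[str]] = None
    sample_pop: Optional[np.ndarray] = None

    @property
    def n_sites(self) -> int:
        return self.pos.size

    def validate(self) -> None:
        if not np.all(self.derived == 2 * self.hom + self.het):
            raise ValueError("derived counts must equal 2*hom + het")
        if np.any(self.derived > 2 * self.called):
            raise ValueError("derived count cannot exceed 2 * called genotypes")
        bad = set(np.unique(self.effect_class)) - set(EFFECT_CLASSES)
        if bad:
            raise ValueError(f"unknown effect classes: {sorted(bad)}")

    def pop_index(self, name: str) -> int:
        try:
            return self.populations.index(name)
        except ValueError:
            raise KeyError(f"population {name!r} not in table") from None

    def class_mask(self, effect_class: str) -> np.ndarray:
        if effect_class not in EFFECT_CLASSES:
            raise ValueError(f"effect_class must be one of {EFFECT_CLASSES}")
        return self.effect_class == effect_class

    @classmethod
    def from_genotypes(cls, chrom, pos, effect_class, genotypes, samples, sample_pop):
        """Build a table (with per-population counts) from a dosage matrix."""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        effect_class = np.asarray(effect_class, dtype=object)
        genotypes = np.asarray(genotypes, dtype=np.int8)
        sample_pop = np.asarray(sample_pop, dtype=object)
        pops = list(dict.fromkeys(sample_pop))  # first-appearance order
        n_sites = pos.size
        derived = np.zeros((n_sites, len(pops)), np.int64)
        called = np.zeros_like(derived)
        hom = np.zeros_like(derived)
        het = np.zeros_like(derived)
        for j, p in enumerate(pops):
            g = genotypes[:, sample_pop == p]
            ok = g >= 0
            called[:, j] = ok.sum(axis=1)
            hom[:, j] = (g == 2).sum(axis=1)
            het[:, j] = (g == 1).sum(axis=1)
            derived[:, j] = 2 * hom[:, j] + het[:, j]
        t = cls(
            chrom=chrom,
            pos=pos,
            effect_class=effect_class,
            populations=pops,
            derived=derived,
            called=called,
            hom=hom,
            het=het,
            genotypes=genotypes,
            samples=list(samples),
            sample_pop=sample_pop,
        )
        t.validate()
        return t


@dataclasses.dataclass
class RxyResult:
    """Rxy' of one population pair and site category, with a contiguous
    block-jackknife confidence interval (normal approximation)."""

    R_raw: float
    R_prime: float
    ci_low: float
    ci_high: float
    n_blocks: int
    popX: str
    popY: str
    category: str


def _frequencies(table: AnnotatedVariantTable, ix: int, iy: int, mask: np.ndarray):
    """Per-site derived frequencies of two populations at masked sites,
    dropping sites without called genotypes in either population."""
    ok = mask & (table.called[:, ix] > 0) & (table.called[:, iy] > 0)
    dx = table.derived[ok, ix] / (2.0 * table.called[ok, ix])
    dy = table.derived[ok, iy] / (2.0 * table.called[ok, iy])
    return dx, dy, ok


def rxy_raw(table: AnnotatedVariantTable, popX: str, popY: str, category: str, site_mask=None) -> float:
    """Derived-allele burden ratio L_{X not Y} / L_{Y not X} over the sites
    of one category, with L_{X not Y} = sum_i dX_i (1 - dY_i) on per-site
    derived frequencies.  NaN when the denominator is zero."""
    ix, iy = table.pop_index(popX), table.pop_index(popY)
    mask = table.class_mask(category)
    if site_mask is not None:
        mask = mask & site_mask
    dx, dy, _ = _frequencies(table, ix, iy, mask)
    lxy = float(np.sum(dx * (1.0 - dy)))
    lyx = float(np.sum(dy * (1.0 - dx)))
    if lyx == 0.0:
        return float("nan")
    return lxy / lyx


def block_jackknife(site_table, statistic: Callable, n_blocks: int = 100):
    """Delete-one contiguous-block jackknife.

    ``site_table`` is either an integer site count or any object with
    ``len``; ``statistic`` maps a boolean keep-mask over sites to a float.
    Blocks are contiguous with near-equal site counts.  Pseudovalues are
    theta_j = n*theta_hat - (n-1)*theta_hat(-j); the CI is
    mean +/- 1.96 * SD/sqrt(n).  Degenerate (NaN) pseudovalues are dropped
    with a warning.  Returns (estimate, ci_low, ci_high).
    """
    n_sites = site_table if isinstance(site_table, (int, np.integer)) else len(site_table)
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if n_blocks > n_sites:
        warnings.warn(f"fewer sites ({n_sites}) than blocks; reducing n_blocks", stacklevel=2)
        n_blocks = n_sites
    full = np.ones(n_sites, dtype=bool)
    theta_hat = float(statistic(full))
    bounds = np.linspace(0, n_sites, n_blocks + 1).astype(int)
    pseudo = np.empty(n_blocks)
    for j in range(n_blocks):
        keep = full.copy()
        keep[bounds[j] : bounds[j + 1]] = False
        pseudo[j] = n_blocks * theta_hat - (n_blocks - 1) * float(statistic(keep))
    ok = np.isfinite(pseudo)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} degenerate jackknife pseudovalues", stacklevel=2)
        pseudo = pseudo[ok]
    nb = pseudo.size
    if nb == 0:
        return float("nan"), float("nan"), float("nan")
    est = float(pseudo.mean())
    se = float(pseudo.std(ddof=1) / np.sqrt(nb)) if nb > 1 else 0.0
    return est, est - 1.96 * se, est + 1.96 * se


def rxy_prime(
    table: AnnotatedVariantTable,
    popX: str,
    popY: str,
    category: str,
    n_blocks: int = 100,
) -> RxyResult:
    """Neutral-normalized burden ratio Rxy' = Rxy(category) / Rxy(neutral),
    cancelling reference/branch-shortening bias shared by the two classes.

    The jackknife leaves out contiguous genomic blocks of the combined
    (category + neutral) site list, ordered by chromosome and position, and
    recomputes the whole ratio on each retained subset.  Rxy' > 1 means
    population X carries an excess of derived alleles in the category
    relative to neutral sites.
    """
    if category == "neutral":
        raise ValueError("category must differ from the neutral normalizer")
    relevant = table.class_mask(category) | table.class_mask("neutral")
    rel_idx = np.flatnonzero(relevant)
    if rel_idx.size == 0:
        raise ValueError("no sites in the requested category or the neutral class")

    def stat(keep_rel: np.ndarray) -> float:
        site_mask = np.zeros(table.n_sites, dtype=bool)
        site_mask[rel_idx[keep_rel]] = True
        num = rxy_raw(table, popX, popY, category, site_mask=site_mask)
        den = rxy_raw(table, popX, popY, "neutral", site_mask=site_mask)
        if not np.isfinite(num) or not np.isfinite(den) or den == 0.0:
            return float("nan")
        return num / den

    r_raw = rxy_raw(table, popX, popY, category)
    est, lo, hi = block_jackknife(int(rel_idx.size), stat, n_blocks=n_blocks)
    r_prime = stat(np.ones(rel_idx.size, dtype=bool))
    return RxyResult(
        R_raw=r_raw,
        R_prime=r_prime,
        ci_low=lo,
        ci_high=hi,
        n_blocks=min(n_blocks, int(rel_idx.size)),
        popX=popX,
        popY=popY,
        category=category,
    )


def empirical_load_counts(table: AnnotatedVariantTable, population: str) -> pd.DataFrame:
    """Per-individual load counts over deleterious-class sites: additive =
    derived alleles (het + 2*hom), recessive = homozygous-derived loci.
    Missing genotypes are skipped.  Requires per-sample genotypes."""
    if table.genotypes is None:
        raise ValueError("per-individual genotypes are required for load counts")
    sel = np.asarray(table.sample_pop) == population
    if not sel.any():
        raise KeyError(f"population {population!r} has no samples")
    g = table.genotypes[np.ix_(table.class_mask("deleterious"), sel)]
    het = (g == 1).sum(axis=0)
    hom = (g == 2).sum(axis=0)
    samples = [s for s, k in zip(table.samples, sel) if k]
    return pd.DataFrame(
        {
            "sample": samples,
            "population": population,
            "additive": het + 2 * hom,
            "recessive": hom,
        }
    )


def fixation_proportion_by_class(table: AnnotatedVariantTable, population: str, effect_class: str) -> float:
    """Fraction of the class's sites fixed for the derived allele among the
    called genotypes of one population."""
    j = table.pop_index(population)
    mask = table.class_mask(effect_class) & (table.called[:, j] > 0)
    n = int(np.count_nonzero(mask))
    if n == 0:
        return float("nan")
    fixed = np.count_nonzero(table.derived[mask, j] == 2 * table.called[mask, j])
    return float(fixed / n)


def windowed_pi(sites: pd.DataFrame, window_size: int = 1_000_000) -> pd.DataFrame:
    """Nucleotide diversity per genomic window as a ratio of sums.

    ``sites`` must have columns chrom, pos, derived, called, covering
    variant *and* invariant genotyped sites (invariant rows have derived 0).
    Per site the number of mismatching haplotype pairs is d*(n-d) and the
    number of comparable pairs n*(n-1)/2 with n = 2*called; windows sum both
    before dividing, so missing genotypes shrink the denominator instead of
    biasing the mean.  Windows with zero comparable pairs give NaN.
    """
    df = sites
    n = 2 * df["called"].to_numpy(dtype=np.float64)
    d = df["derived"].to_numpy(dtype=np.float64)
    mism = d * (n - d)
    comp = n * (n - 1) / 2.0
    win = (df["pos"].to_numpy(dtype=np.int64) - 1) // int(window_size)
    out = (
        pd.DataFrame({"chrom": df["chrom"].to_numpy(), "window": win, "mismatch": mism, "comparable": comp})
        .groupby(["chrom", "window"], sort=True, observed=True)
        .sum()
        .reset_index()
    )
    out["window_start"] = out["window"] * int(window_size) + 1
    with np.errstate(invalid="ignore", divide="ignore"):
        out["pi"] = np.where(out["comparable"] > 0, out["mismatch"] / out["comparable"], np.nan)
    return out[["chrom", "window_start", "pi", "mismatch", "comparable"]]
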