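"""Summary statistics of simulated demes and trajectories.

Per-deme, per-recorded-generation summaries: neutral nucleotide diversity
pi, observed heterozygosity H, mean fitness, per-individual allele counts by
mutation class, realized DFE bins, fixed-deleterious proportion, the
additive/recessive load proxies and the load-to-fitness regression.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import MutationClass, MutationTable, _hom_ids

__all__ = [
    "StatRecord",
    "DfeBinSummary",
    "DFE_BIN_LABELS",
    "deme_site_counts",
    "neutral_pi",
    "observed_heterozygosity",
    "mean_class_allele_count",
    "fitness_change_rate",
    "realized_dfe_bins",
    "fixed_deleterious_proportion",
    "load_proxies",
    "load_fitness_regression",
    "snapshot_records",
    "trajectory_frame",
    "front_series",
    "lethal_purging_drop",
]

# DFE bins over negative selection coefficients, right edges closed:
# weak (-0.0001, 0), mid (-0.001, -0.0001], strong (-1, -0.001], lethal {-1}
DFE_BIN_LABELS = ("weak", "mid", "strong", "lethal")


@dataclasses.dataclass
class StatRecord:
    """Per-deme summary at one recorded generation."""

    generation: int
    deme: int
    census: int
    pi_neutral: float
    H_obs: float
    mean_fitness: float
    mean_lethal_alleles: float
    mean_deleterious_alleles: float
    mean_deleterious_hom_loci: float
    selfed_fraction: float


@dataclasses.dataclass
class DfeBinSummary:
    """Proportions of segregating negatively selected sites per DFE bin."""

    proportions: np.ndarray  # (weak, mid, strong, lethal)
    counts: np.ndarray


def deme_site_counts(deme, table: MutationTable):
    """Derived-allele count per mutation id over the 2N haplotypes of a
    deme; returns (counts, n_haplotypes)."""
    inds = deme.individuals
    if not inds:
        raise ValueError("empty deme")
    arrays = []
    for ind in inds:
        arrays.append(ind.genome_a.ids)
        arrays.append(ind.genome_b.ids)
    ids = np.concatenate(arrays) if arrays else np.empty(0, np.int64)
    counts = np.bincount(ids, minlength=table.n)
    return counts, 2 * len(inds)


def neutral_pi(deme, table: MutationTable, G: Optional[int] = None, counts=None, n_hap=None) -> float:
    """Per-site pairwise diversity at neutral sites over the whole deme:
    sum over sites of 2 p (1-p) * 2N/(2N-1), divided by G."""
    if counts is None:
        counts, n_hap = deme_site_counts(deme, table)
    if G is None:
        raise ValueError("genome length G required")
    if n_hap < 2:
        return float("nan")
    neutral = table.mclass == MutationClass.NEUTRAL
    c = counts[: table.n][neutral]
    c = c[(c > 0) & (c < n_hap)]
    if c.size == 0:
        return 0.0
    p = c / n_hap
    return float(np.sum(2.0 * p * (1.0 - p)) * n_hap / (n_hap - 1) / G)


def observed_heterozygosity(deme, G: int) -> float:
    """Mean over individuals of (number of heterozygous sites) / G."""
    inds = deme.individuals
    if not inds:
        raise ValueError("empty deme")
    het = 0
    for ind in inds:
        het += ind.het_site_count()
    return het / (len(inds) * G)


def mean_class_allele_count(deme, table: MutationTable, mclass, counts=None) -> float:
    """Mean per-individual count of derived alleles of one mutation class."""
    if counts is None:
        counts, _ = deme_site_counts(deme, table)
    mask = table.mclass == int(mclass)
    return float(counts[: table.n][mask].sum() / len(deme.individuals))


def fitness_change_rate(trajectory: pd.DataFrame, deme: int, t: int, lag: int = 100) -> float:
    """Ratio of mean fitness at generation t over mean fitness at t - lag in
    one deme; 1 means no change.  NaN when either record is missing or the
    earlier fitness is zero."""
    sub = trajectory[trajectory["deme"] == deme]
    now = sub[sub["generation"] == t]["mean_fitness"]
    past = sub[sub["generation"] == t - lag]["mean_fitness"]
    if now.empty or past.empty:
        return float("nan")
    w0 = float(past.iloc[0])
    if w0 == 0.0 or not math.isfinite(w0):
        return float("nan")
    return float(now.iloc[0]) / w0


def assign_dfe_bin(s: np.ndarray) -> np.ndarray:
    """Bin index (0 weak, 1 mid, 2 strong, 3 lethal) for negative selection
    coefficients; the bins are left-open/right-closed."""
    s = np.asarray(s, dtype=float)
    if np.any(s >= 0):
        raise ValueError("DFE bins are defined for s < 0 only")
    out = np.empty(s.shape, dtype=np.int8)
    out[:] = 0
    out[s <= -0.0001] = 1
    out[s <= -0.001] = 2
    out[s == -1.0] = 3
    return out


def realized_dfe_bins(deme, table: MutationTable, counts=None, n_hap=None) -> DfeBinSummary:
    """Proportions of segregating deleterious+lethal sites of a deme in the
    four DFE bins.  Every qualifying site lands in exactly one bin; with no
    qualifying site all proportions are NaN."""
    if counts is None:
        counts, n_hap = deme_site_counts(deme, table)
    c = counts[: table.n]
    seg = (c > 0) & (c < n_hap) & (table.s < 0)
    nbin = np.zeros(4, dtype=np.int64)
    if seg.any():
        bins = assign_dfe_bin(table.s[seg])
        nbin = np.bincount(bins, minlength=4).astype(np.int64)
        props = nbin / nbin.sum()
    else:
        props = np.full(4, np.nan)
    return DfeBinSummary(proportions=props, counts=nbin)


def fixed_deleterious_proportion(deme, table: MutationTable, include_lethals: bool = True, counts=None, n_hap=None) -> float:
    """Among negatively selected sites present in the deme, the fraction at
    derived frequency 1 within the deme; NaN with no qualifying site."""
    if counts is None:
        counts, n_hap = deme_site_counts(deme, table)
    c = counts[: table.n]
    neg = table.s < 0
    if not include_lethals:
        neg &= table.mclass != MutationClass.LETHAL
    present = neg & (c > 0)
    if not present.any():
        return float("nan")
    return float(np.count_nonzero(c[present] == n_hap) / np.count_nonzero(present))


def load_proxies(deme, table: MutationTable, include_lethals: bool = False, counts=None):
    """Deme means of the two genetic-load proxies over deleterious-class
    sites: additive = derived alleles per individual (het + 2*hom, the h=0.5
    reading) and recessive = homozygous-derived loci per individual (the h=0
    reading).  Lethals are excluded by default, mirroring the empirical
    split of missense/nonsense versus loss-of-function sites."""
    inds = deme.individuals
    if not inds:
        raise ValueError("empty deme")
    if counts is None:
        counts, _ = deme_site_counts(deme, table)
    mask = table.mclass == MutationClass.DELETERIOUS
    if include_lethals:
        mask = mask | (table.mclass == MutationClass.LETHAL)
    additive = float(counts[: table.n][mask].sum() / len(inds))
    if include_lethals:
        hom_total = 0
        for ind in inds:
            hom = _hom_ids(ind.genome_a, ind.genome_b)
            if hom.size:
                hom_total += int(np.count_nonzero(mask[hom]))
        recessive = hom_total / len(inds)
    else:
        recessive = float(np.mean([ind.n_hom_deleterious for ind in inds]))
    return additive, recessive


def load_fitness_regression(points):
    """OLS of mean fitness on a load proxy over per-deme points.

    ``points`` is an iterable of (load_proxy, mean_fitness) pairs; returns
    (R2, slope, two-sided p-value).  Requires >= 3 points and a predictor
    with non-zero variance.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (load, fitness) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in the load predictor")
    if np.ptp(y) == 0.0:
        return 0.0, 0.0, 1.0  # flat response: the proxy explains nothing
    res = sps.linregress(x, y)
    return float(res.rvalue**2), float(res.slope), float(res.pvalue)


def core_relative_load_points(per_deme_summaries, proxy: str, core_deme: int = 1):
    """(load, fitness) regression points with each replicate referenced to
    its own core deme.

    ``per_deme_summaries`` is a sequence (one entry per replicate) of
    mappings deme -> {"load": (additive, recessive), "mean_fitness": w}.
    Points are (proxy count minus the core's count, fitness divided by the
    core's fitness); expressing both relative to the core removes the fixed
    mutational background, which is shared by every deme of a replicate but
    differs between replicates.
    """
    if proxy not in ("additive", "recessive"):
        raise ValueError("proxy must be 'additive' or 'recessive'")
    k = 0 if proxy == "additive" else 1
    pts = []
    for per_deme in per_deme_summaries:
        if core_deme not in per_deme:
            continue
        ref = per_deme[core_deme]
        w0 = ref["mean_fitness"]
        if not w0 > 0:
            continue
        for d in per_deme.values():
            pts.append((d["load"][k] - ref["load"][k], d["mean_fitness"] / w0))
    return pts


# ---------------------------------------------------------------------------
# recording plumbing used by the simulator


def snapshot_records(state) -> list[StatRecord]:
    cfg = state.cfg
    G = cfg.mutation_model.G
    table = state.table
    cls = table.mclass
    neutral = cls == MutationClass.NEUTRAL
    lethal = cls == MutationClass.LETHAL
    deleterious = cls == MutationClass.DELETERIOUS
    out = []
    for deme in state.demes:
        inds = deme.individuals
        N = len(inds)
        if N == 0:
            continue
        counts, n_hap = deme_site_counts(deme, table)
        c = counts[: table.n]
        if n_hap >= 2:
            cn = c[neutral]
            cn = cn[(cn > 0) & (cn < n_hap)]
            p = cn / n_hap
            pi = float(np.sum(2.0 * p * (1.0 - p)) * n_hap / (n_hap - 1) / G)
        else:
            pi = float("nan")
        het = 0
        hom_del = 0
        wsum = 0.0
        selfed = 0
        for ind in inds:
            het += ind.het_site_count()
            hom_del += ind.n_hom_deleterious
            wsum += ind.fitness
            selfed += ind.is_selfed_offspring
        out.append(
            StatRecord(
                generation=state.generation,
                deme=deme.index,
                census=N,
                pi_neutral=pi,
                H_obs=het / (N * G),
                mean_fitness=wsum / N,
                mean_lethal_alleles=float(c[lethal].sum() / N),
                mean_deleterious_alleles=float(c[deleterious].sum() / N),
                mean_deleterious_hom_loci=hom_del / N,
                selfed_fraction=selfed / N,
            )
        )
    return out


def trajectory_frame(records, cfg=None) -> pd.DataFrame:
    """Tidy DataFrame of StatRecords, annotated with replicate id and sigma."""
    cols = [f.name for f in dataclasses.fields(StatRecord)]
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)
    if cfg is not None:
        df.insert(0, "replicate", cfg.replicate_id)
        df.insert(1, "sigma", cfg.sigma)
    return df


# ---------------------------------------------------------------------------
# front-aligned purging summaries


def front_series(trajectory: pd.DataFrame, column: str = "mean_lethal_alleles") -> pd.DataFrame:
    """Value of ``column`` in the wavefront deme (highest occupied index) at
    each recorded generation."""
    if trajectory.empty:
        return pd.DataFrame(columns=["generation", "front_deme", column])
    idx = trajectory.groupby("generation")["deme"].idxmax()
    sub = trajectory.loc[idx, ["generation", "deme", column]]
    return sub.rename(columns={"deme": "front_deme"}).reset_index(drop=True)


def _weighted_lethal(sub: pd.DataFrame) -> float:
    n = sub["census"].sum()
    if n == 0:
        return float("nan")
    return float((sub["mean_lethal_alleles"] * sub["census"]).sum() / n)


def lethal_purging_drop(trajectory: pd.DataFrame, shift_deme: int, window: int = 200) -> float:
    """Fractional drop of the census-weighted per-individual lethal-allele
    count in the selfing half of the landscape within ``window`` generations
    of the mating shift.

    The baseline is the outcrossing level: the census-weighted lethal count
    over demes below ``shift_deme`` at the generation the expansion front
    first enters the selfing half.  The post value is the census-weighted
    count over demes >= shift_deme at the last record within the window
    (or the end of the run if it comes sooner).  Aggregating over whole
    halves of the landscape keeps both sides averaged over hundreds of
    individuals, so obligate outcrossers fluctuate around zero drop instead
    of hitting spurious zeros in tiny newly founded demes.
    """
    if trajectory.empty:
        return float("nan")
    shifted = trajectory[(trajectory["deme"] >= shift_deme) & (trajectory["census"] > 0)]
    if shifted.empty:
        return float("nan")
    t_shift = int(shifted["generation"].min())
    base_sub = trajectory[(trajectory["generation"] == t_shift) & (trajectory["deme"] < shift_deme)]
    baseline = _weighted_lethal(base_sub)
    if not np.isfinite(baseline) or baseline == 0.0:
        return float("nan")
    in_window = shifted[shifted["generation"] <= t_shift + window]
    t_eval = int(in_window["generation"].max())
    post = _weighted_lethal(shifted[shifted["generation"] == t_eval])
    return 1.0 - post / baseline
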