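"""Genetic entities and fitness machinery for the range-expansion simulator.

Mutations are abstract derived alleles at integer positions on a finite
genome of ``G`` base pairs.  Each mutation carries a selection coefficient
``s`` and a dominance coefficient ``h``; diploid fitness is multiplicative
over carried mutations with the standard factors ``1 + h*s`` for
heterozygotes and ``1 + s`` for homozygotes, clamped at zero.

New mutations fall into four classes -- neutral, beneficial, deleterious and
lethal -- drawn at fixed relative proportions.  Deleterious effects follow a
gamma distribution (shape 1, i.e. exponential, by default) with mean
``|mean_s_del|``; beneficial effects are exponential with mean
``mean_s_ben``; lethals have ``s = -1`` exactly.

The model is finite-sites with collision redraw: a new mutation landing on a
position already used by any mutation in the run is assigned a fresh
position, so every segregating site has a unique position and two haplotypes
carrying the same position carry the same mutation id.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np

__all__ = [
    "MutationClass",
    "MutationModelConfig",
    "MutationTable",
    "HaploidGenome",
    "Individual",
    "empty_genome",
    "draw_selection_coefficient",
    "draw_new_mutations",
    "genotype_fitness_factor",
    "haplotype_weight",
    "individual_fitness",
]


class MutationClass(enum.IntEnum):
    NEUTRAL = 0
    BENEFICIAL = 1
    DELETERIOUS = 2
    LETHAL = 3


CLASS_NAMES = ("neutral", "beneficial", "deleterious", "lethal")


@dataclasses.dataclass(frozen=True)
class MutationModelConfig:
    """Parameters of the mutational input and the genome.

    G : genome length in base pairs.
    mu : per-bp per-generation mutation rate.
    r : per-bp per-generation recombination rate.
    class_proportions : relative proportions of (neutral, beneficial,
        deleterious, lethal) new mutations.
    mean_s_del / mean_s_ben : mean selection coefficient of deleterious
        (negative) and beneficial (positive) mutations.
    gamma_shape_del : shape of the deleterious-effect gamma distribution
        (1 = exponential); the mean is preserved when the shape changes.
    h_nonlethal : dominance coefficient of beneficial and deleterious
        mutations (0.3 default; 0.5 in the fully additive sensitivity set).
    h_lethal : dominance coefficient of lethal mutations (0.02).
    """

    G: int = 10_000_000
    mu: float = 7e-8
    r: float = 1e-8
    class_proportions: tuple[float, float, float, float] = (0.25, 0.001, 0.649, 0.1)
    mean_s_del: float = -0.001
    mean_s_ben: float = 0.01
    gamma_shape_del: float = 1.0
    h_nonlethal: float = 0.3
    h_lethal: float = 0.02

    def validate(self) -> None:
        if self.G < 1:
            raise ValueError("genome length G must be >= 1")
        if self.mu < 0 or self.r < 0:
            raise ValueError("rates must be non-negative")
        if len(self.class_proportions) != 4 or any(p < 0 for p in self.class_proportions):
            raise ValueError("class_proportions must be 4 non-negative numbers")
        if abs(sum(self.class_proportions) - 1.0) > 1e-12:
            raise ValueError("class_proportions must sum to 1")
        if self.mean_s_del >= 0:
            raise ValueError("mean_s_del must be negative")
        if self.mean_s_ben <= 0:
            raise ValueError("mean_s_ben must be positive")
        if self.gamma_shape_del <= 0:
            raise ValueError("gamma_shape_del must be positive")
        for h in (self.h_nonlethal, self.h_lethal):
            if not 0.0 <= h <= 1.0:
                raise ValueError("dominance coefficients must lie in [0, 1]")

    def dominance_for_class(self, mclass: int) -> float:
        return self.h_lethal if mclass == MutationClass.LETHAL else self.h_nonlethal


def draw_selection_coefficient(mclass, cfg: MutationModelConfig, rng, size=None):
    """Draw selection coefficient(s) for one mutation class.

    Neutral mutations have s = 0 exactly and lethals s = -1 exactly.
    Deleterious draws are -Gamma(shape, mean=|mean_s_del|), redrawn on the
    (practically impossible at default parameters) event s <= -1; beneficial
    draws are +Exponential(mean_s_ben).
    """
    scalar = size is None
    n = 1 if scalar else int(size)
    if mclass == MutationClass.NEUTRAL:
        out = np.zeros(n)
    elif mclass == MutationClass.LETHAL:
        out = np.full(n, -1.0)
    elif mclass == MutationClass.BENEFICIAL:
        out = rng.exponential(cfg.mean_s_ben, size=n)
    elif mclass == MutationClass.DELETERIOUS:
        shape = cfg.gamma_shape_del
        scale = -cfg.mean_s_del / shape
        out = -rng.gamma(shape, scale, size=n)
        bad = out <= -1.0
        while bad.any():
            out[bad] = -rng.gamma(shape, scale, size=int(bad.sum()))
            bad = out <= -1.0
    else:
        raise ValueError(f"unknown mutation class {mclass!r}")
    return float(out[0]) if scalar else out


class MutationTable:
    """Columnar, append-only table of every mutation that ever arose.

    Globally fixed mutations are never converted to substitutions: they stay
    in the table and keep contributing a constant factor to every
    individual's fitness, so that core-versus-edge fitness comparisons share
    a single reference.
    """

    __slots__ = ("_pos", "_s", "_h", "_cls", "_gen", "_deme", "n", "_used_positions", "any_selected")

    def __init__(self, capacity: int = 1024):
        self._pos = np.empty(capacity, np.int64)
        self._s = np.empty(capacity, np.float64)
        self._h = np.empty(capacity, np.float64)
        self._cls = np.empty(capacity, np.int8)
        self._gen = np.empty(capacity, np.int64)
        self._deme = np.empty(capacity, np.int32)
        self.n = 0
        self._used_positions: set[int] = set()
        self.any_selected = False  # True once any mutation with s != 0 exists

    # -- column views -------------------------------------------------
    @property
    def position(self):
        return self._pos[: self.n]

    @property
    def s(self):
        return self._s[: self.n]

    @property
    def h(self):
        return self._h[: self.n]

    @property
    def mclass(self):
        return self._cls[: self.n]

    @property
    def origin_generation(self):
        return self._gen[: self.n]

    @property
    def origin_deme(self):
        return self._deme[: self.n]

    def __len__(self) -> int:
        return self.n

    def _grow(self, need: int) -> None:
        cap = self._pos.size
        if self.n + need <= cap:
            return
        new_cap = max(cap * 2, self.n + need)
        for name in ("_pos", "_s", "_h", "_cls", "_gen", "_deme"):
            old = getattr(self, name)
            buf = np.empty(new_cap, old.dtype)
            buf[: self.n] = old[: self.n]
            setattr(self, name, buf)

    @staticmethod
    def _check_invariants(position, s, h, mclass):
        if not 0.0 <= h <= 1.0:
            raise ValueError("h must lie in [0, 1]")
        if mclass == MutationClass.NEUTRAL and s != 0.0:
            raise ValueError("neutral mutations must have s = 0")
        if mclass == MutationClass.LETHAL and s != -1.0:
            raise ValueError("lethal mutations must have s = -1")
        if mclass == MutationClass.DELETERIOUS and not -1.0 < s < 0.0:
            raise ValueError("deleterious mutations must have -1 < s < 0")
        if mclass == MutationClass.BENEFICIAL and s <= 0.0:
            raise ValueError("beneficial mutations must have s > 0")
        if position < 0:
            raise ValueError("position must be non-negative")

    def add(self, position, s, h, mclass, origin_generation=0, origin_deme=0) -> int:
        """Append one mutation; returns its id. Positions must be unique."""
        self._check_invariants(position, s, h, mclass)
        pos = int(position)
        if pos in self._used_positions:
            raise ValueError(f"position {pos} already used by another mutation")
        self._grow(1)
        i = self.n
        self._pos[i] = pos
        self._s[i] = s
        self._h[i] = h
        self._cls[i] = int(mclass)
        self._gen[i] = origin_generation
        self._deme[i] = origin_deme
        self.n += 1
        self._used_positions.add(pos)
        if s != 0.0:
            self.any_selected = True
        return i

    def add_batch(self, positions, s, h, mclass, origin_generation, origin_deme):
        """Append pre-validated mutation draws; returns the new ids."""
        k = len(positions)
        self._grow(k)
        i0, i1 = self.n, self.n + k
        self._pos[i0:i1] = positions
        self._s[i0:i1] = s
        self._h[i0:i1] = h
        self._cls[i0:i1] = mclass
        self._gen[i0:i1] = origin_generation
        self._deme[i0:i1] = origin_deme
        self.n = i1
        self._used_positions.update(int(p) for p in positions)
        if not self.any_selected and np.any(self._s[i0:i1] != 0.0):
            self.any_selected = True
        return np.arange(i0, i1, dtype=np.int64)

    def draw_positions(self, k: int, G: int, rng) -> np.ndarray:
        """Draw k distinct positions uniformly on [0, G), redrawing collisions
        with any position already present in the table (or the batch)."""
        used = self._used_positions
        if k + len(used) > G:
            raise ValueError("genome saturated: cannot place new mutations")
        out = np.empty(k, np.int64)
        got = 0
        while got < k:
            cand = rng.integers(0, G, size=k - got)
            for p in cand:
                pi = int(p)
                if pi in used:
                    continue
                out[got] = pi
                used.add(pi)  # also reserves within this batch
                got += 1
        # positions were added to the used set for reservation; add_batch
        # re-adding them is harmless (set semantics)
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "mutation_id": np.arange(self.n, dtype=np.int64),
                "position": self.position.copy(),
                "s": self.s.copy(),
                "h": self.h.copy(),
                "class": [CLASS_NAMES[c] for c in self.mclass],
                "origin_generation": self.origin_generation.copy(),
                "origin_deme": self.origin_deme.copy(),
            }
        )


_EMPTY_IDS = np.empty(0, np.int64)
_EMPTY_POS = np.empty(0, np.int64)


class HaploidGenome:
    """One haploid genome: mutation ids and their positions, both sorted by
    position.  Instances are immutable after construction and may be shared
    between individuals; the product of heterozygous fitness factors over the
    genome is cached lazily (see :func:`haplotype_weight`)."""

    __slots__ = ("ids", "pos", "_w")

    def __init__(self, ids: np.ndarray, pos: np.ndarray):
        self.ids = ids
        self.pos = pos
        self._w = None

    @property
    def mutations(self) -> np.ndarray:
        """Mutation ids ordered by genomic position."""
        return self.ids

    def __len__(self) -> int:
        return self.ids.size


def empty_genome() -> HaploidGenome:
    return HaploidGenome(_EMPTY_IDS, _EMPTY_POS)


class Individual:
    """A diploid: two haploid genomes plus fitness and bookkeeping caches.

    ``fitness`` is computed once at birth (generations are non-overlapping,
    genomes immutable).  ``n_hom`` is the number of loci carried on both
    haplotypes and ``n_hom_deleterious`` the subset of those in the
    deleterious (non-lethal) class; both feed the per-deme heterozygosity and
    recessive-load summaries without re-intersecting genomes later.
    """

    __slots__ = ("genome_a", "genome_b", "fitness", "deme", "is_selfed_offspring", "_n_hom", "n_hom_deleterious")

    def __init__(self, genome_a, genome_b, table, deme=1, is_selfed_offspring=False):
        self.genome_a = genome_a
        self.genome_b = genome_b
        self.deme = deme
        self.is_selfed_offspring = is_selfed_offspring
        if table.any_selected:
            self.fitness, self._n_hom, self.n_hom_deleterious = _fitness_stats(genome_a, genome_b, table)
        else:
            # all-neutral table: fitness is exactly 1; defer the genome
            # intersection until a statistic asks for it
            self.fitness = 1.0
            self._n_hom = -1
            self.n_hom_deleterious = 0

    @property
    def n_hom(self) -> int:
        if self._n_hom < 0:
            self._n_hom = int(_hom_ids(self.genome_a, self.genome_b).size)
        return self._n_hom

    def het_site_count(self) -> int:
        return self.genome_a.ids.size + self.genome_b.ids.size - 2 * self.n_hom


def genotype_fitness_factor(s: float, h: float, zygosity: str) -> float:
    """Multiplicative fitness factor of one genotype: 1+h*s (het) or 1+s
    (hom), clamped at zero."""
    if zygosity == "het":
        return max(0.0, 1.0 + h * s)
    if zygosity == "hom":
        return max(0.0, 1.0 + s)
    raise ValueError("zygosity must be 'het' or 'hom'")


def haplotype_weight(genome: HaploidGenome, table: MutationTable) -> float:
    """Product of heterozygous factors (1 + h*s) over all mutations on one
    haplotype; cached on the genome (valid for the table it was built from)."""
    w = genome._w
    if w is None:
        if genome.ids.size == 0:
            w = 1.0
        else:
            f = 1.0 + table._h[genome.ids] * table._s[genome.ids]
            np.maximum(f, 0.0, out=f)
            w = float(f.prod())
        genome._w = w
    return w


def _hom_ids(a: HaploidGenome, b: HaploidGenome) -> np.ndarray:
    """Ids of mutations present on both haplotypes (positions are globally
    unique, so equal positions imply equal ids)."""
    if a.pos.size == 0 or b.pos.size == 0:
        return _EMPTY_IDS
    if a.pos.size < b.pos.size:
        a, b = b, a
    if a.pos is b.pos:  # shared (copied) haplotype: everything is hom
        return b.ids
    idx = a.pos.searchsorted(b.pos)
    # out-of-range insertion points can only come from b positions beyond
    # max(a.pos), which cannot match a.pos[0]
    idx[idx == a.pos.size] = 0
    return b.ids[a.pos[idx] == b.pos]


_DELETERIOUS = int(MutationClass.DELETERIOUS)

try:  # optional acceleration of the per-offspring fitness inner loop
    from numba import njit as _njit

    @_njit(cache=True, fastmath=False)
    def _fitness_kernel(a_ids, a_pos, b_ids, b_pos, s, h, cls, wa, wb):  # pragma: no cover - jit
        i = 0
        j = 0
        n_hom = 0
        n_hom_del = 0
        corr = 1.0
        lethal_hom = False
        na = a_pos.size
        nb = b_pos.size
        while i < na and j < nb:
            pa = a_pos[i]
            pb = b_pos[j]
            if pa == pb:
                mid = a_ids[i]
                n_hom += 1
                if cls[mid] == 2:
                    n_hom_del += 1
                sv = s[mid]
                if sv != 0.0:
                    ops = 1.0 + sv
                    if ops <= 0.0:
                        lethal_hom = True
                    else:
                        f = 1.0 + h[mid] * sv
                        corr *= ops / (f * f)
                i += 1
                j += 1
            elif pa < pb:
                i += 1
            else:
                j += 1
        if lethal_hom:
            return 0.0, n_hom, n_hom_del
        w = wa * wb * corr
        if w < 0.0:
            w = 0.0
        return w, n_hom, n_hom_del

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False


def _fitness_stats(a: HaploidGenome, b: HaploidGenome, table: MutationTable):
    """(fitness, n_hom, n_hom_deleterious) for an unordered genome pair.

    Uses the algebraic identity  w = W(a) * W(b) * prod_hom (1+s)/(1+h*s)^2
    where W is the per-haplotype heterozygous-factor product, so that shared
    (copied) haplotypes pay for their factor product only once; the hom
    correction only touches selected sites (the factor is 1 at s = 0).
    """
    wa = haplotype_weight(a, table)
    wb = haplotype_weight(b, table)
    if _HAVE_NUMBA:
        w, n_hom, n_hom_del = _fitness_kernel(a.ids, a.pos, b.ids, b.pos, table._s, table._h, table._cls, wa, wb)
        return float(w), int(n_hom), int(n_hom_del)
    w = wa * wb
    hom = _hom_ids(a, b)
    n_hom = int(hom.size)
    if n_hom:
        s = table._s[hom]
        n_hom_del = int(np.count_nonzero(table._cls[hom] == _DELETERIOUS))
        one_plus_s = 1.0 + s
        if one_plus_s.min() <= 0.0:
            return 0.0, n_hom, n_hom_del  # homozygous lethal
        h = table._h[hom]
        # the correction factor is exactly 1 at s = 0, so neutral hom sites
        # pass through the product unchanged
        w *= float((one_plus_s / np.square(1.0 + h * s)).prod())
    else:
        n_hom_del = 0
    return (w if w > 0.0 else 0.0), n_hom, n_hom_del


def individual_fitness(ind: Individual, table: MutationTable) -> float:
    """Recompute multiplicative fitness from the two genomes.

    Product over the union of carried mutations of the hom factor (1+s) if
    the mutation sits on both haplotypes, else the het factor (1+h*s); a
    mutation-free individual has fitness 1.  Equals the value cached at
    birth.
    """
    ids = np.concatenate([ind.genome_a.ids, ind.genome_b.ids])
    if ids.size and (ids.max() >= table.n or ids.min() < 0):
        raise KeyError("genome refers to a mutation id missing from the table")
    w, _, _ = _fitness_stats(ind.genome_a, ind.genome_b, table)
    return w


def _draw_classes(k: int, cfg: MutationModelConfig, rng) -> np.ndarray:
    cum = np.cumsum(cfg.class_proportions)
    cum[-1] = 1.0  # guard the float sum
    return np.searchsorted(cum, rng.random(k), side="right").astype(np.int8)


def _draw_mutation_batch(k: int, cfg: MutationModelConfig, table: MutationTable, generation, deme, rng):
    """Draw k new mutations (class, s, h, position) and append to the table;
    returns (ids, positions) sorted by position."""
    if k == 1:  # the common case at mu*G < 1
        mc = int(_draw_classes(1, cfg, rng)[0])
        s = np.array([draw_selection_coefficient(mc, cfg, rng)])
        h = np.array([cfg.dominance_for_class(mc)])
        pos = table.draw_positions(1, cfg.G, rng)
        ids = table.add_batch(pos, s, h, np.array([mc], np.int8), generation, deme)
        return ids, pos
    classes = _draw_classes(k, cfg, rng)
    s = np.empty(k)
    h = np.empty(k)
    for mc in (MutationClass.NEUTRAL, MutationClass.BENEFICIAL, MutationClass.DELETERIOUS, MutationClass.LETHAL):
        m = classes == mc
        nm = int(m.sum())
        if nm:
            s[m] = draw_selection_coefficient(mc, cfg, rng, size=nm)
            h[m] = cfg.dominance_for_class(mc)
    pos = table.draw_positions(k, cfg.G, rng)
    order = np.argsort(pos)
    pos, s, h, classes = pos[order], s[order], h[order], classes[order]
    ids = table.add_batch(pos, s, h, classes, generation, deme)
    return ids, pos


def draw_new_mutations(
    gamete: HaploidGenome,
    cfg: MutationModelConfig,
    table: MutationTable,
    generation: int,
    deme: int,
    rng,
) -> HaploidGenome:
    """Add Poisson(mu*G) new mutations to a gamete, preserving position order.

    Returns the input gamete unchanged when no mutation occurs (genomes are
    immutable, so sharing is safe).
    """
    k = rng.poisson(cfg.mu * cfg.G)
    if k == 0:
        return gamete
    return _mutated_gamete(gamete, int(k), cfg, table, generation, deme, rng)


def _mutated_gamete(gamete, k, cfg, table, generation, deme, rng) -> HaploidGenome:
    ids, pos = _draw_mutation_batch(k, cfg, table, generation, deme, rng)
    if k == 1:
        i = int(np.searchsorted(gamete.pos, pos[0]))
        new_ids = np.concatenate((gamete.ids[:i], ids, gamete.ids[i:]))
        new_pos = np.concatenate((gamete.pos[:i], pos, gamete.pos[i:]))
        return HaploidGenome(new_ids, new_pos)
    at = np.searchsorted(gamete.pos, pos)
    return HaploidGenome(np.insert(gamete.ids, at, ids), np.insert(gamete.pos, at, pos))
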