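"""Forward-time simulation of a 1-D range expansion with a mating shift.

The landscape is a line of ``n_demes`` demes under stepping-stone migration
with reflecting boundaries.  Deme 1 (the core, carrying capacity ``K_core``)
is burned in as a closed, obligately outcrossing population for
``burn_in_generations`` (default 4*K_core); the landscape then opens and the
remaining demes (capacity ``K_deme``) are colonized.  From ``shift_deme``
onward the probability that an individual reproduces by self-fertilization
is ``sigma``; before it, populations outcross obligately.

Each generation (discrete, non-overlapping):

1. per-deme expected offspring via Beverton-Holt regulation,
   N' = R*N / (1 + N/M) with M = K/(R-1), so N* = K is the fixed point;
2. fecundity selection: parent i leaves Poisson(w_i / sum_j w_j * N')
   offspring; selfers (designated with probability sigma each generation)
   contribute both gametes, outcrossers draw a uniform mate among the other
   individuals of the deme (a lone outcrosser leaves no offspring -- the
   mate-limitation Allee effect that slows outcrossing colonization fronts);
3. parents die; offspring migrate (probability ``m``, direction uniform,
   boundary demes send all migrants inward);
4. summary statistics are recorded every ``record_interval`` generations.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .core import (
    HaploidGenome,
    Individual,
    MutationModelConfig,
    MutationTable,
    _mutated_gamete,
    empty_genome,
)

__all__ = [
    "SimulationConfig",
    "Deme",
    "SimulationState",
    "beverton_holt_expected",
    "make_gamete",
    "reproduce_deme",
    "migrate",
    "step_generation",
    "run_burn_in",
    "run_expansion",
    "run_replicate",
]


@dataclasses.dataclass
class SimulationConfig:
    """Every parameter of the range-expansion model.

    Demes are labelled 1..n_demes; the core is deme 1 and selfing applies in
    demes >= shift_deme during the expansion phase.
    """

    n_demes: int = 50
    K_core: int = 5000
    K_deme: int = 200
    m: float = 0.05
    R: float = 1.2
    shift_deme: int = 25
    sigma: float = 0.0
    burn_in_generations: Optional[int] = None  # default 4 * K_core
    stop_extra_generations: int = 100
    record_interval: int = 5
    fitness_change_lag: int = 100
    generation_cap: int = 1_000_000
    record_burn_in: bool = False
    mutation_model: MutationModelConfig = dataclasses.field(default_factory=MutationModelConfig)
    seed: int = 0
    replicate_id: int = 0

    @property
    def burn_in(self) -> int:
        return 4 * self.K_core if self.burn_in_generations is None else self.burn_in_generations

    def validate(self) -> None:
        if self.n_demes < 1:
            raise ValueError("n_demes must be >= 1")
        if not 1 <= self.shift_deme <= self.n_demes:
            raise ValueError("shift_deme must lie in [1, n_demes]")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError("sigma must lie in [0, 1]")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("m must lie in [0, 1]")
        if self.R <= 1.0:
            raise ValueError("R must exceed 1")
        if self.K_core < 1 or self.K_deme < 1:
            raise ValueError("carrying capacities must be >= 1")
        self.mutation_model.validate()

    def deme_K(self, index: int) -> int:
        return self.K_core if index == 1 else self.K_deme

    def deme_sigma(self, index: int) -> float:
        return self.sigma if index >= self.shift_deme else 0.0


class Deme:
    """One deme of the landscape: 1-based index, capacity, local selfing
    probability and the individuals currently living there."""

    __slots__ = ("index", "K", "sigma_local", "individuals")

    def __init__(self, index: int, K: int, sigma_local: float):
        self.index = index
        self.K = K
        self.sigma_local = sigma_local
        self.individuals: list[Individual] = []

    def census(self) -> int:
        return len(self.individuals)


class SimulationState:
    """Mutable state of one replicate: demes, mutation table, rng, phase and
    colonization bookkeeping."""

    def __init__(self, cfg: SimulationConfig, rng=None):
        cfg.validate()
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed) if rng is None else rng
        self.generation = 0
        self.table = MutationTable()
        self.demes = [Deme(i, cfg.deme_K(i), cfg.deme_sigma(i)) for i in range(1, cfg.n_demes + 1)]
        base = empty_genome()
        self.demes[0].individuals = [
            Individual(base, base, self.table, deme=1) for _ in range(cfg.K_core)
        ]
        self.phase = "burn_in"
        self.status = "running"
        self.records: list = []
        self.expansion_start_generation: Optional[int] = None
        self.landscape_crossed_generation: Optional[int] = None
        self.colonization_generation = np.full(cfg.n_demes, -1, dtype=np.int64)
        self.colonization_generation[0] = 0

    def census(self) -> np.ndarray:
        return np.array([d.census() for d in self.demes], dtype=np.int64)

    @property
    def expansion_time(self) -> Optional[int]:
        if self.landscape_crossed_generation is None or self.expansion_start_generation is None:
            return None
        return self.landscape_crossed_generation - self.expansion_start_generation


def beverton_holt_expected(N_t: float, K: float, R: float) -> float:
    """Expected total offspring of a deme of size N_t: R*N_t / (1 + N_t/M)
    with M = K/(R-1); the fixed point is N = K."""
    if N_t < 0 or K <= 0 or R <= 1:
        raise ValueError("require N_t >= 0, K > 0, R > 1")
    M = K / (R - 1.0)
    return R * N_t / (1.0 + N_t / M)


def _gamete(parent, mm, table, generation, deme, rng, n_cross, n_mut, pick_u):
    """Build one gamete from pre-drawn event counts (hot path)."""
    if n_cross == 0:
        hap = parent.genome_a if pick_u < 0.5 else parent.genome_b
    else:
        breaks = np.sort(rng.integers(1, mm.G, size=n_cross))
        src = (parent.genome_a, parent.genome_b)
        which = 0 if pick_u < 0.5 else 1
        seg_ids, seg_pos = [], []
        prev = 0
        for b in breaks:
            h = src[which]
            i0 = np.searchsorted(h.pos, prev)
            i1 = np.searchsorted(h.pos, b)
            seg_ids.append(h.ids[i0:i1])
            seg_pos.append(h.pos[i0:i1])
            which ^= 1
            prev = b
        h = src[which]
        i0 = np.searchsorted(h.pos, prev)
        seg_ids.append(h.ids[i0:])
        seg_pos.append(h.pos[i0:])
        hap = HaploidGenome(np.concatenate(seg_ids), np.concatenate(seg_pos))
    if n_mut:
        hap = _mutated_gamete(hap, n_mut, mm, table, generation, deme, rng)
    return hap


def make_gamete(parent: Individual, cfg, table: MutationTable, generation: int, deme: int, rng) -> HaploidGenome:
    """Produce one recombinant gamete with new mutations.

    Crossover count ~ Poisson(r*G) with uniform integer breakpoints in
    [1, G); the starting haplotype is chosen with probability 1/2; new
    mutations are added at rate mu*G (Poisson).
    """
    mm = cfg.mutation_model if isinstance(cfg, SimulationConfig) else cfg
    n_cross = int(rng.poisson(mm.r * mm.G))
    n_mut = int(rng.poisson(mm.mu * mm.G))
    return _gamete(parent, mm, table, generation, deme, rng, n_cross, n_mut, rng.random())


def reproduce_deme(
    individuals: list,
    N_expected: float,
    sigma_local: float,
    cfg: SimulationConfig,
    table: MutationTable,
    generation: int,
    deme_index: int,
    rng,
) -> list:
    """One round of fecundity selection with probabilistic selfing.

    Parent i leaves Poisson((w_i / sum w) * N_expected) offspring.  Parents
    designated selfers (probability sigma_local, independently each
    generation) provide both gametes of each of their offspring; outcrossing
    parents draw, per offspring, a uniform mate among the *other*
    individuals of the deme (obligate outcrossing: never themselves).  A
    lone outcrosser, or a deme whose total fitness is zero, leaves no
    offspring.
    """
    N = len(individuals)
    if N == 0 or N_expected <= 0:
        return []
    w = np.empty(N)
    for i, ind in enumerate(individuals):
        w[i] = ind.fitness
    wsum = w.sum()
    if wsum <= 0.0:
        return []
    counts = rng.poisson(w * (N_expected / wsum))
    if sigma_local > 0.0:
        selfer = rng.random(N) < sigma_local
    else:
        selfer = None
    total = int(counts.sum())
    if total == 0:
        return []
    mm = cfg.mutation_model
    # pre-draw per-gamete event counts to keep scalar rng calls off the hot path
    xo = rng.poisson(mm.r * mm.G, size=2 * total).tolist()
    nm = rng.poisson(mm.mu * mm.G, size=2 * total).tolist()
    pu = rng.random(2 * total).tolist()
    g = 0
    offspring: list[Individual] = []
    for i in range(N):
        c = int(counts[i])
        if c == 0:
            continue
        parent = individuals[i]
        is_self = selfer is not None and bool(selfer[i])
        if not is_self and N == 1:
            g += 2 * c
            continue  # no mate available
        if is_self:
            for _ in range(c):
                ga = _gamete(parent, mm, table, generation, deme_index, rng, xo[g], nm[g], pu[g])
                gb = _gamete(parent, mm, table, generation, deme_index, rng, xo[g + 1], nm[g + 1], pu[g + 1])
                g += 2
                offspring.append(Individual(ga, gb, table, deme=deme_index, is_selfed_offspring=True))
        else:
            mates = rng.integers(0, N - 1, size=c)
            mates += mates >= i
            for k in range(c):
                ga = _gamete(parent, mm, table, generation, deme_index, rng, xo[g], nm[g], pu[g])
                mate = individuals[int(mates[k])]
                gb = _gamete(mate, mm, table, generation, deme_index, rng, xo[g + 1], nm[g + 1], pu[g + 1])
                g += 2
                offspring.append(Individual(ga, gb, table, deme=deme_index, is_selfed_offspring=False))
    return offspring


def migrate(state: SimulationState, cfg: SimulationConfig, rng) -> SimulationState:
    """Stepping-stone migration: each individual moves with probability m,
    direction uniform between the two neighbours; boundary demes send all
    their migrants to their single interior neighbour (reflecting).  Total
    census is conserved."""
    n = cfg.n_demes
    if n == 1 or cfg.m == 0.0:
        return state
    incoming: list[list] = [[] for _ in range(n)]
    for deme in state.demes:
        inds = deme.individuals
        N = len(inds)
        if N == 0:
            continue
        u = rng.random(N)
        movers = np.flatnonzero(u < cfg.m)
        if movers.size == 0:
            continue
        if deme.index == 1:
            targets = np.full(movers.size, 2)
        elif deme.index == n:
            targets = np.full(movers.size, n - 1)
        else:
            left = rng.random(movers.size) < 0.5
            targets = np.where(left, deme.index - 1, deme.index + 1)
        for j, t in zip(movers, targets):
            ind = inds[j]
            ind.deme = int(t)
            incoming[int(t) - 1].append(ind)
        stay = np.flatnonzero(u >= cfg.m)
        deme.individuals = [inds[j] for j in stay]
    for deme in state.demes:
        inc = incoming[deme.index - 1]
        if inc:
            deme.individuals.extend(inc)
    return state


def step_generation(state: SimulationState, cfg: Optional[SimulationConfig] = None, rng=None) -> SimulationState:
    """Advance one generation: regulate -> reproduce -> parents die ->
    migrate (expansion phase only) -> record on schedule."""
    cfg = state.cfg if cfg is None else cfg
    rng = state.rng if rng is None else rng
    expanding = state.phase == "expanding"
    gen_next = state.generation + 1
    for deme in state.demes:
        N = deme.census()
        if N == 0:
            continue
        N_exp = beverton_holt_expected(N, deme.K, cfg.R)
        sigma_local = deme.sigma_local if expanding else 0.0
        deme.individuals = reproduce_deme(
            deme.individuals, N_exp, sigma_local, cfg, state.table, gen_next, deme.index, rng
        )
    if expanding:
        migrate(state, cfg, rng)
    state.generation = gen_next
    total = 0
    for deme in state.demes:
        c = deme.census()
        total += c
        if c > 0 and state.colonization_generation[deme.index - 1] < 0:
            state.colonization_generation[deme.index - 1] = gen_next
    if total == 0:
        state.status = "extinct"
        return state
    if gen_next % cfg.record_interval == 0 and (expanding or cfg.record_burn_in):
        from .simstats import snapshot_records

        state.records.extend(snapshot_records(state))
    return state


def run_burn_in(cfg: SimulationConfig) -> SimulationState:
    """Equilibrate the closed, obligately outcrossing core deme for the
    configured number of generations (default 4*K_core)."""
    state = SimulationState(cfg)
    for _ in range(cfg.burn_in):
        step_generation(state)
        if state.status == "extinct":
            return state
    state.phase = "burned_in"
    return state


def run_expansion(state: SimulationState, cfg: Optional[SimulationConfig] = None):
    """Open the landscape and run until the last deme first reaches its
    carrying capacity, then ``stop_extra_generations`` more.

    Returns ``(trajectory, state)`` where the trajectory is a tidy DataFrame
    of the per-deme records.  ``state.expansion_time`` is the number of
    generations from the start of the expansion to the landscape being
    crossed.  A single-deme landscape is complete immediately.
    """
    from .simstats import trajectory_frame

    cfg = state.cfg if cfg is None else cfg
    state.phase = "expanding"
    state.expansion_start_generation = state.generation
    if state.colonization_generation[0] < 0:
        state.colonization_generation[0] = state.generation
    last = state.demes[-1]
    if cfg.n_demes == 1:
        state.landscape_crossed_generation = state.generation
        state.status = "complete"
        return trajectory_frame(state.records, cfg), state
    while True:
        step_generation(state)
        if state.status == "extinct":
            break
        if state.landscape_crossed_generation is None and last.census() >= cfg.K_deme:
            state.landscape_crossed_generation = state.generation
        if (
            state.landscape_crossed_generation is not None
            and state.generation >= state.landscape_crossed_generation + cfg.stop_extra_generations
        ):
            state.status = "complete"
            break
        if state.generation - state.expansion_start_generation > cfg.generation_cap:
            state.status = "timeout"
            break
    return trajectory_frame(state.records, cfg), state


def run_replicate(cfg: SimulationConfig):
    """Burn-in plus expansion in one call; returns (trajectory, state)."""
    state = run_burn_in(cfg)
    if state.status == "extinct":
        from .simstats import trajectory_frame

        return trajectory_frame(state.records, cfg), state
    return run_expansion(state)
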