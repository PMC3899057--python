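"""Forward-time genealogical dynamics of transmissible identities.

This module implements a biparental, discrete-generation model of a
population in which every individual carries one of two exclusive,
culturally transmitted identities (type-1 or type-2, e.g. Sephardic vs
Ashkenazi).  Parent pairs for each child are drawn from a multinomial
over pair types whose probabilities interpolate, via a preference
parameter ``alpha`` in [0, 1], between random mating (``alpha = 0``) and
exclusive within-type mating (``alpha = 1``)::

    p11 = alpha*x + (1 - alpha)*x**2
    p12 = (1 - alpha)*2*x*(1 - x)
    p22 = alpha*(1 - x) + (1 - alpha)*(1 - x)**2

where ``x`` is the current type-1 fraction.  Children of two same-type
parents inherit that type; children of mixed pairs self-identify as
either type with probability 1/2.  This scheme preserves the expected
type-1 fraction each generation (a martingale in ``x``).

Alongside the self-identified type, each individual carries a
*genealogical identity* flag ``g``: whether any of its generation-0
ancestors (or the individual itself, if a founder) is type-1.  The flag
propagates as the OR of the two parents' flags, so the only reachable
states are (type-1, g=1), (type-2, g=0) and (type-2, g=1).

The deterministic theory tracks q(t), the fraction of type-2
individuals with no type-1 ancestor.  Lacking a type-1 ancestor must
hold for *both* parents, so q contracts quadratically each generation::

    q(t+1) = c * q(t)**2,   c = p22/(1 - x0) = alpha + (1-alpha)*(1-x0)

with closed form q(t) = c**(2**t - 1): a superexponential decline for
alpha < 1.  The fraction of individuals with at least one type-1
ancestor is F(t) = 1 - (1 - x0)*q(t).

The simulation engine records, optionally, the full pedigree
(parent-index layers) and exact founder-ancestor sets as packed
bitsets, enabling ancestor-composition metrics and brute-force oracle
checks of the incremental g propagation.
"""

from __future__ import annotations

import dataclasses
import io
import logging
import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "IdentityType",
    "TYPE1",
    "TYPE2",
    "IndividualState",
    "MatingModel",
    "PairingDistribution",
    "pairing_distribution",
    "offspring_type",
    "offspring_gflag",
    "alpha_from_odds",
    "GrowthSchedule",
    "initial_population",
    "PopulationState",
    "PedigreeLayer",
    "AncestrySets",
    "SimulationResult",
    "next_generation",
    "simulate",
    "founder_ancestor_sets",
    "brute_force_gflags",
    "ancestor_type1_fraction",
    "pairwise_shared_ancestor_fraction",
    "first_passage_generation",
    "TheoryTrajectory",
    "contraction_constant",
    "q_trajectory",
    "q_closed_form",
    "fraction_with_type1_ancestor",
    "theory_trajectory",
    "theory_first_passage",
    "compare_theory_sim",
    "sweep_first_passage",
    "ScenarioConfig",
    "ConfigError",
    "preset_scenario",
    "PRESETS",
    "load_config",
    "SUMMARY_COLUMNS",
    "write_summary",
    "read_summary",
    "write_pedigree",
    "write_fam",
]

logger = logging.getLogger("genident")

# Exact ancestor-set tracking stores n(t) * n0 bits per generation; cap
# the founder count so a tracked run stays within desktop memory.
MAX_TRACKED_FOUNDERS = 20_000

# q values below this are reported as exactly 0 (log-domain underflow floor).
Q_UNDERFLOW = 1e-300


# ---------------------------------------------------------------------------
# Identity types and per-individual state
# ---------------------------------------------------------------------------

class IdentityType(IntEnum):
    """The two exclusive transmissible identities."""

    TYPE1 = 1
    TYPE2 = 2


TYPE1 = IdentityType.TYPE1
TYPE2 = IdentityType.TYPE2


@dataclass(frozen=True)
class IndividualState:
    """Identity plus genealogical flag of a single individual.

    ``g`` is True iff the individual has at least one type-1
    generation-0 ancestor (type-1 founders count as g=True).  The state
    (type-1, g=False) is unreachable: a type-1 child always has a
    type-1 parent, whose g is True.
    """

    tau: IdentityType
    g: bool

    def __post_init__(self) -> None:
        if self.tau == TYPE1 and not self.g:
            raise ValueError("state (type1, g=False) is unreachable")


# ---------------------------------------------------------------------------
# Mating model: assortative pairing distribution and inheritance rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatingModel:
    """Assortative-mating preference.

    alpha = 0 is panmixia (pair types by population proportions only);
    alpha = 1 is exclusive within-type mating.
    """

    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")


@dataclass(frozen=True)
class PairingDistribution:
    """Multinomial probabilities of the three parental pair types."""

    p11: float
    p12: float
    p22: float
    x: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p11, self.p12, self.p22], dtype=float)


def pairing_distribution(x: float, model: Union[MatingModel, float]) -> PairingDistribution:
    """Pair-type probabilities at type-1 fraction ``x`` under ``model``.

    Convex interpolation between the fully assortative limit
    (p11, p12, p22) = (x, 0, 1-x) and the random-mating binomial limit
    (x^2, 2x(1-x), (1-x)^2).  Both the normalization p11+p12+p22 = 1 and
    the conservation property p11 + p12/2 = x hold identically in alpha.
    """
    alpha = model.alpha if isinstance(model, MatingModel) else float(model)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x must be in [0, 1], got {x}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    p11 = alpha * x + (1.0 - alpha) * x * x
    p12 = (1.0 - alpha) * 2.0 * x * (1.0 - x)
    p22 = alpha * (1.0 - x) + (1.0 - alpha) * (1.0 - x) * (1.0 - x)
    return PairingDistribution(p11=p11, p12=p12, p22=p22, x=x)


def offspring_type(parent1_tau: IdentityType, parent2_tau: IdentityType,
                   coin: int) -> IdentityType:
    """Child identity: same-type pairs breed true; mixed pairs flip ``coin``.

    ``coin`` is a fair random bit; the child of a mixed pair is type-1
    iff coin == 1.
    """
    if parent1_tau == parent2_tau:
        return IdentityType(parent1_tau)
    return TYPE1 if coin else TYPE2


def offspring_gflag(parent1: IndividualState, parent2: IndividualState) -> bool:
    """Genealogical flag of a child: False iff both parents are (type-2, g=False)."""
    return parent1.g or parent2.g


def alpha_from_odds(odds: float, mapping: str = "suppression",
                    x_ref: float = 0.2) -> float:
    """Convert an in-group:out-group mating odds ratio to ``alpha``.

    mapping="suppression" (default): alpha = 1 - 1/odds, i.e. the
    cross-type pairing weight (1 - alpha) is suppressed ``odds``-fold
    relative to random mixing.

    mapping="conditional": solves 2*p11/p12 = odds at the reference
    type-1 fraction ``x_ref``, i.e. ``odds`` is the relative likelihood
    that a given type-1 individual pairs with a type-1 rather than a
    type-2 partner.  The two mappings differ by <0.2% in alpha at
    odds=1000, x_ref=0.2.
    """
    if odds < 1.0:
        raise ValueError(f"odds must be >= 1, got {odds}")
    if math.isinf(odds):
        return 1.0
    if mapping == "suppression":
        return 1.0 - 1.0 / odds
    if mapping == "conditional":
        if not 0.0 < x_ref < 1.0:
            raise ValueError("x_ref must be in (0, 1) for the conditional mapping")
        # odds = 2 p11 / p12 = (alpha + (1-alpha) x) / ((1-alpha)(1-x))
        # => alpha = (odds (1-x) - x) / (odds (1-x) + 1 - x)
        num = odds * (1.0 - x_ref) - x_ref
        den = odds * (1.0 - x_ref) + (1.0 - x_ref)
        return num / den
    raise ValueError(f"unknown mapping {mapping!r}; use 'suppression' or 'conditional'")


# ---------------------------------------------------------------------------
# Population growth schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthSchedule:
    """Deterministic population sizes n(0..T).

    ``geometric`` mode interpolates multiplicatively between n0 and
    n_final (rounded to nearest integer, endpoints exact); ``constant``
    requires n0 == n_final.
    """

    n0: int
    n_final: int
    T: int
    mode: str = "constant"

    def __post_init__(self) -> None:
        if self.n0 < 2 or self.n_final < 2:
            raise ValueError("population sizes must be >= 2")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.mode not in ("constant", "geometric"):
            raise ValueError(f"unknown growth mode {self.mode!r}")
        if self.mode == "constant" and self.n0 != self.n_final:
            raise ValueError("constant mode requires n0 == n_final")

    def sizes(self) -> np.ndarray:
        """n(t) for t = 0..T."""
        if self.mode == "constant":
            return np.full(self.T + 1, self.n0, dtype=np.int64)
        ratio = self.n_final / self.n0
        t = np.arange(self.T + 1)
        n = np.rint(self.n0 * ratio ** (t / self.T)).astype(np.int64)
        n[0], n[-1] = self.n0, self.n_final
        return n


# ---------------------------------------------------------------------------
# Simulation engine: per-generation state, pedigree, forward stepping
# ---------------------------------------------------------------------------

@dataclass
class PopulationState:
    """One generation: per-individual types and genealogical flags."""

    t: int
    tau: np.ndarray  # uint8, values in {1, 2}
    g: np.ndarray    # bool

    @property
    def n(self) -> int:
        return self.tau.shape[0]

    @property
    def x(self) -> float:
        """Realized type-1 fraction."""
        return float(np.count_nonzero(self.tau == TYPE1)) / self.n

    def validate(self) -> None:
        if self.tau.shape != self.g.shape:
            raise ValueError("tau and g must have equal length")
        bad = np.count_nonzero((self.tau == TYPE1) & ~self.g)
        if bad:
            raise ValueError(f"{bad} individuals in unreachable state (type1, g=False)")


@dataclass
class PedigreeLayer:
    """Parent indices linking each child of generation t+1 to generation t."""

    parent1: np.ndarray  # int64, index into previous generation
    parent2: np.ndarray

    @property
    def n_children(self) -> int:
        return self.parent1.shape[0]

    def validate(self, n_parents: int) -> None:
        for name, arr in (("parent1", self.parent1), ("parent2", self.parent2)):
            if arr.size and (arr.min() < 0 or arr.max() >= n_parents):
                raise IndexError(
                    f"{name} index out of range [0, {n_parents - 1}]")


def initial_population(n0: int, x0: float) -> PopulationState:
    """Founder generation: round(x0*n0) type-1 founders (g=True), rest type-2 (g=False)."""
    if not 0.0 <= x0 <= 1.0:
        raise ValueError(f"x0 must be in [0, 1], got {x0}")
    n1 = int(round(x0 * n0))
    tau = np.full(n0, TYPE2, dtype=np.uint8)
    tau[:n1] = TYPE1
    g = tau == TYPE1
    return PopulationState(t=0, tau=tau, g=g)


def next_generation(state: PopulationState, model: MatingModel, n_next: int,
                    rng: np.random.Generator) -> tuple[PopulationState, PedigreeLayer]:
    """Draw one offspring generation of size ``n_next``.

    Pair types are multinomial with probabilities from the realized
    type-1 fraction of ``state``; each parent of a pair is drawn
    uniformly with replacement from the corresponding type
    subpopulation (self-pairing allowed, no sexes).  Pair-type
    probabilities are renormalized over feasible pair types if a type
    subpopulation is empty (with exact arithmetic the infeasible
    probabilities are already 0; the renormalization guards float
    residue).
    """
    if n_next < 1:
        raise ValueError(f"n_next must be >= 1, got {n_next}")
    if state.n < 1:
        raise ValueError("state must contain at least one individual")
    idx1 = np.flatnonzero(state.tau == TYPE1)
    idx2 = np.flatnonzero(state.tau == TYPE2)
    x = idx1.size / state.n
    probs = pairing_distribution(x, model).as_array()
    feasible = np.array([idx1.size > 0,
                         idx1.size > 0 and idx2.size > 0,
                         idx2.size > 0])
    probs = np.where(feasible, probs, 0.0)
    probs /= probs.sum()
    k11, k12, k22 = rng.multinomial(n_next, probs)

    parent1 = np.empty(n_next, dtype=np.int64)
    parent2 = np.empty(n_next, dtype=np.int64)
    tau_c = np.empty(n_next, dtype=np.uint8)

    lo, hi = 0, int(k11)
    if k11:
        parent1[lo:hi] = idx1[rng.integers(0, idx1.size, size=k11)]
        parent2[lo:hi] = idx1[rng.integers(0, idx1.size, size=k11)]
        tau_c[lo:hi] = TYPE1
    lo, hi = hi, hi + int(k12)
    if k12:
        parent1[lo:hi] = idx1[rng.integers(0, idx1.size, size=k12)]
        parent2[lo:hi] = idx2[rng.integers(0, idx2.size, size=k12)]
        coin = rng.integers(0, 2, size=k12)
        tau_c[lo:hi] = np.where(coin == 1, np.uint8(TYPE1), np.uint8(TYPE2))
    lo, hi = hi, hi + int(k22)
    if k22:
        parent1[lo:hi] = idx2[rng.integers(0, idx2.size, size=k22)]
        parent2[lo:hi] = idx2[rng.integers(0, idx2.size, size=k22)]
        tau_c[lo:hi] = TYPE2

    g_c = state.g[parent1] | state.g[parent2]
    child = PopulationState(t=state.t + 1, tau=tau_c, g=g_c)
    return child, PedigreeLayer(parent1=parent1, parent2=parent2)


# ---------------------------------------------------------------------------
# Founder-ancestor sets (packed bitsets) and brute-force oracles
# ---------------------------------------------------------------------------

class AncestrySets:
    """Per-individual sets of distinct generation-0 ancestors.

    Stored as an (n, ceil(n0/64)) matrix of uint64 words; founder j's
    set is the singleton {j}, and a child's set is the bitwise OR of
    its parents' sets.
    """

    def __init__(self, bits: np.ndarray, n0: int):
        self.bits = bits
        self.n0 = n0

    @property
    def n(self) -> int:
        return self.bits.shape[0]

    @classmethod
    def founders(cls, n0: int) -> "AncestrySets":
        words = (n0 + 63) // 64
        bits = np.zeros((n0, words), dtype=np.uint64)
        i = np.arange(n0)
        bits[i, i // 64] = np.uint64(1) << (i % 64).astype(np.uint64)
        return cls(bits, n0)

    @classmethod
    def mask_for(cls, indices: np.ndarray, n0: int) -> np.ndarray:
        """Bit mask (one row of words) selecting the given founder indices."""
        words = (n0 + 63) // 64
        mask = np.zeros(words, dtype=np.uint64)
        for i in np.asarray(indices, dtype=np.int64):
            mask[i // 64] |= np.uint64(1) << np.uint64(i % 64)
        return mask

    def children(self, layer: PedigreeLayer) -> "AncestrySets":
        layer.validate(self.n)
        return AncestrySets(self.bits[layer.parent1] | self.bits[layer.parent2],
                            self.n0)

    def set_sizes(self) -> np.ndarray:
        return np.bitwise_count(self.bits).sum(axis=1)

    def intersection_sizes(self, mask: np.ndarray) -> np.ndarray:
        return np.bitwise_count(self.bits & mask).sum(axis=1)

    def intersects(self, mask: np.ndarray) -> np.ndarray:
        """Boolean per individual: does the ancestor set meet ``mask``."""
        return self.intersection_sizes(mask) > 0

    def to_set(self, i: int) -> frozenset[int]:
        row = self.bits[i]
        out = []
        for w, word in enumerate(row):
            word = int(word)
            while word:
                b = word & -word
                out.append(w * 64 + b.bit_length() - 1)
                word ^= b
        return frozenset(out)


def founder_ancestor_sets(pedigree: Sequence[PedigreeLayer], n0: int) -> list[AncestrySets]:
    """Forward dynamic program: ancestor sets for every generation 0..T."""
    out = [AncestrySets.founders(n0)]
    for t, layer in enumerate(pedigree):
        try:
            out.append(out[-1].children(layer))
        except IndexError as exc:
            raise IndexError(f"pedigree layer {t}: {exc}") from exc
    return out


def brute_force_gflags(pedigree: Sequence[PedigreeLayer],
                       founder_types: np.ndarray) -> list[np.ndarray]:
    """Independent oracle for g: recursive pedigree walk per individual.

    Enumerates each individual's generation-0 ancestors by memoized
    depth-first traversal of the parent links and reports True iff any
    of them (or the individual itself, for founders) is type-1.
    Intended for small instances; the incremental engine must agree
    exactly.
    """
    founder_types = np.asarray(founder_types)
    n0 = founder_types.shape[0]
    type1_founders = frozenset(np.flatnonzero(founder_types == TYPE1).tolist())
    memo: dict[tuple[int, int], frozenset[int]] = {}

    def ancestors(t: int, i: int) -> frozenset[int]:
        if t == 0:
            return frozenset((i,))
        key = (t, i)
        got = memo.get(key)
        if got is None:
            layer = pedigree[t - 1]
            got = ancestors(t - 1, int(layer.parent1[i])) | \
                  ancestors(t - 1, int(layer.parent2[i]))
            memo[key] = got
        return got

    flags = [np.array([i in type1_founders for i in range(n0)])]
    for t, layer in enumerate(pedigree, start=1):
        flags.append(np.array([bool(ancestors(t, i) & type1_founders)
                               for i in range(layer.n_children)]))
    return flags


def ancestor_type1_fraction(ancestry: AncestrySets, founder_types: np.ndarray,
                            state: PopulationState, tau: IdentityType) -> float:
    """Mean fraction of generation-0 ancestors that are type-1, among
    individuals of identity ``tau`` (NaN if no such individual)."""
    sel = state.tau == tau
    if not np.any(sel):
        return float("nan")
    mask = AncestrySets.mask_for(np.flatnonzero(founder_types == TYPE1), ancestry.n0)
    frac = ancestry.intersection_sizes(mask) / ancestry.set_sizes()
    return float(frac[sel].mean())


def pairwise_shared_ancestor_fraction(ancestry: AncestrySets, sample_pairs: int,
                                      rng: np.random.Generator) -> float:
    """Mean Jaccard overlap |S_i ∩ S_j| / |S_i ∪ S_j| over random distinct pairs."""
    n = ancestry.n
    if n < 2:
        raise ValueError("need at least two individuals to sample pairs")
    i = rng.integers(0, n, size=sample_pairs)
    j = (i + 1 + rng.integers(0, n - 1, size=sample_pairs)) % n
    inter = np.bitwise_count(ancestry.bits[i] & ancestry.bits[j]).sum(axis=1)
    union = np.bitwise_count(ancestry.bits[i] | ancestry.bits[j]).sum(axis=1)
    return float((inter / union).mean())


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    """Invalid scenario configuration; message lists the offending fields."""


@dataclass
class ScenarioConfig:
    """Full description of one simulation scenario.

    Exactly one of ``alpha`` / ``odds`` must be supplied; ``odds`` is
    converted with :func:`alpha_from_odds` under ``odds_mapping``.
    """

    n0: int = 1000
    n_final: Optional[int] = None
    generations: int = 20
    x0: float = 0.2
    alpha: Optional[float] = None
    odds: Optional[float] = None
    odds_mapping: str = "suppression"
    seed: int = 0
    replicates: int = 1
    growth: str = "constant"
    track_pedigree: bool = False
    track_ancestry: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.n_final is None:
            self.n_final = self.n0
        self.validate()

    def validate(self) -> None:
        bad: list[str] = []
        if (self.alpha is None) == (self.odds is None):
            bad.append("exactly one of alpha/odds must be set")
        if self.alpha is not None and not 0.0 <= self.alpha <= 1.0:
            bad.append(f"alpha={self.alpha} outside [0, 1]")
        if self.odds is not None and self.odds < 1.0:
            bad.append(f"odds={self.odds} must be >= 1")
        if not 0.0 <= self.x0 <= 1.0:
            bad.append(f"x0={self.x0} outside [0, 1]")
        if self.n0 < 2:
            bad.append(f"n0={self.n0} must be >= 2")
        if self.n_final is not None and self.n_final < 2:
            bad.append(f"n_final={self.n_final} must be >= 2")
        if self.generations < 1:
            bad.append(f"generations={self.generations} must be >= 1")
        if self.replicates < 1:
            bad.append(f"replicates={self.replicates} must be >= 1")
        if self.growth not in ("constant", "geometric"):
            bad.append(f"growth={self.growth!r} not in {{constant, geometric}}")
        if self.growth == "constant" and self.n_final not in (None, self.n0):
            bad.append("constant growth requires n_final == n0")
        if self.odds_mapping not in ("suppression", "conditional"):
            bad.append(f"odds_mapping={self.odds_mapping!r} unknown")
        if self.track_ancestry and self.n0 > MAX_TRACKED_FOUNDERS:
            bad.append(
                f"track_ancestry requires n0 <= {MAX_TRACKED_FOUNDERS} (got {self.n0})")
        if bad:
            raise ConfigError("invalid scenario config: " + "; ".join(bad))

    def resolved_alpha(self) -> float:
        if self.alpha is not None:
            return float(self.alpha)
        return alpha_from_odds(float(self.odds), mapping=self.odds_mapping,
                               x_ref=self.x0 if 0.0 < self.x0 < 1.0 else 0.5)

    def schedule(self) -> GrowthSchedule:
        return GrowthSchedule(n0=self.n0, n_final=int(self.n_final),
                              T=self.generations, mode=self.growth)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["resolved_alpha"] = self.resolved_alpha()
        return d

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)


PRESETS = {
    # Small constant population suitable for full-pedigree output and
    # ancestor-line rendering (20% type-1 founders).
    "fig1": dict(n0=50, n_final=50, generations=10, x0=0.2, alpha=0.9,
                 growth="constant", seed=1, track_pedigree=True,
                 track_ancestry=True,
                 note="small constant population, full pedigree recorded"),
    # Large constant population for theory-vs-simulation comparison with
    # strong (but not exclusive) in-group preference; sweep other alpha
    # values with the `sweep`/`compare` commands.
    "fig2": dict(n0=100_000, n_final=100_000, generations=20, x0=0.2,
                 alpha=0.9, growth="constant", seed=1,
                 note="constant large population, strong preference"),
    # Sephardic/Ashkenazi scenario: 20% type-1 founders in 1492, 1000:1
    # in-group:out-group mating odds, ~20 generations to the present,
    # growing population.  Population sizes are desk-scale stand-ins and
    # are config-overridable.
    "sephardic1492": dict(n0=10_000, n_final=100_000, generations=20, x0=0.2,
                          odds=1000.0, growth="geometric", seed=1492,
                          note="stand-in population sizes 1e4 -> 1e5"),
}


def preset_scenario(name: str) -> ScenarioConfig:
    """Return a named preset scenario configuration."""
    try:
        kwargs = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available presets: "
            + ", ".join(sorted(PRESETS))) from None
    return ScenarioConfig(**kwargs)


def load_config(path: Union[str, Path]) -> ScenarioConfig:
    """Load a scenario from a flat key-value (YAML) config file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a key-value mapping")
    known = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError("unknown config keys: " + ", ".join(sorted(unknown)))
    return ScenarioConfig(**data)


# ---------------------------------------------------------------------------
# Full simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Everything recorded from one simulation run."""

    config: ScenarioConfig
    seed: int
    states: list[PopulationState]
    pedigree: Optional[list[PedigreeLayer]]
    ancestry: Optional[list[AncestrySets]]
    summary: pd.DataFrame  # per-generation observables

    @property
    def T(self) -> int:
        return len(self.states) - 1

    def final_state(self) -> PopulationState:
        return self.states[-1]


def _summarize(states: list[PopulationState],
               ancestry: Optional[list[AncestrySets]],
               founder_types: Optional[np.ndarray]) -> pd.DataFrame:
    rows = []
    for st in states:
        n = st.n
        n1 = int(np.count_nonzero(st.tau == TYPE1))
        n2 = n - n1
        ng1 = int(np.count_nonzero(st.g))
        n2_g0 = int(np.count_nonzero((st.tau == TYPE2) & ~st.g))
        row = {
            "t": st.t,
            "n": n,
            "count_type1": n1,
            "x": n1 / n,
            "count_g1": ng1,
            "F_sim": ng1 / n,
            "q_sim": (n2_g0 / n2) if n2 > 0 else float("nan"),
            "A1_type1": float("nan"),
            "A1_type2": float("nan"),
        }
        if ancestry is not None:
            row["A1_type1"] = ancestor_type1_fraction(
                ancestry[st.t], founder_types, st, TYPE1)
            row["A1_type2"] = ancestor_type1_fraction(
                ancestry[st.t], founder_types, st, TYPE2)
        rows.append(row)
    return pd.DataFrame(rows)


def simulate(config: ScenarioConfig,
             rng: Optional[np.random.Generator] = None) -> SimulationResult:
    """Run one forward simulation of the configured scenario.

    Generation 0 has round(x0*n0) type-1 founders (g=True) and the rest
    type-2 (g=False); each subsequent generation is drawn with
    :func:`next_generation` at the size given by the growth schedule.
    Identical seed and config give a bit-identical result.
    """
    config.validate()
    seed = int(config.seed)
    if rng is None:
        rng = np.random.default_rng(seed)
    model = MatingModel(alpha=config.resolved_alpha())
    sizes = config.schedule().sizes()

    track = config.track_pedigree or config.track_ancestry
    state = initial_population(config.n0, config.x0)
    states = [state]
    pedigree: Optional[list[PedigreeLayer]] = [] if track else None
    for t in range(config.generations):
        state, layer = next_generation(state, model, int(sizes[t + 1]), rng)
        states.append(state)
        if pedigree is not None:
            pedigree.append(layer)

    ancestry = None
    founder_types = states[0].tau
    if config.track_ancestry:
        ancestry = founder_ancestor_sets(pedigree, config.n0)

    summary = _summarize(states, ancestry, founder_types)
    if not config.track_pedigree:
        pedigree = None
    return SimulationResult(config=config, seed=seed, states=states,
                            pedigree=pedigree, ancestry=ancestry,
                            summary=summary)


def first_passage_generation(result: SimulationResult) -> Optional[int]:
    """Smallest generation at which every individual has a type-1 ancestor
    (g=True for all), or None if never reached."""
    s = result.summary
    hit = s.index[s["count_g1"] == s["n"]]
    return int(s.loc[hit[0], "t"]) if len(hit) else None


# ---------------------------------------------------------------------------
# Deterministic theory: the q recursion and its closed form
# ---------------------------------------------------------------------------

def contraction_constant(x0: float, alpha: float) -> float:
    """Per-generation contraction c = p22(x0, alpha)/(1 - x0) = alpha + (1-alpha)(1-x0).

    Of the type-2 children of two type-2 parents, only those whose
    parents both lack type-1 ancestors lack one themselves; with the
    type-1 fraction held at x0, that conditional thinning contributes
    one factor of q per parent, giving q(t+1) = c * q(t)**2.
    """
    if not 0.0 <= x0 <= 1.0 or not 0.0 <= alpha <= 1.0:
        raise ValueError("x0 and alpha must be in [0, 1]")
    if x0 == 1.0:
        raise ValueError("x0=1 leaves no type-2 subpopulation; c is undefined")
    return alpha + (1.0 - alpha) * (1.0 - x0)


def q_trajectory(x0: float, alpha: float, T: int) -> np.ndarray:
    """q(0..T) by iterating q(t+1) = c*q(t)^2 in the log domain.

    q(t) is the fraction of type-2 individuals with no type-1 ancestor;
    q(0) = 1.  Values below 1e-300 are reported as exactly 0.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    c = contraction_constant(x0, alpha)
    logc = math.log(c)
    logq = np.empty(T + 1)
    logq[0] = 0.0
    for t in range(T):
        logq[t + 1] = logc + 2.0 * logq[t]
    with np.errstate(under="ignore"):
        q = np.exp(logq)
    q[q < Q_UNDERFLOW] = 0.0
    return q


def q_closed_form(x0: float, alpha: float, t: int) -> float:
    """Closed form q(t) = c**(2**t - 1), evaluated in the log domain."""
    c = contraction_constant(x0, alpha)
    logq = (2 ** t - 1) * math.log(c)
    if logq < math.log(Q_UNDERFLOW):
        return 0.0
    return math.exp(logq)


def fraction_with_type1_ancestor(x0: float, alpha: float, T: int) -> np.ndarray:
    """F(0..T) = 1 - (1 - x0) * q(t): fraction with at least one type-1 ancestor."""
    return 1.0 - (1.0 - x0) * q_trajectory(x0, alpha, T)


@dataclass
class TheoryTrajectory:
    """Deterministic trajectory of the genealogical-identity recursion."""

    x0: float
    alpha: float
    T: int
    c: float
    q: np.ndarray
    F: np.ndarray
    state_probs: pd.DataFrame  # columns p11_state, p20_state, p21_state

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t": np.arange(self.T + 1), "q": self.q, "F": self.F})
        return pd.concat([df, self.state_probs.reset_index(drop=True)], axis=1)


def theory_trajectory(x0: float, alpha: float, T: int) -> TheoryTrajectory:
    """Build the full deterministic trajectory (q, F, and state probabilities).

    State probabilities (type, g): p(1,1) = x0 (constant), p(2,0) =
    (1-x0) q(t), p(2,1) = (1-x0)(1-q(t)); they sum to 1 every
    generation.
    """
    q = q_trajectory(x0, alpha, T)
    F = 1.0 - (1.0 - x0) * q
    state_probs = pd.DataFrame({
        "p11_state": np.full(T + 1, x0),
        "p20_state": (1.0 - x0) * q,
        "p21_state": (1.0 - x0) * (1.0 - q),
    })
    return TheoryTrajectory(x0=x0, alpha=alpha, T=T,
                            c=contraction_constant(x0, alpha),
                            q=q, F=F, state_probs=state_probs)


def compare_theory_sim(result: SimulationResult,
                       theory: TheoryTrajectory) -> pd.DataFrame:
    """Per-generation |F_sim(t) - F_theory(t)| deviation table."""
    s = result.summary
    if len(s) != theory.T + 1:
        raise ValueError(
            f"length mismatch: simulation has {len(s)} generations, "
            f"theory has {theory.T + 1}")
    df = pd.DataFrame({
        "t": s["t"].to_numpy(),
        "F_sim": s["F_sim"].to_numpy(),
        "F_theory": theory.F,
    })
    df["abs_dev"] = np.abs(df["F_sim"] - df["F_theory"])
    return df


def theory_first_passage(x0: float, alpha: float,
                         sizes: np.ndarray) -> Optional[int]:
    """Deterministic analogue of the all-individuals event: smallest t with
    F(t) >= 1 - 1/((1-x0) n(t)), i.e. expected count of g=False below one."""
    if x0 >= 1.0:
        return 0
    T = len(sizes) - 1
    F = fraction_with_type1_ancestor(x0, alpha, T)
    for t in range(T + 1):
        if F[t] >= 1.0 - 1.0 / ((1.0 - x0) * sizes[t]):
            return t
    return None


def sweep_first_passage(x0s: Sequence[float], alphas: Sequence[float], T: int,
                        threshold: float = 0.999) -> pd.DataFrame:
    """Grid over (x0, alpha): first generation with F_theory >= threshold.

    Long-format table with NaN where the threshold is not reached by T.
    """
    rows = []
    for x0 in x0s:
        for alpha in alphas:
            F = fraction_with_type1_ancestor(x0, alpha, T)
            hit = np.flatnonzero(F >= threshold)
            rows.append({"x0": x0, "alpha": alpha,
                         "first_t": int(hit[0]) if hit.size else float("nan")})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Writers: summary table, pedigree TSV, PLINK-style .fam
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = ["t", "n", "count_type1", "x", "count_g1", "F_sim", "q_sim",
                   "F_theory", "q_theory", "A1_type1", "A1_type2"]


def _config_header(config: ScenarioConfig) -> str:
    lines = [f"# {key}: {value}" for key, value in config.to_dict().items()]
    sizes = ",".join(str(int(v)) for v in config.schedule().sizes())
    lines.append(f"# population_sizes: {sizes}")
    return "\n".join(lines) + "\n"


def write_summary(result: SimulationResult, theory: TheoryTrajectory,
                  path: Union[str, Path]) -> None:
    """Write the per-generation summary as TSV with a config-echo comment header."""
    if theory.T != result.T:
        raise ValueError("result and theory must share the same T")
    df = result.summary.copy()
    df["F_theory"] = theory.F
    df["q_theory"] = theory.q
    df = df[SUMMARY_COLUMNS]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_config_header(result.config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g",
                  lineterminator="\n")


def read_summary(path: Union[str, Path]) -> tuple[pd.DataFrame, dict]:
    """Read a summary TSV; returns (table, parsed config-echo header)."""
    header: dict[str, str] = {}
    body = io.StringIO()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                header[key.strip()] = value.strip()
            else:
                body.write(line)
    body.seek(0)
    return pd.read_csv(body, sep="\t"), header


def write_pedigree(result: SimulationResult, path: Union[str, Path]) -> None:
    """Write the recorded pedigree as TSV.

    One row per individual: generation, index within generation,
    parent1 index, parent2 index ("." for founders), type (1|2), g
    (0|1).  Parent indices are validated against the previous
    generation on write.
    """
    if result.pedigree is None:
        raise ValueError(
            "pedigree was not recorded; re-run with track_pedigree=True")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_config_header(result.config))
        fh.write("generation\tindividual\tparent1\tparent2\ttype\tg\n")
        for st in result.states:
            if st.t == 0:
                p1 = p2 = ["."] * st.n
            else:
                layer = result.pedigree[st.t - 1]
                layer.validate(result.states[st.t - 1].n)
                p1 = layer.parent1.tolist()
                p2 = layer.parent2.tolist()
            for i in range(st.n):
                fh.write(f"{st.t}\t{i}\t{p1[i]}\t{p2[i]}\t"
                         f"{int(st.tau[i])}\t{int(st.g[i])}\n")


def write_fam(result: SimulationResult, path: Union[str, Path]) -> None:
    """PLINK-style .fam export of the recorded pedigree.

    Columns: family ID (generation tag), individual ID g<t>_i<k>,
    father ID, mother ID (0 for founders), sex 0 (the model is
    sexless), phenotype = type.  The two parent slots are arbitrarily
    assigned to the father/mother columns.
    """
    if result.pedigree is None:
        raise ValueError(
            "pedigree was not recorded; re-run with track_pedigree=True")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for st in result.states:
            for i in range(st.n):
                if st.t == 0:
                    pa = ma = "0"
                else:
                    layer = result.pedigree[st.t - 1]
                    pa = f"g{st.t - 1}_i{int(layer.parent1[i])}"
                    ma = f"g{st.t - 1}_i{int(layer.parent2[i])}"
                fh.write(f"g{st.t} g{st.t}_i{i} {pa} {ma} 0 {int(st.tau[i])}\n")
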