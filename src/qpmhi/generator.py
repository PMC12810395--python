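"""Stage 1: surrogate-guided genetic proposal of candidate molecules.

Each optimization iteration builds a *fresh* pool of N valid, filtered,
deduplicated candidates by running a small genetic algorithm over the
robust token encoding (see :mod:`qpmhi.encoding`): point mutations and
single-point crossovers of token sequences, with a fitness that balances
exploitation (weighted sum of per-objective posterior means, with weights
resampled on the simplex every generation to diversify trade-off
pressure) and exploration (posterior standard deviation, weighted by β).

Every valid, filter-passing individual ever created is accumulated, so the
pool mixes all generations; already-labeled molecules are excluded.  The
whole procedure is a deterministic function of (seed, labeled data, model
state).
"""

from __future__ import annotations

import logging
import os
import sys
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem

from . import encoding
from .surrogate import SurrogateModel

logger = logging.getLogger(__name__)

__all__ = [
    "Candidate",
    "FilterSpec",
    "GAConfig",
    "sa_score",
    "mutate",
    "crossover",
    "fitness",
    "generate_pool",
]


@dataclass(frozen=True)
class Candidate:
    """One pool member: canonical SMILES plus provenance."""

    smiles: str
    provenance: str = "seed"  # seed | mutation | crossover | random


_SASCORER = None
_SASCORER_FAILED = False


def _load_sascorer():
    """RDKit contrib Ertl–Schuffenhauer synthetic-accessibility scorer."""
    global _SASCORER, _SASCORER_FAILED
    if _SASCORER is None and not _SASCORER_FAILED:
        try:
            from rdkit.Chem import RDConfig

            path = os.path.join(RDConfig.RDContribDir, "SA_Score")
            if path not in sys.path:
                sys.path.append(path)
            import sascorer  # type: ignore

            _SASCORER = sascorer
        except Exception:
            _SASCORER_FAILED = True
            logger.warning(
                "Ertl–Schuffenhauer SA scorer unavailable; falling back to the "
                "ring-count + size heuristic"
            )
    return _SASCORER


def _heuristic_sa(mol) -> float:
    """Cheap synthetic-accessibility stand-in: bigger and ringier is harder."""
    from rdkit.Chem import rdMolDescriptors

    heavy = mol.GetNumHeavyAtoms()
    rings = rdMolDescriptors.CalcNumRings(mol)
    spiro = rdMolDescriptors.CalcNumSpiroAtoms(mol)
    bridge = rdMolDescriptors.CalcNumBridgeheadAtoms(mol)
    score = 1.0 + 0.06 * heavy + 0.35 * rings + 1.0 * (spiro + bridge)
    return float(np.clip(score, 1.0, 10.0))


def sa_score(smiles: str, method: str = "auto") -> float:
    """Synthetic-accessibility score in [1, 10] (lower = easier).

    ``method``: 'ertl' (fragment-contribution score), 'heuristic'
    (ring-count + size), or 'auto' (ertl when available, else heuristic).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    if method not in ("auto", "ertl", "heuristic"):
        raise ValueError(f"unknown SA method {method!r}")
    if method in ("auto", "ertl"):
        scorer = _load_sascorer()
        if scorer is not None:
            return float(scorer.calculateScore(mol))
        if method == "ertl":
            raise RuntimeError("Ertl SA scorer requested but unavailable")
    return _heuristic_sa(mol)


@dataclass(frozen=True)
class FilterSpec:
    """Hard feasibility filters applied to every generated candidate."""

    max_smiles_length: int = 108
    max_sa_score: float = 8.0
    substructure_required: str | None = None
    sa_method: str = "auto"
    custom: tuple[Callable[[str], bool], ...] = ()

    def passes(self, smiles: str) -> bool:
        if len(smiles) > self.max_smiles_length:
            return False
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return False
        if sa_score(smiles, self.sa_method) > self.max_sa_score:
            return False
        if self.substructure_required is not None:
            patt = Chem.MolFromSmarts(self.substructure_required)
            if patt is None or not mol.HasSubstructMatch(patt):
                return False
        return all(pred(smiles) for pred in self.custom)


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 60
    generations: int = 25
    mutation_rate: float = 0.9
    crossover_rate: float = 0.4
    elite_fraction: float = 0.2
    beta: float = 1.0  # exploration weight on posterior sd
    pool_target: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "crossover_rate", "elite_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.pool_target < 1:
            raise ValueError("pool_target must be positive")


def mutate(smiles: str, rng: np.random.Generator, mutation_rate: float = 1.0) -> str | None:
    """Single random token edit (insert/delete/substitute) on the encoding.

    Returns the child's canonical SMILES, the parent unchanged when the
    mutation-rate coin fails, or None when the parent cannot be encoded or
    the edit decodes to nothing.  Filter rejection is handled by callers.
    """
    if rng.random() >= mutation_rate:
        return Chem.CanonSmiles(smiles)
    tokens = encoding.encode(smiles)
    if tokens is None:
        return None
    tokens = list(tokens)
    op = rng.choice(["insert", "delete", "substitute"])
    alphabet = encoding.MUTATION_ALPHABET
    if op == "insert" or not tokens:
        pos = int(rng.integers(0, len(tokens) + 1))
        tokens.insert(pos, alphabet[int(rng.integers(len(alphabet)))])
    elif op == "delete":
        tokens.pop(int(rng.integers(len(tokens))))
    else:
        pos = int(rng.integers(len(tokens)))
        tokens[pos] = alphabet[int(rng.integers(len(alphabet)))]
    return encoding.decode(tokens)


def crossover(a: str, b: str, rng: np.random.Generator) -> str | None:
    """Single-point recombination of two token encodings.

    One split fraction is drawn and applied to both parents, so crossing a
    molecule with itself reproduces it exactly.
    """
    ta = encoding.encode(a)
    tb = encoding.encode(b)
    if ta is None or tb is None:
        return None
    frac = rng.random()
    i = int(round(frac * len(ta)))
    j = int(round(frac * len(tb)))
    child = list(ta[:i]) + list(tb[j:])
    if not child:
        return None
    return encoding.decode(child)


def fitness(
    smiles_list: Sequence[str],
    model: SurrogateModel,
    featurizer: Callable[[Sequence[str]], np.ndarray],
    weights: np.ndarray,
    beta: float,
) -> np.ndarray:
    """GA fitness: weighted posterior means plus β × mean posterior sd.

    Means and sds are used on the standardized objective scale so that the
    simplex weights are commensurable across objectives.
    """
    X = featurizer(list(smiles_list))
    mean, sd = model.predict(X, return_std=True)
    mean_s = (mean - model.y_mean) / model.y_std
    sd_s = sd / model.y_std
    weights = np.asarray(weights, dtype=float)
    return mean_s @ weights + beta * sd_s.mean(axis=1)


def generate_pool(
    seeds: Sequence[str],
    model: SurrogateModel,
    cfg: GAConfig,
    filters: FilterSpec,
    featurizer: Callable[[Sequence[str]], np.ndarray],
    exclude: Sequence[str] = (),
) -> list[Candidate]:
    """Run the GA and return up to ``cfg.pool_target`` fresh candidates.

    The population is initialized half from the top-fitness labeled seeds
    and half uniformly at random from the labeled set.  Every valid,
    filter-passing, previously-unseen individual created in any generation
    is accumulated; the GA stops as soon as the target is reached or the
    generation budget runs out (returning fewer with a warning).
    """
    if not seeds:
        raise ValueError("need a nonempty seed set")
    rng = np.random.default_rng(cfg.seed)
    seeds = [Chem.CanonSmiles(s) for s in seeds]
    excluded = set(seeds) | {Chem.CanonSmiles(s) for s in exclude}
    m = model.m

    fit0 = fitness(seeds, model, featurizer, np.full(m, 1.0 / m), cfg.beta)
    order = np.argsort(-fit0)
    half = cfg.population_size // 2
    top = [seeds[i] for i in order[:half]]
    rand = [seeds[i] for i in rng.integers(0, len(seeds), cfg.population_size - len(top))]
    population = top + rand

    pool: dict[str, Candidate] = {}

    def consider(smi: str | None, provenance: str) -> str | None:
        if smi is None:
            return None
        if smi not in excluded and smi not in pool and filters.passes(smi):
            pool[smi] = Candidate(smiles=smi, provenance=provenance)
        return smi

    n_elite = max(1, int(round(cfg.elite_fraction * cfg.population_size)))
    for _ in range(cfg.generations):
        if len(pool) >= cfg.pool_target:
            break
        # resample trade-off weights each generation (uniform on the simplex)
        weights = rng.dirichlet(np.ones(m))
        scores = fitness(population, model, featurizer, weights, cfg.beta)
        order = np.argsort(-scores)
        elites = [population[i] for i in order[:n_elite]]
        children: list[str] = list(elites)
        while len(children) < cfg.population_size:
            if rng.random() < cfg.crossover_rate and len(population) >= 2:
                i, j = rng.integers(0, len(population), 2)
                child = consider(crossover(population[i], population[j], rng), "crossover")
            else:
                i = int(rng.integers(len(population)))
                child = consider(mutate(population[i], rng, cfg.mutation_rate), "mutation")
            if child is not None and Chem.MolFromSmiles(child) is not None:
                children.append(child)
            else:
                # fall back to a random seed so the population never shrinks
                children.append(seeds[int(rng.integers(len(seeds)))])
        population = children

    if not pool:
        raise RuntimeError("generator produced zero valid candidates")
    out = list(pool.values())[: cfg.pool_target]
    if len(out) < cfg.pool_target:
        logger.warning(
            "generation budget exhausted with %d/%d pool candidates",
            len(out),
            cfg.pool_target,
        )
    return out
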