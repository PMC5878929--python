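"""Synthetic microsatellite-like datasets with controllable differentiation.

Genotypes are generated under the Balding-Nichols island model: ancestral
allele frequencies at each locus are Dirichlet-distributed, each
population's frequencies are drawn from ``Dirichlet(p (1 - F) / F)`` so
that the expected standardised variance among populations equals ``F``,
and individuals carry two independent allele draws per locus
(Hardy-Weinberg and linkage equilibrium).  The model is parameterised by
the very quantity (F_ST) that drives assignment power, which makes it the
natural generator for panel power studies; microsatellite realism is
limited to allele-count ranges (no stepwise mutation model -- the
assignment math only consumes frequencies).

``simulate_starling_like`` provides the default study conditions: three
populations of 30/32/32 individuals typed at 29 loci, with one population
genetically distant (pairwise theta near 0.08) and the other two close
(near 0.026), arranged through a two-level hierarchical F.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype_io import GenotypeTable

# Default hierarchical F for the starling-like preset.  With population A
# drawn from the ancestor at F_a, and populations B, C drawn from a shared
# cluster (itself at F_cluster from the ancestor) at F_within, pairwise
# theta expectations are approximately (F_a + F_cluster + F_within)/2 for
# A-B and A-C, and F_within for B-C.
STARLING_F_DISTANT = 0.069
STARLING_F_CLUSTER = 0.069
STARLING_F_WITHIN = 0.026
STARLING_SIZES = {"Munglinup": 30, "Mallala": 32, "Orange": 32}
STARLING_N_LOCI = 29


@dataclass
class SimulationConfig:
    """Parameters of a flat (single-F) Balding-Nichols simulation."""

    n_populations: int = 3
    individuals_per_population: int | Sequence[int] = 30
    n_loci: int = 29
    min_alleles: int = 2
    max_alleles: int = 20
    fst: float | Sequence[float] = 0.05
    ancestral_concentration: float = 1.0
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        fs = np.atleast_1d(np.asarray(self.fst, dtype=float))
        if np.any((fs <= 0) | (fs >= 1)):
            raise ValueError("fst must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_populations < 1 or self.n_loci < 1:
            raise ValueError("counts must be >= 1")
        if not 2 <= self.min_alleles <= self.max_alleles:
            raise ValueError("need 2 <= min_alleles <= max_alleles")

    def sizes(self) -> list[int]:
        if np.isscalar(self.individuals_per_population):
            return [int(self.individuals_per_population)] * self.n_populations
        sizes = [int(x) for x in self.individuals_per_population]
        if len(sizes) != self.n_populations:
            raise ValueError("one size per population required")
        return sizes

    def per_locus_fst(self) -> np.ndarray:
        fs = np.atleast_1d(np.asarray(self.fst, dtype=float))
        if fs.size == 1:
            return np.repeat(fs, self.n_loci)
        if fs.size != self.n_loci:
            raise ValueError("fst must be scalar or one value per locus")
        return fs


@dataclass
class SimulationTruth:
    """Latent state of a simulated dataset: population frequencies per locus
    (aligned to allele codes 1..k) and the ground truth for any planted
    dispersers (individual id -> true source population)."""

    populations: list[str]
    n_alleles: list[int]
    frequencies: dict[str, list[np.ndarray]]
    planted: dict[str, tuple[str, str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "populations": self.populations,
            "n_alleles": self.n_alleles,
            "frequencies": {
                pop: [f.tolist() for f in per_locus]
                for pop, per_locus in self.frequencies.items()
            },
            "planted": {
                ind: list(v) for ind, v in self.planted.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _bn_frequencies(
    base: np.ndarray, f: float, rng: np.random.Generator
) -> np.ndarray:
    """One Balding-Nichols draw around ``base`` with parameter ``f``."""
    alpha = np.maximum(base, 1e-9) * (1.0 - f) / f
    return rng.dirichlet(alpha)


def _draw_genotypes(
    freqs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, 2) allele codes (1-based) from one frequency vector."""
    cum = np.cumsum(freqs)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random((n, 2))) + 1


def _assemble_table(
    pop_names: list[str],
    sizes: list[int],
    freqs: dict[str, list[np.ndarray]],
    n_loci: int,
    missing_rate: float,
    rng: np.random.Generator,
    metadata: dict,
) -> GenotypeTable:
    ids: list[str] = []
    labels: list[str] = []
    blocks: list[np.ndarray] = []
    for pop, size in zip(pop_names, sizes):
        geno = np.zeros((size, n_loci, 2), dtype=np.int64)
        for l in range(n_loci):
            geno[:, l, :] = _draw_genotypes(freqs[pop][l], size, rng)
        if missing_rate > 0:
            miss = rng.random((size, n_loci)) < missing_rate
            geno[miss] = 0
        blocks.append(geno)
        ids.extend(f"{pop}_{i + 1:03d}" for i in range(size))
        labels.extend([pop] * size)
    return GenotypeTable(
        individual_ids=ids,
        population_labels=labels,
        locus_names=[f"L{l + 1:02d}" for l in range(n_loci)],
        alleles=np.concatenate(blocks, axis=0),
        metadata=metadata,
    )


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeTable, SimulationTruth]:
    """Simulate a flat Balding-Nichols dataset.

    Reproducible under ``config.seed``.  A locus whose realised sample is
    monomorphic across all populations (possible at small k and strong
    drift) is redrawn, so every emitted locus is polymorphic.
    """
    rng = np.random.default_rng(config.seed)
    pop_names = [f"pop{i + 1}" for i in range(config.n_populations)]
    sizes = config.sizes()
    fs = config.per_locus_fst()
    n_alleles: list[int] = []
    freqs: dict[str, list[np.ndarray]] = {p: [] for p in pop_names}
    # latent frequencies per locus, redrawing until sample polymorphism is
    # guaranteed possible (at least two alleles with non-negligible mass)
    for l in range(config.n_loci):
        for _ in range(100):
            k = int(rng.integers(config.min_alleles, config.max_alleles + 1))
            base = rng.dirichlet(
                np.full(k, config.ancestral_concentration)
            )
            per_pop = [_bn_frequencies(base, fs[l], rng) for _ in pop_names]
            # require expected polymorphism: pooled minor-allele mass > 0.02
            pooled = np.mean(per_pop, axis=0)
            if 1.0 - pooled.max() > 0.02:
                break
        n_alleles.append(k)
        for p, f in zip(pop_names, per_pop):
            freqs[p].append(f)
    table = _assemble_table(
        pop_names,
        sizes,
        freqs,
        config.n_loci,
        config.missing_rate,
        rng,
        metadata={"generator": "balding-nichols", "seed": config.seed},
    )
    truth = SimulationTruth(
        populations=pop_names, n_alleles=n_alleles, frequencies=freqs
    )
    return table, truth


def simulate_starling_like(
    seed: int = 0,
    missing_rate: float = 0.01,
    min_alleles: int = 2,
    max_alleles: int = 20,
) -> tuple[GenotypeTable, SimulationTruth]:
    """Simulate the default study conditions: 3 populations (30/32/32
    individuals) x 29 microsatellite loci, one distant population and a
    close pair, via a two-level hierarchical Balding-Nichols model.

    Pairwise theta is expected near 0.08 for the distant pairs and near
    0.026 within the close pair.
    """
    rng = np.random.default_rng(seed)
    pop_names = list(STARLING_SIZES)
    distant = pop_names[0]  # Munglinup analogue
    close = pop_names[1:]
    n_loci = STARLING_N_LOCI
    n_alleles: list[int] = []
    freqs: dict[str, list[np.ndarray]] = {p: [] for p in pop_names}
    for l in range(n_loci):
        for _ in range(100):
            k = int(rng.integers(min_alleles, max_alleles + 1))
            base = rng.dirichlet(np.ones(k))
            f_distant = _bn_frequencies(base, STARLING_F_DISTANT, rng)
            cluster = _bn_frequencies(base, STARLING_F_CLUSTER, rng)
            f_close = [
                _bn_frequencies(cluster, STARLING_F_WITHIN, rng)
                for _ in close
            ]
            pooled = np.mean([f_distant] + f_close, axis=0)
            if 1.0 - pooled.max() > 0.02:
                break
        n_alleles.append(k)
        freqs[distant].append(f_distant)
        for p, f in zip(close, f_close):
            freqs[p].append(f)
    sizes = [STARLING_SIZES[p] for p in pop_names]
    table = _assemble_table(
        pop_names,
        sizes,
        freqs,
        n_loci,
        missing_rate,
        rng,
        metadata={"generator": "starling-like", "seed": seed},
    )
    truth = SimulationTruth(
        populations=pop_names, n_alleles=n_alleles, frequencies=freqs
    )
    return table, truth


def plant_dispersers(
    table: GenotypeTable,
    truth: SimulationTruth,
    plan: Sequence[tuple[str, str, int]],
    seed: int = 0,
) -> tuple[GenotypeTable, SimulationTruth]:
    """Append true dispersers: individuals whose genotype is drawn from one
    population's latent frequencies but who are labelled with another.

    ``plan`` entries are ``(source_population, labelled_population, count)``
    with source != label.  Planted ids are recorded in
    ``truth.planted[id] = (source, label)``.
    """
    for source, label, _ in plan:
        for p in (source, label):
            if p not in truth.populations:
                raise KeyError(f"unknown population {p!r}")
        if source == label:
            raise ValueError("planted dispersers must have source != label")
    rng = np.random.default_rng(seed)
    n_loci = table.n_loci
    new_ids: list[str] = []
    new_labels: list[str] = []
    new_geno: list[np.ndarray] = []
    planted = dict(truth.planted)
    counter = len(planted)
    for source, label, count in plan:
        for _ in range(count):
            counter += 1
            ind = f"disperser_{counter:03d}"
            geno = np.zeros((n_loci, 2), dtype=np.int64)
            for l in range(n_loci):
                geno[l] = _draw_genotypes(
                    truth.frequencies[source][l], 1, rng
                )[0]
            new_ids.append(ind)
            new_labels.append(label)
            new_geno.append(geno)
            planted[ind] = (source, label)
    if not new_ids:
        return table, truth
    out = GenotypeTable(
        individual_ids=list(table.individual_ids) + new_ids,
        population_labels=list(table.population_labels) + new_labels,
        locus_names=list(table.locus_names),
        alleles=np.concatenate(
            [table.alleles, np.stack(new_geno, axis=0)], axis=0
        ),
        metadata=dict(table.metadata),
    )
    new_truth = SimulationTruth(
        populations=list(truth.populations),
        n_alleles=list(truth.n_alleles),
        frequencies=truth.frequencies,
        planted=planted,
    )
    return out, new_truth
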