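"""Genotype containers and file formats.

The canonical in-memory object is :class:`GenotypeTable`: a rectangular
individuals x loci array of diploid genotypes with a population label per
individual.  Allele codes are opaque non-negative integers (no base-pair
size semantics); code 0 is reserved for missing data, and a genotype is
either fully called (both alleles > 0) or fully missing -- a half-call is
coerced to missing on construction, the conservative reading used by most
assignment software.

Two formats are supported: GENEPOP (2- or 3-digit encoding, the de-facto
interchange format for co-dominant microsatellite data) and a flat table
with one row per individual and two columns per locus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = 0


class GenotypeParseError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class GenotypeTable:
    """Diploid multi-locus genotypes with population labels.

    Parameters
    ----------
    individual_ids
        Unique identifier per individual.
    population_labels
        Population label per individual (same length as ``individual_ids``).
    locus_names
        Unique locus names, in column order.
    alleles
        Integer array of shape ``(n_individuals, n_loci, 2)``; allele code
        0 means missing.  Half-calls (exactly one allele 0) are coerced to
        fully missing.
    metadata
        Free-form provenance mapping.
    """

    individual_ids: list[str]
    population_labels: list[str]
    locus_names: list[str]
    alleles: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.population_labels = [str(p) for p in self.population_labels]
        self.locus_names = [str(l) for l in self.locus_names]
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n, m = len(self.individual_ids), len(self.locus_names)
        if self.alleles.shape != (n, m, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} does not match "
                f"{n} individuals x {m} loci x 2"
            )
        if len(self.population_labels) != n:
            raise ValueError("one population label required per individual")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        if len(set(self.locus_names)) != m:
            raise ValueError("locus names must be unique")
        if np.any(self.alleles < 0):
            raise ValueError("allele codes must be non-negative")
        # half-call -> fully missing
        half = (self.alleles == MISSING).any(axis=2)
        self.alleles[half] = MISSING

    # -- basic introspection -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.population_labels:
            seen.setdefault(p)
        return list(seen)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci); True where the genotype is missing."""
        return (self.alleles == MISSING).all(axis=2)

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {p: 0 for p in self.populations}
        for p in self.population_labels:
            sizes[p] += 1
        return sizes

    def individuals_in(self, population: str) -> list[str]:
        return [
            i
            for i, p in zip(self.individual_ids, self.population_labels)
            if p == population
        ]

    def index_of(self, individual_id: str) -> int:
        try:
            return self.individual_ids.index(individual_id)
        except ValueError:
            raise KeyError(f"unknown individual id {individual_id!r}") from None

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.individual_ids == other.individual_ids
            and self.population_labels == other.population_labels
            and self.locus_names == other.locus_names
            and np.array_equal(self.alleles, other.alleles)
        )


# ---------------------------------------------------------------------------
# table surgery


def subset(
    table: GenotypeTable,
    loci: Sequence[str] | None = None,
    individuals: Sequence[str] | None = None,
) -> GenotypeTable:
    """Return a new table restricted to the requested loci/individuals.

    The order of ``loci`` is respected in the output (panels are built by
    consecutively adding ranked loci, so order is meaningful); ``individuals``
    likewise.  Unknown names raise ``KeyError``.
    """
    if loci is None:
        loci = list(table.locus_names)
    if individuals is None:
        individuals = list(table.individual_ids)
    locus_index = {name: j for j, name in enumerate(table.locus_names)}
    try:
        lcols = [locus_index[name] for name in loci]
    except KeyError as e:
        raise KeyError(f"unknown locus {e.args[0]!r}") from None
    rows = [table.index_of(i) for i in individuals]
    return GenotypeTable(
        individual_ids=[table.individual_ids[r] for r in rows],
        population_labels=[table.population_labels[r] for r in rows],
        locus_names=list(loci),
        alleles=table.alleles[np.ix_(rows, lcols)].copy(),
        metadata=dict(table.metadata),
    )


def relabel(table: GenotypeTable, moves: Mapping[str, str]) -> GenotypeTable:
    """Return a copy with the mapped individuals assigned new population labels.

    This is how simulated dispersal is implemented: moving an individual
    from A to B means relabelling its sampled population; the genotype is
    untouched.  Target labels must be populations already present in the
    table.
    """
    pops = set(table.populations)
    for ind, target in moves.items():
        table.index_of(ind)  # raises KeyError for unknown individuals
        if target not in pops:
            raise KeyError(f"target population {target!r} not present in table")
    labels = [
        moves.get(ind, lab)
        for ind, lab in zip(table.individual_ids, table.population_labels)
    ]
    return GenotypeTable(
        individual_ids=list(table.individual_ids),
        population_labels=labels,
        locus_names=list(table.locus_names),
        alleles=table.alleles.copy(),
        metadata=dict(table.metadata),
    )


# ---------------------------------------------------------------------------
# GENEPOP format

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(path) -> GenotypeTable:
    """Parse a GENEPOP file (2- or 3-digit allele encoding).

    Populations are delimited by ``POP`` records; a genotype string of all
    zeros is missing.  The separator after the individual id may be a comma
    (standard) or plain whitespace.  Allele digit width is inferred from the
    first genotype and must be consistent across the file.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    title = lines[0].strip()

    # locus names: one per line, or a single comma-separated line
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if not loci:
        raise GenotypeParseError(f"{path}: no locus names before first POP")
    if i >= len(lines):
        raise GenotypeParseError(f"{path}: no POP record found")

    ids: list[str] = []
    labels: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_counter = 0
    pop_label = ""
    members_in_pop = 0
    digits: int | None = None

    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        line = raw.strip()
        if not line:
            continue
        if _POP_RE.match(line):
            if pop_counter > 0 and members_in_pop == 0:
                raise GenotypeParseError(
                    f"{path}:{lineno + 1}: empty population {pop_label!r}"
                )
            pop_counter += 1
            pop_label = f"pop{pop_counter}"
            members_in_pop = 0
            continue
        if "," in line:
            ind_id, _, rest = line.partition(",")
            ind_id = ind_id.strip()
            genostrs = rest.split()
        else:
            parts = line.split()
            ind_id, genostrs = parts[0], parts[1:]
        if not ind_id:
            raise GenotypeParseError(f"{path}:{lineno + 1}: missing individual id")
        if len(genostrs) != len(loci):
            raise GenotypeParseError(
                f"{path}:{lineno + 1}: expected {len(loci)} genotypes, "
                f"got {len(genostrs)}"
            )
        genos: list[tuple[int, int]] = []
        for g in genostrs:
            if not g.isdigit() or len(g) not in (4, 6):
                raise GenotypeParseError(
                    f"{path}:{lineno + 1}: malformed genotype {g!r}"
                )
            width = len(g) // 2
            if digits is None:
                digits = width
            elif width != digits:
                raise GenotypeParseError(
                    f"{path}:{lineno + 1}: inconsistent allele digit width "
                    f"({width} vs {digits})"
                )
            genos.append((int(g[:width]), int(g[width:])))
        ids.append(ind_id)
        labels.append(pop_label)
        rows.append(genos)
        members_in_pop += 1

    if members_in_pop == 0:
        raise GenotypeParseError(f"{path}: last population is empty")
    if len(set(ids)) != len(ids):
        dup = next(x for x in ids if ids.count(x) > 1)
        raise GenotypeParseError(f"{path}: duplicate individual id {dup!r}")

    alleles = np.array(rows, dtype=np.int64).reshape(len(ids), len(loci), 2)
    return GenotypeTable(
        individual_ids=ids,
        population_labels=labels,
        locus_names=loci,
        alleles=alleles,
        metadata={"source": str(path), "format": "genepop", "title": title},
    )


def write_genepop(table: GenotypeTable, path, digits: int = 3) -> None:
    """Write ``table`` as GENEPOP with the given allele digit width.

    Population order is preserved (individuals are grouped by label in
    first-appearance order).  Allele codes must fit in ``digits`` digits.
    """
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    limit = 10**digits
    if int(table.alleles.max(initial=0)) >= limit:
        raise ValueError(
            f"allele code {int(table.alleles.max())} does not fit in "
            f"{digits}-digit encoding"
        )
    with open(path, "w") as fh:
        fh.write(table.metadata.get("title", "sdapower export") + "\n")
        for locus in table.locus_names:
            fh.write(locus + "\n")
        for pop in table.populations:
            fh.write("POP\n")
            for ind in table.individuals_in(pop):
                r = table.index_of(ind)
                genos = " ".join(
                    f"{a:0{digits}d}{b:0{digits}d}" for a, b in table.alleles[r]
                )
                fh.write(f"{ind} , {genos}\n")


# ---------------------------------------------------------------------------
# flat tabular format: id,pop,<locus>_1,<locus>_2,...


def read_table(path) -> GenotypeTable:
    """Read the flat tabular format (CSV/TSV autodetected by pandas).

    Header is ``id,pop`` then two columns per locus named ``<locus>_1`` and
    ``<locus>_2``; missing alleles are empty cells or 0.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={0: str, 1: str})
    cols = list(df.columns)
    if len(cols) < 4 or cols[0].lower() != "id" or cols[1].lower() != "pop":
        raise GenotypeParseError(
            f"{path}: expected header 'id,pop,<locus>_1,<locus>_2,...'"
        )
    allele_cols = cols[2:]
    if len(allele_cols) % 2:
        raise GenotypeParseError(f"{path}: odd number of allele columns")
    loci: list[str] = []
    for c1, c2 in zip(allele_cols[::2], allele_cols[1::2]):
        if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2]):
            raise GenotypeParseError(
                f"{path}: allele columns {c1!r},{c2!r} not paired as _1/_2"
            )
        loci.append(c1[:-2])
    vals = df[allele_cols].fillna(0).to_numpy(dtype=np.int64)
    alleles = vals.reshape(len(df), len(loci), 2)
    return GenotypeTable(
        individual_ids=df[cols[0]].tolist(),
        population_labels=df[cols[1]].tolist(),
        locus_names=loci,
        alleles=alleles,
        metadata={"source": str(path), "format": "table"},
    )


def write_table(table: GenotypeTable, path) -> None:
    """Write the flat tabular format as CSV (missing coded as 0)."""
    data: dict[str, Iterable] = {
        "id": table.individual_ids,
        "pop": table.population_labels,
    }
    for j, locus in enumerate(table.locus_names):
        data[f"{locus}_1"] = table.alleles[:, j, 0]
        data[f"{locus}_2"] = table.alleles[:, j, 1]
    pd.DataFrame(data).to_csv(path, index=False)
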