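"""Simulated Disperser Analysis: the panel power-analysis engine.

The procedure validates a marker panel by artificially "moving" one
candidate individual per population into every possible combination of
populations (k populations with one candidate each give k^k placement
treatments, the no-movement treatment included), rebuilding nested locus
panels ranked by polymorphic information content (PIC) in both directions,
rerunning first-generation migrant detection on every (treatment, panel)
cell, and classifying the outcome for each candidate:

* placed at home, not flagged        -> correct_resident
* placed at home, flagged            -> false_positive
* placed away, flagged, right source -> correct_disperser
* placed away, not flagged           -> false_negative
* placed away, flagged, wrong source -> wrong_source

The summary of interest is the minimal panel size from which a candidate
is classified correctly at every larger size across all treatments, and
the quick "worst-case" variant: move each candidate to its most similar
population (lowest pairwise mutual information) and rank loci lowest-PIC
first.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assignment import AssignmentConfig, LikelihoodModel, detect_migrants
from .genotype_io import GenotypeTable, relabel, subset
from .popgen_stats import (
    HIGHEST_FIRST,
    LOWEST_FIRST,
    LocusStats,
    rank_loci,
)

logger = logging.getLogger(__name__)

CORRECT_RESIDENT = "correct_resident"
CORRECT_DISPERSER = "correct_disperser"
FALSE_POSITIVE = "false_positive"
FALSE_NEGATIVE = "false_negative"
WRONG_SOURCE = "wrong_source"
ERROR = "error"
CORRECT_OUTCOMES = frozenset({CORRECT_RESIDENT, CORRECT_DISPERSER})


@dataclass(frozen=True)
class TreatmentPlan:
    """One placement of the designated simulated dispersers.

    ``placements`` maps each candidate individual id to the population it
    is labelled with for this treatment; identity placements (candidate
    stays home) are legitimate treatments.
    """

    treatment_id: int | str
    placements: dict[str, str] = field(default_factory=dict)

    def moves(self, homes: dict[str, str]) -> dict[str, str]:
        """The relabelling map (only candidates actually moved)."""
        return {
            ind: pop
            for ind, pop in self.placements.items()
            if homes[ind] != pop
        }


@dataclass
class SDAGrid:
    """Long-format outcome records over treatments x panels x directions."""

    records: pd.DataFrame
    candidates: dict[str, str]  # population -> individual id

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# candidate selection and treatment enumeration


def select_candidates(
    table: GenotypeTable,
    baseline_results,
    seed: int = 0,
    membership_threshold: float = 0.05,
    override: dict[str, str] | None = None,
) -> dict[str, str]:
    """Pick one simulated-disperser candidate per population.

    Individuals whose baseline membership p-value (from migrant detection
    on the unmodified table) falls below ``membership_threshold`` are
    excluded -- they may be real dispersers.  ``override`` maps population
    to an explicit individual id and is returned verbatim.
    """
    if override is not None:
        for pop, ind in override.items():
            if pop not in table.populations:
                raise KeyError(f"unknown population {pop!r}")
            table.index_of(ind)
        return dict(override)
    by_id = {r.individual_id: r for r in baseline_results}
    rng = np.random.default_rng(seed)
    chosen: dict[str, str] = {}
    for pop in table.populations:
        eligible = [
            ind
            for ind in table.individuals_in(pop)
            if ind in by_id
            and not math.isnan(by_id[ind].p_value)
            and by_id[ind].p_value >= membership_threshold
        ]
        if not eligible:
            raise ValueError(f"no eligible candidate in population {pop!r}")
        chosen[pop] = eligible[int(rng.integers(len(eligible)))]
    return chosen


def enumerate_treatments(
    candidates: dict[str, str], populations: list[str]
) -> list[TreatmentPlan]:
    """All placement functions of the candidates onto the populations.

    With one candidate per population (m = k) this is the full k^k set of
    movement treatments; the identity placement (everyone home) has
    treatment id 0.  In the general m-candidate case, k^m plans.
    """
    for pop in candidates:
        if pop not in populations:
            raise KeyError(f"candidate population {pop!r} not in populations")
    cands = list(candidates.values())
    homes = list(candidates.keys())
    plans: list[TreatmentPlan] = []
    identity = tuple(homes)
    all_placements = list(itertools.product(populations, repeat=len(cands)))
    # identity placement first, id 0
    ordered = [identity] + [p for p in all_placements if p != identity]
    for tid, placement in enumerate(ordered):
        plans.append(
            TreatmentPlan(
                treatment_id=tid,
                placements=dict(zip(cands, placement)),
            )
        )
    return plans


def prefix_series(
    ranked_highest_first: list[str],
) -> dict[str, list[list[str]]]:
    """Nested panels for both ranking directions.

    Given loci ranked highest-PIC first, the highest-first direction gets
    all L prefixes (sizes 1..L, the full panel included) and the
    lowest-first direction gets L-1 prefixes of the reversed ranking (the
    full panel would duplicate the one already analysed): 2L-1 panels in
    total.
    """
    if not ranked_highest_first:
        raise ValueError("empty locus ranking")
    L = len(ranked_highest_first)
    lowest = list(reversed(ranked_highest_first))
    return {
        HIGHEST_FIRST: [ranked_highest_first[:m] for m in range(1, L + 1)],
        LOWEST_FIRST: [lowest[:m] for m in range(1, L)],
    }


# ---------------------------------------------------------------------------
# the grid


def _classify(placed_home: bool, result) -> str:
    if result is None or math.isnan(result.p_value):
        return ERROR
    if placed_home:
        return FALSE_POSITIVE if result.flagged_disperser else CORRECT_RESIDENT
    if not result.flagged_disperser:
        return FALSE_NEGATIVE
    return (
        CORRECT_DISPERSER
        if result.assigned_source == result.true_home
        else WRONG_SOURCE
    )


def run_grid(
    table: GenotypeTable,
    candidates: dict[str, str],
    plans: list[TreatmentPlan],
    panels: dict[str, list[list[str]]],
    config: AssignmentConfig,
) -> SDAGrid:
    """Execute the full treatments x panels assignment grid.

    For every (plan, direction, panel): relabel candidates per the plan,
    subset to the panel, rerun migrant detection (null distributions are
    recomputed for the relabelled table -- moving a candidate changes its
    new home population's allele frequencies), and classify each candidate.
    Non-candidate individuals are scored but not recorded.  A cell that
    fails (e.g. a candidate with no called locus in a 1-locus panel) is
    recorded with outcome ``error`` rather than dropped.
    """
    homes = {ind: pop for pop, ind in candidates.items()}
    cand_ids = list(homes)
    rows = []
    for plan in plans:
        moves = plan.moves(homes)
        relabelled = relabel(table, moves) if moves else table
        for direction, panel_list in panels.items():
            for panel in panel_list:
                sub = subset(relabelled, loci=panel)
                cell_cfg = replace(
                    config,
                    seed=_cell_seed(config.seed, plan.treatment_id,
                                    direction, len(panel)),
                )
                try:
                    lik = LikelihoodModel(sub)
                    results = {
                        r.individual_id: r
                        for r in detect_migrants(sub, cell_cfg, lik)
                    }
                except Exception as exc:  # record, never drop silently
                    logger.warning(
                        "cell failed (treatment=%s, %s, %d loci): %s",
                        plan.treatment_id, direction, len(panel), exc,
                    )
                    results = {}
                for ind in cand_ids:
                    res = results.get(ind)
                    if res is not None:
                        res.true_home = homes[ind]
                    placed = plan.placements[ind]
                    outcome = _classify(placed == homes[ind], res)
                    rows.append(
                        {
                            "treatment_id": plan.treatment_id,
                            "disperser": ind,
                            "home": homes[ind],
                            "placed_in": placed,
                            "direction": direction,
                            "panel_size": len(panel),
                            "outcome": outcome,
                            "p_value": res.p_value if res else float("nan"),
                            "assigned_source": res.assigned_source
                            if res
                            else None,
                        }
                    )
    return SDAGrid(records=pd.DataFrame(rows), candidates=dict(candidates))


def _cell_seed(seed: int, treatment_id, direction: str, size: int) -> int:
    from .assignment import derive_seed

    return derive_seed(seed, "cell", treatment_id, direction, size)


# ---------------------------------------------------------------------------
# summaries


def minimal_panel(
    grid: SDAGrid, criterion: frozenset[str] = CORRECT_OUTCOMES
) -> pd.DataFrame:
    """Smallest panel size from which a candidate is always classified
    correctly, per (disperser, direction).

    Returns the minimal m such that every panel of size >= m yields a
    correct outcome across all treatments; ``inf`` when no such size
    exists.
    """
    df = grid.records
    if df.empty:
        raise ValueError("empty grid")
    rows = []
    for (disp, direction), sub in df.groupby(["disperser", "direction"]):
        sizes = np.sort(sub["panel_size"].unique())
        ok_by_size = {
            int(m): bool(
                sub.loc[sub["panel_size"] == m, "outcome"]
                .isin(criterion)
                .all()
            )
            for m in sizes
        }
        minimal: float = math.inf
        for m in sizes[::-1]:
            if ok_by_size[int(m)]:
                minimal = int(m)
            else:
                break
        rows.append(
            {
                "disperser": disp,
                "direction": direction,
                "minimal_panel_size": minimal,
            }
        )
    return pd.DataFrame(rows)


def worst_case_plan(
    table: GenotypeTable,
    differentiation: pd.DataFrame,
    candidates: dict[str, str],
) -> tuple[TreatmentPlan, str]:
    """The stringent quick check: move every candidate to the population
    most genetically similar to its home (minimal pairwise mutual
    information, theta as fallback) and rank loci lowest-PIC first.

    Ties in similarity are broken lexicographically (and logged).
    """
    metric = (
        "mutual_information"
        if "mutual_information" in differentiation.columns
        and differentiation["mutual_information"].notna().all()
        else "theta_fst"
    )
    sim: dict[tuple[str, str], float] = {}
    for _, row in differentiation.iterrows():
        sim[(row["pop_a"], row["pop_b"])] = float(row[metric])
        sim[(row["pop_b"], row["pop_a"])] = float(row[metric])
    placements: dict[str, str] = {}
    for pop, ind in candidates.items():
        others = [p for p in table.populations if p != pop]
        if not others:
            raise ValueError("worst-case plan needs >= 2 populations")
        vals = {o: sim[(pop, o)] for o in others}
        best = min(vals.values())
        tied = sorted(o for o, v in vals.items() if v == best)
        if len(tied) > 1:
            logger.warning(
                "similarity tie for %s: %s; choosing %s", pop, tied, tied[0]
            )
        placements[ind] = tied[0]
    return (
        TreatmentPlan(treatment_id="worst_case", placements=placements),
        LOWEST_FIRST,
    )


# ---------------------------------------------------------------------------
# plotting

_OUTCOME_COLOURS = {
    CORRECT_RESIDENT: "#2166ac",
    CORRECT_DISPERSER: "#2166ac",
    FALSE_NEGATIVE: "#b2182b",
    FALSE_POSITIVE: "#b2182b",
    WRONG_SOURCE: "#ef8a62",
    ERROR: "#999999",
}


def plot_grid(grid: SDAGrid, path) -> None:
    """Heatmap per (disperser, direction): treatments on the y-axis, panel
    size on the x-axis, colour by outcome class (correct / not recognised /
    wrong source)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    df = grid.records
    dispersers = sorted(df["disperser"].unique())
    directions = sorted(df["direction"].unique())
    classes = list(_OUTCOME_COLOURS)
    cmap = ListedColormap([_OUTCOME_COLOURS[c] for c in classes])
    fig, axes = plt.subplots(
        len(directions),
        len(dispersers),
        figsize=(4 * len(dispersers), 3 * len(directions)),
        squeeze=False,
    )
    for i, direction in enumerate(directions):
        for j, disp in enumerate(dispersers):
            sub = df[(df["disperser"] == disp) & (df["direction"] == direction)]
            piv = sub.pivot_table(
                index="treatment_id",
                columns="panel_size",
                values="outcome",
                aggfunc="first",
            )
            mat = piv.map(lambda o: classes.index(o)).to_numpy(float)
            ax = axes[i][j]
            ax.imshow(
                mat, aspect="auto", cmap=cmap, vmin=0, vmax=len(classes) - 1
            )
            ax.set_title(f"{disp} ({direction})", fontsize=9)
            ax.set_xlabel("panel size")
            ax.set_ylabel("treatment")
    handles = [
        Patch(color=_OUTCOME_COLOURS[c], label=c) for c in classes
    ]
    fig.legend(handles=handles, loc="lower center", ncol=3, fontsize=8)
    fig.tight_layout(rect=(0, 0.08, 1, 1))
    fig.savefig(path, dpi=150)
    plt.close(fig)


def rank_for_sda(locus_stats: list[LocusStats]) -> list[str]:
    """Global highest-PIC-first ranking used to build the nested panels."""
    return rank_loci(locus_stats, HIGHEST_FIRST)
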