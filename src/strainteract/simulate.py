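"""Synthetic study generator for the intraspecific-interaction pipeline.

Emulates the full data layout of a conspecific-isolate interaction study —
pairwise ANI among isolates with planted genotypic groups, a randomised
mono/coculture design quantified by qPCR, conditioned-medium amino-acid
time courses, matched transcription tables, and a gene-family
presence/absence matrix — so every downstream stage can be exercised and
validated with no external data.

The defaults reproduce the study conditions the pipeline was built around:
9 isolates in genotypic groups of sizes 3/5/1, within-group ANI above
99.6% and between-group ANI between 98.7 and 99.4% (so the planted
partition is exactly recoverable at a 99.5% cut-off), 4 biological
replicates sampled on Days 0/2/4/6/8 from a total inoculum of 1e6 CFU/mL,
facilitation of the slow-growing middle group by the other two groups, and
a planted producer/consumer amino-acid network with matching terminal-gene
upregulation.

Growth is a log-linear endpoint model — log10 copies gained per day per
group, plus additive group-to-group interaction shifts in coculture, plus
Gaussian noise on the log10 scale — not a mechanistic ODE: downstream
analysis only consumes endpoint and daily biomass, so only that
statistical structure is modelled.  Amino-acid noise is multiplicative
lognormal (concentrations are positive and HPLC error scales with level).

One global seed drives independent per-table substreams (derivation order:
ANI=1, design=2, growth=3, amino/transcription=4, gene families=5), so
each table can be regenerated on its own, bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import ANITable, roman_label
from .cooperation import AMINO_ACIDS
from .fitness import DEFAULT_CURVE, StandardCurve

__all__ = [
    "SimConfig",
    "planted_assignment",
    "gen_ani_matrix",
    "gen_design",
    "gen_growth",
    "gen_pathway_map",
    "gen_amino_profiles",
    "gen_gene_families",
    "representatives",
    "default_interaction_effects",
    "default_production_roles",
]

_STREAMS = {"ani": 1, "design": 2, "growth": 3, "amino": 4, "gene_families": 5}

#: Total inoculum density per trial (CFU/mL), split equally among members.
INITIAL_DENSITY = 1e6

# Per-day log10 gain per group, chosen so 8-day monocultures land at the
# characteristic final biomasses of the three genotypic groups
# (8.10 / 7.77 / 8.00 log10 copies/mL from a 1e6 inoculum).
_DEFAULT_BASELINES = ((8.10 - 6.0) / 8, (7.77 - 6.0) / 8, (8.00 - 6.0) / 8)


def default_interaction_effects(
    facilitation: float = math.log10(2.0),
    inhibition: float = -math.log10(1.25),
    n_groups: int = 3,
) -> dict[tuple[int, int], float]:
    """Planted group-to-group effects on log10 final abundance.

    Group 1 (the slow grower) is facilitated (+log10 2) by either other
    group; groups 0 and 2 are mildly inhibited (-log10 1.25) by any
    cross-group partner.  Same-group pairs have no effect.
    """
    eff: dict[tuple[int, int], float] = {}
    for g in range(n_groups):
        for h in range(n_groups):
            if g == h:
                eff[(g, h)] = 0.0
            elif g == 1:
                eff[(g, h)] = facilitation
            else:
                eff[(g, h)] = inhibition
    return eff


def default_production_roles() -> frozenset[tuple[int, int, str]]:
    """Planted producer -> consumer amino-acid roles over the six group pairs.

    Eleven distinct amino acids across six ordered group pairs, the
    structure of a three-group cross-feeding scheme.
    """
    pairs = {
        (0, 1): ("methionine", "histidine", "tryptophan"),
        (1, 0): ("phenylalanine", "glycine", "threonine"),
        (0, 2): ("methionine", "histidine"),
        (2, 0): ("phenylalanine", "cysteine"),
        (1, 2): ("glutamate", "proline"),
        (2, 1): ("glutamine", "cysteine", "tyrosine"),
    }
    return frozenset(
        (x, y, aa) for (x, y), aas in pairs.items() for aa in aas
    )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions described in the module docstring;
    see individual fields for units.
    """

    n_isolates: int = 9
    group_sizes: tuple[int, ...] = (3, 5, 1)
    ani_within_range: tuple[float, float] = (99.6, 100.0)
    ani_between_range: tuple[float, float] = (98.7, 99.4)
    n_replicates: int = 4
    days: tuple[int, ...] = (0, 2, 4, 6, 8)
    #: log10 copies/mL gained per day in monoculture, one value per group
    log10_baseline_growth: tuple[float, ...] = _DEFAULT_BASELINES
    #: (focal group, partner group) -> additive shift on log10 final abundance;
    #: None -> the planted default pattern for the config's group count
    interaction_effect: Mapping[tuple[int, int], float] | None = None
    growth_noise_sd: float = 0.1
    #: (producer group, consumer group, amino acid); None -> the planted
    #: six-pair network when there are three groups, otherwise no roles
    production_roles: frozenset[tuple[int, int, str]] | None = None
    production_ratio: float = 2.0
    utilisation_ratio: float = 0.5
    concentration_noise_cv: float = 0.1
    terminal_gene_log2fc: float = 3.0
    background_log2fc_sd: float = 0.25
    n_background_genes: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interaction_effect is None:
            object.__setattr__(
                self,
                "interaction_effect",
                default_interaction_effects(n_groups=self.n_groups)
                if self.n_groups == 3
                else {(g, h): 0.0 for g in range(self.n_groups) for h in range(self.n_groups)},
            )
        if self.production_roles is None:
            object.__setattr__(
                self,
                "production_roles",
                default_production_roles() if self.n_groups == 3 else frozenset(),
            )
        if sum(self.group_sizes) != self.n_isolates:
            raise ValueError("group_sizes must sum to n_isolates")
        for lo, hi in (self.ani_within_range, self.ani_between_range):
            if not (0 < lo <= hi <= 100):
                raise ValueError("ANI ranges must lie within (0, 100] with lo <= hi")
        if self.ani_between_range[1] >= self.ani_within_range[0] and self.n_groups > 1:
            raise ValueError("within-group ANI range must lie entirely above the between-group range")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if not self.days or self.days[0] != 0:
            raise ValueError("sampling days must start at Day 0")
        if len(self.log10_baseline_growth) != len(self.group_sizes):
            raise ValueError("one baseline growth rate per group required")
        if not self.production_ratio > 1:
            raise ValueError("production_ratio must exceed 1")
        if not 0 < self.utilisation_ratio < 1:
            raise ValueError("utilisation_ratio must lie in (0, 1)")
        ng = self.n_groups
        for x, y, aa in self.production_roles:
            if not (0 <= x < ng and 0 <= y < ng and x != y):
                raise ValueError(f"production role references invalid group pair ({x}, {y})")
            if aa not in AMINO_ACIDS:
                raise ValueError(f"production role references unknown amino acid {aa!r}")
            if (y, x, aa) in self.production_roles:
                raise ValueError(
                    f"conflicting reciprocal roles for {aa} between groups {x} and {y}"
                )

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    @property
    def final_day(self) -> int:
        return max(self.days)

    def isolates(self) -> tuple[str, ...]:
        return tuple(f"isolate_{i + 1}" for i in range(self.n_isolates))

    def rng(self, stream: str) -> np.random.Generator:
        """Substream generator: independent per table, reproducible per seed."""
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def group_labels(self) -> tuple[str, ...]:
        return tuple(roman_label(g) for g in range(self.n_groups))


def planted_assignment(config: SimConfig) -> dict[str, int]:
    """Isolate -> planted group index (isolates listed group by group)."""
    assignment: dict[str, int] = {}
    idx = 0
    for g, size in enumerate(config.group_sizes):
        for _ in range(size):
            assignment[f"isolate_{idx + 1}"] = g
            idx += 1
    return assignment


def representatives(config: SimConfig) -> dict[str, list[str]]:
    """Two representative isolates per group (first and last member).

    Mirrors a design in which each group enters two independent coculture
    experiment sets through different member isolates; singleton groups
    contribute the same isolate to both sets.
    """
    assignment = planted_assignment(config)
    reps: dict[str, list[str]] = {}
    for g in range(config.n_groups):
        members = [i for i, gg in assignment.items() if gg == g]
        reps[roman_label(g)] = sorted({members[0], members[-1]}, key=members.index)
    return reps


def gen_ani_matrix(config: SimConfig) -> ANITable:
    """Pairwise ANI matrix with planted block structure.

    Within-group pairs draw uniformly from ``ani_within_range``,
    between-group pairs from ``ani_between_range``; the diagonal is 100.
    Because the two ranges are disjoint, single-linkage classification at
    any threshold strictly between them returns exactly the planted groups.
    """
    rng = config.rng("ani")
    assignment = planted_assignment(config)
    isolates = config.isolates()
    n = config.n_isolates
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            same = assignment[isolates[i]] == assignment[isolates[j]]
            lo, hi = config.ani_within_range if same else config.ani_between_range
            v = float(rng.uniform(lo, hi))
            values[i, j] = values[j, i] = v
    table = ANITable(isolates, values)
    table.validate()
    return table


def gen_design(
    config: SimConfig,
    n_cocultures: int = 86,
    size_range: tuple[int, int] = (2, 3),
) -> pd.DataFrame:
    """Randomised culture design: one monoculture per isolate + cocultures.

    Coculture member sets are distinct random subsets with sizes uniform
    over ``size_range``; each trial's focal isolate (the one quantified,
    sitting in the lower chamber) is drawn uniformly from its members.
    Total inoculum is 1e6 CFU/mL split equally among members.

    Returns a DataFrame with columns ``trial_id, layout, focal, members``.
    """
    lo, hi = size_range
    if not (2 <= lo <= hi <= config.n_isolates):
        raise ValueError(f"size_range {size_range} must lie within [2, {config.n_isolates}]")
    isolates = config.isolates()
    pools = {
        k: [tuple(c) for c in combinations(isolates, k)] for k in range(lo, hi + 1)
    }
    total = sum(len(v) for v in pools.values())
    if n_cocultures > total:
        raise ValueError(
            f"requested {n_cocultures} cocultures but only {total} distinct member subsets exist"
        )
    rng = config.rng("design")
    for k in pools:
        pools[k] = [pools[k][i] for i in rng.permutation(len(pools[k]))]
    used: dict[int, int] = {k: 0 for k in pools}

    rows = [
        {"trial_id": f"mono_{iso}", "layout": "monoculture", "focal": iso, "members": iso}
        for iso in isolates
    ]
    sizes = list(pools)
    for c in range(n_cocultures):
        open_sizes = [k for k in sizes if used[k] < len(pools[k])]
        k = int(open_sizes[rng.integers(len(open_sizes))])
        members = pools[k][used[k]]
        used[k] += 1
        focal = members[int(rng.integers(len(members)))]
        layout = "pairwise" if len(members) == 2 else "multi"
        rows.append(
            {
                "trial_id": f"co_{c + 1:03d}",
                "layout": layout,
                "focal": focal,
                "members": ",".join(members),
            }
        )
    return pd.DataFrame(rows)


def gen_growth(
    design: pd.DataFrame,
    config: SimConfig,
    curve: StandardCurve = DEFAULT_CURVE,
) -> pd.DataFrame:
    """Biomass observations (log10 copies/mL and Ct) for every trial.

    Observation model per trial x replicate x day d::

        log10 Q(d) = log10(1e6 / n_members)            # equal-split inoculum
                   + d * baseline[group(focal)]
                   + sum_h effect[(group(focal), h)]    # distinct partner groups, d > 0
                   + Normal(0, growth_noise_sd)         # d > 0

    Day-0 observations are exact (they define the inoculum); interaction
    shifts apply from the first post-inoculation sample on, so the final
    day carries the full planted effect.  Ct values are emitted through
    the forward standard curve.

    Raises
    ------
    KeyError
        If a focal/partner group pair occurring in the design has no entry
        in ``config.interaction_effect`` (the pair is named).
    """
    if design.empty:
        raise ValueError("design has no trials")
    assignment = planted_assignment(config)
    rng = config.rng("growth")
    days = np.asarray(config.days)
    reps = config.n_replicates
    rows: list[dict] = []
    for _, trial in design.iterrows():
        members = trial["members"].split(",")
        focal = trial["focal"]
        g = assignment[focal]
        base = config.log10_baseline_growth[g]
        partner_groups = sorted({assignment[m] for m in members if m != focal})
        effect = 0.0
        for h in partner_groups:
            if (g, h) not in config.interaction_effect:
                raise KeyError(
                    f"no interaction effect defined for group pair ({g}, {h}) "
                    f"(trial {trial['trial_id']})"
                )
            effect += config.interaction_effect[(g, h)]
        log10_init = math.log10(INITIAL_DENSITY / len(members))
        noise = rng.normal(0.0, config.growth_noise_sd, size=(reps, days.size))
        for r in range(reps):
            for di, d in enumerate(days):
                if d == 0:
                    val = log10_init
                else:
                    val = log10_init + d * base + effect + noise[r, di]
                rows.append(
                    {
                        "trial_id": trial["trial_id"],
                        "isolate": focal,
                        "replicate": r + 1,
                        "day": int(d),
                        "log10_copies": val,
                        "ct": curve.slope * val + curve.intercept,
                    }
                )
    return pd.DataFrame(rows)


def gen_pathway_map(config: SimConfig) -> pd.DataFrame:
    """Terminal biosynthesis gene per (isolate, amino acid), deterministic."""
    rows = [
        {"isolate": iso, "amino_acid": aa, "gene": f"{iso}|{aa}_terminal"}
        for iso in config.isolates()
        for aa in AMINO_ACIDS
    ]
    return pd.DataFrame(rows)


def gen_amino_profiles(
    config: SimConfig, baseline_mg_l: float = 50.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Conditioned-medium amino-acid time courses + matching transcription.

    For each ordered pair of distinct groups (focal X grown in Y-conditioned
    medium) and each of the 18 amino acids, concentrations follow
    ``baseline * factor(d) * lognormal noise`` where the Day-8 factor is
    ``production_ratio`` if the role (X produces for Y) is planted,
    ``utilisation_ratio`` if the reciprocal role is planted, and 1
    otherwise; intermediate days interpolate geometrically.  With zero
    noise the final/initial ratio is exactly the planted factor.

    The transcription table covers each group's representative isolates in
    every coculture condition ``vs_<partner>``: the terminal gene of a
    planted produced amino acid carries ``terminal_gene_log2fc`` with a
    small adjusted p; every other gene draws log2FC ~ Normal(0,
    background_log2fc_sd) with uniform adjusted p.  Terminal genes are
    tagged COG category E (amino-acid transport and metabolism).
    """
    rng = config.rng("amino")
    labels = config.group_labels()
    reps = representatives(config)
    final_day = config.final_day
    cv = config.concentration_noise_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0

    # keys: (focal group, medium-source group, amino acid); a planted role
    # X -> Y means X accumulates `aa` growing in Y's spent medium and Y
    # depletes it growing in X's spent medium
    role_conc: dict[tuple[int, int, str], float] = {}
    for x, y, aa in config.production_roles:
        role_conc[(x, y, aa)] = config.production_ratio
        role_conc[(y, x, aa)] = config.utilisation_ratio

    amino_rows: list[dict] = []
    for gx in range(config.n_groups):
        for gy in range(config.n_groups):
            if gx == gy:
                continue
            for aa in AMINO_ACIDS:
                factor = role_conc.get((gx, gy, aa), 1.0)
                for d in config.days:
                    f_d = factor ** (d / final_day) if d > 0 else 1.0
                    mean = baseline_mg_l * f_d
                    if sigma > 0:
                        mult = rng.lognormal(-0.5 * sigma * sigma, sigma, size=config.n_replicates)
                    else:
                        mult = np.ones(config.n_replicates)
                    for r in range(config.n_replicates):
                        amino_rows.append(
                            {
                                "focal_group": labels[gx],
                                "medium_source": labels[gy],
                                "amino_acid": aa,
                                "day": int(d),
                                "replicate": r + 1,
                                "concentration": mean * float(mult[r]),
                            }
                        )
    profiles = pd.DataFrame(amino_rows)

    produced_by_pair: dict[tuple[int, int], set[str]] = {}
    for x, y, aa in config.production_roles:
        produced_by_pair.setdefault((x, y), set()).add(aa)

    cog_pool = list("CDEFGHIJKLMNOPQTUV")
    tx_rows: list[dict] = []
    for gx in range(config.n_groups):
        for gy in range(config.n_groups):
            if gx == gy:
                continue
            condition = f"vs_{labels[gy]}"
            planted = produced_by_pair.get((gx, gy), set())
            for iso in reps[labels[gx]]:
                for aa in AMINO_ACIDS:
                    if aa in planted:
                        fc = config.terminal_gene_log2fc
                        padj = float(rng.uniform(1e-6, 1e-3))
                    else:
                        fc = float(rng.normal(0.0, config.background_log2fc_sd))
                        padj = float(rng.uniform(0.0, 1.0))
                    tx_rows.append(
                        {
                            "isolate": iso,
                            "gene": f"{iso}|{aa}_terminal",
                            "condition": condition,
                            "log2_fold_change": fc,
                            "p_adjusted": padj,
                            "cog_category": "E",
                        }
                    )
                for k in range(config.n_background_genes):
                    tx_rows.append(
                        {
                            "isolate": iso,
                            "gene": f"{iso}|bg{k:03d}",
                            "condition": condition,
                            "log2_fold_change": float(rng.normal(0.0, config.background_log2fc_sd)),
                            "p_adjusted": float(rng.uniform(0.0, 1.0)),
                            "cog_category": cog_pool[int(rng.integers(len(cog_pool)))],
                        }
                    )
    transcription = pd.DataFrame(tx_rows)
    return profiles, transcription


def gen_gene_families(
    config: SimConfig,
    n_core: int = 1200,
    n_group_specific: int = 200,
    n_private: int = 120,
) -> pd.DataFrame:
    """Binary gene-family presence/absence matrix with group structure.

    Every isolate carries the core families; each group adds its own
    group-specific block; each isolate additionally carries a random
    subset of a private-accessory pool, so unions grow when groups are
    combined.  Family counts land in the plausible range for a
    small-genome lactic acid bacterium (roughly 1.4-1.7 thousand).
    """
    rng = config.rng("gene_families")
    assignment = planted_assignment(config)
    isolates = config.isolates()
    cols = (
        [f"core_{i:04d}" for i in range(n_core)]
        + [
            f"grp{g}_{i:04d}"
            for g in range(config.n_groups)
            for i in range(n_group_specific)
        ]
        + [f"acc_{i:04d}" for i in range(n_private * 2)]
    )
    mat = np.zeros((len(isolates), len(cols)), dtype=int)
    mat[:, :n_core] = 1
    for k, iso in enumerate(isolates):
        g = assignment[iso]
        start = n_core + g * n_group_specific
        mat[k, start : start + n_group_specific] = 1
        acc = rng.choice(n_private * 2, size=n_private, replace=False)
        mat[k, n_core + config.n_groups * n_group_specific + acc] = 1
    return pd.DataFrame(mat, index=list(isolates), columns=cols)
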