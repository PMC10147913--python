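"""Relative-fitness analysis of mono- and coculture growth experiments.

The focal isolate of each culture trial is quantified by qPCR; cycle
thresholds (Ct) convert to template copies through the assay's linear
standard curve Ct = slope * log10(copies) + intercept.  Relative fitness
of an isolate in coculture is its log2 growth relative to its log2 growth
in monoculture::

    W = log2(Q_final_co / Q_initial) / log2(Q_final_mono / Q_initial)

so W = 1 means the partners had no effect, W > 1 facilitation, W < 1
inhibition, and monocultures have W = 1 by definition.  Final biomass is
the replicate mean; replicate-level observations feed the Welch t-tests of
coculture-vs-monoculture biomass, and a grouping scheme turns the trial
table into a cross-group versus within-group contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import GroupingScheme, roman_label
from .stats import pearson_fit, two_sample_t

__all__ = [
    "StandardCurve",
    "DEFAULT_CURVE",
    "ct_to_copies",
    "relative_fitness",
    "fitness_table",
    "scheme_contrast",
    "ContrastResult",
    "fitness_ani_correlation",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear qPCR standard curve, Ct = slope * log10(copies) + intercept.

    ``slope`` must be negative (more template -> earlier crossing).
    """

    slope: float
    intercept: float
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise ValueError("standard-curve slope must be negative")

    def ct(self, copies: float) -> float:
        """Forward evaluation: expected Ct for a copy number."""
        if copies <= 0:
            raise ValueError("copy number must be positive")
        return self.slope * math.log10(copies) + self.intercept


#: Calibration of the species-specific qPCR assay used throughout:
#: Ct = -3.804 * log10(copies) + 43.816 (R^2 = 0.9996).
DEFAULT_CURVE = StandardCurve(slope=-3.804, intercept=43.816, r_squared=0.9996)


def ct_to_copies(curve: StandardCurve, ct: float) -> float:
    """Invert the standard curve: Ct -> template copies per mL.

    copies = 10 ** ((intercept - ct) / (-slope)); strictly decreasing in Ct.
    """
    if not np.isfinite(ct):
        raise ValueError("Ct must be finite")
    return float(10.0 ** ((curve.intercept - ct) / (-curve.slope)))


def relative_fitness(q_initial: float, q_final_co: float, q_final_mono: float) -> float:
    """Relative fitness of an isolate in coculture vs monoculture.

    All three quantities are biomasses (copies/mL) on the same scale; the
    statistic is invariant to rescaling them jointly.  Monoculture fitness
    is 1 by construction (q_final_co == q_final_mono).

    Raises
    ------
    ValueError
        If any input is non-positive, or the monoculture did not change
        from the inoculum (zero log-growth denominator).
    """
    for name, q in (("q_initial", q_initial), ("q_final_co", q_final_co),
                    ("q_final_mono", q_final_mono)):
        if not (np.isfinite(q) and q > 0):
            raise ValueError(f"{name} must be positive and finite, got {q}")
    denom = math.log2(q_final_mono / q_initial)
    if denom == 0.0:
        raise ValueError("monoculture final biomass equals the inoculum: relative fitness undefined")
    return math.log2(q_final_co / q_initial) / denom


def _replicate_final(biomass: pd.DataFrame, trial: str, day: int) -> np.ndarray:
    sel = biomass[(biomass["trial_id"] == trial) & (biomass["day"] == day)]
    return sel["log10_copies"].to_numpy(dtype=float)


def fitness_table(
    biomass: pd.DataFrame,
    design: pd.DataFrame,
    final_day: int = 8,
    curve: StandardCurve = DEFAULT_CURVE,
    per_trial_tests: bool = True,
) -> pd.DataFrame:
    """Per-trial relative fitness and coculture-vs-monoculture biomass tests.

    Parameters
    ----------
    biomass
        Long table with columns ``trial_id, isolate, replicate, day`` and
        either ``log10_copies`` or ``ct`` (Ct is converted through the
        standard curve).  Only the focal isolate of each trial is observed.
    design
        One row per trial: ``trial_id, layout, focal, members`` (members
        comma-joined).  Every coculture focal must also appear as the focal
        of a monoculture trial.
    final_day
        Sampling day treated as the endpoint (default 8).
    per_trial_tests
        When False the per-trial Welch t-tests are skipped (cheaper for
        large resampling studies); the fitness values are unaffected.

    Returns
    -------
    DataFrame with one row per trial: replicate-mean log10 biomass at Day 0
    and the final day, mono and co means +/- sd, relative fitness computed
    on replicate means, and the Welch t/p of co-vs-mono replicate final
    biomass.  Monoculture rows carry relative_fitness exactly 1.
    """
    biomass = biomass.copy()
    if "log10_copies" not in biomass.columns:
        if "ct" not in biomass.columns:
            raise ValueError("biomass table needs a 'log10_copies' or 'ct' column")
        biomass["log10_copies"] = np.log10(
            [ct_to_copies(curve, c) for c in biomass["ct"].to_numpy(dtype=float)]
        )

    if not set(biomass["day"]).issuperset({0, final_day}):
        raise ValueError(f"biomass table must contain Day 0 and Day {final_day}")

    mono_trial: dict[str, str] = {}
    for _, row in design.iterrows():
        if row["layout"] == "monoculture":
            mono_trial[row["focal"]] = row["trial_id"]

    stats = (
        biomass[biomass["day"].isin([0, final_day])]
        .groupby(["trial_id", "day"])["log10_copies"]
        .agg(["mean", "std", "count"])
    )

    rows = []
    for _, trial in design.iterrows():
        tid, focal, layout = trial["trial_id"], trial["focal"], trial["layout"]
        members = trial["members"].split(",") if isinstance(trial["members"], str) else list(trial["members"])
        partners = [m for m in members if m != focal]
        try:
            q0 = stats.loc[(tid, 0), "mean"]
            qf = stats.loc[(tid, final_day), "mean"]
            qf_sd = stats.loc[(tid, final_day), "std"]
        except KeyError as exc:
            raise ValueError(f"trial {tid} lacks Day 0 / Day {final_day} observations") from exc

        if layout == "monoculture":
            fitness = 1.0
            t = p = np.nan
            mono_mean, mono_sd = qf, qf_sd
        else:
            if focal not in mono_trial:
                raise ValueError(f"no monoculture trial for focal isolate {focal!r}")
            mid = mono_trial[focal]
            m0 = stats.loc[(mid, 0), "mean"]
            mf = stats.loc[(mid, final_day), "mean"]
            mono_mean, mono_sd = mf, stats.loc[(mid, final_day), "std"]
            # Eq on replicate means; log10 scale cancels the log2 ratio
            denom = mf - m0
            if denom == 0.0:
                raise ValueError(f"monoculture {mid} shows zero net growth; fitness undefined")
            fitness = (qf - q0) / denom
            if per_trial_tests:
                t, p = two_sample_t(
                    _replicate_final(biomass, tid, final_day),
                    _replicate_final(biomass, mid, final_day),
                )
            else:
                t = p = np.nan

        rows.append(
            {
                "trial_id": tid,
                "focal": focal,
                "layout": layout,
                "partners": ",".join(partners),
                "n_members": len(members),
                "day0_mean": float(q0),
                "growth_gain": float(qf - q0),
                "co_final_mean": float(qf),
                "co_final_sd": float(qf_sd),
                "mono_final_mean": float(mono_mean),
                "mono_final_sd": float(mono_sd),
                "relative_fitness": float(fitness),
                "t_biomass": float(t),
                "p_biomass": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if (out["relative_fitness"] < 0).any():
        negative = out.loc[out["relative_fitness"] < 0, "trial_id"].tolist()
        out.attrs["negative_fitness_trials"] = negative
    return out


@dataclass
class ContrastResult:
    """Cross-group vs within-group contrast under one grouping scheme.

    ``applicable`` is False when one of the two classes is empty (e.g. a
    one-group scheme has no cross-group trials), in which case the test
    fields are NaN.
    """

    threshold: float
    n_cross: int
    n_within: int
    applicable: bool
    t_biomass: float
    p_biomass: float
    t_growth: float
    p_growth: float
    t_fitness: float
    p_fitness: float
    cross_mean_biomass: float
    within_mean_biomass: float
    cross_mean_growth: float
    within_mean_growth: float
    cross_mean_fitness: float
    within_mean_fitness: float
    by_combination: pd.DataFrame | None = None

    def significant(self, alpha: float = 0.05) -> bool:
        """Cross-group interaction detected: growth-gain contrast p < alpha.

        The log10 growth gain (final minus Day-0 biomass) is the headline
        statistic because it is invariant to the inoculum split across
        coculture members and independent across trials; the raw final
        biomass and relative-fitness contrasts are reported alongside.
        """
        return self.applicable and self.p_growth < alpha

    def stars(self) -> str:
        if not self.applicable or not np.isfinite(self.p_growth):
            return "na"
        if self.p_growth < 0.001:
            return "***"
        if self.p_growth < 0.01:
            return "**"
        if self.p_growth < 0.05:
            return "*"
        return "ns"


def scheme_contrast(
    fitness: pd.DataFrame,
    design: pd.DataFrame,
    scheme: GroupingScheme,
    alpha: float = 0.05,
) -> ContrastResult:
    """Test whether group-spanning cocultures differ from same-group cultures.

    Each trial is labelled ``cross`` (members span >= 2 groups of the
    scheme) or ``within`` (all members one group; monocultures included).
    Welch t-tests compare the two classes on three trial-level statistics:
    final biomass (replicate-mean log10 copies/mL), log10 growth gain
    (final minus Day 0), and relative fitness.  The growth-gain contrast is
    the headline (see :meth:`ContrastResult.significant`): unlike raw final
    biomass it is not confounded by the inoculum being split across
    coculture members, and unlike relative fitness its trial-level values
    do not share a monoculture reference, so they are independent across
    trials.  A per-group-combination breakdown against the within class is
    attached.
    """
    members_of = {
        row["trial_id"]: (row["members"].split(",") if isinstance(row["members"], str) else list(row["members"]))
        for _, row in design.iterrows()
    }
    fit = fitness.copy()
    classes = []
    combos = []
    for tid in fit["trial_id"]:
        mem = members_of[tid]
        missing = [m for m in mem if m not in scheme.assignment]
        if missing:
            raise KeyError(f"scheme lacks isolate(s) {missing} for trial {tid}")
        groups = sorted({scheme.assignment[m] for m in mem})
        classes.append("cross" if len(groups) > 1 else "within")
        combos.append("+".join(roman_label(g) for g in groups))
    fit["combination_class"] = classes
    fit["group_combination"] = combos

    cross = fit[fit["combination_class"] == "cross"]
    within = fit[fit["combination_class"] == "within"]
    applicable = len(cross) >= 2 and len(within) >= 2

    if applicable:
        tb, pb = two_sample_t(cross["co_final_mean"], within["co_final_mean"])
        tg, pg = two_sample_t(cross["growth_gain"], within["growth_gain"])
        tf, pf = two_sample_t(cross["relative_fitness"], within["relative_fitness"])
    else:
        tb = pb = tg = pg = tf = pf = np.nan

    by_rows = []
    if applicable:
        for combo, sub in cross.groupby("group_combination"):
            if len(sub) >= 2:
                ct, cp = two_sample_t(sub["growth_gain"], within["growth_gain"])
            else:
                ct = cp = np.nan
            by_rows.append(
                {
                    "group_combination": combo,
                    "n_trials": len(sub),
                    "mean_growth_gain": float(sub["growth_gain"].mean()),
                    "mean_fitness": float(sub["relative_fitness"].mean()),
                    "t_growth": ct,
                    "p_growth": cp,
                    "significant": bool(np.isfinite(cp) and cp < alpha),
                }
            )

    return ContrastResult(
        threshold=scheme.threshold,
        n_cross=len(cross),
        n_within=len(within),
        applicable=applicable,
        t_biomass=float(tb) if applicable else np.nan,
        p_biomass=float(pb) if applicable else np.nan,
        t_growth=float(tg) if applicable else np.nan,
        p_growth=float(pg) if applicable else np.nan,
        t_fitness=float(tf) if applicable else np.nan,
        p_fitness=float(pf) if applicable else np.nan,
        cross_mean_biomass=float(cross["co_final_mean"].mean()) if len(cross) else np.nan,
        within_mean_biomass=float(within["co_final_mean"].mean()) if len(within) else np.nan,
        cross_mean_growth=float(cross["growth_gain"].mean()) if len(cross) else np.nan,
        within_mean_growth=float(within["growth_gain"].mean()) if len(within) else np.nan,
        cross_mean_fitness=float(cross["relative_fitness"].mean()) if len(cross) else np.nan,
        within_mean_fitness=float(within["relative_fitness"].mean()) if len(within) else np.nan,
        by_combination=pd.DataFrame(by_rows) if by_rows else None,
    )


def fitness_ani_correlation(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
) -> dict[str, float]:
    """Pearson correlation of relative fitness against partner ANI.

    ``points`` are (partner ANI percent, relative fitness) pairs.  Returns
    r, its two-sided p (t-distribution, n-2 df), and the least-squares
    slope/intercept.
    """
    if isinstance(points, pd.DataFrame):
        x = points.iloc[:, 0].to_numpy(dtype=float)
        y = points.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    r, p, slope, intercept = pearson_fit(x, y)
    return {"r": r, "p": p, "slope": slope, "intercept": intercept, "n": int(len(x))}
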