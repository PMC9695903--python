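"""Monte-Carlo sweeps: empirical RAF probabilities versus theory.

Each sweep runs the TAP simulator many times over a grid of (M, p)
points and records how often the resulting network contains an RAF —
either the *all-network* RAF event (every reaction catalyzed; the event
whose probability the closed-form theory gives) or the *any-RAF* event
(non-empty maxRAF).  Empirical frequencies carry binomial standard
errors and are paired with the theoretical all-network probability.

The transition point of a sweep that varies p at fixed M is the level of
catalysis f = p*(M - M0) at which the empirical probability first
crosses a target level (0.5 by default), linearly interpolated between
the bracketing grid points.  Its logarithmic growth in M is the model's
signature behaviour.

Replicates are seeded by hierarchical seed-sequence spawning from one
master seed, so every grid point is independent, individually
re-runnable, and the whole sweep is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import raf
from .sim import TapParams, run_tap
from .theory import p_all, required_level_of_catalysis

__all__ = [
    "SweepConfig",
    "SweepResult",
    "TransitionEstimate",
    "estimate_raf_probability",
    "estimate_transition_point",
    "fig2_table",
    "fig3_table",
    "fig4_table",
    "figure_suite",
    "PROFILES",
]

RAF_MODES = ("all", "any")

#: Columns of every sweep table, in order.
SWEEP_COLUMNS = [
    "M",
    "p",
    "f",
    "n",
    "successes",
    "q_hat",
    "se",
    "p_all_theory",
]


@dataclass(frozen=True)
class SweepConfig:
    """A Monte-Carlo sweep definition.

    ``grid`` lists (M, p) points; ``replicates`` runs are performed per
    point; ``raf_mode`` selects the event whose frequency is estimated:
    ``"all"`` for the all-network RAF (every reaction catalyzed) or
    ``"any"`` for a non-empty maxRAF.
    """

    grid: tuple[tuple[int, float], ...]
    replicates: int
    seed: int
    raf_mode: str = "all"
    M0: int = 10
    alpha: float = 0.01
    K: int = 4

    def __post_init__(self) -> None:
        grid = tuple((int(m), float(p)) for m, p in self.grid)
        object.__setattr__(self, "grid", grid)
        if not grid:
            raise ValueError("sweep grid is empty")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.raf_mode not in RAF_MODES:
            raise ValueError(
                f"raf_mode must be one of {RAF_MODES}, got {self.raf_mode!r}"
            )
        for m, p in grid:
            # Fail at configuration time, not mid-sweep.
            TapParams(M=m, M0=self.M0, alpha=self.alpha, K=self.K, p=p)


@dataclass(frozen=True)
class SweepResult:
    """Per-grid-point empirical frequencies with standard errors."""

    config: SweepConfig
    table: pd.DataFrame = field(compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in SWEEP_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"sweep table missing columns {missing}")


def _replicate_seed(ss: np.random.SeedSequence) -> int:
    # TapParams carries a plain integer seed; derive one per replicate
    # from the spawned sequence, kept below 2**31.
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _binomial_se(k: int, n: int) -> float:
    q = k / n
    return math.sqrt(q * (1.0 - q) / n)


def estimate_raf_probability(config: SweepConfig) -> SweepResult:
    """Run the sweep and estimate the RAF probability at every grid point.

    Every replicate executes a full TAP run; ``raf_mode`` decides the
    per-run success predicate.  A failing replicate aborts the sweep —
    replicates are never silently dropped.
    """
    master = np.random.SeedSequence(config.seed)
    point_seqs = master.spawn(len(config.grid))
    rows = []
    for (m, p), point_seq in zip(config.grid, point_seqs):
        rep_seqs = point_seq.spawn(config.replicates)
        successes = 0
        for rep_seq in rep_seqs:
            params = TapParams(
                M=m, M0=config.M0, alpha=config.alpha, K=config.K, p=p,
                seed=_replicate_seed(rep_seq),
            )
            run = run_tap(params)
            if config.raf_mode == "all":
                hit = raf.all_reactions_catalyzed(run.system)
            else:
                hit = not raf.max_raf(run.system).is_empty
            successes += bool(hit)
        n = config.replicates
        rows.append(
            {
                "M": m,
                "p": p,
                "f": p * (m - config.M0),
                "n": n,
                "successes": successes,
                "q_hat": successes / n,
                "se": _binomial_se(successes, n),
                "p_all_theory": p_all(m, config.M0, p),
            }
        )
    table = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    return SweepResult(config=config, table=table)


@dataclass(frozen=True)
class TransitionEstimate:
    """Interpolated crossing of the empirical probability curve.

    ``f`` is the level of catalysis at the crossing; ``se`` propagates
    the binomial standard errors of the two bracketing grid points
    through the linear interpolation (zero for an exact grid hit).
    """

    f: float
    se: float
    level: float


def estimate_transition_point(
    result: SweepResult, level: float = 0.5
) -> TransitionEstimate:
    """Level of catalysis at which the empirical curve crosses ``level``.

    The sweep must vary p (hence f) at a single fixed M.  If some grid
    point hits ``level`` exactly, its f is returned; otherwise the first
    upward crossing is located and f is linearly interpolated between
    the two bracketing points.  No smoothing is applied — noisy curves
    are the caller's cue to raise the replicate count.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    tab = result.table.sort_values("f").reset_index(drop=True)
    if tab["M"].nunique() != 1:
        raise ValueError("transition estimation requires a fixed-M sweep")
    q = tab["q_hat"].to_numpy()
    f = tab["f"].to_numpy()
    se = tab["se"].to_numpy()
    for i in range(len(tab)):
        if q[i] == level:
            return TransitionEstimate(f=float(f[i]), se=0.0, level=level)
    for i in range(len(tab) - 1):
        if q[i] < level < q[i + 1]:
            dq = q[i + 1] - q[i]
            df = f[i + 1] - f[i]
            w = (level - q[i]) / dq
            f_star = f[i] + w * df
            slope = df / dq
            se_star = abs(slope) * math.hypot((1.0 - w) * se[i], w * se[i + 1])
            return TransitionEstimate(f=float(f_star), se=float(se_star), level=level)
    raise ValueError(
        f"empirical curve never crosses {level}: observed range "
        f"[{q.min():.3f}, {q.max():.3f}] over f in [{f.min():.3g}, {f.max():.3g}]"
    )


# ---------------------------------------------------------------------------
# Figure-style experiment suites
# ---------------------------------------------------------------------------

#: Replicate counts per profile.  "full" carries the statistical weight
#: used for the headline checks; "fast" regenerates each table in about a
#: minute; "smoke" exercises the plumbing only.
PROFILES = {
    "smoke": {"fig2_reps": 5, "fig3_reps": 5, "fig4_reps": 8,
              "fig2_M": (100, 400), "fig3_M": (100, 250),
              "fig4_M": (100, 250), "fig_points": 4},
    "fast": {"fig2_reps": 40, "fig3_reps": 40, "fig4_reps": 60,
             "fig2_M": (250, 500, 750, 1000, 1250, 1500, 1750, 2000),
             "fig3_M": (100, 250, 500, 1000),
             "fig4_M": (150, 250, 400, 650, 1000), "fig_points": 7},
    "full": {"fig2_reps": 500, "fig3_reps": 500, "fig4_reps": 500,
              "fig2_M": (250, 500, 750, 1000, 1250, 1500, 1750, 2000, 2500),
              "fig3_M": (100, 250, 500, 1000, 1250),
              "fig4_M": (150, 250, 400, 650, 1000, 1250), "fig_points": 9},
}


def _f_grid(m: int, n_points: int, half_width: float = 1.8) -> np.ndarray:
    """p-sweep grid centered on the predicted transition f for this M."""
    center = required_level_of_catalysis(m, 0.5)
    return np.linspace(center - half_width, center + half_width, n_points)


def fig2_table(profile: str = "fast", seed: int = 0) -> pd.DataFrame:
    """RAF probability against network size M at fixed p = 0.005.

    Columns: the sweep schema for the all-network RAF event plus an
    ``any_q_hat``/``any_se`` pair for the any-RAF event, so the table
    carries the empirical points for both curves and the closed-form
    all-network probability.
    """
    prof = _profile(profile)
    grid = tuple((m, 0.005) for m in prof["fig2_M"])
    base = dict(replicates=prof["fig2_reps"], M0=10, alpha=0.01, K=4)
    all_res = estimate_raf_probability(
        SweepConfig(grid=grid, seed=seed, raf_mode="all", **base)
    )
    any_res = estimate_raf_probability(
        SweepConfig(grid=grid, seed=seed + 1, raf_mode="any", **base)
    )
    tab = all_res.table.copy()
    tab["any_q_hat"] = any_res.table["q_hat"]
    tab["any_se"] = any_res.table["se"]
    return tab


def fig3_table(profile: str = "fast", seed: int = 0) -> pd.DataFrame:
    """All-network RAF probability against f = p(M-M0) for several M."""
    prof = _profile(profile)
    tables = []
    for j, m in enumerate(prof["fig3_M"]):
        grid = tuple((m, float(f) / (m - 10)) for f in _f_grid(m, prof["fig_points"]))
        res = estimate_raf_probability(
            SweepConfig(
                grid=grid, replicates=prof["fig3_reps"], seed=seed + j,
                raf_mode="all", M0=10, alpha=0.01, K=4,
            )
        )
        tables.append(res.table)
    return pd.concat(tables, ignore_index=True)


def fig4_table(profile: str = "fast", seed: int = 0) -> pd.DataFrame:
    """Transition level of catalysis against M, versus ln(M) + ln(1/ln 2).

    For each M a p-sweep (all-network RAF mode) is run and the f at
    which the empirical curve crosses 0.5 is interpolated; the theory
    column is the asymptotic logarithmic law.
    """
    prof = _profile(profile)
    rows = []
    for j, m in enumerate(prof["fig4_M"]):
        grid = tuple((m, float(f) / (m - 10)) for f in _f_grid(m, prof["fig_points"]))
        res = estimate_raf_probability(
            SweepConfig(
                grid=grid, replicates=prof["fig4_reps"], seed=seed + j,
                raf_mode="all", M0=10, alpha=0.01, K=4,
            )
        )
        est = estimate_transition_point(res, level=0.5)
        rows.append(
            {
                "M": m,
                "f_transition": est.f,
                "f_se": est.se,
                "f_theory": required_level_of_catalysis(m, 0.5),
                "n": prof["fig4_reps"],
            }
        )
    return pd.DataFrame(rows)


def _profile(name: str) -> dict:
    try:
        return PROFILES[name]
    except KeyError:
        raise ValueError(
            f"unknown profile {name!r}; expected one of {sorted(PROFILES)}"
        ) from None


def figure_suite(
    profile: str = "fast", seed: int = 0, figures: tuple[str, ...] = ("fig2", "fig3", "fig4")
) -> dict[str, pd.DataFrame]:
    """Regenerate the requested figure tables from one master seed."""
    builders = {"fig2": fig2_table, "fig3": fig3_table, "fig4": fig4_table}
    unknown = set(figures) - set(builders)
    if unknown:
        raise ValueError(f"unknown figures {sorted(unknown)}")
    return {name: builders[name](profile=profile, seed=seed) for name in figures}
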