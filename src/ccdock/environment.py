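"""Partner competition in sampled crowded environments.

The interaction rank (IR) of a pair (P1, P2) within an environment is
the best rank of the pair's NII among all pairs featuring P1 or P2 as
receptor: the pair is ranked within the NII row of P1 and within the row
of P2 (descending), and the better position is kept.  Sampling many
random environments around a target complex yields an IR distribution
whose mean and spread, together with the per-environment AUC, form a
signature separating three partner populations: strong competitors
(low, stable rank), never-competing proteins (high, stable rank), and
partners of intermediate, variable strength.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import Config, DEFAULTS
from .evaluation import GoldStandard, roc_auc

log = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass
class Environment:
    """A sampled set of complexes competing with a target complex."""

    complexes: list[Pair]
    target: Pair
    env_id: int = 0

    def __post_init__(self) -> None:
        if self.target not in self.complexes:
            raise ValueError("environment must contain the target complex")

    @property
    def proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b in self.complexes:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)


@dataclass
class IRSignature:
    query: str
    candidate: str
    mean_ir: float
    sd_ir: float
    mean_auc: float
    label: str  # strong_competitor | never_competes | intermediate
    ranks: np.ndarray = field(default_factory=lambda: np.array([]))


def interaction_rank(nii: pd.DataFrame, pair: Pair,
                     scope: Iterable[str] | None = None) -> int:
    """Best rank of the pair within the NII rows of its two partners.

    Ties share the best position; a masked (NaN) target entry is
    undefined and raises.
    """
    p1, p2 = pair
    cols = list(nii.columns if scope is None else scope)
    for p in pair:
        if p not in nii.index:
            raise KeyError(p)

    def row_rank(receptor: str, partner: str) -> int:
        row = nii.loc[receptor, cols].to_numpy(dtype=float)
        target = nii.loc[receptor, partner]
        if np.isnan(target):
            raise ValueError(f"masked NII entry for ({receptor}, {partner})")
        better = np.nansum(row > target)
        return int(better) + 1

    return min(row_rank(p1, p2), row_rank(p2, p1))


def sample_environments(complexes: Sequence[Pair], target: Pair,
                        n_sets: int | None = None,
                        n_complexes: int | None = None,
                        seed: int = 0,
                        config: Config = DEFAULTS) -> list[Environment]:
    """Random environments: the target complex plus (n_complexes - 1)
    others sampled uniformly without replacement, reproducibly from the
    seed (one sub-seed per environment)."""
    n_sets = config.env_n_sets if n_sets is None else n_sets
    n_cpx = config.env_n_complexes if n_complexes is None else n_complexes
    others = [c for c in complexes if c != target]
    if n_cpx - 1 > len(others):
        raise ValueError(f"need {n_cpx - 1} non-target complexes, "
                         f"have {len(others)}")
    envs = []
    for k in range(n_sets):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        picked = [others[i] for i in
                  rng.choice(len(others), size=n_cpx - 1, replace=False)]
        envs.append(Environment([target] + picked, target, env_id=k))
    return envs


def _environment_auc(nii: pd.DataFrame, env: Environment) -> float:
    gold = GoldStandard(native_pairs=set(map(frozenset, env.complexes)),
                        universe=set(env.proteins))
    try:
        return roc_auc(nii.loc[env.proteins, env.proteins], gold)
    except ValueError:
        return float("nan")


def ir_distribution(nii: pd.DataFrame, pair: Pair,
                    environments: Sequence[Environment]
                    ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Per-environment interaction ranks and AUCs of a pair.

    Returns (mean rank, population standard deviation, ranks, aucs).
    """
    ranks = np.array([interaction_rank(nii, pair, env.proteins)
                      for env in environments], dtype=float)
    aucs = np.array([_environment_auc(nii, env) for env in environments])
    return float(ranks.mean()), float(ranks.std()), ranks, aucs


def signature(query: str, candidates: Sequence[str], nii: pd.DataFrame,
              complexes: Sequence[Pair], seed: int = 0,
              n_sets: int | None = None, n_complexes: int | None = None,
              config: Config = DEFAULTS) -> list[IRSignature]:
    """IR signature of a query protein against candidate partners.

    Each candidate pair is embedded in its own sampled environments; the
    three-population label uses the configured rank and spread
    thresholds.
    """
    sigs = []
    for cand in candidates:
        target = (query, cand)
        base = [c for c in complexes if query not in c and cand not in c]
        envs = sample_environments(base + [target], target, n_sets,
                                   n_complexes, seed=seed, config=config)
        mean_ir, sd_ir, ranks, aucs = ir_distribution(nii, target, envs)
        # the per-row ranking caps at the scope size, so "always last"
        # means a mean rank near the number of proteins in the environment
        scope_size = len(envs[0].proteins)
        if mean_ir <= config.label_t_low and sd_ir <= config.label_s_stable:
            label = "strong_competitor"
        elif mean_ir >= scope_size - config.label_t_high_margin \
                and sd_ir <= config.label_s_stable:
            label = "never_competes"
        else:
            label = "intermediate"
        sigs.append(IRSignature(query, cand, mean_ir, sd_ir,
                                float(np.nanmean(aucs)), label, ranks))
    return sigs


def false_positives_at(query: str, signatures: Sequence[IRSignature],
                       native_partner: str,
                       ir_threshold: float | None = None,
                       config: Config = DEFAULTS) -> int:
    """Number of non-native candidates whose mean IR clears the
    threshold (competitors that would be reported alongside the true
    partner)."""
    t = config.ir_top if ir_threshold is None else ir_threshold
    return sum(1 for s in signatures
               if s.query == query and s.candidate != native_partner
               and s.mean_ir <= t)


def rank_recovery_table(nii: pd.DataFrame, native_pairs: Sequence[Pair],
                        fractions: Sequence[float] = (0.01, 0.05, 0.10, 0.15,
                                                      0.20, 0.30, 0.40, 0.50)
                        ) -> pd.DataFrame:
    """Cumulative counts of proteins whose native partner ranks within
    the top round(f * N) NII scores of their row.

    The top-set size is the nearest integer of f * N, floored at 1.
    Returns one row per fraction with columns (fraction, top, count,
    percent).
    """
    partner_of: dict[str, str] = {}
    for a, b in native_pairs:
        partner_of[a] = b
        partner_of[b] = a
    proteins = [p for p in nii.index if p in partner_of]
    n = len(proteins)
    ranks = {}
    for p in proteins:
        try:
            ranks[p] = interaction_rank(nii, (p, partner_of[p]))
        except ValueError:
            ranks[p] = np.inf  # masked: never recovered
    rows = []
    for f in fractions:
        top = max(1, int(round(f * n)))
        count = sum(1 for p in proteins if ranks[p] <= top)
        rows.append({"fraction": f, "top": top, "count": count,
                     "percent": 100.0 * count / n if n else np.nan})
    table = pd.DataFrame(rows)
    if not table["count"].is_monotonic_increasing:
        raise AssertionError("recovery counts must be non-decreasing")
    return table
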