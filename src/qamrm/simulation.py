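"""Synthetic data generation and the parameter-recovery study.

The generator draws, per person, a latent class from the mixing distribution,
an ability theta ~ N(0, sd^2), and Bernoulli responses through the Rasch IRF
at the class's anchored difficulties.  The default truth follows the recovery
study design: K = 3 attributes, J = 14 items, uniform mixing over the 8
profiles, standard-normal ability, and level difficulty values

* 2-level items: (-2, 2)
* 3-level items: (-2, 1, 2)
* 4-level items: (-2, -1, 1, 2)

with ascending level index (1 = all required attributes mastered) receiving
ascending difficulty, i.e. level 1 is easiest at -2.

The recovery study repeats simulate -> fit -> record (estimate - truth) and
95% Wald CI coverage per difficulty slot, and averages over replications.
Per-replication seeds derive deterministically from the master seed, so
results are independent of execution order.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .estimation import FitConfig, fit_em
from .likelihood import QAMRMParams, ResponseMatrix, class_difficulty_matrix
from .qstructure import (
    AnchorMap,
    LatentClassSpace,
    ParameterLayout,
    QMatrix,
    build_anchor_map,
    build_layout,
    enumerate_profiles,
)

DEFAULT_LEVEL_VALUES: dict[int, tuple[float, ...]] = {
    1: (0.0,),
    2: (-2.0, 2.0),
    3: (-2.0, 1.0, 2.0),
    4: (-2.0, -1.0, 1.0, 2.0),
}


@dataclass(frozen=True)
class TruthSpec:
    """Generating truth: Q-matrix, anchoring mode, level values, mixing, ability.

    ``level_values[L]`` is the strictly increasing tuple of difficulty values
    used by items with L realized levels (level 1, the full-mastery level,
    gets the smallest value).
    """

    q: QMatrix
    mode: str
    level_values: Mapping[int, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_VALUES)
    )
    mixing: np.ndarray | None = None  # default uniform over the class space
    ability_sd: float = 1.0

    def __post_init__(self) -> None:
        for L, vals in self.level_values.items():
            if len(vals) != L:
                raise ValueError(f"level_values[{L}] must have {L} entries")
            if not all(a < b for a, b in zip(vals, vals[1:])):
                raise ValueError(f"level_values[{L}] must be strictly increasing")
        if self.mixing is not None:
            m = np.asarray(self.mixing, dtype=float)
            if (m <= 0).any() or not np.isclose(m.sum(), 1.0):
                raise ValueError("mixing must be positive and sum to 1")
            object.__setattr__(self, "mixing", m)

    def default_space(self) -> LatentClassSpace:
        return enumerate_profiles(self.q.n_attributes)

    def true_params(
        self, space: LatentClassSpace | None = None
    ) -> tuple[QAMRMParams, ParameterLayout, AnchorMap]:
        """Expand the truth to slot difficulties for a given class space."""
        space = space or self.default_space()
        amap = build_anchor_map(self.q, space, self.mode)
        layout = build_layout(amap, anchored=True)
        b = np.empty(layout.n_difficulty)
        for s, (j, _lv) in enumerate(layout.difficulty_slots):
            n_lv = int(amap.n_levels[j])
            if n_lv not in self.level_values:
                raise KeyError(
                    f"no level values defined for items with {n_lv} levels"
                )
            # rank of this slot among the item's slots, in ascending level order
            rank = sum(
                1
                for (jj, ll) in layout.difficulty_slots[:s]
                if jj == j
            )
            b[s] = self.level_values[n_lv][rank]
        mixing = (
            self.mixing
            if self.mixing is not None
            else np.full(space.n_classes, 1.0 / space.n_classes)
        )
        if mixing.size != space.n_classes:
            raise ValueError("mixing length does not match the class space")
        params = QAMRMParams(
            difficulties=b, mixing=mixing, ability_sd=self.ability_sd
        )
        return params, layout, amap


def simulate_dataset(
    truth: TruthSpec,
    n: int,
    seed: int,
    space: LatentClassSpace | None = None,
) -> tuple[ResponseMatrix, np.ndarray, np.ndarray]:
    """Draw (responses, true classes, true abilities) from the generating truth."""
    if n < 1:
        raise ValueError("need at least one person")
    space = space or truth.default_space()
    params, layout, _ = truth.true_params(space)
    rng = np.random.default_rng(seed)
    classes = rng.choice(space.n_classes, size=n, p=params.mixing)
    thetas = rng.normal(0.0, truth.ability_sd, size=n)
    B = class_difficulty_matrix(params, layout)  # (J, G)
    probs = expit(thetas[:, None] - B[:, classes].T)  # (N, J)
    values = (rng.random((n, truth.q.n_items)) < probs).astype(float)
    y = ResponseMatrix(values=values, item_labels=truth.q.item_labels)
    return y, classes, thetas


@dataclass
class RecoveryReport:
    """Bias and 95% CI coverage of the difficulty estimates across replications."""

    mode: str
    n: int
    replications: int
    n_used: int
    n_failed: int
    seed: int
    slots: tuple[tuple[int, int], ...]
    truth: np.ndarray  # (S,)
    bias: np.ndarray  # (S,) per-slot mean signed bias
    abs_bias: np.ndarray  # (S,) per-slot mean absolute error
    coverage: np.ndarray  # (S,) per-slot CI coverage
    pooled_bias: float  # unweighted mean over slots of signed bias
    pooled_abs_bias: float
    pooled_coverage: float
    valid: bool  # False when more than 10% of replications failed

    def to_frame(self, item_labels: Sequence[str] | None = None) -> pd.DataFrame:
        items = [j for j, _ in self.slots]
        rows = {
            "item": [item_labels[j] if item_labels else j + 1 for j in items],
            "level": [lv for _, lv in self.slots],
            "truth": self.truth,
            "bias": self.bias,
            "abs_bias": self.abs_bias,
            "coverage": self.coverage,
        }
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "n": self.n,
            "replications": self.replications,
            "replications_used": self.n_used,
            "replications_failed": self.n_failed,
            "seed": self.seed,
            "pooled_bias": self.pooled_bias,
            "pooled_abs_bias": self.pooled_abs_bias,
            "pooled_coverage": self.pooled_coverage,
            "valid": self.valid,
        }


def run_recovery_study(
    truth: TruthSpec,
    n: int,
    replications: int,
    cfg: FitConfig,
    seed: int,
    space: LatentClassSpace | None = None,
    ci_z: float = 1.959963984540054,
) -> RecoveryReport:
    """Simulate -> fit -> score, ``replications`` times, and pool the results.

    A replication counts as failed when EM does not converge or the observed
    information is unusable; failed replications are excluded and counted, and
    the report is flagged invalid when more than 10% fail.
    """
    if replications < 1:
        raise ValueError("need at least one replication")
    space = space or truth.default_space()
    true_params, layout, _ = truth.true_params(space)
    b_true = true_params.difficulties
    S = layout.n_difficulty
    errs = np.full((replications, S), np.nan)
    covers = np.full((replications, S), np.nan)
    ok = np.zeros(replications, dtype=bool)
    children = np.random.SeedSequence(seed).spawn(replications)
    cfg = replace(cfg, compute_se=True)
    for r, child in enumerate(children):
        s_sim, s_fit = (int(s) % 2**31 for s in child.generate_state(2))
        y, _, _ = simulate_dataset(truth, n, seed=s_sim, space=space)
        fit = fit_em(y, truth.q, space, truth.mode, cfg=replace(cfg, seed=s_fit))
        if not (fit.converged and fit.se is not None and fit.se.ok
                and np.isfinite(fit.se.difficulties).all()):
            continue
        est = fit.params.difficulties
        se = fit.se.difficulties
        errs[r] = est - b_true
        covers[r] = (est - ci_z * se <= b_true) & (b_true <= est + ci_z * se)
        ok[r] = True
    n_used = int(ok.sum())
    n_failed = replications - n_used
    if n_used == 0:
        raise RuntimeError("every replication failed to converge")
    bias = errs[ok].mean(axis=0)
    abs_bias = np.abs(errs[ok]).mean(axis=0)
    coverage = covers[ok].mean(axis=0)
    return RecoveryReport(
        mode=truth.mode,
        n=n,
        replications=replications,
        n_used=n_used,
        n_failed=n_failed,
        seed=seed,
        slots=layout.difficulty_slots,
        truth=b_true,
        bias=bias,
        abs_bias=abs_bias,
        coverage=coverage,
        pooled_bias=float(bias.mean()),
        pooled_abs_bias=float(np.abs(bias).mean()),
        pooled_coverage=float(coverage.mean()),
        valid=n_failed <= 0.1 * replications,
    )
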