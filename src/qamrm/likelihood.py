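"""Rasch item response function and the anchored-mixture marginal likelihood.

The model: person i belongs to latent class g (an attribute profile) with
prior probability pi_g; within every class ability is continuous,
theta ~ N(0, sigma^2) with the mean fixed at 0 for identification and one
variance shared across classes.  Given theta, responses are locally
independent Rasch:

    P(Y_ij = 1 | theta, g) = exp(theta - b_{j, L_jg}) / (1 + exp(theta - b_{j, L_jg}))

where L_jg is the anchor map's difficulty level of item j in class g, so
classes sharing a level share the difficulty parameter literally.  The
marginal likelihood integrates theta out with Gauss-Hermite quadrature and
sums over classes.

All likelihood computations are carried out in log space.  Missing responses
(NaN) are treated as ignorable and simply skipped in the product over items.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from .qstructure import ParameterLayout


def irf(theta, b):
    """Rasch item response function P = sigma(theta - b), overflow-safe.

    Strictly increasing in ability ``theta``, strictly decreasing in
    difficulty ``b``; depends on the pair only through theta - b.
    """
    return expit(np.asarray(theta, dtype=float) - np.asarray(b, dtype=float))


# ---------------------------------------------------------------------------
# Quadrature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadratureRule:
    """Nodes and normalized weights approximating integration against N(0, sd^2)."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.shape != weights.shape or nodes.ndim != 1:
            raise ValueError("nodes and weights must be matching 1-D arrays")
        if (weights <= 0).any():
            raise ValueError("quadrature weights must be positive")
        weights = weights / weights.sum()
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @property
    def size(self) -> int:
        return self.nodes.size

    @classmethod
    def gauss_hermite(cls, n: int = 31, sd: float = 1.0) -> "QuadratureRule":
        """Gauss-Hermite rule rescaled to the N(0, sd^2) ability density."""
        if n < 1:
            raise ValueError("need at least one node")
        if sd <= 0:
            raise ValueError("ability sd must be positive")
        x, w = np.polynomial.hermite.hermgauss(n)
        return cls(nodes=np.sqrt(2.0) * sd * x, weights=w / np.sqrt(np.pi))

    @classmethod
    def degenerate(cls, value: float = 0.0) -> "QuadratureRule":
        """Single-node rule: the sd -> 0 limit, ability pinned at ``value``."""
        return cls(nodes=np.array([value]), weights=np.array([1.0]))


# ---------------------------------------------------------------------------
# Parameters and responses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QAMRMParams:
    """Free parameters: slot difficulties, mixing proportions, shared ability sd.

    The ability mean is fixed at 0 (identification convention: with the trait
    location pinned, all anchored difficulties sit on one common scale) and is
    not a free parameter.  Difficulties are logits in the convention
    ``P = sigma(theta - b)``; larger b means a harder item.
    """

    difficulties: np.ndarray  # one value per layout slot
    mixing: np.ndarray  # (G,), sums to 1
    ability_sd: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.difficulties, dtype=float)
        m = np.asarray(self.mixing, dtype=float)
        if not np.isfinite(d).all():
            raise ValueError("difficulties must be finite")
        if (m <= 0).any() or not np.isclose(m.sum(), 1.0, atol=1e-8):
            raise ValueError("mixing proportions must be positive and sum to 1")
        if not self.ability_sd > 0:
            raise ValueError("ability_sd must be positive")
        object.__setattr__(self, "difficulties", d)
        object.__setattr__(self, "mixing", m / m.sum())

    @property
    def ability_mean(self) -> float:
        return 0.0

    @property
    def n_classes(self) -> int:
        return self.mixing.size


def class_difficulty_matrix(params: QAMRMParams, layout: ParameterLayout) -> np.ndarray:
    """Expand slot difficulties to the full items x classes matrix b_{jg}."""
    if params.difficulties.size != layout.n_difficulty:
        raise ValueError(
            f"params carry {params.difficulties.size} difficulties but the "
            f"layout defines {layout.n_difficulty} slots"
        )
    return params.difficulties[layout.slot_of]


@dataclass(frozen=True)
class ResponseMatrix:
    """Dichotomous responses, persons x items; NaN marks a missing response."""

    values: np.ndarray  # (N, J) float with NaN for missing
    item_labels: tuple[str, ...] = ()
    person_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("response matrix must be 2-D (persons x items)")
        observed = ~np.isnan(values)
        body = values[observed]
        if not np.isin(body, (0.0, 1.0)).all():
            raise ValueError("responses must be 0, 1 or missing (NaN)")
        empty_rows = np.flatnonzero(~observed.any(axis=1))
        if empty_rows.size:
            raise ValueError(
                f"person row(s) {empty_rows.tolist()} have no observed response"
            )
        empty_cols = np.flatnonzero(~observed.any(axis=0))
        if empty_cols.size:
            raise ValueError(
                f"item column(s) {empty_cols.tolist()} have no observed response"
            )
        object.__setattr__(self, "values", values)
        if not self.item_labels:
            object.__setattr__(
                self,
                "item_labels",
                tuple(f"item{j + 1}" for j in range(values.shape[1])),
            )

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def complete(self) -> bool:
        return bool(self.mask.all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.item_labels))


def read_responses(path: str | Path) -> ResponseMatrix:
    """Read a response matrix from delimited text (header = item labels)."""
    frame = pd.read_csv(path, sep=None, engine="python")
    values = frame.to_numpy(dtype=float)
    return ResponseMatrix(
        values=values, item_labels=tuple(str(c) for c in frame.columns)
    )


def write_responses(y: ResponseMatrix, path: str | Path) -> None:
    frame = y.to_frame()
    # keep observed cells as bare integers in the file
    frame.to_csv(path, index=False, na_rep="NA", float_format="%.0f")


# ---------------------------------------------------------------------------
# Log-likelihoods
# ---------------------------------------------------------------------------

def response_loglik_nodes(
    y: ResponseMatrix, B: np.ndarray, quad: QuadratureRule
) -> np.ndarray:
    """log P(y_i | theta_q, class g) for every person, class and node.

    Returns an (N, G, Q) array; missing items contribute nothing.  This is the
    computational core of the E-step, arranged as two dense matmuls.
    """
    theta = quad.nodes
    J, G = B.shape
    Q = theta.size
    logits = theta[None, None, :] - B[:, :, None]  # (J, G, Q)
    lp = -np.logaddexp(0.0, -logits)  # log P(correct)
    lq = lp - logits  # log P(incorrect)
    lp = lp.reshape(J, G * Q)
    lq = lq.reshape(J, G * Q)
    if y.complete:
        vals = y.values
        ll = vals @ lp + (1.0 - vals) @ lq
    else:
        mask = y.mask
        y1 = np.where(mask, y.values, 0.0)
        y0 = mask - y1
        ll = y1 @ lp + y0 @ lq
    return ll.reshape(y.n_persons, G, Q)


def class_conditional_loglik(
    y: ResponseMatrix,
    params: QAMRMParams,
    layout: ParameterLayout,
    quad: QuadratureRule,
) -> np.ndarray:
    """N x G matrix of log integral_theta prod_j P(y_ij | theta, b_{j,L_jg}) dF(theta)."""
    B = class_difficulty_matrix(params, layout)
    ll = response_loglik_nodes(y, B, quad)
    out = logsumexp(ll + np.log(quad.weights)[None, None, :], axis=2)
    if not np.isfinite(out).all():
        raise FloatingPointError("non-finite class-conditional log-likelihood")
    return out


def marginal_loglik(
    y: ResponseMatrix,
    params: QAMRMParams,
    layout: ParameterLayout,
    quad: QuadratureRule,
) -> float:
    """Marginal log-likelihood: sum_i log sum_g pi_g exp(class-conditional ll)."""
    cc = class_conditional_loglik(y, params, layout, quad)
    return float(logsumexp(cc + np.log(params.mixing)[None, :], axis=1).sum())
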