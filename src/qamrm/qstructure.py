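"""Latent-class structure: Q-matrices, attribute-profile spaces and anchoring maps.

A Q-matrix is a binary items x attributes incidence matrix declaring which
latent skills each item requires.  In a Q-matrix anchored mixture Rasch model
the latent classes are attribute profiles (binary mastery vectors), and the
Q-matrix ties item difficulties across classes *a priori*: two classes whose
mastery intersects an item's required set in the same way share that item's
difficulty parameter.  These equality constraints act as anchor items, placing
every class on one common logit scale without post-hoc linking.

The anchoring comes in two flavours:

* ``non_compensatory`` (conjunctive): an item sits at its easy level only for
  classes that master *all* attributes it requires — each item has at most two
  difficulty levels.
* ``compensatory`` (disjunctive): each additional mastered required attribute
  lowers the item one difficulty level — an item requiring ``m`` attributes has
  up to ``m + 1`` levels.

This module builds and validates those structures and the parameter layout
(free difficulty slots) they induce.
"""
from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NON_COMPENSATORY = "non_compensatory"
COMPENSATORY = "compensatory"
ANCHOR_MODES = (NON_COMPENSATORY, COMPENSATORY)

MAX_ATTRIBUTES = 12


class QMatrixFormatError(ValueError):
    """A Q-matrix file or array contains cells that are not 0/1."""


class QMatrixValidationError(ValueError):
    """A structurally invalid Q-matrix (all-zero row or column)."""


class HierarchyError(ValueError):
    """An invalid attribute-hierarchy specification."""


# ---------------------------------------------------------------------------
# Q-matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QMatrix:
    """Binary items x attributes incidence matrix.

    ``entries[j, k] == 1`` iff attribute ``k`` is required to answer item ``j``
    correctly.  Every item must require at least one attribute and every
    attribute must be measured by at least one item.
    """

    entries: np.ndarray
    item_labels: tuple[str, ...]
    attribute_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries)
        if entries.ndim != 2:
            raise QMatrixFormatError("Q-matrix must be two-dimensional")
        if not np.isin(entries, (0, 1)).all():
            bad = entries[~np.isin(entries, (0, 1))].ravel()[0]
            raise QMatrixFormatError(
                f"Q-matrix cells must be 0 or 1; found {bad!r}"
            )
        entries = entries.astype(np.int8)
        object.__setattr__(self, "entries", entries)
        if len(self.item_labels) != entries.shape[0]:
            raise QMatrixFormatError("item label count does not match rows")
        if len(self.attribute_labels) != entries.shape[1]:
            raise QMatrixFormatError("attribute label count does not match columns")
        zero_rows = np.flatnonzero(entries.sum(axis=1) == 0)
        if zero_rows.size:
            names = ", ".join(self.item_labels[j] for j in zero_rows)
            raise QMatrixValidationError(
                f"item(s) {names} require no attribute (all-zero Q-matrix row)"
            )
        zero_cols = np.flatnonzero(entries.sum(axis=0) == 0)
        if zero_cols.size:
            names = ", ".join(self.attribute_labels[k] for k in zero_cols)
            raise QMatrixValidationError(
                f"attribute(s) {names} are measured by no item (all-zero column)"
            )

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries,
            index=list(self.item_labels),
            columns=list(self.attribute_labels),
        )

    @classmethod
    def from_array(
        cls,
        entries: np.ndarray | Sequence[Sequence[int]],
        item_labels: Sequence[str] | None = None,
        attribute_labels: Sequence[str] | None = None,
    ) -> "QMatrix":
        entries = np.asarray(entries)
        j, k = entries.shape
        items = tuple(item_labels) if item_labels is not None else tuple(
            f"item{i + 1}" for i in range(j)
        )
        attrs = tuple(attribute_labels) if attribute_labels is not None else tuple(
            f"a{i + 1}" for i in range(k)
        )
        return cls(entries=entries, item_labels=items, attribute_labels=attrs)


def read_qmatrix(path: str | Path) -> QMatrix:
    """Read a Q-matrix from delimited text (comma or tab).

    Expected layout: header row of attribute labels, first column item labels,
    body cells in {0, 1}.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    values = frame.to_numpy()
    if values.size == 0:
        raise QMatrixFormatError(f"{path}: empty Q-matrix")
    try:
        numeric = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise QMatrixFormatError(f"{path}: non-numeric Q-matrix cell ({exc})") from exc
    if not np.isin(numeric, (0.0, 1.0)).all():
        raise QMatrixFormatError(f"{path}: Q-matrix cells must be 0 or 1")
    return QMatrix(
        entries=numeric.astype(np.int8),
        item_labels=tuple(str(i) for i in frame.index),
        attribute_labels=tuple(str(c) for c in frame.columns),
    )


# ---------------------------------------------------------------------------
# Latent class space
# ---------------------------------------------------------------------------

def profile_label(profile: Iterable[int]) -> str:
    return "".join(str(int(a)) for a in profile)


@dataclass(frozen=True)
class LatentClassSpace:
    """The admissible attribute profiles, in canonical order.

    Canonical order is binary counting with the first attribute most
    significant: for K=3 the full space is (000), (001), (010), ..., (111),
    labelled g1..g8.  A hierarchy restricts the space to a subset of profiles;
    for a linear mastery hierarchy over K attributes exactly K+1 monotone
    profiles survive.
    """

    profiles: np.ndarray  # (G, K) int8
    hierarchy: str | None = None

    def __post_init__(self) -> None:
        profiles = np.asarray(self.profiles, dtype=np.int8)
        if profiles.ndim != 2:
            raise HierarchyError("profiles must be a 2-D array")
        if not np.isin(profiles, (0, 1)).all():
            raise HierarchyError("profiles must be binary")
        keys = [tuple(int(a) for a in row) for row in profiles]
        if len(set(keys)) != len(keys):
            raise HierarchyError("duplicate attribute profiles")
        order = np.lexsort(profiles.T[::-1])
        object.__setattr__(self, "profiles", profiles[order])

    @property
    def n_classes(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.profiles.shape[1]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(profile_label(p) for p in self.profiles)

    def index_of(self, profile: Iterable[int]) -> int:
        key = tuple(int(a) for a in profile)
        for g, row in enumerate(self.profiles):
            if tuple(int(a) for a in row) == key:
                return g
        raise KeyError(f"profile {key} not in class space")


def _parse_chain(spec: str, K: int) -> list[int]:
    """Parse a linear-hierarchy chain such as ``"a3 < a2 < a1"`` or ``"3<2<1"``.

    The chain lists attributes in prerequisite order (leftmost mastered first)
    and must mention each of the K attributes exactly once.
    """
    tokens = [t.strip() for t in re.split(r"<|->|≺", spec) if t.strip()]
    chain: list[int] = []
    for tok in tokens:
        m = re.fullmatch(r"(?:[A-Za-z_]*?)(\d+)", tok)
        if not m:
            raise HierarchyError(f"cannot parse hierarchy token {tok!r}")
        idx = int(m.group(1)) - 1
        if not 0 <= idx < K:
            raise HierarchyError(f"attribute index {tok!r} outside 1..{K}")
        chain.append(idx)
    if len(set(chain)) != len(chain):
        raise HierarchyError(f"cyclic hierarchy: attribute repeated in {spec!r}")
    if len(chain) != K:
        raise HierarchyError(
            f"hierarchy {spec!r} must mention each of the {K} attributes once"
        )
    return chain


def enumerate_profiles(
    K: int,
    hierarchy: str | Sequence[Sequence[int]] | None = None,
) -> LatentClassSpace:
    """Enumerate the latent class space over K binary attributes.

    Without a hierarchy the space is the full set of 2**K profiles.  With a
    linear hierarchy (chain string, e.g. ``"a3<a2<a1"`` meaning attribute 3
    must be mastered before 2 before 1) only the K+1 monotone profiles remain.
    A general restriction can be given as an explicit list of profiles.
    """
    if not 1 <= K <= MAX_ATTRIBUTES:
        raise ValueError(
            f"number of attributes must be between 1 and {MAX_ATTRIBUTES}, got {K}"
        )
    if hierarchy is None:
        profiles = np.array(list(itertools.product((0, 1), repeat=K)), dtype=np.int8)
        return LatentClassSpace(profiles=profiles)
    if isinstance(hierarchy, str):
        chain = _parse_chain(hierarchy, K)
        rows = []
        for m in range(K + 1):
            row = np.zeros(K, dtype=np.int8)
            row[chain[:m]] = 1
            rows.append(row)
        return LatentClassSpace(profiles=np.array(rows), hierarchy=hierarchy)
    profiles = np.asarray(list(hierarchy), dtype=np.int8)
    if profiles.ndim != 2 or profiles.shape[1] != K:
        raise HierarchyError(f"explicit profile list must be G x {K}")
    return LatentClassSpace(profiles=profiles, hierarchy="explicit")


def read_profile_list(path: str | Path, K: int) -> LatentClassSpace:
    """Read an explicit hierarchy (one profile per row) from delimited text."""
    frame = pd.read_csv(path, sep=None, engine="python", header=None)
    values = frame.to_numpy()
    if values.shape[1] == K + 1:  # optional leading label column
        values = values[:, 1:]
    return enumerate_profiles(K, hierarchy=values.astype(int))


# ---------------------------------------------------------------------------
# Anchor map and parameter layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnchorMap:
    """Item x class matrix of difficulty-level indices (1 = easiest).

    ``levels[j, g]`` is the difficulty level of item ``j`` in class ``g``:
    1 when the class masters everything the item requires, increasing with
    unmastered required attributes (compensatory) or jumping straight to 2 for
    any deficit (non-compensatory).  ``n_levels[j]`` counts the distinct
    levels actually realized by the profiles present in the class space; only
    realized levels receive free parameters.
    """

    mode: str
    levels: np.ndarray  # (J, G) int
    n_levels: np.ndarray  # (J,) int

    @property
    def n_items(self) -> int:
        return self.levels.shape[0]

    @property
    def n_classes(self) -> int:
        return self.levels.shape[1]

    def distinct_levels(self, item: int) -> np.ndarray:
        return np.unique(self.levels[item])


def build_anchor_map(q: QMatrix, space: LatentClassSpace, mode: str) -> AnchorMap:
    """Derive the anchoring (level) map from a Q-matrix and a class space.

    The level of item j in class g depends on the profile only through how
    many of the item's required attributes the class has *not* mastered:
    non-compensatory collapses any deficit to level 2, compensatory counts
    each missing attribute as one level.
    """
    if mode not in ANCHOR_MODES:
        raise ValueError(f"mode must be one of {ANCHOR_MODES}, got {mode!r}")
    if q.n_attributes != space.n_attributes:
        raise ValueError(
            f"Q-matrix has {q.n_attributes} attributes but the class space "
            f"has {space.n_attributes}"
        )
    # deficits[j, g] = number of attributes required by item j not mastered by g
    deficits = q.entries @ (1 - space.profiles.T)
    if mode == NON_COMPENSATORY:
        levels = 1 + (deficits > 0).astype(np.int64)
    else:
        levels = (1 + deficits).astype(np.int64)
    n_levels = np.array([np.unique(row).size for row in levels])
    return AnchorMap(mode=mode, levels=levels, n_levels=n_levels)


@dataclass(frozen=True)
class ParameterLayout:
    """Free-parameter bookkeeping for a (possibly anchored) mixture Rasch model.

    ``difficulty_slots`` lists the (item, level) pairs that receive a free
    difficulty parameter, item-major with levels ascending; for the
    unconstrained mixture Rasch layout the second member is the class index + 1
    (every item x class cell is free).  ``slot_of[j, g]`` maps each cell to its
    slot.  Mixing proportions contribute G − 1 free parameters and the shared
    ability variance one more.
    """

    anchored: bool
    difficulty_slots: tuple[tuple[int, int], ...]
    slot_of: np.ndarray  # (J, G) int
    n_classes: int

    @property
    def n_items(self) -> int:
        return self.slot_of.shape[0]

    @property
    def n_difficulty(self) -> int:
        return len(self.difficulty_slots)

    @property
    def n_mixing(self) -> int:
        return self.n_classes - 1

    @property
    def n_variance(self) -> int:
        return 1

    @property
    def n_total(self) -> int:
        return self.n_difficulty + self.n_mixing + self.n_variance


def build_layout(amap: AnchorMap, anchored: bool = True) -> ParameterLayout:
    """Lay out the free difficulty slots implied by an anchor map.

    Anchored: one slot per (item, realized level); unconstrained (plain
    mixture Rasch): one slot per (item, class) cell.
    """
    J, G = amap.levels.shape
    slot_of = np.empty((J, G), dtype=np.int64)
    slots: list[tuple[int, int]] = []
    if anchored:
        for j in range(J):
            index_of_level = {}
            for lv in np.unique(amap.levels[j]):
                index_of_level[int(lv)] = len(slots)
                slots.append((j, int(lv)))
            for g in range(G):
                slot_of[j, g] = index_of_level[int(amap.levels[j, g])]
    else:
        for j in range(J):
            for g in range(G):
                slot_of[j, g] = len(slots)
                slots.append((j, g + 1))
    return ParameterLayout(
        anchored=anchored,
        difficulty_slots=tuple(slots),
        slot_of=slot_of,
        n_classes=G,
    )
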