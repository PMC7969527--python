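"""Bundled design fixtures.

Two designs ship with the package:

* the 14-item, 3-attribute recovery design used throughout the simulation
  study (6 one-attribute, 6 two-attribute and 2 three-attribute items), and
* the 28-item, 3-skill ECPE Q-matrix (morphosyntactic, cohesive and lexical
  rules, measured by 13, 6 and 18 items respectively) together with its
  linear mastery hierarchy lexical -> cohesive -> morphosyntactic.

The ECPE response data themselves are not bundled; see the repository's
``scripts/ecpe_export.R`` for exporting them from the CDM R package.
"""
from __future__ import annotations

from importlib import resources

from .qstructure import LatentClassSpace, QMatrix, enumerate_profiles, read_qmatrix
from .simulation import TruthSpec

ECPE_HIERARCHY = "a3 < a2 < a1"  # lexical before cohesive before morphosyntactic


def _data_path(name: str):
    return resources.files("qamrm").joinpath("data", name)


def recovery_design_qmatrix() -> QMatrix:
    """The 14-item, 3-attribute Q-matrix of the parameter-recovery design."""
    with resources.as_file(_data_path("recovery_design_qmatrix.csv")) as p:
        return read_qmatrix(p)


def recovery_truth(mode: str) -> TruthSpec:
    """Generating truth for the recovery study under the given anchoring mode.

    Uniform mixing over the 8 profiles, N(0,1) ability, and the standard level
    values (-2, 2) / (-2, 1, 2) / (-2, -1, 1, 2).
    """
    return TruthSpec(q=recovery_design_qmatrix(), mode=mode)


def ecpe_qmatrix() -> QMatrix:
    """The 28 x 3 ECPE Q-matrix."""
    with resources.as_file(_data_path("ecpe_qmatrix.csv")) as p:
        return read_qmatrix(p)


def ecpe_class_space(hierarchical: bool = True) -> LatentClassSpace:
    """ECPE class space: the 4-profile linear hierarchy, or all 8 profiles."""
    if hierarchical:
        return enumerate_profiles(3, hierarchy=ECPE_HIERARCHY)
    return enumerate_profiles(3)
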