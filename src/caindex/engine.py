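"""The Comparative Anatomy Index engine.

Scores the similarity of anatomical structures between a *control* species and
comparison species from discrete character states.  For each structure j of
species i, each attribute k carries a relative frequency P_ijk in [0, 1]; the
weighted attribute-frequency average

    PAF = P_w(ij) = sum_k w_k * P_ijk / sum_k w_k

summarizes the structure, and the Comparative Anatomy Index

    CAI_ii' = | P_w(ij) - P_w(i'j) |

is the per-structure distance between the control i and a comparison species
i' (0 identical, 1 maximally different or absent).  The group index GCAI is
the distance of group means, equal to the mean of member CAIs under the
modal-control convention (the control's attribute frequencies are fixed at 1).

Deviation rules
---------------
Attribute frequencies for a comparison species are expressed as deviations
d_k = 1 - P_i'jk from the control state:

* component attributes (innervation, origin, insertion): a quarter unit per
  differing component, capped at 1; two non-empty states sharing no component
  score the full cap (a completely different state);
* vascularization: species with the same number of palmar arterial arches
  score 0, otherwise 1/2 (one arch vs two);
* structure count: d = min(1, 1/4 * |k_control - k_other|);
* variant-head frequencies: where a comparison species carries an extra head
  with frequency f, innervation, origin and count score d = 3/4 * f instead
  of set comparison;
* a structure absent in the comparison species scores CAI = 1 outright.

Published table cells that no counting rule reproduces are pinned by explicit
:class:`~caindex.characters.DeviationOverride` entries and flagged in every
result.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .characters import (
    ATTRIBUTE_KINDS,
    AttributeKind,
    ComparisonResult,
    ComponentSet,
    DeviationOverride,
    GroupResult,
    ObservationFrequency,
    SpeciesProfile,
    StructureState,
    WeightScheme,
)
from .rounding import round_half_up

__all__ = [
    "DeviationMode",
    "DeviationRule",
    "frequency",
    "count_penalty",
    "variant_frequency_penalty",
    "component_deviation",
    "attribute_deviation",
    "paf",
    "cai",
    "group_gcai",
    "compare_profiles",
    "pairwise_matrix",
    "PairwiseResult",
    "upgma_tree",
]


class DeviationMode(str, enum.Enum):
    """How differing components are counted."""

    SYMMETRIC_DIFFERENCE = "symmetric_difference"
    MISSING_ONLY = "missing_only"


@dataclass(frozen=True)
class DeviationRule:
    """Counting rule for component deviations.

    ``quarter_unit`` is the deviation per differing component (default 1/4);
    ``cap`` the maximum attribute deviation (fixed at 1).
    """

    mode: DeviationMode = DeviationMode.SYMMETRIC_DIFFERENCE
    quarter_unit: float = 0.25
    cap: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.quarter_unit <= 1:
            raise ValueError("quarter_unit must lie in (0, 1]")
        if self.cap != 1.0:
            raise ValueError("cap is fixed at 1")


def frequency(obs: ObservationFrequency) -> float:
    """Relative frequency P = r_v / N of the modal state."""
    if obs.n == 0:
        raise ZeroDivisionError("relative frequency undefined for N = 0")
    if not obs.is_valid:
        raise ValueError(f"invalid observation frequency {obs.r_v}/{obs.n}")
    return obs.r_v / obs.n


def count_penalty(k_control: float, k_other: float) -> float:
    """Frequency credited for a structure-count difference.

    1 - 1/4 per structure more or fewer than the control, floored at 0.
    A structure absent in the comparison species (k_other = 0 while the
    control has it) is credited 0 outright.
    """
    if k_control < 0 or k_other < 0:
        raise ValueError("structure counts must be non-negative")
    if k_control > 0 and k_other == 0:
        return 0.0
    return max(0.0, 1.0 - 0.25 * abs(k_control - k_other))


def variant_frequency_penalty(f: float) -> float:
    """Frequency credited when an extra/variant head occurs with frequency f.

    1 - 3/4 * f: a variant present in a quarter of specimens credits 13/16.
    """
    if not 0 <= f <= 1:
        raise ValueError("variant frequency must lie in [0, 1]")
    return 1.0 - 0.75 * f


def component_deviation(
    control: ComponentSet,
    other: ComponentSet,
    rule: DeviationRule = DeviationRule(),
) -> float:
    """Deviation between two component sets under the counting rule.

    Identical sets score 0.  Otherwise a quarter unit per differing component
    (symmetric difference, or components of the control missing from the
    other set under ``missing_only``), capped at 1.  Two non-empty sets with
    no component in common are a completely different state and score the
    full cap, as does a comparison state with no components at all.
    """
    if control == other:
        return 0.0
    if not control and not other:
        return 0.0
    if not control or not other or not (control & other):
        return rule.cap
    if rule.mode is DeviationMode.MISSING_ONLY:
        v = len(control - other)
    else:
        v = len(control ^ other)
    return min(rule.cap, v * rule.quarter_unit)


_SET_KINDS = (AttributeKind.INNERVATION, AttributeKind.ORIGIN, AttributeKind.INSERTION)
_VARIANT_KINDS = (AttributeKind.INNERVATION, AttributeKind.ORIGIN, AttributeKind.COUNT)


def attribute_deviation(
    kind: AttributeKind,
    control_state: StructureState,
    other_state: StructureState,
    rule: DeviationRule = DeviationRule(),
    overrides: Sequence[DeviationOverride] = (),
    *,
    control_species: Optional[str] = None,
    other_species: Optional[str] = None,
) -> tuple[float, bool]:
    """Deviation d_k = 1 - P_i'jk for one attribute.

    Returns ``(deviation, overridden)``; an override matching the cell wins
    over every rule.  ``control_species``/``other_species`` identify the
    comparison for override matching (they default to empty, which only
    unconditional overrides can match).
    """
    if control_state.structure_name != other_state.structure_name:
        raise ValueError(
            f"attribute deviation across different structures: "
            f"{control_state.structure_name!r} vs {other_state.structure_name!r}"
        )
    for ov in overrides:
        if ov.matches(
            control_species or "", other_species or "", other_state.structure_name, kind
        ):
            return float(ov.delta), True

    if kind in _VARIANT_KINDS and (
        other_state.variant_frequency is not None
        or control_state.variant_frequency is not None
    ):
        # the variant-head rule scores the *difference* in variant frequency
        # (identical variants cancel); the credited frequency 1 - 3/4 f is
        # carried at the 3-decimal working precision of the reported tables
        # (13/16 enters as 0.813)
        f = abs(
            (other_state.variant_frequency or 0.0)
            - (control_state.variant_frequency or 0.0)
        )
        if f > 0:
            return 1.0 - round_half_up(variant_frequency_penalty(f), 3), False

    if kind is AttributeKind.COUNT:
        pen = count_penalty(control_state.count.effective, other_state.count.effective)
        return 1.0 - pen, False
    if kind is AttributeKind.VASCULARIZATION:
        # species-level palmar-arch rule: same number of arches -> identical
        # supply frequency (1), otherwise 1/2 -> deviation 1/2
        return 0.0 if control_state.palmar_arches == other_state.palmar_arches else 0.5, False
    return (
        component_deviation(control_state.components(kind), other_state.components(kind), rule),
        False,
    )


def paf(deviations: Mapping[AttributeKind, float], weights: WeightScheme = WeightScheme()) -> float:
    """Weighted attribute-frequency average sum(w_k (1 - d_k)) / sum(w_k)."""
    missing = [k for k in ATTRIBUTE_KINDS if k not in deviations]
    if missing:
        raise ValueError(f"deviations missing for: {[k.code for k in missing]}")
    num = sum(weights[k] * (1.0 - float(deviations[k])) for k in ATTRIBUTE_KINDS)
    return num / weights.total


def cai(
    control: SpeciesProfile,
    other: SpeciesProfile,
    structure_key: tuple,
    weights: WeightScheme = WeightScheme(),
    rule: DeviationRule = DeviationRule(),
    overrides: Sequence[DeviationOverride] = (),
) -> ComparisonResult:
    """Per-structure CAI between a control and a comparison species.

    The control's attribute frequencies are fixed at 1 (modal-control
    convention), so CAI = 1 - PAF(other).  A structure the control has but
    the comparison species lacks scores 1 outright.
    """
    if structure_key not in control.states:
        raise KeyError(f"structure {structure_key!r} missing from control profile")
    if structure_key not in other.states:
        raise KeyError(f"structure {structure_key!r} missing from comparison profile")
    c_state = control.states[structure_key]
    o_state = other.states[structure_key]
    group, name = structure_key

    if o_state.absent and not c_state.absent:
        deviations = {k: 1.0 for k in ATTRIBUTE_KINDS}
        return ComparisonResult(
            structure_name=name,
            group=group,
            paf_control=1.0,
            paf_other=0.0,
            cai=1.0,
            deviations=deviations,
            overridden=frozenset(),
            structure_absent=True,
        )
    if c_state.absent and o_state.absent:
        deviations = {k: 0.0 for k in ATTRIBUTE_KINDS}
        return ComparisonResult(name, group, 1.0, 1.0, 0.0, deviations)

    deviations = {}
    overridden = set()
    for kind in ATTRIBUTE_KINDS:
        d, from_override = attribute_deviation(
            kind,
            c_state,
            o_state,
            rule,
            overrides,
            control_species=control.species_name,
            other_species=other.species_name,
        )
        deviations[kind] = d
        if from_override:
            overridden.add(kind)
    paf_other = paf(deviations, weights)
    return ComparisonResult(
        structure_name=name,
        group=group,
        paf_control=1.0,
        paf_other=paf_other,
        cai=abs(1.0 - paf_other),
        deviations=deviations,
        overridden=frozenset(overridden),
    )


#: decimals used for the reported (rounded-member) group index
REPORT_DECIMALS = 3


def group_gcai(
    control: SpeciesProfile,
    other: SpeciesProfile,
    group: str,
    weights: WeightScheme = WeightScheme(),
    rule: DeviationRule = DeviationRule(),
    overrides: Sequence[DeviationOverride] = (),
) -> GroupResult:
    """Group index between a control and a comparison species.

    Both profiles must carry the same structures in the group (absent
    structures are encoded with count 0, not omitted).
    """
    c_keys = sorted(control.group_states(group))
    o_keys = sorted(other.group_states(group))
    if c_keys != o_keys:
        raise ValueError(
            f"group {group!r} structure sets differ: control has "
            f"{[k[1] for k in c_keys]}, comparison has {[k[1] for k in o_keys]}"
        )
    if not c_keys:
        raise ValueError(f"group {group!r} has no structures")
    members = tuple(
        cai(control, other, key, weights, rule, overrides) for key in c_keys
    )
    mean_cai = float(np.mean([r.cai for r in members]))
    formula = abs(
        float(np.mean([r.paf_control for r in members]))
        - float(np.mean([r.paf_other for r in members]))
    )
    reported = float(
        np.mean([round_half_up(r.cai, REPORT_DECIMALS) for r in members])
    )
    return GroupResult(
        group=group,
        member_results=members,
        gcai_mean=mean_cai,
        gcai_formula=formula,
        gcai_reported=reported,
    )


def compare_profiles(
    control: SpeciesProfile,
    others: Iterable[SpeciesProfile],
    weights: WeightScheme = WeightScheme(),
    rule: DeviationRule = DeviationRule(),
    overrides: Sequence[DeviationOverride] = (),
) -> dict:
    """Full comparison of each species in ``others`` against the control.

    Returns ``{species_name: {group: GroupResult}}`` over the control's
    groups, the building block for the report tables.
    """
    out: dict = {}
    for other in others:
        if other.species_name == control.species_name:
            continue
        out[other.species_name] = {
            g: group_gcai(control, other, g, weights, rule, overrides)
            for g in control.groups()
        }
    return out


@dataclass(frozen=True)
class PairwiseResult:
    """A pairwise species distance matrix.

    ``distances`` is symmetrized as (M + M^T)/2 from the raw ``directed``
    matrix, in which row a holds the distances with species a in the control
    role (the control role matters when modal frequencies or overrides
    differ, so the raw matrix need not be symmetric).
    """

    distances: pd.DataFrame
    directed: pd.DataFrame
    level: str
    symmetrized: bool = True

    @property
    def max_asymmetry(self) -> float:
        m = self.directed.to_numpy(dtype=float)
        return float(np.abs(m - m.T).max())


def pairwise_matrix(
    profiles: Sequence[SpeciesProfile],
    weights: WeightScheme = WeightScheme(),
    rule: DeviationRule = DeviationRule(),
    overrides: Sequence[DeviationOverride] = (),
    level: str = "overall",
) -> PairwiseResult:
    """Distance matrix over all species, each taken in turn as control.

    ``level`` is ``"overall"`` (mean CAI across every shared structure) or a
    group name (mean CAI across that group).  Overrides carry a control
    species and only apply in that control's rows.
    """
    if len(profiles) < 2:
        raise ValueError("pairwise matrix needs at least two profiles")
    names = [p.species_name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species names in profiles")
    key_sets = [set(p.states) for p in profiles]
    if any(ks != key_sets[0] for ks in key_sets[1:]):
        raise ValueError("profiles do not share the same structure keys")

    if level == "overall":
        keys = sorted(profiles[0].states)
    else:
        keys = sorted(k for k in profiles[0].states if k[0] == level)
        if not keys:
            raise ValueError(f"no structures in group {level!r}")

    n = len(profiles)
    directed = np.zeros((n, n))
    for a, ctrl in enumerate(profiles):
        for b, oth in enumerate(profiles):
            if a == b:
                continue
            vals = [cai(ctrl, oth, k, weights, rule, overrides).cai for k in keys]
            directed[a, b] = float(np.mean(vals))
    sym = (directed + directed.T) / 2.0
    return PairwiseResult(
        distances=pd.DataFrame(sym, index=names, columns=names),
        directed=pd.DataFrame(directed, index=names, columns=names),
        level=level,
    )


def upgma_tree(matrix: pd.DataFrame):
    """UPGMA (average-linkage) tree from a symmetric distance matrix.

    Returns a rooted, ultrametric ``skbio.TreeNode`` with branch lengths;
    labels are pre-sorted lexicographically so that tied merges resolve
    deterministically by label order.
    """
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform
    from skbio import TreeNode

    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError("distance matrix must be square")
    labels = sorted(str(x) for x in matrix.index)
    m = matrix.loc[labels, labels].to_numpy(dtype=float)
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.abs(np.diag(m)).max() > 1e-12:
        raise ValueError("distance matrix must have a zero diagonal")
    if (m < 0).any():
        raise ValueError("distance matrix must be non-negative")
    linkage = average(squareform(m, checks=False))
    return TreeNode.from_linkage_matrix(linkage, labels)
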