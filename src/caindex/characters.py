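"""Domain types for discrete anatomical character data.

The comparative framework scores each anatomical structure (a muscle, in the
packaged hand dataset) on five attributes: innervation, origin, insertion,
vascularization, and the number of such structures per hand.  A species is a
named collection of structure states organized into structure groups (for the
hand: central, hypothenar, thenar).  These types are the single home for every
symbol the scoring engine uses.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional


class AttributeKind(enum.Enum):
    """The five scored attributes, in their fixed weighting order k = 1..5."""

    INNERVATION = ("innervation", 1)
    ORIGIN = ("origin", 2)
    INSERTION = ("insertion", 3)
    VASCULARIZATION = ("vascularization", 4)
    COUNT = ("count", 5)

    def __init__(self, code: str, index: int) -> None:
        self.code = code
        self.index = index

    @classmethod
    def from_code(cls, code: str) -> "AttributeKind":
        for kind in cls:
            if kind.code == code:
                return kind
        raise ValueError(f"unknown attribute kind: {code!r}")


#: Attribute kinds in k order, for iteration.
ATTRIBUTE_KINDS = tuple(sorted(AttributeKind, key=lambda k: k.index))

#: Structure groups of the hand, in the order of the source tables.
GROUPS = ("central", "hypothenar", "thenar")


_WS = re.compile(r"\s+")


def normalize_component_label(raw: str) -> str:
    """Normalize a free-text anatomical component label.

    Lowercases, trims, and collapses internal whitespace.  Idempotent.
    Raises ``ValueError`` on empty or blank input.
    """
    if raw is None or not str(raw).strip():
        raise ValueError("component label is empty or blank")
    return _WS.sub(" ", str(raw).strip()).lower()


@dataclass(frozen=True)
class WeightScheme:
    """Per-attribute weights w_k.

    The default (3, 2, 2, 1, 1) prioritizes innervation over origin and
    insertion, and those over vascularization and structure count — the
    attributes that vary least across the evolutionary scale carry the most
    weight, so the index emphasizes phylogenetically conserved characters.
    """

    weights: Mapping[AttributeKind, float] = field(
        default_factory=lambda: {
            AttributeKind.INNERVATION: 3.0,
            AttributeKind.ORIGIN: 2.0,
            AttributeKind.INSERTION: 2.0,
            AttributeKind.VASCULARIZATION: 1.0,
            AttributeKind.COUNT: 1.0,
        }
    )

    def __post_init__(self) -> None:
        missing = [k for k in AttributeKind if k not in self.weights]
        if missing:
            raise ValueError(f"weights missing for: {[k.code for k in missing]}")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("all weights must be positive")

    @property
    def total(self) -> float:
        return float(sum(self.weights.values()))

    def __getitem__(self, kind: AttributeKind) -> float:
        return float(self.weights[kind])

    @classmethod
    def from_sequence(cls, values: Iterable[float]) -> "WeightScheme":
        vals = [float(v) for v in values]
        if len(vals) != 5:
            raise ValueError("expected exactly five weights (k = 1..5)")
        return cls(dict(zip(ATTRIBUTE_KINDS, vals)))


class ComponentSet(frozenset):
    """A finite set of normalized anatomical component labels.

    Label equality after normalization is the equality test; the labels are
    free text, not a controlled vocabulary.
    """

    def __new__(cls, components: Iterable[str] = ()) -> "ComponentSet":
        return super().__new__(cls, (normalize_component_label(c) for c in components))

    def __repr__(self) -> str:  # stable, sorted — useful in findings/messages
        return f"ComponentSet({sorted(self)!r})"


@dataclass(frozen=True)
class StructureCount:
    """Number of structures per hand, possibly a range (e.g. "6-7").

    A point count has ``low == high``; the effective value used by the count
    penalty is the midpoint.  Zero encodes a structure absent in the species.
    Range sanity (low ≤ high, non-negative) is checked by ``validate_profile``
    so that malformed inputs surface as findings rather than exceptions.
    """

    low: float
    high: float

    @property
    def is_valid(self) -> bool:
        return self.low >= 0 and self.high >= 0 and self.low <= self.high

    @property
    def effective(self) -> float:
        return (self.low + self.high) / 2.0

    @classmethod
    def point(cls, value: float) -> "StructureCount":
        return cls(value, value)


@dataclass(frozen=True)
class ObservationFrequency:
    """r_v of N structures observed with the modal state (e.g. 16/16 hands).

    Bounds (0 ≤ r_v ≤ N, N > 0) are checked by ``validate_profile`` so that
    malformed inputs surface as findings rather than exceptions; ``value``
    itself refuses N ≤ 0.
    """

    r_v: int
    n: int

    @property
    def is_valid(self) -> bool:
        return self.n > 0 and 0 <= self.r_v <= self.n

    @property
    def value(self) -> Fraction:
        if self.n <= 0:
            raise ZeroDivisionError("relative frequency undefined for N <= 0")
        return Fraction(self.r_v, self.n)


@dataclass(frozen=True)
class StructureState:
    """One structure's five attribute states for one species.

    ``palmar_arches`` is a species-level character (1 or 2 arterial palmar
    arches) repeated on every state, because the vascularization score is
    decided per species, not per muscle.  ``variant_frequency`` carries the
    frequency of an extra/variant head where one is reported (the two-headed
    flexor pollicis brevis); when set, the engine scores innervation, origin
    and count by the frequency-weighted rule instead of set comparison.
    """

    structure_name: str
    group: str
    innervation: ComponentSet
    origin: ComponentSet
    insertion: ComponentSet
    supply: ComponentSet
    palmar_arches: int
    count: StructureCount
    frequency: ObservationFrequency
    variant_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.palmar_arches not in (1, 2):
            raise ValueError("palmar_arches must be 1 or 2")
        if self.variant_frequency is not None and not 0 <= self.variant_frequency <= 1:
            raise ValueError("variant_frequency must lie in [0, 1]")

    @property
    def absent(self) -> bool:
        return self.count.effective == 0

    def components(self, kind: AttributeKind) -> ComponentSet:
        mapping = {
            AttributeKind.INNERVATION: self.innervation,
            AttributeKind.ORIGIN: self.origin,
            AttributeKind.INSERTION: self.insertion,
            AttributeKind.VASCULARIZATION: self.supply,
        }
        if kind not in mapping:
            raise ValueError(f"{kind.code} has no component set")
        return mapping[kind]


@dataclass(frozen=True)
class SpeciesProfile:
    """A named species' structure states, keyed by (group, structure_name)."""

    species_name: str
    states: Mapping[tuple, StructureState]

    @classmethod
    def from_states(cls, species_name: str, states: Iterable[StructureState]) -> "SpeciesProfile":
        keyed = {}
        for st in states:
            key = (st.group, st.structure_name)
            if key in keyed:
                raise ValueError(f"duplicate structure {key!r} in profile {species_name!r}")
            keyed[key] = st
        return cls(species_name, keyed)

    def groups(self) -> tuple:
        return tuple(g for g in GROUPS if any(k[0] == g for k in self.states))

    def group_states(self, group: str) -> dict:
        return {k: v for k, v in self.states.items() if k[0] == group}

    def __iter__(self):
        return iter(self.states.values())


@dataclass(frozen=True)
class DeviationOverride:
    """A per-cell deviation pinned by the dataset ledger.

    Used where no counting rule reproduces a published table cell; every
    override carries a note citing the cell it pins.  ``control_species``
    restricts the override to comparisons against that control (overrides
    encode control-relative cells and must not fire when the pairwise matrix
    rotates another species into the control role).
    """

    species_name: str
    structure_name: str
    kind: AttributeKind
    delta: float
    note: str
    control_species: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 <= self.delta <= 1:
            raise ValueError("override delta must lie in [0, 1]")
        if not self.note.strip():
            raise ValueError("override note must cite its source cell")

    def matches(self, control: str, other: str, structure_name: str, kind: AttributeKind) -> bool:
        if self.control_species is not None and self.control_species != control:
            return False
        return (
            self.species_name == other
            and self.structure_name == structure_name
            and self.kind == kind
        )


@dataclass(frozen=True)
class ComparisonResult:
    """Per-structure CAI with its per-attribute deviation breakdown."""

    structure_name: str
    group: str
    paf_control: float
    paf_other: float
    cai: float
    deviations: Mapping[AttributeKind, float]
    overridden: frozenset = frozenset()  # AttributeKinds pinned by override
    structure_absent: bool = False

    def __post_init__(self) -> None:
        if abs(self.cai - abs(self.paf_control - self.paf_other)) > 1e-12:
            raise ValueError("cai must equal |paf_control - paf_other|")
        if not -1e-12 <= self.cai <= 1 + 1e-12:
            raise ValueError("cai out of [0, 1]")

    @property
    def has_override(self) -> bool:
        return bool(self.overridden)


@dataclass(frozen=True)
class GroupResult:
    """Per-group GCAI with the member CAIs.

    ``gcai_mean`` is the arithmetic mean of the member CAIs at full precision;
    ``gcai_formula`` is |mean PAF(control) − mean PAF(other)|.  Under the
    modal-control convention the two coincide.  ``gcai_reported`` averages the
    member CAIs after rounding them half-up to the reporting precision
    (3 decimals) — the headline value, matching how grouped index tables are
    conventionally assembled from their printed per-structure entries.
    """

    group: str
    member_results: tuple
    gcai_mean: float
    gcai_formula: float
    gcai_reported: float

    @property
    def m(self) -> int:
        return len(self.member_results)

    @property
    def has_override(self) -> bool:
        return any(r.has_override for r in self.member_results)


def validate_profile(profile: SpeciesProfile) -> list:
    """Check a profile's invariants; return one finding string per violation.

    Findings, not exceptions: a well-formed profile yields an empty list.
    Frozen dataclass constructors already reject frankly impossible values;
    this validates the cross-field rules (required non-empty component sets,
    group membership, key consistency).
    """
    findings: list = []
    if not str(profile.species_name).strip():
        findings.append("species_name is empty")
    for key, st in profile.states.items():
        name = f"{st.group}/{st.structure_name}"
        if key != (st.group, st.structure_name):
            findings.append(f"{name}: keyed as {key!r}, inconsistent with state")
        if not st.frequency.is_valid:
            findings.append(
                f"{name}: observation frequency r_v={st.frequency.r_v}/N={st.frequency.n} "
                "violates 0 <= r_v <= N, N > 0"
            )
        if not st.count.is_valid:
            findings.append(
                f"{name}: structure count low={st.count.low}, high={st.count.high} "
                "violates 0 <= low <= high"
            )
        if not st.absent:
            if not st.origin:
                findings.append(f"{name}: present structure with empty origin")
            if not st.insertion:
                findings.append(f"{name}: present structure with empty insertion")
    arches = {s.palmar_arches for s in profile}
    if len(arches) > 1:
        findings.append(
            f"palmar_arches is a species-level character but differs across "
            f"structures ({sorted(arches)})"
        )
    for group in profile.groups():
        if not profile.group_states(group):
            findings.append(f"group {group!r} present but empty")
    return findings
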