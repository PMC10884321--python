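"""Packaged hand-muscle character dataset and character-table file formats.

The packaged fixture encodes the modal character states of twelve intrinsic
hand muscles (four per structure group: central, hypothenar, thenar) for five
primates — *Sapajus* (bearded capuchin, the control species), human,
chimpanzee, gorilla and baboon (*Papio*) — together with the per-cell
deviation overrides its source ledger pins and every published index value
the engine is expected to reproduce.

File formats
------------
Character tables travel as CSV/TSV (one row per species × structure, component
lists joined with ``" | "``) or structured JSON; both round-trip exactly.
NEXUS is export-only (a standard morphological DATA block, one discretized
deviation character per structure × attribute); trees are exported as newick.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .characters import (
    ATTRIBUTE_KINDS,
    AttributeKind,
    ComponentSet,
    DeviationOverride,
    ObservationFrequency,
    SpeciesProfile,
    StructureCount,
    StructureState,
    validate_profile,
)
from .engine import DeviationRule, attribute_deviation

CONTROL_SPECIES = "Sapajus"

#: canonical column order of the CSV character-table schema
CSV_COLUMNS = [
    "species",
    "group",
    "structure",
    "innervation",
    "origin",
    "insertion",
    "supply",
    "count_low",
    "count_high",
    "r_v",
    "n",
    "palmar_arches",
    "variant_frequency",
    "source",
]

_COMPONENT_SEP = " | "


@dataclass(frozen=True)
class PrintedValue:
    """One published index value with its reporting precision and source."""

    species: str
    scope: str  # "structure" or "group"
    group: str
    structure: Optional[str]
    value: float
    decimals: int
    overridden: bool
    source: str

    @property
    def key(self) -> tuple:
        if self.scope == "group":
            return (self.species, self.group)
        return (self.species, self.structure)


@dataclass(frozen=True)
class FixtureBundle:
    """The packaged dataset: profiles, overrides, and published values."""

    profiles: Mapping[str, SpeciesProfile]
    overrides: tuple
    printed_results: tuple
    control_species: str = CONTROL_SPECIES
    sources: Mapping[tuple, str] = field(default_factory=dict)

    @property
    def control(self) -> SpeciesProfile:
        return self.profiles[self.control_species]

    def comparison_profiles(self) -> list:
        return [p for name, p in self.profiles.items() if name != self.control_species]

    def printed(self, species: str, name: str) -> PrintedValue:
        for pv in self.printed_results:
            if pv.key == (species, name):
                return pv
        raise KeyError((species, name))


def _parse_components(cell: str) -> ComponentSet:
    if cell is None or not str(cell).strip():
        return ComponentSet()
    return ComponentSet(p for p in str(cell).split("|") if p.strip())


def _format_components(cs: ComponentSet) -> str:
    return _COMPONENT_SEP.join(sorted(cs))


def _row_to_state(row: Mapping, where: str) -> StructureState:
    for col in ("species", "group", "structure", "count_low", "count_high", "r_v", "n", "palmar_arches"):
        if col not in row or row[col] is None or str(row[col]).strip() == "":
            raise ValueError(f"{where}: missing required field {col!r}")
    vf = row.get("variant_frequency")
    vf = None if vf is None or str(vf).strip() == "" else float(vf)
    try:
        return StructureState(
            structure_name=str(row["structure"]).strip(),
            group=str(row["group"]).strip(),
            innervation=_parse_components(row.get("innervation", "")),
            origin=_parse_components(row.get("origin", "")),
            insertion=_parse_components(row.get("insertion", "")),
            supply=_parse_components(row.get("supply", "")),
            palmar_arches=int(float(row["palmar_arches"])),
            count=StructureCount(float(row["count_low"]), float(row["count_high"])),
            frequency=ObservationFrequency(int(float(row["r_v"])), int(float(row["n"]))),
            variant_frequency=vf,
        )
    except ValueError as exc:
        raise ValueError(f"{where}: {exc}") from exc


def _rows_to_profiles(rows: Sequence[Mapping]) -> list:
    by_species: dict = {}
    for i, row in enumerate(rows):
        st = _row_to_state(row, where=f"row {i + 1}")
        by_species.setdefault(str(row["species"]).strip(), []).append(st)
    return [SpeciesProfile.from_states(name, states) for name, states in by_species.items()]


def read_character_table(path, fmt: Optional[str] = None) -> list:
    """Read species profiles from a CSV/TSV or JSON character table.

    ``fmt`` is "csv" or "json"; inferred from the suffix when omitted.
    Raises ``ValueError`` naming the offending row/field on schema errors.
    """
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        doc = json.loads(path.read_text())
        profiles = []
        for entry in doc.get("species", []):
            states = []
            for j, s in enumerate(entry.get("structures", [])):
                row = dict(s)
                row.setdefault("species", entry.get("name"))
                row.setdefault("palmar_arches", entry.get("palmar_arches"))
                states.append(
                    _row_to_state(row, where=f"species {entry.get('name')!r} structure {j + 1}")
                )
            profiles.append(SpeciesProfile.from_states(entry["name"], states))
        if not profiles:
            raise ValueError(f"{path}: no species entries")
        return profiles
    if fmt != "csv":
        raise ValueError(f"unknown character-table format {fmt!r}")
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delim)
        missing = [c for c in CSV_COLUMNS if c not in (reader.fieldnames or []) and c != "source"]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        rows = list(reader)
    if not rows:
        raise ValueError(f"{path}: empty character table")
    return _rows_to_profiles(rows)


def _state_to_row(species: str, st: StructureState) -> dict:
    return {
        "species": species,
        "group": st.group,
        "structure": st.structure_name,
        "innervation": _format_components(st.innervation),
        "origin": _format_components(st.origin),
        "insertion": _format_components(st.insertion),
        "supply": _format_components(st.supply),
        "count_low": st.count.low,
        "count_high": st.count.high,
        "r_v": st.frequency.r_v,
        "n": st.frequency.n,
        "palmar_arches": st.palmar_arches,
        "variant_frequency": "" if st.variant_frequency is None else st.variant_frequency,
        "source": "",
    }


def write_character_table(profiles: Sequence[SpeciesProfile], path, fmt: Optional[str] = None) -> None:
    """Write species profiles as a CSV or JSON character table (round-trips)."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to write")
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        doc = {
            "species": [
                {
                    "name": p.species_name,
                    "palmar_arches": next(iter(p)).palmar_arches,
                    "structures": [
                        {k: v for k, v in _state_to_row(p.species_name, st).items()
                         if k not in ("species", "source", "palmar_arches")}
                        for st in (p.states[k] for k in sorted(p.states))
                    ],
                }
                for p in profiles
            ]
        }
        path.write_text(json.dumps(doc, indent=1))
        return
    if fmt != "csv":
        raise ValueError(f"unknown character-table format {fmt!r}")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for p in profiles:
            for key in sorted(p.states):
                writer.writerow(_state_to_row(p.species_name, p.states[key]))


def _read_packaged(name: str) -> str:
    return resources.files("caindex").joinpath("data", name).read_text()


def load_fixture() -> FixtureBundle:
    """Load the packaged five-species, twelve-muscle dataset.

    The returned bundle validates clean, keeps every structure group at four
    members (absent muscles are encoded with count 0, not omitted), and
    carries all 60 published index values (48 per-muscle, 12 per-group).
    """
    with resources.as_file(resources.files("caindex").joinpath("data", "profiles.csv")) as p:
        profiles = {pr.species_name: pr for pr in read_character_table(p, "csv")}
    # source citations per (species, structure), kept out of the state objects
    sources = {}
    reader = csv.DictReader(_read_packaged("profiles.csv").splitlines())
    for row in reader:
        sources[(row["species"], row["structure"])] = row["source"]

    overrides = []
    for row in csv.DictReader(_read_packaged("overrides.csv").splitlines()):
        overrides.append(
            DeviationOverride(
                species_name=row["species"],
                structure_name=row["structure"],
                kind=AttributeKind.from_code(row["kind"]),
                delta=float(row["delta"]),
                note=row["note"],
                control_species=row["control_species"] or None,
            )
        )

    printed = tuple(
        PrintedValue(**entry) for entry in json.loads(_read_packaged("printed_results.json"))
    )

    expected = {"Sapajus", "Human", "Chimpanzee", "Gorilla", "Papio"}
    if set(profiles) != expected:
        raise ValueError(f"packaged data corrupted: species {sorted(profiles)}")
    for name, prof in profiles.items():
        findings = validate_profile(prof)
        if findings:
            raise ValueError(f"packaged profile {name!r} invalid: {findings}")
        if len(prof.states) != 12:
            raise ValueError(f"packaged profile {name!r} has {len(prof.states)} structures")
    return FixtureBundle(
        profiles=profiles,
        overrides=tuple(overrides),
        printed_results=printed,
        sources=sources,
    )


def export_nexus(
    profiles: Sequence[SpeciesProfile],
    path,
    control_species: str = CONTROL_SPECIES,
    rule: DeviationRule = DeviationRule(),
) -> None:
    """Export a NEXUS morphological DATA block of discretized deviations.

    Each structure × attribute becomes one discrete character whose state is
    the deviation from the control species in quarter units (0–4); the
    control row is therefore all zeros.  Export-only: morphological NEXUS
    dialects vary too much for a general reader.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to export")
    names = [p.species_name for p in profiles]
    if control_species not in names:
        raise ValueError(f"control species {control_species!r} not among profiles")
    control = profiles[names.index(control_species)]
    keys = sorted(control.states)
    nchar = len(keys) * len(ATTRIBUTE_KINDS)

    lines = [
        "#NEXUS",
        "[character coding: per-attribute deviation from the control species"
        f" ({control_species}), in quarter units discretized to states 0-4]",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={len(profiles)} NCHAR={nchar};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="01234" MISSING=?;',
        "    CHARLABELS",
    ]
    for group, structure in keys:
        for kind in ATTRIBUTE_KINDS:
            lines.append(f"        '{structure}_{kind.code}'")
    lines.append("    ;")
    lines.append("    MATRIX")
    for p in profiles:
        states = []
        for key in keys:
            for kind in ATTRIBUTE_KINDS:
                if p.species_name == control_species:
                    states.append("0")
                    continue
                o_state = p.states[key]
                if o_state.absent and not control.states[key].absent:
                    states.append("4")
                    continue
                d, _ = attribute_deviation(kind, control.states[key], o_state, rule)
                states.append(str(min(4, round(d / 0.25))))
        taxon = p.species_name.replace(" ", "_")
        lines.append(f"        {taxon:<16s}{''.join(states)}")
    lines += ["    ;", "END;", ""]
    Path(path).write_text("\n".join(lines))


def export_newick(tree, path) -> None:
    """Write a tree (``skbio.TreeNode``) as newick with 6-decimal lengths."""
    import re
    from io import StringIO

    buf = StringIO()
    tree.write(buf, format="newick")
    s = buf.getvalue()

    def _fmt(m):
        return f":{float(m.group(1)):.6f}"

    s = re.sub(r":([0-9.eE+-]+)", _fmt, s)
    Path(path).write_text(s)
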