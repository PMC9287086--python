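"""Compound registry: analytes, internal standards and their acquisition metadata.

The packaged default registry covers the 45 PFAS analytes and 23 stable
isotope-labeled internal standards of the validated drinking-water panel,
spanning eight chemical classes (sulfonates, carboxylates, fluorotelomer
sulfonates, sulfonamides, sulfonamidoacetic acids, ether acids, zwitterions
and chloro-ether "other" compounds).  Molecular formulas were compiled from
the systematic compound names; expected retention times are synthetic
placeholders spread over the 20-minute gradient, and fragment templates are
synthetic plausible PFAS fragments — each row's ``provenance`` column says
so.  A mass-only ``reference`` row carries the Hydro-EVE near-isobar of
6:2 FTS (deprotonated m/z 426.9657), for which no public formula exists.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import chem
from .chem import ElementCounts, IonSpecies

__all__ = [
    "CompoundRecord",
    "CompoundRegistry",
    "RegistryError",
    "read_registry",
    "write_registry",
    "load_default_registry",
    "write_transition_list",
]

_SPECIES = {
    "[M-H]": IonSpecies.DEPROTONATED,
    "[M+H]": IonSpecies.PROTONATED,
    "[M-CO2-H]": IonSpecies.DEPROTONATED_DECARBOXYLATED,
}


class RegistryError(ValueError):
    """Raised when a registry file violates its invariants."""


@dataclass(frozen=True)
class CompoundRecord:
    """One analyte, internal standard or reference mass in the panel."""

    id: str
    name: str
    chem_class: str
    formula: str  # Hill string; empty for mass-only entries
    n13c: int = 0
    n2h: int = 0
    mass_only_mz: Optional[float] = None  # ion m/z for formula-less entries
    ion_species: IonSpecies = IonSpecies.DEPROTONATED
    rt_min: float = 0.0
    early_eluter: bool = False
    role: str = "analyte"  # analyte | internal_standard | reference
    surrogate_is: str = ""
    fragments: Tuple[Tuple[float, float], ...] = ()
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("analyte", "internal_standard", "reference"):
            raise RegistryError(f"{self.id}: unknown role {self.role!r}")
        if not self.formula and self.mass_only_mz is None:
            raise RegistryError(f"{self.id}: needs a formula or a mass_only_mz")

    @property
    def is_internal_standard(self) -> bool:
        return self.role == "internal_standard"

    @property
    def polarity(self) -> str:
        return self.ion_species.polarity

    @property
    def element_counts(self) -> Optional[ElementCounts]:
        if not self.formula:
            return None
        return chem.parse_formula(self.formula, n13c=self.n13c, n2h=self.n2h)

    @property
    def precursor_mz(self) -> float:
        """Theoretical ion m/z (neutral-H convention) or the stored mass."""
        f = self.element_counts
        if f is None:
            assert self.mass_only_mz is not None
            return self.mass_only_mz
        return chem.ion_mz(f, self.ion_species)

    @property
    def fluorines(self) -> Optional[int]:
        f = self.element_counts
        return None if f is None else chem.fluorine_count(f)


@dataclass
class CompoundRegistry:
    """Validated collection of compound records with unique ids."""

    records: List[CompoundRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        errors: List[str] = []
        seen: Dict[str, int] = {}
        for rec in self.records:
            seen[rec.id] = seen.get(rec.id, 0) + 1
        for cid, n in seen.items():
            if n > 1:
                errors.append(f"duplicate compound id: {cid}")
        by_id = {r.id: r for r in self.records}
        for rec in self.records:
            if rec.role == "analyte":
                if not rec.surrogate_is:
                    errors.append(f"{rec.id}: analyte without an assigned internal standard")
                elif rec.surrogate_is not in by_id:
                    errors.append(
                        f"{rec.id}: assigned internal standard {rec.surrogate_is!r} not in registry"
                    )
                elif not by_id[rec.surrogate_is].is_internal_standard:
                    errors.append(
                        f"{rec.id}: assigned standard {rec.surrogate_is!r} is not an internal standard"
                    )
            if rec.chem_class == "zwitterion" and rec.polarity != "+":
                errors.append(f"{rec.id}: zwitterions must be positive-mode (protonated)")
            if rec.formula:
                try:
                    rec.precursor_mz  # raises on illegal species/formula pairs
                except chem.FormulaError as exc:
                    errors.append(f"{rec.id}: {exc}")
        if errors:
            raise RegistryError("; ".join(errors))

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, cid: str) -> CompoundRecord:
        for rec in self.records:
            if rec.id == cid:
                return rec
        raise KeyError(cid)

    def __contains__(self, cid: str) -> bool:
        return any(r.id == cid for r in self.records)

    @property
    def analytes(self) -> List[CompoundRecord]:
        return [r for r in self.records if r.role == "analyte"]

    @property
    def internal_standards(self) -> List[CompoundRecord]:
        return [r for r in self.records if r.role == "internal_standard"]

    def measurable(self) -> List[CompoundRecord]:
        """Analytes + internal standards (reference masses excluded)."""
        return [r for r in self.records if r.role != "reference"]


_COLUMNS = [
    "id", "name", "chem_class", "formula", "n13c", "n2h", "mass_only_mz",
    "ion_species", "rt_min", "early_eluter", "role", "surrogate_is",
    "fragments", "provenance",
]


def _format_fragments(frags: Sequence[Tuple[float, float]]) -> str:
    return ";".join(f"{mz:.4f}:{ab:g}" for mz, ab in frags)


def _parse_fragments(text: str) -> Tuple[Tuple[float, float], ...]:
    if not text:
        return ()
    out = []
    for part in text.split(";"):
        mz_s, ab_s = part.split(":")
        out.append((float(mz_s), float(ab_s)))
    return tuple(out)


def read_registry(path: str | Path) -> CompoundRegistry:
    """Read a registry CSV/TSV (delimiter sniffed from the header line)."""
    path = Path(path)
    text = path.read_text()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    rows = list(csv.DictReader(text.splitlines(), delimiter=delim))
    if not rows:
        raise RegistryError(f"{path}: empty registry")
    missing = [c for c in _COLUMNS if c not in rows[0]]
    if missing:
        raise RegistryError(f"{path}: missing columns {missing}")
    records = []
    for row in rows:
        species = row["ion_species"].strip()
        if species not in _SPECIES:
            raise RegistryError(f"{row['id']}: unknown ion species {species!r}")
        records.append(
            CompoundRecord(
                id=row["id"].strip(),
                name=row["name"].strip(),
                chem_class=row["chem_class"].strip(),
                formula=row["formula"].strip(),
                n13c=int(row["n13c"] or 0),
                n2h=int(row["n2h"] or 0),
                mass_only_mz=float(row["mass_only_mz"]) if row["mass_only_mz"] else None,
                ion_species=_SPECIES[species],
                rt_min=float(row["rt_min"]),
                early_eluter=row["early_eluter"].strip() in ("1", "true", "True"),
                role=row["role"].strip(),
                surrogate_is=row["surrogate_is"].strip(),
                fragments=_parse_fragments(row["fragments"].strip()),
                provenance=row.get("provenance", "").strip(),
            )
        )
    return CompoundRegistry(records)


def write_registry(reg: CompoundRegistry, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_COLUMNS)
        writer.writeheader()
        for rec in reg:
            writer.writerow(
                {
                    "id": rec.id,
                    "name": rec.name,
                    "chem_class": rec.chem_class,
                    "formula": rec.formula,
                    "n13c": rec.n13c,
                    "n2h": rec.n2h,
                    "mass_only_mz": "" if rec.mass_only_mz is None else repr(rec.mass_only_mz),
                    "ion_species": rec.ion_species.value,
                    "rt_min": repr(rec.rt_min),
                    "early_eluter": int(rec.early_eluter),
                    "role": rec.role,
                    "surrogate_is": rec.surrogate_is,
                    "fragments": _format_fragments(rec.fragments),
                    "provenance": rec.provenance,
                }
            )


def load_default_registry() -> CompoundRegistry:
    """The packaged 45-analyte / 23-internal-standard panel."""
    ref = importlib.resources.files("pfasquant") / "data" / "registry.csv"
    with importlib.resources.as_file(ref) as path:
        return read_registry(path)


_ADDUCT = {
    IonSpecies.DEPROTONATED: "[M-H]",
    IonSpecies.PROTONATED: "[M+H]",
    IonSpecies.DEPROTONATED_DECARBOXYLATED: "[M-CO2-H]",
}


def write_transition_list(reg: CompoundRegistry, path: str | Path, list_name: str = "PFAS") -> None:
    """Write a Skyline-importable small-molecule transition list.

    One precursor row per compound plus one row per fragment.  Mass-only
    entries are emitted with the stored ion m/z in place of a formula and
    flagged in the Note column.
    """
    path = Path(path)
    header = [
        "Molecule List Name", "Precursor Name", "Molecular Formula",
        "Precursor Adduct", "Precursor Charge", "Precursor m/z",
        "Explicit Retention Time", "Product m/z", "Product Charge", "Note",
    ]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in reg:
            charge = rec.ion_species.charge
            note = "" if rec.formula else "mass-only entry (no formula)"
            base = [
                list_name, rec.name, rec.formula, _ADDUCT[rec.ion_species],
                charge, f"{rec.precursor_mz:.4f}", f"{rec.rt_min:.2f}",
            ]
            writer.writerow(base + ["", "", note])
            for mz, _ab in rec.fragments:
                writer.writerow(base + [f"{mz:.4f}", charge, note])
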