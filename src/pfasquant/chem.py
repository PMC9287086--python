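"""Molecular formulas, exact ion masses, isotope patterns and ppm arithmetic.

Mass conventions
----------------
PFAS are quantified as singly charged (de)protonated ions.  By default the
ion m/z is computed with the *neutral hydrogen atom* mass and the electron
mass ignored::

    [M-H]-  ->  M - m(H)
    [M+H]+  ->  M + m(H)

which is the convention most targeted small-molecule software prints.  The
physically exact convention (subtract a proton, i.e. account for the electron
kept by the anion) is available via ``electron_correction=True``; the two
differ by ~0.0011 Da.

The atomic mass and isotope-abundance table is a packaged snapshot of IUPAC
monoisotopic masses (6+ decimals); it is never fetched at run time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Tuple

__all__ = [
    "ElementCounts",
    "IonSpecies",
    "IsotopePattern",
    "FormulaError",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_difference",
    "mz_window",
    "isotope_pattern",
    "fluorine_count",
    "ELECTRON_MASS",
    "MONOISOTOPIC",
]

# Monoisotopic mass of the most abundant isotope, Da (IUPAC/CODATA snapshot).
MONOISOTOPIC: Dict[str, float] = {
    "C": 12.0,
    "H": 1.007825032,
    "N": 14.003074005,
    "O": 15.994914620,
    "F": 18.998403163,
    "S": 31.972071174,
    "P": 30.973761998,
    "Na": 22.989769282,
    "Cl": 34.968852682,
    "K": 38.963706486,
    "Br": 78.918337600,
    "I": 126.904471900,
}

# Heavy-isotope masses used for stable-isotope labels.
MASS_13C = 13.003354835
MASS_2H = 2.014101778

ELECTRON_MASS = 0.000548580

# Natural isotope distributions: element -> [(mass Da, abundance fraction)].
# Monoisotopic elements carry a single entry.
ISOTOPES: Dict[str, List[Tuple[float, float]]] = {
    "C": [(12.0, 0.9893), (13.003354835, 0.0107)],
    "H": [(1.007825032, 0.999885), (2.014101778, 0.000115)],
    "N": [(14.003074005, 0.99636), (15.000108899, 0.00364)],
    "O": [(15.994914620, 0.99757), (16.999131757, 0.00038), (17.999159613, 0.00205)],
    "S": [(31.972071174, 0.9499), (32.971458910, 0.0075), (33.967866900, 0.0425), (35.967080710, 0.0001)],
    "F": [(18.998403163, 1.0)],
    "P": [(30.973761998, 1.0)],
    "Na": [(22.989769282, 1.0)],
    "Cl": [(34.968852682, 0.7576), (36.965902602, 0.2424)],
    "K": [(38.963706486, 0.932581), (40.961825258, 0.067302)],
    "Br": [(78.918337600, 0.5069), (80.916289700, 0.4931)],
    "I": [(126.904471900, 1.0)],
}

_CO2 = {"C": 1, "O": 2}


class FormulaError(ValueError):
    """Raised on malformed or chemically impossible formulas."""


@dataclass(frozen=True)
class ElementCounts:
    """Element composition of a neutral molecule, with optional isotope labels.

    ``counts`` maps element symbols to non-negative integers.  ``n13c`` and
    ``n2h`` record how many carbon/hydrogen positions carry a stable-isotope
    label (13C / deuterium) in internal standards; they never exceed the
    corresponding element count.
    """

    counts: Dict[str, int] = field(default_factory=dict)
    n13c: int = 0
    n2h: int = 0

    def __post_init__(self) -> None:
        for sym, n in self.counts.items():
            if sym not in MONOISOTOPIC:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if n < 0:
                raise FormulaError(f"negative count for {sym}")
        if not any(n > 0 for n in self.counts.values()):
            raise FormulaError("formula must contain at least one atom")
        if self.n13c < 0 or self.n2h < 0:
            raise FormulaError("label counts must be non-negative")
        if self.n13c > self.counts.get("C", 0):
            raise FormulaError("13C label count exceeds carbon count")
        if self.n2h > self.counts.get("H", 0):
            raise FormulaError("2H label count exceeds hydrogen count")

    def __getitem__(self, sym: str) -> int:
        return self.counts.get(sym, 0)

    def __add__(self, other: "ElementCounts") -> "ElementCounts":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementCounts(merged, self.n13c + other.n13c, self.n2h + other.n2h)

    def __sub__(self, other: "ElementCounts") -> "ElementCounts":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) - n
            if merged[sym] < 0:
                raise FormulaError(f"cannot remove {n} {sym} from {format_formula(self)}")
            if merged[sym] == 0:
                del merged[sym]
        return ElementCounts(merged, self.n13c, self.n2h)


class IonSpecies(Enum):
    """Single-charge ion species observed for PFAS under ESI.

    Most PFAS ionize as [M-H]-; zwitterionic sulfonamido-amines only as
    [M+H]+; ether acids such as HFPO-DA and PEPA predominate as the in-source
    decarboxylated anion [M-CO2-H]-.
    """

    DEPROTONATED = "[M-H]"
    PROTONATED = "[M+H]"
    DEPROTONATED_DECARBOXYLATED = "[M-CO2-H]"

    @property
    def polarity(self) -> str:
        return "+" if self is IonSpecies.PROTONATED else "-"

    @property
    def charge(self) -> int:
        return 1 if self is IonSpecies.PROTONATED else -1


@dataclass(frozen=True)
class IsotopePattern:
    """Theoretical isotope envelope: (m/z, abundance) pairs, base peak = 1."""

    peaks: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("empty isotope pattern")
        mzs = [p[0] for p in self.peaks]
        abunds = [p[1] for p in self.peaks]
        if any(b <= 0 or b > 1 + 1e-12 for b in abunds):
            raise ValueError("abundances must lie in (0, 1]")
        if abs(max(abunds) - 1.0) > 1e-9:
            raise ValueError("base peak abundance must be 1")
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("m/z must be strictly increasing")

    @property
    def mz(self) -> Tuple[float, ...]:
        return tuple(p[0] for p in self.peaks)

    @property
    def abundance(self) -> Tuple[float, ...]:
        return tuple(p[1] for p in self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str, n13c: int = 0, n2h: int = 0) -> ElementCounts:
    """Parse a Hill-style formula string (e.g. ``"C8H5F13O3S"``).

    Isotope labels are never embedded in the string; they arrive as separate
    ``n13c`` / ``n2h`` arguments (mirroring the registry columns).
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        sym, digits = m.group(1), m.group(2)
        if sym not in MONOISOTOPIC:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for {sym} at position {pos}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return ElementCounts(counts, n13c=n13c, n2h=n2h)


def format_formula(f: ElementCounts) -> str:
    """Canonical Hill-order formatter: C, H, then remaining symbols alphabetically."""
    order: List[str] = []
    if f["C"]:
        order.append("C")
        if f["H"]:
            order.append("H")
        order += sorted(s for s in f.counts if s not in ("C", "H") and f[s] > 0)
    else:
        order = sorted(s for s in f.counts if f[s] > 0)
    out = []
    for sym in order:
        n = f[sym]
        out.append(sym if n == 1 else f"{sym}{n}")
    return "".join(out)


def monoisotopic_mass(f: ElementCounts) -> float:
    """Monoisotopic mass in Da; labeled positions use the heavy-isotope mass."""
    mass = sum(MONOISOTOPIC[sym] * n for sym, n in f.counts.items())
    mass += f.n13c * (MASS_13C - MONOISOTOPIC["C"])
    mass += f.n2h * (MASS_2H - MONOISOTOPIC["H"])
    return mass


def ion_mz(f: ElementCounts, species: IonSpecies, electron_correction: bool = False) -> float:
    """m/z of a singly charged ion of ``f`` for the given species.

    With ``electron_correction`` the electron mass is added to anions and
    subtracted from cations (the physically exact proton convention).
    """
    m_h = MONOISOTOPIC["H"]
    if species is IonSpecies.DEPROTONATED:
        mz = monoisotopic_mass(f) - m_h
        if electron_correction:
            mz += ELECTRON_MASS
    elif species is IonSpecies.PROTONATED:
        mz = monoisotopic_mass(f) + m_h
        if electron_correction:
            mz -= ELECTRON_MASS
    elif species is IonSpecies.DEPROTONATED_DECARBOXYLATED:
        if f["C"] < 1 or f["O"] < 2:
            raise FormulaError(
                f"decarboxylation needs >=1 C and >=2 O; got {format_formula(f)}"
            )
        mz = monoisotopic_mass(f - ElementCounts(dict(_CO2))) - m_h
        if electron_correction:
            mz += ELECTRON_MASS
    else:  # pragma: no cover
        raise ValueError(species)
    return mz


def ppm_difference(mz_ref: float, mz_other: float) -> float:
    """Absolute mass difference in parts per million of the reference m/z."""
    if mz_ref <= 0:
        raise ValueError("reference m/z must be positive")
    return abs(mz_ref - mz_other) / mz_ref * 1e6


def mz_window(mz: float, tol_ppm: float) -> Tuple[float, float]:
    """Closed extraction interval [mz·(1−tol/1e6), mz·(1+tol/1e6)]."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if tol_ppm < 0:
        raise ValueError("ppm tolerance must be non-negative")
    return mz * (1 - tol_ppm / 1e6), mz * (1 + tol_ppm / 1e6)


def _element_distribution(sym: str, n: int, prune: float) -> List[Tuple[float, float]]:
    """Isotopologue (mass, probability) distribution of n atoms of one element."""
    single = ISOTOPES[sym]
    dist: List[Tuple[float, float]] = [(0.0, 1.0)]
    for _ in range(n):
        nxt: Dict[int, Tuple[float, float]] = {}
        for mass, p in dist:
            for im, ip in single:
                key = round((mass + im) * 1e4)
                m2, p2 = nxt.get(key, (mass + im, 0.0))
                nxt[key] = (m2, p2 + p * ip)
        dist = [(m, p) for m, p in nxt.values() if p > prune]
    return dist


def isotope_pattern(
    f: ElementCounts,
    threshold: float = 1e-3,
    merge_da: float = 0.01,
    charge_species: IonSpecies | None = None,
) -> IsotopePattern:
    """Theoretical isotope envelope of ``f`` by per-element convolution.

    Labeled positions (13C / 2H) are fixed at their heavy-isotope mass and do
    not contribute combinatorial spread.  Peaks closer than ``merge_da`` are
    merged (intensity-weighted centroid), abundances are normalized to a base
    peak of 1 and peaks below ``threshold`` dropped.  If ``charge_species`` is
    given the m/z axis is shifted to the corresponding ion.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    prune = min(1e-9, threshold * 1e-4)
    dist: List[Tuple[float, float]] = [(0.0, 1.0)]
    label_mass = f.n13c * MASS_13C + f.n2h * MASS_2H
    for sym, n in sorted(f.counts.items()):
        if sym == "C":
            n -= f.n13c
        elif sym == "H":
            n -= f.n2h
        if n == 0 or len(ISOTOPES[sym]) == 1:
            # monoisotopic elements only shift the mass
            dist = [(m + MONOISOTOPIC[sym] * n, p) for m, p in dist]
            continue
        edist = _element_distribution(sym, n, prune)
        conv: Dict[int, Tuple[float, float]] = {}
        for m1, p1 in dist:
            for m2, p2 in edist:
                key = round((m1 + m2) * 1e4)
                mm, pp = conv.get(key, (m1 + m2, 0.0))
                conv[key] = (mm, pp + p1 * p2)
        dist = [(m, p) for m, p in conv.values() if p > prune]
    dist = [(m + label_mass, p) for m, p in dist]
    if charge_species is not None:
        mono = monoisotopic_mass(f)
        shift = ion_mz(f, charge_species) - mono
        dist = [(m + shift, p) for m, p in dist]
    # merge peaks within merge_da
    dist.sort()
    merged: List[List[float]] = []
    for m, p in dist:
        if merged and m - merged[-1][0] <= merge_da:
            m0, p0 = merged[-1]
            merged[-1] = [(m0 * p0 + m * p) / (p0 + p), p0 + p]
        else:
            merged.append([m, p])
    base = max(p for _, p in merged)
    peaks = tuple(
        (m, p / base) for m, p in merged if p / base >= threshold
    )
    return IsotopePattern(peaks)


def fluorine_count(f: ElementCounts) -> int:
    """Number of fluorine atoms — the surrogate-IS similarity coordinate."""
    return f["F"]
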