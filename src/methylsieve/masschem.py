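"""Monoisotopic mass bookkeeping for residues, modifications, peptides and fragments.

All masses are monoisotopic and derived at import time from a single table of
atomic masses, so every downstream number (modification deltas, peptide masses,
fragment m/z, ppm errors) is bit-reproducible from five constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ATOMIC_MASS",
    "PROTON_MASS",
    "WATER_MASS",
    "TRIMETHYLAMINE_MASS",
    "TRIMETHYLAMINE_NOMINAL_MASS",
    "RESIDUE_MASS",
    "STANDARD_RESIDUES",
    "Modification",
    "MODIFICATION_REGISTRY",
    "METHYL_MOD_BY_DEGREE",
    "METHYL_DEGREE_BY_MOD",
    "UnknownModificationError",
    "PeptideError",
    "ModifiedPeptide",
    "mod_delta",
    "formula_mass",
    "peptide_mass",
    "peptide_mz",
    "mass_to_mz",
    "mz_to_neutral_mass",
    "ppm_error",
    "fragment_ions",
]

# Atomic monoisotopic masses (Da). Single source of truth for the package.
ATOMIC_MASS: Mapping[str, float] = {
    "C": 12.0000000,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

# Integer (nominal) masses, used only for nominal-mass labelling.
_NOMINAL_MASS: Mapping[str, int] = {"C": 12, "H": 1, "N": 14, "O": 16, "S": 32}

#: Mass added per charge in m/z conversion (proton, not hydrogen atom).
PROTON_MASS: float = 1.00727646677


def formula_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass of an elemental composition, e.g. ``{"C": 1, "H": 2}``."""
    return sum(ATOMIC_MASS[el] * n for el, n in formula.items())


def _nominal_mass(formula: Mapping[str, int]) -> int:
    return sum(_NOMINAL_MASS[el] * n for el, n in formula.items())


WATER_MASS: float = formula_mass({"H": 2, "O": 1})

#: Trimethylamine (C3H9N), the diagnostic neutral loss of trimethyl-Lys.
_TRIMETHYLAMINE_FORMULA = {"C": 3, "H": 9, "N": 1}
TRIMETHYLAMINE_MASS: float = formula_mass(_TRIMETHYLAMINE_FORMULA)
TRIMETHYLAMINE_NOMINAL_MASS: int = _nominal_mass(_TRIMETHYLAMINE_FORMULA)

# Residue (amino-acid minus water) elemental compositions.
_RESIDUE_FORMULA: Mapping[str, Mapping[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

RESIDUE_MASS: Mapping[str, float] = {
    aa: formula_mass(f) for aa, f in _RESIDUE_FORMULA.items()
}

STANDARD_RESIDUES: tuple[str, ...] = tuple(sorted(RESIDUE_MASS))

#: Position marker for N-terminal modifications in ``ModifiedPeptide.mods``.
NTERM = 0


class UnknownModificationError(KeyError):
    """Raised when a modification name is not in the registry."""


class PeptideError(ValueError):
    """Raised for invalid peptide sequences or modification placements."""


@dataclass(frozen=True)
class Modification:
    """A named mass shift with its allowed targets.

    ``methyl_degree`` is the number of methyl groups for the methyl series
    (1-3) and ``None`` for everything else; at most one methyl-series mod may
    sit on a residue.
    """

    name: str
    delta_mass: float
    target_residues: frozenset[str]  # one-letter codes, plus "nterm"
    methyl_degree: int | None = None

    def targets(self, residue: str) -> bool:
        return residue in self.target_residues


_CH2 = formula_mass({"C": 1, "H": 2})


def _mod(name, formula, targets, degree=None) -> Modification:
    return Modification(name, formula_mass(formula), frozenset(targets), degree)


# Variable-modification set used for the searches, plus fixed
# carbamidomethyl-Cys and acetyl-Lys as the competing hypothesis for
# trimethyl-Lys disambiguation.
MODIFICATION_REGISTRY: Mapping[str, Modification] = {
    m.name: m
    for m in (
        _mod("monomethyl", {"C": 1, "H": 2}, {"K", "R"}, degree=1),
        _mod("dimethyl", {"C": 2, "H": 4}, {"K", "R"}, degree=2),
        _mod("trimethyl", {"C": 3, "H": 6}, {"K"}, degree=3),
        _mod("acetyl", {"C": 2, "H": 2, "O": 1}, {"K", "nterm"}),
        _mod("oxidation", {"O": 1}, {"M"}),
        _mod("dioxidation", {"O": 2}, {"M"}),
        _mod("trioxidation", {"O": 3}, {"C"}),
        _mod("carbamidomethyl", {"C": 2, "H": 3, "N": 1, "O": 1}, {"C"}),
    )
}

METHYL_MOD_BY_DEGREE: Mapping[int, str] = {1: "monomethyl", 2: "dimethyl", 3: "trimethyl"}
METHYL_DEGREE_BY_MOD: Mapping[str, int] = {v: k for k, v in METHYL_MOD_BY_DEGREE.items()}


def mod_delta(name: str) -> float:
    """Monoisotopic mass delta of a registered modification.

    Raises :class:`UnknownModificationError` for names not in the registry.
    """
    try:
        return MODIFICATION_REGISTRY[name].delta_mass
    except KeyError:
        raise UnknownModificationError(
            f"unknown modification {name!r}; known: {sorted(MODIFICATION_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with positioned modifications.

    ``mods`` is a tuple of ``(position, name)`` pairs where position is
    1-based within the peptide, or 0 for the N-terminus. ``charge`` is
    optional and only needed for m/z computations.
    """

    sequence: str
    mods: tuple[tuple[int, str], ...] = ()
    charge: int | None = None

    def __post_init__(self):
        if not self.sequence:
            raise PeptideError("empty peptide sequence")
        for aa in self.sequence:
            if aa not in RESIDUE_MASS:
                raise PeptideError(f"unknown residue {aa!r} in {self.sequence!r}")
        object.__setattr__(self, "mods", tuple(sorted(self.mods)))
        methyl_positions: set[int] = set()
        for pos, name in self.mods:
            mod = MODIFICATION_REGISTRY.get(name)
            if mod is None:
                raise UnknownModificationError(f"unknown modification {name!r}")
            if pos < 0 or pos > len(self.sequence):
                raise PeptideError(
                    f"mod position {pos} outside peptide of length {len(self.sequence)}"
                )
            target = "nterm" if pos == NTERM else self.sequence[pos - 1]
            if not mod.targets(target):
                raise PeptideError(
                    f"{name} cannot target {target!r} at position {pos}"
                )
            if mod.methyl_degree is not None:
                if pos in methyl_positions:
                    raise PeptideError(
                        f"more than one methyl-class mod at position {pos}"
                    )
                methyl_positions.add(pos)
        if self.charge is not None and self.charge < 1:
            raise PeptideError(f"charge must be >= 1, got {self.charge}")

    def methyl_sites(self) -> list[tuple[int, int]]:
        """``(position, degree)`` for every methyl-series mod on the peptide."""
        out = []
        for pos, name in self.mods:
            deg = MODIFICATION_REGISTRY[name].methyl_degree
            if deg is not None:
                out.append((pos, deg))
        return out

    def with_mod_replaced(self, position: int, new_name: str) -> "ModifiedPeptide":
        """Copy with the mod at ``position`` swapped for ``new_name``."""
        mods = tuple(
            (p, new_name if p == position else n) for p, n in self.mods
        )
        return ModifiedPeptide(self.sequence, mods, self.charge)


def peptide_mass(p: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification deltas."""
    mass = WATER_MASS + sum(RESIDUE_MASS[aa] for aa in p.sequence)
    mass += sum(mod_delta(name) for _, name in p.mods)
    return mass


def mass_to_mz(neutral_mass: float, charge: int) -> float:
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def mz_to_neutral_mass(mz: float, charge: int) -> float:
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * PROTON_MASS


def peptide_mz(p: ModifiedPeptide, charge: int | None = None) -> float:
    z = charge if charge is not None else p.charge
    if z is None:
        raise PeptideError("no charge available for m/z computation")
    return mass_to_mz(peptide_mass(p), z)


def ppm_error(observed_mass: float, theoretical_mass: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical_mass <= 0:
        raise ValueError(f"theoretical mass must be > 0, got {theoretical_mass}")
    return 1e6 * (observed_mass - theoretical_mass) / theoretical_mass


def _mods_by_position(p: ModifiedPeptide) -> dict[int, list[str]]:
    by_pos: dict[int, list[str]] = {}
    for pos, name in p.mods:
        by_pos.setdefault(pos, []).append(name)
    return by_pos


def fragment_ions(
    p: ModifiedPeptide,
    series: Iterable[str] = ("b", "y"),
    charge: int = 1,
) -> list[tuple[str, float]]:
    """b/y fragment ions with modification deltas on the covering fragments.

    Returns ``(label, m/z)`` pairs, e.g. ``("b2+", 201.1)``. N-terminal mods
    ride on b ions; a mod at residue i appears on b_j for j >= i and on
    y_k for k >= n - i + 1.
    """
    n = len(p.sequence)
    if n < 2:
        raise PeptideError("fragment ions need a peptide of length >= 2")
    if charge < 1 or charge > 2:
        raise ValueError(f"fragment charge must be 1 or 2, got {charge}")
    series = set(series)
    unknown = series - {"b", "y"}
    if unknown:
        raise ValueError(f"unsupported ion series {sorted(unknown)}")

    by_pos = _mods_by_position(p)
    mod_mass_at = {
        pos: sum(mod_delta(name) for name in names) for pos, names in by_pos.items()
    }
    ions: list[tuple[str, float]] = []
    tag = "+" * charge
    if "b" in series:
        # b_i neutral = sum of first i residues + covering mods (incl. N-term)
        running = mod_mass_at.get(NTERM, 0.0)
        for i in range(1, n):
            running += RESIDUE_MASS[p.sequence[i - 1]] + mod_mass_at.get(i, 0.0)
            ions.append((f"b{i}{tag}", mass_to_mz(running, charge)))
    if "y" in series:
        # y_k neutral = sum of last k residues + water + covering mods
        running = WATER_MASS
        for k in range(1, n):
            pos = n - k + 1
            running += RESIDUE_MASS[p.sequence[pos - 1]] + mod_mass_at.get(pos, 0.0)
            ions.append((f"y{k}{tag}", mass_to_mz(running, charge)))
    return ions
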