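"""Target-ion database model and adduct mass arithmetic.

The targeted extraction workflow is driven by a curated table of lipid ions:
each row is one adduct of one lipid in one electrospray polarity, carrying the
m/z value to extract, the expected retention time, and identity metadata
(name, InChIKey, internal-standard flag).  "Known unknowns" are reproducibly
detected ions with m/z and retention time but no molecular identification;
they carry an empty InChIKey by convention, never sentinel numbers.

Mass arithmetic uses IUPAC monoisotopic atomic masses hard-coded in one table
for bit-exact reproducibility, and includes the electron mass in adduct m/z
values (a protonated ion is lighter than "M + mass of H" by one electron).
Only singly charged adducts are supported.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ADDUCTS",
    "ElementalFormula",
    "formula",
    "monoisotopic_mass",
    "adduct_mz",
    "display_mz",
    "tg_formula",
    "TargetIon",
    "IonDatabase",
    "load_ion_database",
    "DatabaseSchemaError",
    "DatabaseValidationError",
    "CalibrationInfeasibleError",
]

#: IUPAC monoisotopic masses (Da) of the elements needed for common lipids.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.98976928,
}

ELECTRON_MASS = 0.000548579909
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS


class DatabaseSchemaError(ValueError):
    """A required column is missing from a database table."""


class DatabaseValidationError(ValueError):
    """Database rows violate a structural invariant (e.g. duplicate keys)."""


class CalibrationInfeasibleError(DatabaseValidationError):
    """A present ionization mode has fewer than 3 internal standards, so the
    quadratic retention-time recalibration cannot be fitted."""


# ---------------------------------------------------------------------------
# Elemental formulas and adduct arithmetic
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _hill_order(items: Iterable[tuple[str, int]]) -> tuple[tuple[str, int], ...]:
    # Hill convention: C first, H second, the rest alphabetical.
    rank = {"C": (0, ""), "H": (1, "")}
    return tuple(sorted(items, key=lambda kv: rank.get(kv[0], (2, kv[0]))))


@dataclasses.dataclass(frozen=True)
class ElementalFormula:
    """An element -> count map with positive integer counts."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "ElementalFormula":
        items = []
        for element, n in counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol {element!r}")
            if int(n) != n or n <= 0:
                raise ValueError(
                    f"element count must be a positive integer: {element}={n!r}"
                )
            items.append((str(element), int(n)))
        return cls(_hill_order(items))

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a plain formula string such as ``"C61H102O6"``."""
        text = text.strip()
        if not text:
            raise ValueError("empty formula string")
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls.from_counts(counts)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def add(self, **elements: int) -> "ElementalFormula":
        """Return a new formula with extra atoms (e.g. ``f.add(C=1, H=2)``)."""
        counts = self.as_dict()
        for element, n in elements.items():
            counts[element] = counts.get(element, 0) + n
            if counts[element] == 0:
                del counts[element]
        return ElementalFormula.from_counts(counts)

    def __str__(self) -> str:
        return "".join(
            f"{el}{n if n != 1 else ''}" for el, n in self.counts
        )


def formula(text: str | None = None, **counts: int) -> ElementalFormula:
    """Convenience constructor: ``formula("C5H4N4")`` or ``formula(C=5, H=4, N=4)``."""
    if text is not None:
        if counts:
            raise TypeError("pass either a formula string or keyword counts")
        return ElementalFormula.parse(text)
    return ElementalFormula.from_counts(counts)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic (exact) mass of a neutral formula in Da."""
    if not f.counts:
        raise ValueError("empty formula")
    total = 0.0
    for element, n in f.counts:
        try:
            total += n * MONOISOTOPIC_MASS[element]
        except KeyError:
            raise ValueError(f"unknown element symbol {element!r}") from None
    return total


def _m(symbol: str, k: int = 1) -> float:
    return k * MONOISOTOPIC_MASS[symbol]


#: Supported singly charged adducts: label -> (neutral mass delta, polarity).
ADDUCTS: Mapping[str, tuple[float, int]] = {
    "[M+H]+": (_m("H"), +1),
    "[M+NH4]+": (_m("N") + _m("H", 4), +1),
    "[M+Na]+": (_m("Na"), +1),
    "[M-H]-": (-_m("H"), -1),
    "[M+OAc]-": (_m("C", 2) + _m("H", 3) + _m("O", 2), -1),
}


def normalize_adduct_label(label: str) -> str:
    """Map typographic minus signs to ASCII so both spellings are accepted."""
    return label.replace("−", "-").replace("–", "-").strip()


def adduct_mz(f: ElementalFormula, adduct: str) -> float:
    """m/z (Th) of a singly charged adduct of a neutral formula.

    The electron mass is subtracted for positive and added for negative ions.
    The value is returned at full precision; use :func:`display_mz` for the
    conventional 4-decimal display rounding.
    """
    label = normalize_adduct_label(adduct)
    if label not in ADDUCTS:
        raise ValueError(f"unsupported adduct label {adduct!r}")
    delta, polarity = ADDUCTS[label]
    return monoisotopic_mass(f) + delta - polarity * ELECTRON_MASS


def display_mz(mz: float, decimals: int = 4) -> float:
    """Half-even rounding of an m/z value for display (default 4 decimals)."""
    return float(np.round(mz, decimals))


def tg_formula(total_acyl_carbons: int, double_bonds: int) -> ElementalFormula:
    """Elemental formula of a triacylglycerol from its C:DB shorthand.

    A TG with ``n`` total acyl carbons and ``d`` double bonds has formula
    C(n+3) H(2n+2-2d) O6 (glycerol backbone plus three acyl chains).
    """
    n, d = int(total_acyl_carbons), int(double_bonds)
    if n < 6:
        raise ValueError("a triacylglycerol needs at least 2 carbons per acyl chain")
    if d < 0:
        raise ValueError("double bond count must be non-negative")
    hydrogens = 2 * n + 2 - 2 * d
    if hydrogens <= 0:
        raise ValueError(
            f"TG({n}:{d}) is chemically impossible (hydrogen count {hydrogens})"
        )
    return formula(C=n + 3, H=hydrogens, O=6)


# ---------------------------------------------------------------------------
# Target ions and the ion database
# ---------------------------------------------------------------------------

MODES = ("positive", "negative")
MODE_TOKENS = {"positive": "ESI+", "negative": "ESI-"}
_MODE_ALIASES = {
    "esi+": "positive",
    "positive": "positive",
    "pos": "positive",
    "+": "positive",
    "esi-": "negative",
    "negative": "negative",
    "neg": "negative",
    "-": "negative",
}


def parse_mode(token: str) -> str:
    key = normalize_adduct_label(str(token)).lower()
    if key not in _MODE_ALIASES:
        raise ValueError(f"unrecognized ionization mode token {token!r}")
    return _MODE_ALIASES[key]


@dataclasses.dataclass(frozen=True)
class TargetIon:
    """One database row: a lipid's adduct in one ionization mode."""

    ion_id: str
    lipid_id: str
    name: str
    mode: str  # "positive" | "negative"
    adduct: str
    mz: float
    expected_rt: float  # minutes
    inchikey: str = ""
    is_internal_standard: bool = False
    is_known: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not self.mz > 0:
            raise ValueError(f"{self.ion_id}: mz must be positive")
        if not self.expected_rt > 0:
            raise ValueError(f"{self.ion_id}: expected_rt must be positive")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.mode, normalize_adduct_label(self.adduct), self.lipid_id)


DATABASE_COLUMNS = (
    "ion_id",
    "lipid_id",
    "name",
    "mode",
    "adduct",
    "mz",
    "expected_rt",
    "inchikey",
    "is_internal_standard",
    "is_known",
)


class IonDatabase:
    """A validated collection of :class:`TargetIon` rows.

    Uniqueness of ``ion_id`` and of the ``(mode, adduct, lipid_id)`` key is
    enforced at construction.  The internal-standard count per mode is only
    checked by :func:`load_ion_database` when ``require_standards=True``,
    because small tables are legitimate outside the calibration context.
    """

    def __init__(self, ions: Iterable[TargetIon], rejected: pd.DataFrame | None = None):
        self._ions: list[TargetIon] = list(ions)
        self.rejected = rejected if rejected is not None else pd.DataFrame(
            columns=["row", "ion_id", "reason"]
        )
        seen_ids: set[str] = set()
        seen_keys: dict[tuple[str, str, str], str] = {}
        for ion in self._ions:
            if ion.ion_id in seen_ids:
                raise DatabaseValidationError(f"duplicate ion_id {ion.ion_id!r}")
            seen_ids.add(ion.ion_id)
            if ion.key in seen_keys:
                raise DatabaseValidationError(
                    f"duplicate (mode, adduct, lipid_id) key {ion.key!r} "
                    f"for ions {seen_keys[ion.key]!r} and {ion.ion_id!r}"
                )
            seen_keys[ion.key] = ion.ion_id
        self._by_id = {ion.ion_id: ion for ion in self._ions}

    def __len__(self) -> int:
        return len(self._ions)

    def __iter__(self) -> Iterator[TargetIon]:
        return iter(self._ions)

    def __contains__(self, ion_id: str) -> bool:
        return ion_id in self._by_id

    def get(self, ion_id: str) -> TargetIon:
        try:
            return self._by_id[ion_id]
        except KeyError:
            raise KeyError(f"unknown ion_id {ion_id!r}") from None

    @property
    def ion_ids(self) -> list[str]:
        return [ion.ion_id for ion in self._ions]

    @property
    def modes(self) -> list[str]:
        return [m for m in MODES if any(ion.mode == m for ion in self._ions)]

    def count(self, mode: str | None = None) -> int:
        if mode is None:
            return len(self._ions)
        return sum(ion.mode == mode for ion in self._ions)

    def internal_standards(self, mode: str | None = None) -> list[TargetIon]:
        return [
            ion
            for ion in self._ions
            if ion.is_internal_standard and (mode is None or ion.mode == mode)
        ]

    def lipid_groups(self) -> dict[str, list[TargetIon]]:
        """All ions of each lipid, keyed by ``lipid_id`` (insertion order)."""
        groups: dict[str, list[TargetIon]] = {}
        for ion in self._ions:
            groups.setdefault(ion.lipid_id, []).append(ion)
        return groups

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ion in self._ions:
            row = dataclasses.asdict(ion)
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(DATABASE_COLUMNS))
        return df.set_index("ion_id", drop=False)

    def write_csv(self, path: str | Path) -> None:
        df = self.to_frame().reset_index(drop=True).copy()
        df["mode"] = df["mode"].map(MODE_TOKENS)
        df.to_csv(path, index=False)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in {"true", "t", "1", "yes"}:
        return True
    if token in {"false", "f", "0", "no", ""}:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean flag")


def load_ion_database(
    source: str | Path | pd.DataFrame,
    require_standards: bool = False,
    strict_rows: bool = False,
) -> IonDatabase:
    """Load and validate a target-ion database from CSV or a DataFrame.

    Row-level invariant violations (non-positive m/z or retention time,
    inconsistent identity flags, unparsable numbers) are rejected and listed
    in the returned database's ``rejected`` report (or raised when
    ``strict_rows=True``).  Structural violations (missing columns, duplicate
    keys) always raise.  With ``require_standards=True`` every ionization mode
    present in the table must carry at least 3 internal standards, the minimum
    for the quadratic retention-time recalibration.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in DATABASE_COLUMNS if c not in df.columns]
    if missing:
        raise DatabaseSchemaError(f"missing required column(s): {', '.join(missing)}")

    ions: list[TargetIon] = []
    rejected_rows: list[dict] = []
    for idx, row in df.iterrows():
        reason = None
        try:
            mode = parse_mode(row["mode"])
            mz = float(row["mz"])
            rt = float(row["expected_rt"])
            is_std = _parse_bool(row["is_internal_standard"])
            is_known = _parse_bool(row["is_known"])
            inchikey = str(row["inchikey"]).strip()
            if pd.isna(mz) or mz <= 0:
                reason = "mz must be positive"
            elif pd.isna(rt) or rt <= 0:
                reason = "expected_rt must be positive"
            elif is_std and not is_known:
                reason = "internal standards must be flagged as known"
            elif not is_known and inchikey:
                reason = "a known unknown must have an empty InChIKey"
        except (ValueError, TypeError) as exc:
            reason = str(exc)
        if reason is not None:
            if strict_rows:
                raise DatabaseValidationError(f"row {idx}: {reason}")
            rejected_rows.append(
                {"row": idx, "ion_id": str(row.get("ion_id", "")), "reason": reason}
            )
            continue
        ions.append(
            TargetIon(
                ion_id=str(row["ion_id"]).strip(),
                lipid_id=str(row["lipid_id"]).strip(),
                name=str(row["name"]).strip(),
                mode=mode,
                adduct=normalize_adduct_label(str(row["adduct"])),
                mz=mz,
                expected_rt=rt,
                inchikey=inchikey,
                is_internal_standard=is_std,
                is_known=is_known,
            )
        )

    rejected = pd.DataFrame(rejected_rows, columns=["row", "ion_id", "reason"])
    if len(rejected):
        warnings.warn(
            f"rejected {len(rejected)} database row(s); see IonDatabase.rejected",
            stacklevel=2,
        )
    db = IonDatabase(ions, rejected=rejected)
    if require_standards:
        for mode in db.modes:
            n_std = len(db.internal_standards(mode))
            if n_std < 3:
                raise CalibrationInfeasibleError(
                    f"mode {mode!r} has {n_std} internal standard(s); "
                    "at least 3 are required for the quadratic RT recalibration"
                )
    return db
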