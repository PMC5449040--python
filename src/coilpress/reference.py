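"""Embedded random-coil pressure-coefficient reference tables.

The library holds the backbone amide ``15N`` and ``1HN`` pressure
coefficients of the 20 canonical amino acids measured in random-coil
model tetrapeptides over 0.1-200 MPa: the atmospheric-pressure shift
``delta0`` (ppm), the first- and second-order pressure coefficients
``B1`` (ppm/GPa) and ``B2`` (ppm/GPa^2) with their fit standard
deviations, and, where measured, the one-bond amide coupling
``1J(HN)`` in Hz.

The nitrogen table has 22 rows (His at pH 4.0 and pH 8.5, Pro as cis
and trans isomers); the proton table has 19 rows (no Pro amide proton,
His at pH 4.0 only). Every invariant of the tables is re-validated
each time the bundled data are loaded.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from .model import PressureCoefficients

__all__ = [
    "Nucleus",
    "Variant",
    "ReferenceEntry",
    "ReferenceLibrary",
    "ReferenceDataError",
    "ReferenceLookupError",
    "load_reference",
    "get_entry",
    "table_mean",
]

_CANONICAL_RESIDUES = frozenset(
    [
        "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
        "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    ]
)

_CSV_HEADER = [
    "residue",
    "variant",
    "nucleus",
    "delta0_ppm",
    "B1_ppm_per_GPa",
    "B1_err",
    "B2_ppm_per_GPa2",
    "B2_err",
    "oneJ_HN_Hz",
]


class ReferenceDataError(ValueError):
    """Raised when reference data violate a table invariant."""


class ReferenceLookupError(LookupError):
    """Raised when a residue/nucleus/variant combination is not in the tables."""


class Nucleus(str, enum.Enum):
    """Backbone amide nucleus of a reference entry."""

    N15 = "N15"
    H1N = "H1N"

    @classmethod
    def coerce(cls, value: Union["Nucleus", str]) -> "Nucleus":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            raise ReferenceLookupError(
                f"unknown nucleus {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


class Variant(str, enum.Enum):
    """Measurement variant of a residue (protonation state or Pro isomer)."""

    STANDARD = "standard"
    PH4 = "pH4.0"
    PH85 = "pH8.5"
    CIS = "cis"
    TRANS = "trans"

    @classmethod
    def coerce(cls, value: Union["Variant", str]) -> "Variant":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            raise ReferenceLookupError(
                f"unknown variant {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True)
class ReferenceEntry:
    """One residue/variant/nucleus row of the coefficient tables.

    Units: ``delta0`` ppm, ``B1`` ppm/GPa, ``B2`` ppm/GPa^2,
    ``oneJ_HN`` Hz (stored with its negative sign as printed).
    """

    residue: str
    variant: Variant
    nucleus: Nucleus
    delta0: float
    delta0_err: float
    B1: float
    B1_err: float
    B2: float
    B2_err: float
    oneJ_HN: Optional[float] = None

    def __post_init__(self) -> None:
        if self.residue not in _CANONICAL_RESIDUES:
            raise ReferenceDataError(
                f"{self.residue!r} is not a canonical three-letter residue code"
            )
        object.__setattr__(self, "variant", Variant.coerce(self.variant))
        object.__setattr__(self, "nucleus", Nucleus.coerce(self.nucleus))
        for name in ("delta0", "delta0_err", "B1", "B1_err", "B2", "B2_err"):
            if not math.isfinite(getattr(self, name)):
                raise ReferenceDataError(f"{self.key}: non-finite {name}")

    @property
    def key(self) -> str:
        return f"{self.residue}/{self.variant.value}/{self.nucleus.value}"

    @property
    def oneJ_HN_magnitude(self) -> Optional[float]:
        """|1J(HN)| in Hz, or None where not measured."""
        return None if self.oneJ_HN is None else abs(self.oneJ_HN)

    @property
    def coefficients(self) -> PressureCoefficients:
        """The (delta0, B1, B2) triple with standard errors, p0 = 0.1 MPa."""
        return PressureCoefficients(
            delta0=self.delta0,
            B1=self.B1,
            B2=self.B2,
            delta0_err=self.delta0_err,
            B1_err=self.B1_err,
            B2_err=self.B2_err,
        )

    def to_dict(self) -> dict:
        return {
            "residue": self.residue,
            "variant": self.variant.value,
            "nucleus": self.nucleus.value,
            "delta0": self.delta0,
            "delta0_err": self.delta0_err,
            "B1": self.B1,
            "B1_err": self.B1_err,
            "B2": self.B2,
            "B2_err": self.B2_err,
            "oneJ_HN": self.oneJ_HN,
        }

    @classmethod
    def from_dict(cls, record: dict) -> "ReferenceEntry":
        known = {f.name for f in fields(cls)}
        unknown = set(record) - known
        if unknown:
            raise ReferenceDataError(f"unknown reference fields: {sorted(unknown)}")
        return cls(**record)


# expected row counts per nucleus
_EXPECTED_COUNTS = {Nucleus.N15: 22, Nucleus.H1N: 19}
# 1J(HN) extremes printed in the nitrogen table, Hz
_ONEJ_RANGE = (-99.5, -92.7)
_DELTA0_RANGE = {Nucleus.N15: (109.0, 136.0), Nucleus.H1N: (8.0, 8.6)}


class ReferenceLibrary:
    """Validated, queryable collection of :class:`ReferenceEntry` rows."""

    def __init__(self, entries: Iterable[ReferenceEntry], validate: bool = True):
        self._entries = tuple(entries)
        self._index = {}
        for e in self._entries:
            k = (e.residue, e.variant, e.nucleus)
            if k in self._index:
                raise ReferenceDataError(f"duplicate reference entry {e.key}")
            self._index[k] = e
        if validate:
            self.validate()

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[ReferenceEntry]:
        return iter(self._entries)

    @property
    def entries(self) -> tuple:
        return self._entries

    def subset(self, nucleus: Union[Nucleus, str]) -> tuple:
        nucleus = Nucleus.coerce(nucleus)
        return tuple(e for e in self._entries if e.nucleus is nucleus)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check every table invariant; raise ReferenceDataError naming the first violation."""
        for nucleus, expected in _EXPECTED_COUNTS.items():
            n = len(self.subset(nucleus))
            if n != expected:
                raise ReferenceDataError(
                    f"expected exactly {expected} {nucleus.value} entries, found {n}"
                )
        for e in self._entries:
            if not e.B1 > 0:
                raise ReferenceDataError(f"{e.key}: B1 must be positive, got {e.B1}")
            if not e.B2 < 0:
                raise ReferenceDataError(f"{e.key}: B2 must be negative, got {e.B2}")
            lo, hi = _DELTA0_RANGE[e.nucleus]
            if not lo <= e.delta0 <= hi:
                raise ReferenceDataError(
                    f"{e.key}: delta0 {e.delta0} outside [{lo}, {hi}] ppm"
                )
            if e.oneJ_HN is not None:
                jlo, jhi = _ONEJ_RANGE
                if not jlo <= e.oneJ_HN <= jhi:
                    raise ReferenceDataError(
                        f"{e.key}: oneJ_HN {e.oneJ_HN} outside [{jlo}, {jhi}] Hz"
                    )
            if e.nucleus is Nucleus.H1N and e.oneJ_HN is not None:
                raise ReferenceDataError(f"{e.key}: proton entries carry no 1J(HN)")

    # -- queries ------------------------------------------------------------

    def get_entry(
        self,
        residue: str,
        nucleus: Union[Nucleus, str],
        variant: Optional[Union[Variant, str]] = None,
    ) -> ReferenceEntry:
        """Return the unique entry for residue/nucleus/variant.

        When ``variant`` is omitted, His defaults to its pH 4.0 form and
        Pro to the trans isomer; all other residues use the standard row.
        Combinations absent from the tables (e.g. Pro/H1N) raise
        :class:`ReferenceLookupError` rather than returning a default.
        """
        if residue not in _CANONICAL_RESIDUES:
            raise ReferenceLookupError(
                f"unknown residue code {residue!r}; expected a canonical "
                "three-letter code such as 'Ala'"
            )
        nucleus = Nucleus.coerce(nucleus)
        if variant is None:
            variant = {
                "His": Variant.PH4,
                "Pro": Variant.TRANS,
            }.get(residue, Variant.STANDARD)
        else:
            variant = Variant.coerce(variant)
        try:
            return self._index[(residue, variant, nucleus)]
        except KeyError:
            raise ReferenceLookupError(
                f"{residue}/{variant.value}/{nucleus.value} is not in the "
                "reference tables"
            ) from None

    def table_mean(self, nucleus: Union[Nucleus, str], order: int) -> float:
        """Arithmetic mean of delta0 (order 0), B1 (1) or B2 (2) over a whole table.

        All rows of the nucleus enter the average (22 for N15 including
        both His pH forms and both Pro isomers; 19 for H1N). No rounding
        is applied here.
        """
        if order not in (0, 1, 2):
            raise ValueError(f"order must be 0, 1 or 2, got {order}")
        attr = {0: "delta0", 1: "B1", 2: "B2"}[order]
        values = [getattr(e, attr) for e in self.subset(nucleus)]
        return sum(values) / len(values)

    def oneJ_values(self) -> tuple:
        return tuple(e.oneJ_HN for e in self._entries if e.oneJ_HN is not None)

    def oneJ_range(self) -> float:
        """max - min of the stored 1J(HN) couplings, in Hz."""
        j = self.oneJ_values()
        return max(j) - min(j)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "format": "coilpress-reference",
            "version": 1,
            "entries": [e.to_dict() for e in self._entries],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "ReferenceLibrary":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            text = Path(source).read_text()
        else:
            text = source
        payload = json.loads(text)
        try:
            records = payload["entries"]
        except (TypeError, KeyError):
            raise ReferenceDataError("reference JSON lacks an 'entries' list") from None
        return cls(ReferenceEntry.from_dict(r) for r in records)

    def to_csv(self, path: Union[str, Path, None] = None) -> str:
        rows = [",".join(_CSV_HEADER)]
        for e in self._entries:
            j = "" if e.oneJ_HN is None else repr(e.oneJ_HN)
            rows.append(
                f"{e.residue},{e.variant.value},{e.nucleus.value},"
                f"{e.delta0!r},{e.B1!r},{e.B1_err!r},{e.B2!r},{e.B2_err!r},{j}"
            )
        text = "\n".join(rows) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_csv(cls, source: Union[str, Path]) -> "ReferenceLibrary":
        if isinstance(source, Path) or "\n" not in str(source):
            text = Path(source).read_text()
        else:
            text = str(source)
        reader = csv.DictReader(text.splitlines())
        if reader.fieldnames != _CSV_HEADER:
            raise ReferenceDataError(
                f"bad CSV header {reader.fieldnames}; expected {_CSV_HEADER}"
            )
        entries = []
        for row in reader:
            entries.append(
                ReferenceEntry(
                    residue=row["residue"],
                    variant=row["variant"],
                    nucleus=row["nucleus"],
                    delta0=float(row["delta0_ppm"]),
                    # the caption-level delta0 uncertainty is nucleus-wide
                    delta0_err=0.01 if row["nucleus"] == "N15" else 0.001,
                    B1=float(row["B1_ppm_per_GPa"]),
                    B1_err=float(row["B1_err"]),
                    B2=float(row["B2_ppm_per_GPa2"]),
                    B2_err=float(row["B2_err"]),
                    oneJ_HN=float(row["oneJ_HN_Hz"]) if row["oneJ_HN_Hz"] else None,
                )
            )
        return cls(entries)


_cached_library: Optional[ReferenceLibrary] = None


def load_reference() -> ReferenceLibrary:
    """Load (and validate) the bundled reference tables.

    The parsed library is cached; the bundled JSON is read once per process.
    """
    global _cached_library
    if _cached_library is None:
        text = resources.files("coilpress.data").joinpath("reference.json").read_text()
        _cached_library = ReferenceLibrary.from_json(text)
    return _cached_library


def get_entry(residue, nucleus, variant=None) -> ReferenceEntry:
    """Module-level shorthand for ``load_reference().get_entry(...)``."""
    return load_reference().get_entry(residue, nucleus, variant)


def table_mean(nucleus, order) -> float:
    """Module-level shorthand for ``load_reference().table_mean(...)``."""
    return load_reference().table_mean(nucleus, order)
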