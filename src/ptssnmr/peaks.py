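"""Curated 13C chemical-shift assignments for stratum corneum components.

The shipped table covers the shifts printed in the source assignments for
intact pig stratum corneum: lipid hydrocarbon-chain markers, cholesterol ring
carbons, and the keratin filament core/terminal amino-acid markers.  Users can
merge their own (larger) tables; user entries take precedence on
(shift_ppm, moiety).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "AssignmentEntry",
    "SignatureSet",
    "COMPONENT_CLASSES",
    "SIGNATURE_GROUPS",
    "AssignmentTable",
    "load_default_table",
    "lookup_shift",
    "peaks_in_window",
    "signature_set",
]

COMPONENT_CLASSES = frozenset({
    "lipid_chain", "cholesterol", "keratin_core", "keratin_terminal",
    "cornified_envelope", "mixed",
})

SIGNATURE_GROUPS = ("lipids", "keratin_core", "keratin_terminals", "cholesterol_mobile")


@dataclass(frozen=True)
class AssignmentEntry:
    shift_ppm: float
    moiety: str
    component_class: str
    multiplicity: int
    source: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.shift_ppm <= 220.0:
            raise ValueError(f"shift_ppm out of 13C range: {self.shift_ppm}")
        if self.component_class not in COMPONENT_CLASSES:
            raise ValueError(f"unknown component_class: {self.component_class}")
        if self.multiplicity not in (1, 2, 3):
            raise ValueError(f"multiplicity must be 1, 2 or 3, got {self.multiplicity}")


@dataclass(frozen=True)
class SignatureSet:
    """Signature peaks of one component group with per-peak query windows."""

    group: str
    entries: tuple[AssignmentEntry, ...]
    window_half_width_ppm: float = 0.3
    #: explicit (lo, hi) windows; falls back to shift +- half-width when None
    windows: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.group not in SIGNATURE_GROUPS:
            raise ValueError(f"unknown signature group: {self.group}")
        if not self.entries:
            raise ValueError("signature set must be non-empty")

    def peak_windows(self) -> list[tuple[float, float]]:
        if self.windows is not None:
            return list(self.windows)
        h = self.window_half_width_ppm
        return [(e.shift_ppm - h, e.shift_ppm + h) for e in self.entries]


class LookupError_(KeyError):
    """Unknown moiety; carries the nearest table names as a hint."""


def _norm(name: str) -> str:
    return " ".join(name.lower().replace("_", " ").split())


class AssignmentTable:
    """In-memory assignment table with lookup, window and signature queries."""

    def __init__(self, entries: list[AssignmentEntry]):
        seen: dict[tuple[float, str], AssignmentEntry] = {}
        for e in entries:
            seen[(e.shift_ppm, _norm(e.moiety))] = e
        self.entries: list[AssignmentEntry] = sorted(seen.values(), key=lambda e: e.shift_ppm)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AssignmentTable":
        with open(path, newline="") as fh:
            return cls._parse(fh)

    @classmethod
    def _parse(cls, fh) -> "AssignmentTable":
        entries = []
        for row in csv.DictReader(fh):
            entries.append(AssignmentEntry(
                shift_ppm=float(row["shift_ppm"]),
                moiety=row["moiety"].strip(),
                component_class=row["component_class"].strip(),
                multiplicity=int(row["multiplicity"]),
                source=row.get("source", "").strip(),
                notes=row.get("notes", "").strip(),
            ))
        return cls(entries)

    def merged_with(self, other: "AssignmentTable") -> "AssignmentTable":
        """Merge; ``other`` entries win on (shift, moiety) collisions."""
        return AssignmentTable(self.entries + other.entries)

    # -- queries ------------------------------------------------------------

    def lookup_shift(self, moiety: str) -> float:
        key = _norm(moiety)
        # Accept common greek spellings: "Gly C_alpha" == "gly c alpha".
        for e in self.entries:
            if _norm(e.moiety) == key:
                return e.shift_ppm
        # compound peaks match on any constituent, e.g. "Leu C_beta"
        for e in self.entries:
            if key in [_norm(p) for p in e.moiety.split("+")]:
                return e.shift_ppm
        import difflib
        names = [e.moiety for e in self.entries]
        near = difflib.get_close_matches(moiety, names, n=3, cutoff=0.0)
        raise LookupError_(f"unknown moiety {moiety!r}; nearest: {near}")

    def peaks_in_window(self, lo_ppm: float, hi_ppm: float) -> list[AssignmentEntry]:
        if not lo_ppm < hi_ppm:
            raise ValueError(f"inverted window bounds: ({lo_ppm}, {hi_ppm})")
        return [e for e in self.entries if lo_ppm <= e.shift_ppm <= hi_ppm]

    def _by_class(self, component_class: str) -> list[AssignmentEntry]:
        return [e for e in self.entries if e.component_class == component_class]

    def signature_set(self, group: str, window_half_width_ppm: float = 0.3) -> SignatureSet:
        """Canonical signature-peak set of one component group.

        lipids: all-trans and trans/gauche (CH2)n, (omega-1)CH2, omega CH3;
        keratin_terminals: Gly C_alpha, Ser C_alpha, Ser C_beta;
        keratin_core: Leu C_beta/Lys C_epsilon plus the helical C_alpha
        region (window fixed at [58.0, 60.0] ppm so the core window stays
        clear of the terminal Ser C_alpha at 56.7 ppm and of mobile
        cholesterol C14/C17 at 57.6 ppm);
        cholesterol_mobile: the ring carbons visible only near RH = 85%.
        """
        h = window_half_width_ppm
        if group == "lipids":
            shifts = (33.4, 30.5, 23.3, 14.6)
            entries = tuple(e for s in shifts for e in self.entries
                            if e.shift_ppm == s and e.component_class == "lipid_chain")
            return SignatureSet(group, entries, h)
        if group == "keratin_terminals":
            entries = tuple(e for e in self._by_class("keratin_terminal"))
            return SignatureSet(group, entries, h)
        if group == "keratin_core":
            entries = tuple(e for e in self._by_class("keratin_core"))
            windows = []
            for e in entries:
                if "region" in e.moiety.lower():
                    windows.append((58.0, 60.0))
                else:
                    windows.append((e.shift_ppm - h, e.shift_ppm + h))
            return SignatureSet(group, entries, h, windows=tuple(windows))
        if group == "cholesterol_mobile":
            entries = tuple(e for e in self._by_class("cholesterol"))
            windows = []
            for e in entries:
                if "c24" in e.moiety.lower():
                    windows.append((40.4, 40.9))
                else:
                    windows.append((e.shift_ppm - h, e.shift_ppm + h))
            return SignatureSet(group, entries, h, windows=tuple(windows))
        raise ValueError(f"unknown signature group: {group!r}; "
                         f"expected one of {SIGNATURE_GROUPS}")


_DEFAULT: AssignmentTable | None = None


def load_default_table() -> AssignmentTable:
    """The versioned table shipped with the package (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("ptssnmr.data").joinpath("assignments_v1.csv")
        with ref.open("r", newline="") as fh:
            _DEFAULT = AssignmentTable._parse(fh)
    return _DEFAULT


# Module-level convenience wrappers over the default table.

def lookup_shift(moiety: str) -> float:
    return load_default_table().lookup_shift(moiety)


def peaks_in_window(lo_ppm: float, hi_ppm: float) -> list[AssignmentEntry]:
    return load_default_table().peaks_in_window(lo_ppm, hi_ppm)


def signature_set(group: str, window_half_width_ppm: float = 0.3) -> SignatureSet:
    return load_default_table().signature_set(group, window_half_width_ppm)
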