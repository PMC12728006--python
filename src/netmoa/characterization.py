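"""Disease and drug characterizations: effectors, motives, profiles, bioflags.

A disease is characterized at the protein level as a set of *effectors* —
proteins whose functional activation (+1) or inactivation (-1) is associated
with the disease — grouped into pathophysiological processes called *motives*
(e.g. intestinal barrier disruption, chronic Th1/Th17 inflammation, tissue
remodelling). Drugs are characterized by their target profiles (proteins the
drug activates or inhibits, plus optional pseudotargets representing blocked
interactions) and by *bioflags*: downstream proteins the literature reports
as modulated by treatment, used to corroborate model behaviour.

Gene symbols are the canonical protein key throughout; UniProt accessions are
optional metadata. All sign columns accept a small alias alphabet:
``up``/``+1``/arrows for activation, ``down``/``-1`` for inhibition, and
``none``/``0`` for "no modulation" (allowed only in treatment-modulation
columns, never as a disease sign).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence


class CharacterizationError(ValueError):
    """Malformed or inconsistent characterization input."""


# Modulation / disease-sign alphabet. The triangle and arrow glyphs mirror the
# table notation conventionally used in mechanism-of-action reports.
_SIGN_ALIASES = {
    "up": 1, "+1": 1, "1": 1, "+": 1, "↑": 1, "▲": 1,
    "down": -1, "-1": -1, "-": -1, "↓": -1, "▼": -1,
    "none": 0, "0": 0, "▬": 0, "": 0,
}

# Symbol aliases for protein ids that appear in mixed spellings in the
# literature (case, hyphens); normalized to the bare gene symbol.
SYMBOL_ALIASES = {
    "MADCAM-1": "MADCAM1",
    "MADCAM—1": "MADCAM1",
    "CADH1": "CDH1",
}


def normalize_symbol(raw: str) -> str:
    """Normalize a gene symbol: strip, uppercase, resolve known aliases."""
    sym = raw.strip().upper().replace(" ", "")
    return SYMBOL_ALIASES.get(sym, sym)


def parse_sign(raw: str | int, *, allow_zero: bool = False,
               context: str = "") -> int:
    """Map a sign token to {-1, 0, +1}.

    Zero ("no modulation") is only legal in treatment-modulation columns.
    """
    key = str(raw).strip().lower()
    if key not in _SIGN_ALIASES:
        raise CharacterizationError(
            f"unrecognized sign {raw!r}" + (f" ({context})" if context else ""))
    value = _SIGN_ALIASES[key]
    if value == 0 and not allow_zero:
        raise CharacterizationError(
            f"sign {raw!r} is zero/none, not allowed here"
            + (f" ({context})" if context else ""))
    return value


@dataclass(frozen=True)
class Protein:
    id: str
    uniprot_ac: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise CharacterizationError("protein id must be non-empty")


@dataclass(frozen=True)
class Motive:
    """A pathophysiological process grouping effectors; small positive id."""
    id: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise CharacterizationError(f"motive id must be positive: {self.id}")


@dataclass(frozen=True)
class EffectorAssignment:
    """One (protein, motive) membership with its disease activation sign."""
    protein: str
    motive: int
    disease_sign: int

    def __post_init__(self) -> None:
        if self.disease_sign not in (-1, 1):
            raise CharacterizationError(
                f"disease sign must be +1/-1 for {self.protein}/M{self.motive}")


@dataclass
class DiseaseCharacterization:
    """Effector assignments plus the motives they reference.

    A protein may appear in several motives, possibly with different signs
    (e.g. a cytokine hyperactive in inflammation but hypoactive in
    remodelling); at most one assignment exists per (protein, motive) pair.
    """
    assignments: list[EffectorAssignment] = field(default_factory=list)
    motives: dict[int, Motive] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for a in self.assignments:
            key = (a.protein, a.motive)
            if key in seen:
                raise CharacterizationError(
                    f"duplicate effector assignment {a.protein}/M{a.motive}")
            seen.add(key)
            if a.motive not in self.motives:
                self.motives[a.motive] = Motive(a.motive)

    @property
    def proteins(self) -> set[str]:
        return {a.protein for a in self.assignments}

    def motive_assignments(self, motive: int) -> list[EffectorAssignment]:
        if motive not in self.motives:
            raise CharacterizationError(f"unknown motive {motive}")
        return [a for a in self.assignments if a.motive == motive]

    def sign(self, protein: str, motive: int) -> int:
        for a in self.assignments:
            if a.protein == protein and a.motive == motive:
                return a.disease_sign
        raise KeyError((protein, motive))

    def subset(self, motives: Iterable[int]) -> "DiseaseCharacterization":
        keep = set(motives)
        return DiseaseCharacterization(
            assignments=[a for a in self.assignments if a.motive in keep],
            motives={m: mo for m, mo in self.motives.items() if m in keep})


def unique_effector_count(chars: DiseaseCharacterization) -> int:
    """Number of distinct effector proteins across all motives."""
    return len(chars.proteins)


@dataclass
class DrugProfile:
    """A drug's target profile: protein -> effect sign, plus pseudotargets.

    Pseudotargets are proteins not physically bound by the drug but clamped
    in the model to represent a blocked interaction; they behave identically
    to targets at propagation time, their special status is metadata only.
    """
    name: str
    targets: dict[str, int]
    pseudotargets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.targets:
            raise CharacterizationError(f"drug {self.name!r} has no targets")
        overlap = set(self.targets) & set(self.pseudotargets)
        if overlap:
            raise CharacterizationError(
                f"pseudotargets overlap targets for {self.name}: {sorted(overlap)}")
        for p, s in {**self.targets, **self.pseudotargets}.items():
            if s not in (-1, 1):
                raise CharacterizationError(
                    f"effect sign for {p} must be +1/-1, got {s}")

    @property
    def all_targets(self) -> dict[str, int]:
        return {**self.targets, **self.pseudotargets}


@dataclass(frozen=True)
class Bioflag:
    protein: str
    expected_sign: int

    def __post_init__(self) -> None:
        if self.expected_sign not in (-1, 1):
            raise CharacterizationError(
                f"bioflag sign must be +1/-1 for {self.protein}")


@dataclass
class ComplementaryTableRow:
    """One row of a complementary/convergent-mechanism table.

    ``modulation`` holds the per-treatment symbol in {-1 (down), +1 (up),
    0 (no modulation)} for drug A, drug B and the combination.
    """
    protein: str
    motives: list[int]
    disease_signs: list[int]
    mod_a: int
    mod_b: int
    mod_combo: int

    def __post_init__(self) -> None:
        if len(self.motives) != len(self.disease_signs):
            raise CharacterizationError(
                f"{self.protein}: {len(self.motives)} motives but "
                f"{len(self.disease_signs)} disease signs")


@dataclass
class BioflagTableRow:
    uniprot: str
    protein: str
    bioflag_sign: int
    status_single: str
    status_combo: str


# ---------------------------------------------------------------------------
# I/O

def _read_tsv(path: Path) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in fh if not r.lstrip().startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    return [dict(r) for r in reader]


def load_characterization(path: str | Path,
                          format: str = "tsv") -> DiseaseCharacterization:
    """Read a disease characterization.

    TSV columns: ``protein  motive  disease_sign``, one row per
    (protein, motive). JSON: list of objects with the same keys.
    """
    path = Path(path)
    if format == "tsv":
        if path.stat().st_size == 0:
            return DiseaseCharacterization()
        raw = _read_tsv(path)
    elif format == "json":
        raw = json.loads(path.read_text() or "[]")
    else:
        raise CharacterizationError(f"unknown format {format!r}")
    assignments = []
    for i, row in enumerate(raw, start=1):
        try:
            assignments.append(EffectorAssignment(
                protein=normalize_symbol(row["protein"]),
                motive=int(row["motive"]),
                disease_sign=parse_sign(row["disease_sign"],
                                        context=f"row {i}")))
        except (KeyError, TypeError) as exc:
            raise CharacterizationError(f"row {i}: missing field {exc}") from exc
    return DiseaseCharacterization(assignments=assignments)


def save_characterization(chars: DiseaseCharacterization, path: str | Path,
                          format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("protein\tmotive\tdisease_sign\n")
            for a in chars.assignments:
                fh.write(f"{a.protein}\t{a.motive}\t{a.disease_sign}\n")
    elif format == "json":
        path.write_text(json.dumps(
            [{"protein": a.protein, "motive": a.motive,
              "disease_sign": a.disease_sign} for a in chars.assignments],
            indent=1))
    else:
        raise CharacterizationError(f"unknown format {format!r}")


def load_drug_profile(path: str | Path, format: str = "tsv",
                      name: str | None = None) -> DrugProfile:
    """Read a drug profile TSV (``protein  effect_sign  is_pseudotarget``)."""
    path = Path(path)
    if format == "tsv":
        raw = _read_tsv(path)
    elif format == "json":
        raw = json.loads(path.read_text())
    else:
        raise CharacterizationError(f"unknown format {format!r}")
    targets: dict[str, int] = {}
    pseudo: dict[str, int] = {}
    for i, row in enumerate(raw, start=1):
        protein = normalize_symbol(row["protein"])
        sign = parse_sign(row["effect_sign"], context=f"row {i}")
        is_pseudo = str(row.get("is_pseudotarget", "false")).strip().lower() \
            in ("true", "1", "yes")
        (pseudo if is_pseudo else targets)[protein] = sign
    return DrugProfile(name=name or path.stem, targets=targets,
                       pseudotargets=pseudo)


def save_drug_profile(profile: DrugProfile, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein\teffect_sign\tis_pseudotarget\n")
        for p, s in profile.targets.items():
            fh.write(f"{p}\t{s}\tfalse\n")
        for p, s in profile.pseudotargets.items():
            fh.write(f"{p}\t{s}\ttrue\n")


def load_bioflags(path: str | Path) -> list[Bioflag]:
    """Read bioflags from a TSV with ``protein`` and a sign column."""
    seen: dict[str, Bioflag] = {}
    for i, row in enumerate(_read_tsv(Path(path)), start=1):
        protein = normalize_symbol(row["protein"])
        if protein in seen:
            raise CharacterizationError(f"duplicate bioflag {protein} (row {i})")
        sign_col = row.get("bioflag_sign", row.get("expected_sign", ""))
        seen[protein] = Bioflag(protein, parse_sign(sign_col, context=f"row {i}"))
    return list(seen.values())


def load_complementary_table(path: str | Path) -> list[ComplementaryTableRow]:
    """Read a Table-1/2 dialect fixture.

    Columns: ``protein  motives(;list)  disease_signs(;list)  mod_a  mod_b
    mod_combo``.
    """
    rows = []
    for i, row in enumerate(_read_tsv(Path(path)), start=1):
        motives = [int(m) for m in row["motives"].split(";")]
        signs = [parse_sign(s, context=f"row {i}")
                 for s in row["disease_signs"].split(";")]
        rows.append(ComplementaryTableRow(
            protein=normalize_symbol(row["protein"]),
            motives=motives, disease_signs=signs,
            mod_a=parse_sign(row["mod_a"], allow_zero=True, context=f"row {i}"),
            mod_b=parse_sign(row["mod_b"], allow_zero=True, context=f"row {i}"),
            mod_combo=parse_sign(row["mod_combo"], allow_zero=True,
                                 context=f"row {i}")))
    return rows


def save_complementary_table(rows: Sequence[ComplementaryTableRow],
                             path: str | Path) -> None:
    """Write rows in the Table-1/2 fixture dialect."""
    sym = {1: "up", -1: "down", 0: "none"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein\tmotives\tdisease_signs\tmod_a\tmod_b\tmod_combo\n")
        for r in rows:
            fh.write("\t".join([
                r.protein,
                ";".join(str(m) for m in r.motives),
                ";".join(sym[s] for s in r.disease_signs),
                sym[r.mod_a], sym[r.mod_b], sym[r.mod_combo]]) + "\n")


def load_bioflag_table(path: str | Path) -> list[BioflagTableRow]:
    """Read a bioflag corroboration fixture (Table-3A dialect)."""
    valid = {"corroborated", "antagonised", "blank", "below_threshold"}
    rows = []
    for i, row in enumerate(_read_tsv(Path(path)), start=1):
        for col in ("status_single", "status_combo"):
            if row[col] not in valid:
                raise CharacterizationError(
                    f"row {i}: bad status {row[col]!r} in {col}")
        rows.append(BioflagTableRow(
            uniprot=row["uniprot"].strip(),
            protein=normalize_symbol(row["protein"]),
            bioflag_sign=parse_sign(row["bioflag_sign"], context=f"row {i}"),
            status_single=row["status_single"],
            status_combo=row["status_combo"]))
    return rows


def characterization_from_table(
        rows: Sequence[ComplementaryTableRow]) -> DiseaseCharacterization:
    """Build a disease characterization from complementary-table rows."""
    assignments = [
        EffectorAssignment(r.protein, m, s)
        for r in rows for m, s in zip(r.motives, r.disease_signs)]
    return DiseaseCharacterization(assignments=assignments)


def fixture_path(name: str) -> Path:
    """Path to a packaged fixture TSV by basename (without extension)."""
    ref = resources.files("netmoa.fixtures") / f"{name}.tsv"
    return Path(str(ref))


def load_fixture_tables() -> dict[str, object]:
    """Load all packaged table fixtures into one dict."""
    return {
        "complementary": load_complementary_table(
            fixture_path("table1_complementary")),
        "convergent": load_complementary_table(fixture_path("table2_convergent")),
        "bioflags_a": load_bioflag_table(fixture_path("table3a_bioflags_vdz")),
        "profile_a": load_drug_profile(fixture_path("profile_vdz"), name="VDZ"),
        "profile_b": load_drug_profile(fixture_path("profile_jaki"), name="JAKi"),
    }
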