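"""Domain types, TSV readers/writers, and packaged compound-table fixtures.

The central container is :class:`CompoundLibrary`, an ordered, id-unique
collection of :class:`CompoundRecord`. Two fixtures ship with the package:

``table1``
    The 66 candidate compounds (M001-M066) of the modified seven-herb
    Yimusake formula with their predicted oral-bioavailability (OB, %) and
    drug-likeness (DL) scores and herb attributions.
``table3``
    The 37 compounds of the three animal drugs (Moschus S01-S21,
    Ambra Grisea L01-L09, Bullwhip N01-N07); OB/DL are unknown and stored
    as missing, never as zero.

Compound tables are TSV with header ``id, name, ob, dl, herbs, rescued``
plus an optional ``descriptors`` column (semicolon-separated numbers).
The ``herbs`` cell is a comma-separated list; a compound attributed to
several herbs occupies a single row with a multi-element herb set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import pandas as pd

__all__ = [
    "CompoundRecord",
    "CompoundLibrary",
    "FormulaDefinition",
    "TargetAnnotation",
    "SchemaError",
    "ValidationError",
    "read_compound_table",
    "write_compound_table",
    "load_fixture",
    "read_annotation_table",
    "write_annotation_table",
]

HERB_DELIMITER = ","
DESCRIPTOR_DELIMITER = ";"
FIXTURE_NAMES = ("table1", "table3")


class SchemaError(ValueError):
    """A required column is missing or cannot be parsed."""


class ValidationError(ValueError):
    """A record or table violates a domain invariant."""


@dataclass(frozen=True)
class CompoundRecord:
    """One screened molecule.

    ``ob`` (oral bioavailability, percent of an oral dose reaching systemic
    circulation) and ``dl`` (drug-likeness, Tanimoto similarity to the mean
    descriptor vector of known drugs) may be ``None`` when unknown, as for
    the animal-drug compounds whose scores were never predicted.
    ``rescued`` marks literature-justified retention despite filter failure.
    """

    compound_id: str
    name: str
    ob: Optional[float] = None
    dl: Optional[float] = None
    herbs: frozenset[str] = field(default_factory=frozenset)
    rescued: bool = False
    descriptors: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        if not self.herbs:
            raise ValidationError(
                f"compound {self.compound_id!r}: herb set must be non-empty"
            )
        if self.ob is not None and not (0.0 <= self.ob <= 100.0):
            raise ValidationError(
                f"compound {self.compound_id!r}: ob={self.ob} outside [0, 100]"
            )
        if self.dl is not None and not (0.0 <= self.dl <= 1.0):
            raise ValidationError(
                f"compound {self.compound_id!r}: dl={self.dl} outside [0, 1]"
            )
        if self.descriptors is not None and any(d < 0 for d in self.descriptors):
            raise ValidationError(
                f"compound {self.compound_id!r}: descriptors must be non-negative"
            )

    @property
    def has_scores(self) -> bool:
        return self.ob is not None and self.dl is not None


class CompoundLibrary:
    """Ordered collection of compound records with unique ids."""

    def __init__(self, records: Iterable[CompoundRecord] = ()) -> None:
        self._records: dict[str, CompoundRecord] = {}
        for rec in records:
            if rec.compound_id in self._records:
                raise ValidationError(f"duplicate compound id {rec.compound_id!r}")
            self._records[rec.compound_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self._records.values())

    def __contains__(self, compound_id: object) -> bool:
        return compound_id in self._records

    def __getitem__(self, compound_id: str) -> CompoundRecord:
        return self._records[compound_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompoundLibrary):
            return NotImplemented
        return list(self) == list(other)

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def herbs(self) -> set[str]:
        """All herb names attributed to at least one compound."""
        out: set[str] = set()
        for rec in self:
            out |= rec.herbs
        return out

    def by_herb(self, herb: str) -> list[CompoundRecord]:
        """Compounds attributed to *herb* (deduplicated by construction)."""
        return [rec for rec in self if herb in rec.herbs]

    def subset(self, compound_ids: Iterable[str]) -> "CompoundLibrary":
        wanted = set(compound_ids)
        missing = wanted - set(self._records)
        if missing:
            raise ValidationError(f"unknown compound ids: {sorted(missing)}")
        return CompoundLibrary(rec for rec in self if rec.compound_id in wanted)


@dataclass(frozen=True)
class FormulaDefinition:
    """A named formula: herb/component name -> set of compound ids."""

    formula_id: str
    components: Mapping[str, frozenset[str]]

    def validate_against(self, library: CompoundLibrary) -> None:
        for component, ids in self.components.items():
            missing = set(ids) - set(library.ids)
            if missing:
                raise ValidationError(
                    f"formula {self.formula_id!r}, component {component!r}: "
                    f"unknown compound ids {sorted(missing)}"
                )

    def all_compound_ids(self) -> set[str]:
        out: set[str] = set()
        for ids in self.components.values():
            out |= set(ids)
        return out


@dataclass(frozen=True)
class TargetAnnotation:
    """Disease-association flag and pathway memberships for one target."""

    target_id: str
    gene_name: Optional[str] = None
    disease_associated: Optional[bool] = None
    pathways: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.target_id:
            raise ValidationError("target_id must be non-empty")


_DEFAULT_DIALECT = {
    "id": "id",
    "name": "name",
    "ob": "ob",
    "dl": "dl",
    "herbs": "herbs",
    "rescued": "rescued",
    "descriptors": "descriptors",
}


def _parse_score(value: object, column: str, row: int) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise SchemaError(
            f"row {row}: non-numeric {column} value {text!r}"
        ) from exc


def read_compound_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> CompoundLibrary:
    """Read a compound TSV into a :class:`CompoundLibrary`.

    *dialect* maps the canonical field names (``id``, ``name``, ``ob``,
    ``dl``, ``herbs``, optionally ``rescued`` and ``descriptors``) to the
    file's column names. Row order is preserved; duplicate ids are rejected.
    """
    columns = dict(_DEFAULT_DIALECT)
    if dialect:
        columns.update(dialect)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for key in ("id", "name", "ob", "dl", "herbs"):
        if columns[key] not in frame.columns:
            raise SchemaError(f"missing required column {columns[key]!r}")

    records = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        row_map = dict(zip(frame.columns, row))
        herbs = frozenset(
            h.strip()
            for h in str(row_map[columns["herbs"]]).split(HERB_DELIMITER)
            if h.strip()
        )
        rescued = False
        if columns["rescued"] in frame.columns:
            rescued = str(row_map[columns["rescued"]]).strip() in {"1", "true", "True"}
        descriptors = None
        if columns["descriptors"] in frame.columns:
            cell = str(row_map[columns["descriptors"]]).strip()
            if cell:
                descriptors = tuple(
                    float(x) for x in cell.split(DESCRIPTOR_DELIMITER)
                )
        records.append(
            CompoundRecord(
                compound_id=str(row_map[columns["id"]]).strip(),
                name=str(row_map[columns["name"]]).strip(),
                ob=_parse_score(row_map[columns["ob"]], "ob", row_number),
                dl=_parse_score(row_map[columns["dl"]], "dl", row_number),
                herbs=herbs,
                rescued=rescued,
                descriptors=descriptors,
            )
        )
    return CompoundLibrary(records)


def write_compound_table(library: CompoundLibrary, path: str | Path) -> Path:
    """Write *library* as TSV so that reading it back is the identity."""
    rows = []
    any_descriptors = any(rec.descriptors is not None for rec in library)
    for rec in library:
        row = {
            "id": rec.compound_id,
            "name": rec.name,
            "ob": "" if rec.ob is None else format(rec.ob, "g"),
            "dl": "" if rec.dl is None else format(rec.dl, "g"),
            "herbs": HERB_DELIMITER.join(sorted(rec.herbs)),
            "rescued": int(rec.rescued),
        }
        if any_descriptors:
            row["descriptors"] = (
                ""
                if rec.descriptors is None
                else DESCRIPTOR_DELIMITER.join(format(d, "g") for d in rec.descriptors)
            )
        rows.append(row)
    columns = ["id", "name", "ob", "dl", "herbs", "rescued"]
    if any_descriptors:
        columns.append("descriptors")
    frame = pd.DataFrame(rows, columns=columns)
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path


def load_fixture(name: str) -> CompoundLibrary:
    """Load a packaged fixture, ``"table1"`` (66 records) or ``"table3"`` (37)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    source = resources.files("formulanet.data").joinpath(f"{name}.tsv")
    with resources.as_file(source) as path:
        return read_compound_table(path)


def default_whitelist() -> frozenset[str]:
    """Rescue list shipped with the ``table1`` fixture: the compounds whose
    retention rests on reported pharmacological activity rather than on the
    OB/DL thresholds."""
    return frozenset(
        rec.compound_id for rec in load_fixture("table1") if rec.rescued
    )


def read_annotation_table(path: str | Path) -> dict[str, TargetAnnotation]:
    """Read a target-annotation TSV (``target``, optional ``gene_name``,
    ``disease_associated`` in {0,1,unknown/blank}, ``pathways`` comma list)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "target" not in frame.columns:
        raise SchemaError("missing required column 'target'")
    out: dict[str, TargetAnnotation] = {}
    for row in frame.itertuples(index=False):
        row_map = dict(zip(frame.columns, row))
        target_id = str(row_map["target"]).strip()
        if target_id in out:
            raise ValidationError(f"duplicate target id {target_id!r}")
        flag_text = str(row_map.get("disease_associated", "")).strip().lower()
        if flag_text in {"", "unknown", "na"}:
            flag: Optional[bool] = None
        else:
            flag = flag_text in {"1", "true", "yes"}
        pathways = frozenset(
            p.strip()
            for p in str(row_map.get("pathways", "")).split(",")
            if p.strip()
        )
        gene = str(row_map.get("gene_name", "")).strip() or None
        out[target_id] = TargetAnnotation(
            target_id=target_id,
            gene_name=gene,
            disease_associated=flag,
            pathways=pathways,
        )
    return out


def write_annotation_table(
    annotations: Mapping[str, TargetAnnotation], path: str | Path
) -> Path:
    rows = []
    for ann in annotations.values():
        if ann.disease_associated is None:
            flag = "unknown"
        else:
            flag = int(ann.disease_associated)
        rows.append(
            {
                "target": ann.target_id,
                "gene_name": ann.gene_name or "",
                "disease_associated": flag,
                "pathways": ",".join(sorted(ann.pathways)),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["target", "gene_name", "disease_associated", "pathways"]
    )
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path
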