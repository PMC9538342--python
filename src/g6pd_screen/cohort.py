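"""Cohort containers and I/O for NBS-positive infant records.

The central object is :class:`CohortTable`, a validated list of
:class:`InfantRecord`.  Each record holds the two confirmatory assay
results used in Chinese newborn-screening follow-up of G6PD deficiency —
the G6PD/6PGD activity ratio and the 12-variant targeted genotyping
panel — plus the Sanger sequencing result used as the gold standard for
panel-negative infants.

A packaged 555-record reference cohort (437 males, 118 females) is
reconstructed deterministically from published stratum counts; the nine
panel-negative, sequencing-positive infants carry their individually
reported activity ratios and variants.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Sex",
    "Zygosity",
    "CarrierStatus",
    "VariantCall",
    "PanelDefinition",
    "DEFAULT_PANEL",
    "InfantRecord",
    "CohortTable",
    "Stratum",
    "StratumTable",
    "CohortValidationError",
    "load_cohort",
    "write_cohort",
    "expand_strata",
    "tabulate_strata",
    "reference_strata",
    "reference_cohort",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Zygosity(str, Enum):
    HEMIZYGOUS = "hemizygous"
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"


class CarrierStatus(str, Enum):
    CARRIER = "carrier"
    NON_CARRIER = "non_carrier"


class CohortValidationError(ValueError):
    """Raised when a record or cohort violates a domain invariant."""


@dataclass(frozen=True, order=True)
class VariantCall:
    """A single G6PD variant observed by an assay, with zygosity."""

    cdna: str
    zygosity: Zygosity


@dataclass(frozen=True)
class PanelDefinition:
    """The set of cDNA variants a targeted genotyping kit can detect.

    The default panel is the 12 common Chinese G6PD variants targeted by
    the approved melting-curve genotyping kit.
    """

    variants: tuple[tuple[str, str], ...]  # (cDNA name, allele name)

    def __post_init__(self) -> None:
        names = [cdna for cdna, _ in self.variants]
        if len(set(names)) != len(names):
            raise CohortValidationError("panel cDNA names must be unique")

    @property
    def cdna_names(self) -> frozenset[str]:
        return frozenset(cdna for cdna, _ in self.variants)

    def __contains__(self, cdna: str) -> bool:
        return cdna in self.cdna_names


#: The 12-variant targeted panel used throughout.
DEFAULT_PANEL = PanelDefinition(
    variants=(
        ("c.95A>G", "Gaohe"),
        ("c.383T>C", "Vanua Lava"),
        ("c.392G>T", "Quing Yan"),
        ("c.487G>A", "Mahidol"),
        ("c.517T>C", "Nankang"),
        ("c.592C>T", "Coimbra"),
        ("c.871G>A", "Viangchan"),
        ("c.1004C>A", "Fushan"),
        ("c.1024C>T", "Chinese-5"),
        ("c.1360C>T", "Maewo"),
        ("c.1376G>T", "Canton"),
        ("c.1388G>A", "Kaiping"),
    )
)


def _check_zygosity(sex: Sex, calls: Iterable[VariantCall], where: str) -> None:
    for call in calls:
        if sex is Sex.MALE and call.zygosity is not Zygosity.HEMIZYGOUS:
            raise CohortValidationError(
                f"{where}: males carry X-linked variants hemizygously, got "
                f"{call.zygosity.value} {call.cdna}"
            )
        if sex is Sex.FEMALE and call.zygosity is Zygosity.HEMIZYGOUS:
            raise CohortValidationError(
                f"{where}: females cannot be hemizygous ({call.cdna})"
            )


@dataclass(frozen=True)
class InfantRecord:
    """One NBS-positive infant and its confirmatory test results.

    ``panel_result`` is the targeted-genotyping outcome: an empty tuple
    means no target variant detected (negative).  ``sanger_result`` is
    ``None`` when sequencing was not done, an empty tuple when it was
    done and negative, and a tuple of calls when positive.
    """

    id: str
    sex: Sex
    activity_ratio: float
    panel_result: tuple[VariantCall, ...] = ()
    sanger_result: tuple[VariantCall, ...] | None = None
    age_days: int | None = None
    panel: PanelDefinition = field(default=DEFAULT_PANEL, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.activity_ratio < 0:
            raise CohortValidationError(
                f"record {self.id}: activity ratio must be >= 0, "
                f"got {self.activity_ratio}"
            )
        if self.age_days is not None and self.age_days < 0:
            raise CohortValidationError(f"record {self.id}: negative age_days")
        _check_zygosity(self.sex, self.panel_result, f"record {self.id}")
        if self.sanger_result is not None:
            _check_zygosity(self.sex, self.sanger_result, f"record {self.id}")
        for call in self.panel_result:
            if call.cdna not in self.panel:
                raise CohortValidationError(
                    f"record {self.id}: panel result {call.cdna} is not a "
                    f"member of the targeted panel"
                )

    @property
    def panel_positive(self) -> bool:
        return len(self.panel_result) > 0

    @property
    def sanger_done(self) -> bool:
        return self.sanger_result is not None

    @property
    def sanger_positive(self) -> bool:
        return self.sanger_result is not None and len(self.sanger_result) > 0


@dataclass(frozen=True)
class CohortTable:
    """An immutable, id-unique collection of infant records."""

    records: tuple[InfantRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate record ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, predicate) -> "CohortTable":
        return CohortTable(
            records=tuple(r for r in self.records if predicate(r)),
            provenance=self.provenance,
        )

    def count_by_sex(self) -> dict[Sex, int]:
        out = {Sex.MALE: 0, Sex.FEMALE: 0}
        for r in self.records:
            out[r.sex] += 1
        return out


# ---------------------------------------------------------------------------
# Stratum tables


@dataclass(frozen=True)
class Stratum:
    """A (sex, panel, activity, Sanger) cell with a count.

    ``variants``/``ratios``/``ages`` may be empty (defaults apply), hold a
    single value shared by every record, or hold exactly ``count`` values.
    """

    sex: Sex
    panel_status: str  # "positive" | "negative"
    activity_status: str  # "deficient" | "normal"
    sanger_status: str  # "positive" | "negative" | "not_done"
    count: int
    zygosity: Zygosity | None = None
    variants: tuple[str, ...] = ()
    ratios: tuple[float, ...] = ()
    ages: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.count < 0:
            raise CohortValidationError("stratum count must be nonnegative")
        for name, values in (
            ("variants", self.variants),
            ("ratios", self.ratios),
            ("ages", self.ages),
        ):
            if len(values) not in (0, 1, self.count):
                raise CohortValidationError(
                    f"stratum {name} must have 0, 1 or count={self.count} "
                    f"entries, got {len(values)}"
                )
        if self.panel_status not in ("positive", "negative"):
            raise CohortValidationError(f"bad panel_status {self.panel_status!r}")
        if self.activity_status not in ("deficient", "normal"):
            raise CohortValidationError(
                f"bad activity_status {self.activity_status!r}"
            )
        if self.sanger_status not in ("positive", "negative", "not_done"):
            raise CohortValidationError(f"bad sanger_status {self.sanger_status!r}")


@dataclass(frozen=True)
class StratumTable:
    rows: tuple[Stratum, ...]

    def total(self) -> int:
        return sum(s.count for s in self.rows)


# Representative in-range activity ratios for strata that do not carry
# individually reported values.  Only the deficient/normal side of the 1.0
# cutoff matters downstream; the values themselves are inert.
REPRESENTATIVE_RATIO = {"deficient": 0.30, "normal": 1.30}

_SEX_PREFIX = {Sex.MALE: "M", Sex.FEMALE: "F"}


def _per_record(values: Sequence, i: int, default):
    if len(values) == 0:
        return default
    if len(values) == 1:
        return values[0]
    return values[i]


def expand_strata(
    strata: StratumTable, panel: PanelDefinition = DEFAULT_PANEL
) -> CohortTable:
    """Realize a stratum table as one record per counted infant.

    Ids are deterministic (``{sex letter}{stratum index}-{running index}``)
    so repeated expansion is byte-identical.
    """
    records: list[InfantRecord] = []
    for si, s in enumerate(strata.rows, start=1):
        default_ratio = REPRESENTATIVE_RATIO[s.activity_status]
        default_zyg = s.zygosity or (
            Zygosity.HEMIZYGOUS if s.sex is Sex.MALE else Zygosity.HETEROZYGOUS
        )
        for i in range(s.count):
            variant = _per_record(s.variants, i, None)
            calls: tuple[VariantCall, ...] = ()
            if variant is not None:
                calls = (VariantCall(variant, default_zyg),)
            panel_result: tuple[VariantCall, ...] = ()
            sanger_result: tuple[VariantCall, ...] | None
            if s.panel_status == "positive":
                if variant is None:
                    raise CohortValidationError(
                        f"stratum {si}: panel-positive stratum needs a variant"
                    )
                panel_result = calls
            if s.sanger_status == "not_done":
                sanger_result = None
            elif s.sanger_status == "negative":
                sanger_result = ()
            else:
                if variant is None:
                    raise CohortValidationError(
                        f"stratum {si}: Sanger-positive stratum needs a variant"
                    )
                sanger_result = calls
            records.append(
                InfantRecord(
                    id=f"{_SEX_PREFIX[s.sex]}{si}-{i + 1:03d}",
                    sex=s.sex,
                    activity_ratio=float(_per_record(s.ratios, i, default_ratio)),
                    panel_result=panel_result,
                    sanger_result=sanger_result,
                    age_days=_per_record(s.ages, i, None),
                    panel=panel,
                )
            )
    return CohortTable(records=tuple(records), provenance="expanded from strata")


def tabulate_strata(cohort: CohortTable, cutoff: float = 1.0) -> dict:
    """Collapse a cohort back to (sex, panel, activity, Sanger) cell counts."""
    out: dict[tuple, int] = {}
    for r in cohort:
        if r.sanger_result is None:
            sanger = "not_done"
        elif r.sanger_positive:
            sanger = "positive"
        else:
            sanger = "negative"
        key = (
            r.sex,
            "positive" if r.panel_positive else "negative",
            "deficient" if r.activity_ratio < cutoff else "normal",
            sanger,
        )
        out[key] = out.get(key, 0) + 1
    return out


# ---------------------------------------------------------------------------
# Cohort CSV dialect

_COLUMNS = ["id", "sex", "age_days", "activity_ratio", "panel_result", "sanger_result"]


def _format_calls(calls: tuple[VariantCall, ...]) -> str:
    return ";".join(f"{c.cdna}:{c.zygosity.value}" for c in calls)


def _parse_calls(cell: str, where: str) -> tuple[VariantCall, ...]:
    calls = []
    for part in cell.split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            raise CohortValidationError(
                f"{where}: variant cell {part!r} must be 'cDNA:zygosity'"
            )
        cdna, zyg = part.rsplit(":", 1)
        try:
            calls.append(VariantCall(cdna.strip(), Zygosity(zyg.strip())))
        except ValueError as exc:
            raise CohortValidationError(f"{where}: unknown zygosity {zyg!r}") from exc
    return tuple(calls)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort in the package's delimited-text dialect.

    Empty ``panel_result`` means panel-negative; empty ``sanger_result``
    means sequencing not done, the literal ``negative`` means sequenced
    and negative.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for r in cohort:
            if r.sanger_result is None:
                sanger = ""
            elif len(r.sanger_result) == 0:
                sanger = "negative"
            else:
                sanger = _format_calls(r.sanger_result)
            writer.writerow(
                [
                    r.id,
                    r.sex.value,
                    "" if r.age_days is None else r.age_days,
                    repr(r.activity_ratio),
                    _format_calls(r.panel_result),
                    sanger,
                ]
            )


def load_cohort(
    path: str | Path, panel: PanelDefinition = DEFAULT_PANEL
) -> CohortTable:
    """Load and validate a cohort CSV, reporting errors with row numbers."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _COLUMNS if c not in header]
        if missing:
            raise CohortValidationError(f"{path}: missing required columns {missing}")
        records = []
        for rownum, row in enumerate(reader, start=2):
            where = f"{path.name} row {rownum}"
            try:
                sex = Sex(row["sex"].strip().lower())
            except ValueError:
                raise CohortValidationError(
                    f"{where}: unknown sex token {row['sex']!r}"
                ) from None
            panel_cell = row["panel_result"].strip()
            panel_calls = (
                ()
                if panel_cell.lower() in ("", "negative")
                else _parse_calls(panel_cell, where)
            )
            sanger_cell = row["sanger_result"].strip()
            if sanger_cell == "":
                sanger_calls: tuple[VariantCall, ...] | None = None
            elif sanger_cell.lower() in ("negative", "not_detected"):
                sanger_calls = ()
            else:
                sanger_calls = _parse_calls(sanger_cell, where)
            age_cell = row["age_days"].strip()
            try:
                record = InfantRecord(
                    id=row["id"].strip(),
                    sex=sex,
                    activity_ratio=float(row["activity_ratio"]),
                    panel_result=panel_calls,
                    sanger_result=sanger_calls,
                    age_days=int(age_cell) if age_cell else None,
                    panel=panel,
                )
            except CohortValidationError as exc:
                raise CohortValidationError(f"{where}: {exc}") from None
            records.append(record)
    return CohortTable(records=tuple(records), provenance=str(path))


# ---------------------------------------------------------------------------
# Packaged reference cohort


def _read_packaged_csv(name: str) -> list[dict]:
    text = resources.files("g6pd_screen.data").joinpath(name).read_text("utf-8")
    return list(csv.DictReader(io.StringIO(text)))


def reference_strata() -> StratumTable:
    """The published stratum counts of the 555-infant reference cohort."""
    rows = []
    for row in _read_packaged_csv("reference_strata.csv"):
        rows.append(
            Stratum(
                sex=Sex(row["sex"]),
                panel_status=row["panel_status"],
                activity_status=row["activity_status"],
                sanger_status=row["sanger_status"],
                count=int(row["count"]),
                zygosity=Zygosity(row["zygosity"]) if row["zygosity"] else None,
                variants=tuple(v for v in row["variants"].split(";") if v),
                ratios=tuple(float(v) for v in row["ratios"].split(";") if v),
                ages=tuple(int(v) for v in row["ages"].split(";") if v),
            )
        )
    return StratumTable(rows=tuple(rows))


def reference_cohort() -> CohortTable:
    """The packaged 555-record NBS-positive reference cohort.

    Reconstructed deterministically from published stratum counts: 437
    males (413 panel-positive deficient, 1 panel-positive with normal
    activity, 7 panel-negative deficient resolved by sequencing, 16
    non-carriers) and 118 females (58 panel-positive deficient, 36
    panel-positive heterozygotes with normal activity, 2 panel-negative
    deficient resolved by sequencing, 22 non-carriers).
    """
    cohort = expand_strata(reference_strata())
    return replace(cohort, provenance="packaged 555-infant reference cohort")
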