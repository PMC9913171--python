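"""Domain types for blastoid B-cell neoplasm case records.

A :class:`CaseRecord` captures one patient specimen: the flow-cytometry
immunophenotype expressed relative to internal reference populations
(granulocytes for CD45 intensity, hematogones for CD10/CD38, mature B cells
for CD20), immunohistochemistry percent-positive values, genetic flags
(FISH rearrangements, karyotype complexity, mutations), specimen site and
lymphoma history.

Missingness is first-class throughout: enum fields carry an explicit
``unknown`` token and numeric/boolean fields use ``None``.  Marker panels in
practice are incomplete in different ways per case, so per-marker
denominators differ and "unknown" must never be silently coerced to
negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterator, Optional

UNKNOWN = "unknown"

# Allowed tokens per enum-valued field (exclusive of "unknown", valid everywhere).
ENUM_VALUES: dict[str, frozenset[str]] = {
    "cd45_vs_granulocytes": frozenset({"greater", "not_greater"}),
    "cd10_level": frozenset({"bright_ge_hematogones", "not_bright", "negative"}),
    "cd20_vs_mature_b": frozenset({"ge", "lt"}),
    "cd38_level": frozenset({"bright_approx_hematogones", "not_bright"}),
    "tdt_flow": frozenset({"positive", "negative"}),
    "cd34": frozenset({"positive", "negative"}),
    "surface_light_chain": frozenset({"monotypic", "absent"}),
    "myeloid_markers": frozenset({"positive", "negative"}),
    "tdt_ihc": frozenset({"positive", "negative"}),
    "cyclin_d1": frozenset({"positive", "negative"}),
    "group_truth": frozenset({"HGBL", "BALL"}),
    "site": frozenset({"bone_marrow", "extramedullary"}),
}

PERCENT_FIELDS = ("myc_pct", "bcl6_pct", "bcl2_pct", "ki67_pct")
BOOL_FIELDS = (
    "history_nhl",
    "myc_r",
    "bcl2_r",
    "bcl6_r",
    "ccnd1_r",
    "complex_karyotype",
    "ball_translocation",
    "tp53_mut",
    "kras_mut",
    "nras_mut",
)

#: Exact column order of the cohort exchange format (CSV header / JSON keys).
COHORT_COLUMNS = [
    "case_id",
    "group_truth",
    "site",
    "history_nhl",
    "cd45_vs_granulocytes",
    "cd10_level",
    "cd20_vs_mature_b",
    "cd38_level",
    "tdt_flow",
    "cd34",
    "surface_light_chain",
    "myeloid_markers",
    "myc_pct",
    "bcl6_pct",
    "bcl2_pct",
    "tdt_ihc",
    "cyclin_d1",
    "ki67_pct",
    "myc_r",
    "bcl2_r",
    "bcl6_r",
    "ccnd1_r",
    "complex_karyotype",
    "ball_translocation",
    "tp53_mut",
    "kras_mut",
    "nras_mut",
]


class CohortValidationError(ValueError):
    """Raised when a cohort file or record violates the exchange contract."""


def _check_enum(name: str, value: str) -> str:
    if value == UNKNOWN:
        return value
    if value not in ENUM_VALUES[name]:
        raise CohortValidationError(
            f"invalid value {value!r} for field {name!r}; "
            f"expected one of {sorted(ENUM_VALUES[name]) + [UNKNOWN]}"
        )
    return value


def _check_pct(name: str, value: Optional[float]) -> Optional[float]:
    if value is None:
        return None
    value = float(value)
    if not 0.0 <= value <= 100.0:
        raise CohortValidationError(
            f"percent field {name!r} out of range [0, 100]: {value}"
        )
    return value


@dataclass
class FlowProfile:
    """Flow-cytometry calls relative to internal reference populations."""

    cd45_vs_granulocytes: str = UNKNOWN
    cd10_level: str = UNKNOWN
    cd20_vs_mature_b: str = UNKNOWN
    cd38_level: str = UNKNOWN
    tdt_flow: str = UNKNOWN
    cd34: str = UNKNOWN
    surface_light_chain: str = UNKNOWN
    myeloid_markers: str = UNKNOWN

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            setattr(self, f.name, _check_enum(f.name, getattr(self, f.name)))


@dataclass
class IhcProfile:
    """Immunohistochemistry percent-positive values and binary calls.

    Positivity cutoffs applied downstream are >=30% for BCL6, >=40% for MYC
    and >=50% for BCL2.  TdT by IHC is recorded as a binary call: any
    reported positivity counts as positive (the extent of staining in
    lymphoma cells is often partial and no percent cutoff is applied).
    """

    myc_pct: Optional[float] = None
    bcl6_pct: Optional[float] = None
    bcl2_pct: Optional[float] = None
    tdt_ihc: str = UNKNOWN
    cyclin_d1: str = UNKNOWN
    ki67_pct: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("myc_pct", "bcl6_pct", "bcl2_pct", "ki67_pct"):
            setattr(self, name, _check_pct(name, getattr(self, name)))
        self.tdt_ihc = _check_enum("tdt_ihc", self.tdt_ihc)
        self.cyclin_d1 = _check_enum("cyclin_d1", self.cyclin_d1)


@dataclass
class GeneticProfile:
    """Tri-state genetic flags: True / False / None (= not assessed).

    ``complex_karyotype`` means >=3 numerical and structural abnormalities;
    ``ball_translocation`` means any B-ALL-associated translocation
    (BCR::ABL1, KMT2A/MLL rearrangement, or TCF3/E2A rearrangement).
    """

    myc_r: Optional[bool] = None
    bcl2_r: Optional[bool] = None
    bcl6_r: Optional[bool] = None
    ccnd1_r: Optional[bool] = None
    complex_karyotype: Optional[bool] = None
    ball_translocation: Optional[bool] = None
    tp53_mut: Optional[bool] = None
    kras_mut: Optional[bool] = None
    nras_mut: Optional[bool] = None


@dataclass
class CaseRecord:
    """One patient specimen with immunophenotypic and genetic findings."""

    case_id: str
    group_truth: str = UNKNOWN
    site: str = UNKNOWN
    history_nhl: Optional[bool] = None
    flow: FlowProfile = field(default_factory=FlowProfile)
    ihc: IhcProfile = field(default_factory=IhcProfile)
    genetics: GeneticProfile = field(default_factory=GeneticProfile)

    def __post_init__(self) -> None:
        if not self.case_id:
            raise CohortValidationError("case_id must be a non-empty string")
        self.group_truth = _check_enum("group_truth", self.group_truth)
        self.site = _check_enum("site", self.site)

    def consolidated_tdt(self) -> str:
        """TdT call pooled across modalities: flow if known, else IHC.

        Flow and IHC TdT agree in the large majority of dual-tested cases;
        where they disagree (typically weak partial IHC positivity with
        negative flow) the flow call wins.
        """
        if self.flow.tdt_flow != UNKNOWN:
            return self.flow.tdt_flow
        return self.ihc.tdt_ihc

    def tdt_modality_discordant(self) -> bool:
        """True when both modalities are known and disagree."""
        return (
            self.flow.tdt_flow != UNKNOWN
            and self.ihc.tdt_ihc != UNKNOWN
            and self.flow.tdt_flow != self.ihc.tdt_ihc
        )


@dataclass
class Cohort:
    """Ordered collection of case records with a provenance tag."""

    cases: list[CaseRecord] = field(default_factory=list)
    provenance: str = "user"  # fixture | synthetic | user

    def __post_init__(self) -> None:
        if self.provenance not in ("fixture", "synthetic", "user"):
            raise CohortValidationError(
                f"invalid provenance {self.provenance!r}"
            )
        seen: set[str] = set()
        for case in self.cases:
            if case.case_id in seen:
                raise CohortValidationError(
                    f"duplicate case_id {case.case_id!r} in cohort"
                )
            seen.add(case.case_id)

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self) -> Iterator[CaseRecord]:
        return iter(self.cases)

    def __getitem__(self, key):
        if isinstance(key, str):
            for case in self.cases:
                if case.case_id == key:
                    return case
            raise KeyError(key)
        return self.cases[key]

    def subset(self, case_ids) -> "Cohort":
        wanted = set(case_ids)
        return Cohort(
            cases=[c for c in self.cases if c.case_id in wanted],
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# flat-record conversion (shared by CSV and JSON I/O)

def case_to_record(case: CaseRecord) -> dict:
    """Flatten a CaseRecord to the exchange-format dict (unknown -> None)."""
    rec: dict = {"case_id": case.case_id}
    rec["group_truth"] = None if case.group_truth == UNKNOWN else case.group_truth
    rec["site"] = None if case.site == UNKNOWN else case.site
    rec["history_nhl"] = case.history_nhl
    for f in dc_fields(FlowProfile):
        v = getattr(case.flow, f.name)
        rec[f.name] = None if v == UNKNOWN else v
    for name in ("myc_pct", "bcl6_pct", "bcl2_pct"):
        rec[name] = getattr(case.ihc, name)
    for name in ("tdt_ihc", "cyclin_d1"):
        v = getattr(case.ihc, name)
        rec[name] = None if v == UNKNOWN else v
    rec["ki67_pct"] = case.ihc.ki67_pct
    for name in BOOL_FIELDS:
        if name == "history_nhl":
            continue
        rec[name] = getattr(case.genetics, name)
    return {col: rec[col] for col in COHORT_COLUMNS}


def record_to_case(rec: dict) -> CaseRecord:
    """Build a CaseRecord from an exchange-format dict (None/'' -> unknown)."""

    def enum(name: str) -> str:
        v = rec.get(name)
        return UNKNOWN if v in (None, "") else str(v)

    def pct(name: str) -> Optional[float]:
        v = rec.get(name)
        if v in (None, ""):
            return None
        try:
            return float(v)
        except (TypeError, ValueError):
            raise CohortValidationError(
                f"case {rec.get('case_id')!r}: field {name!r} is not numeric: {v!r}"
            ) from None

    def boolean(name: str) -> Optional[bool]:
        v = rec.get(name)
        if v in (None, ""):
            return None
        if isinstance(v, bool):
            return v
        s = str(v).strip().lower()
        if s in ("true", "1", "1.0"):
            return True
        if s in ("false", "0", "0.0"):
            return False
        raise CohortValidationError(
            f"case {rec.get('case_id')!r}: field {name!r} is not boolean: {v!r}"
        )

    case_id = rec.get("case_id")
    if case_id in (None, ""):
        raise CohortValidationError("row with empty case_id")
    try:
        return CaseRecord(
            case_id=str(case_id),
            group_truth=enum("group_truth"),
            site=enum("site"),
            history_nhl=boolean("history_nhl"),
            flow=FlowProfile(
                cd45_vs_granulocytes=enum("cd45_vs_granulocytes"),
                cd10_level=enum("cd10_level"),
                cd20_vs_mature_b=enum("cd20_vs_mature_b"),
                cd38_level=enum("cd38_level"),
                tdt_flow=enum("tdt_flow"),
                cd34=enum("cd34"),
                surface_light_chain=enum("surface_light_chain"),
                myeloid_markers=enum("myeloid_markers"),
            ),
            ihc=IhcProfile(
                myc_pct=pct("myc_pct"),
                bcl6_pct=pct("bcl6_pct"),
                bcl2_pct=pct("bcl2_pct"),
                tdt_ihc=enum("tdt_ihc"),
                cyclin_d1=enum("cyclin_d1"),
                ki67_pct=pct("ki67_pct"),
            ),
            genetics=GeneticProfile(
                myc_r=boolean("myc_r"),
                bcl2_r=boolean("bcl2_r"),
                bcl6_r=boolean("bcl6_r"),
                ccnd1_r=boolean("ccnd1_r"),
                complex_karyotype=boolean("complex_karyotype"),
                ball_translocation=boolean("ball_translocation"),
                tp53_mut=boolean("tp53_mut"),
                kras_mut=boolean("kras_mut"),
                nras_mut=boolean("nras_mut"),
            ),
        )
    except CohortValidationError as exc:
        raise CohortValidationError(f"case {case_id!r}: {exc}") from None


# ---------------------------------------------------------------------------
# completeness reporting

@dataclass
class CompletenessReport:
    """Which required inputs of a scoring system are missing for a case."""

    case_id: str
    system: str
    scoreable: bool
    missing: list[str]
    tdt_modality_discordant: bool = False


def validate_for_system(case: CaseRecord, system: str) -> CompletenessReport:
    """Report whether a case carries every input a scoring system needs.

    The six-point system needs the five flow criteria (CD45, CD10, CD20,
    CD38 and a TdT call from either modality) plus MYC evidence (IHC percent
    or rearrangement status).  The three-point system needs BCL6 percent, a
    TdT call from either modality, and MYC evidence.
    """
    if system not in ("six_point", "three_point"):
        raise ValueError(f"unknown scoring system {system!r}")
    missing: list[str] = []
    if system == "six_point":
        for name in (
            "cd45_vs_granulocytes",
            "cd10_level",
            "cd20_vs_mature_b",
            "cd38_level",
        ):
            if getattr(case.flow, name) == UNKNOWN:
                missing.append(name)
    else:
        if case.ihc.bcl6_pct is None:
            missing.append("bcl6_pct")
    if case.consolidated_tdt() == UNKNOWN:
        missing.append("tdt")
    if case.ihc.myc_pct is None and case.genetics.myc_r is None:
        missing.append("myc_evidence")
    return CompletenessReport(
        case_id=case.case_id,
        system=system,
        scoreable=not missing,
        missing=missing,
        tdt_modality_discordant=case.tdt_modality_discordant(),
    )
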