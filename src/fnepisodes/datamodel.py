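"""Administrative-claims data model and the configurable codeset registry.

Four record types make up a claims dataset: members, enrollment spans,
medical claims, and pharmacy claims.  They are plain frozen dataclasses;
:class:`ClaimsDataset` bundles them with per-member indexes used by the
episode builder.  Every clinical rule downstream consults diagnosis,
procedure, and drug codes exclusively through :class:`CodeSets`, which is
loaded from a YAML/JSON config — swapping the config changes behaviour
with no code change.
"""

from __future__ import annotations

import datetime as dt
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

Date = dt.date

SETTINGS = ("inpatient", "emergency_room", "physician_office", "other_outpatient")
SEXES = ("male", "female")
PAYERS = ("commercial", "medicare", "medicaid", "unknown")
REGIONS = ("northeast", "midwest", "south", "west", "unknown")

#: codeset names every clinical rule depends on; load_codesets refuses a
#: config in which any of these is absent or empty.
REQUIRED_CODESETS = (
    "neutropenia_dx",
    "fever_dx",
    "bacterial_infection_dx",
    "fungal_infection_dx",
    "gcsf_short",
    "gcsf_long",
    "antibacterial",
    "antifungal",
    "antiviral",
    "nccn_parenteral_antibiotic_proc",
    "bmt_sct_cart_proc",
    "excluded_heme_dx",
    "covid_dx",
    "bone_met_dx",
    "surgery_proc",
    "radiation_codes",
    "liver_dysfunction_dx",
    "kidney_dysfunction_dx",
    "nhl_dx",
    "cll_dx",
    "other_hematologic_dx",
    "breast_dx",
    "lung_dx",
    "colorectal_dx",
    "prostate_dx",
    "other_solid_dx",
)

CANCER_GROUPS = (
    "NHL",
    "CLL",
    "other_hematologic",
    "breast",
    "lung",
    "colorectal",
    "prostate",
    "other_solid",
)

#: cancer group -> dx codeset name
CANCER_GROUP_SETS = {
    "NHL": "nhl_dx",
    "CLL": "cll_dx",
    "other_hematologic": "other_hematologic_dx",
    "breast": "breast_dx",
    "lung": "lung_dx",
    "colorectal": "colorectal_dx",
    "prostate": "prostate_dx",
    "other_solid": "other_solid_dx",
}

RISK_ORDER = {"low_undefined": 0, "intermediate": 1, "high": 2}


class SchemaError(ValueError):
    """A required column is missing or a table-level contract is broken."""


class ConfigError(ValueError):
    """The codeset / CPI configuration is invalid."""


@dataclass(frozen=True)
class Member:
    member_id: str
    birth_year: int
    sex: str
    payer: str
    region: str


@dataclass(frozen=True)
class EnrollmentSpan:
    member_id: str
    start_date: Date
    end_date: Date


@dataclass(frozen=True)
class MedicalClaim:
    claim_id: str
    member_id: str
    service_date: Date
    discharge_date: Date | None
    setting: str
    dx_codes: tuple[str, ...]
    proc_codes: tuple[str, ...]
    paid_amount: float


@dataclass(frozen=True)
class PharmacyClaim:
    claim_id: str
    member_id: str
    fill_date: Date
    drug_code: str
    paid_amount: float


@dataclass(frozen=True)
class Regimen:
    """A configured chemotherapy regimen with its FN-risk label.

    ``drugs`` are the chemo/biologic codes (pharmacy or procedure) that must
    all appear in the chemotherapy treatment window for the regimen to
    match.  ``requires_dx`` names a dx codeset that must additionally be
    evidenced in the pre-episode window (context-dependent agents such as
    docetaxel or topotecan).  ``min_admin_count`` requires that many
    distinct administration dates of the regimen's drugs over the 180-day
    lookback (cycle-count conditions for doxorubicin/cyclophosphamide).
    """

    name: str
    risk: str
    drugs: frozenset[str]
    requires_dx: str | None = None
    min_admin_count: int = 1


@dataclass(frozen=True)
class CCICondition:
    name: str
    weight: float
    codes: frozenset[str]


def _normalize_code(code) -> str:
    return str(code).strip().upper()


@dataclass
class CodeSets:
    """Named code lists plus regimen and comorbidity-weight configuration."""

    sets: dict[str, frozenset[str]]
    regimens: list[Regimen]
    oral_antibiotic_combinations: list[tuple[str, ...]]
    cci_conditions: dict[str, CCICondition]
    unknown_names: tuple[str, ...] = ()

    def __getitem__(self, name: str) -> frozenset[str]:
        try:
            return self.sets[name]
        except KeyError:
            raise ConfigError(f"codeset {name!r} is not configured") from None

    # -- derived unions used throughout the rules -------------------------
    @property
    def infection_fever_dx(self) -> frozenset[str]:
        return self["fever_dx"] | self["bacterial_infection_dx"] | self["fungal_infection_dx"]

    @property
    def fn_dx(self) -> frozenset[str]:
        """Neutropenia, infection, or fever — the FN-defining dx union."""
        return self["neutropenia_dx"] | self.infection_fever_dx

    @property
    def gcsf_all(self) -> frozenset[str]:
        return self["gcsf_short"] | self["gcsf_long"]

    @property
    def antimicrobial_all(self) -> frozenset[str]:
        return self["antibacterial"] | self["antifungal"] | self["antiviral"]

    @property
    def chemo_codes(self) -> frozenset[str]:
        extra = self.sets.get("chemo_codes", frozenset())
        drugs: set[str] = set(extra)
        for regimen in self.regimens:
            drugs |= regimen.drugs
        return frozenset(drugs)


def load_codesets(config_path: str | Path | None = None) -> CodeSets:
    """Load the codeset registry from YAML (or the shipped defaults).

    The config maps codeset name -> {system, codes}; codes may be plain
    strings or {code, system} mappings.  Duplicate codes within one set are
    deduplicated.  Required codesets must be present and non-empty.
    """
    if config_path is None:
        ref = importlib.resources.files("fnepisodes.resources") / "default_codesets.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(config_path) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError("codeset config must be a mapping")

    sets: dict[str, frozenset[str]] = {}
    for name, entry in (raw.get("codesets") or {}).items():
        if isinstance(entry, Mapping):
            codes = entry.get("codes", [])
        else:
            codes = entry
        parsed = []
        for item in codes or []:
            if isinstance(item, Mapping):
                parsed.append(_normalize_code(item["code"]))
            else:
                parsed.append(_normalize_code(item))
        sets[str(name)] = frozenset(parsed)

    regimens = []
    for spec in raw.get("regimens") or []:
        risk = str(spec["risk"])
        if risk not in RISK_ORDER:
            raise ConfigError(f"regimen {spec.get('name')!r} has unknown risk {risk!r}")
        regimens.append(
            Regimen(
                name=str(spec["name"]),
                risk=risk,
                drugs=frozenset(_normalize_code(c) for c in spec["drugs"]),
                requires_dx=spec.get("requires_dx"),
                min_admin_count=int(spec.get("min_admin_count", 1)),
            )
        )

    combos = [tuple(str(n) for n in combo) for combo in raw.get("oral_antibiotic_combinations") or []]

    cci: dict[str, CCICondition] = {}
    for name, spec in (raw.get("cci_conditions") or {}).items():
        weight = float(spec["weight"])
        if weight <= 0:
            raise ConfigError(f"cci condition {name!r} has non-positive weight {weight}")
        cci[str(name)] = CCICondition(
            name=str(name),
            weight=weight,
            codes=frozenset(_normalize_code(c) for c in spec["codes"]),
        )

    known = set(REQUIRED_CODESETS) | {"chemo_codes"} | {
        name for combo in combos for name in combo
    }
    unknown = tuple(sorted(n for n in sets if n not in known))

    missing = [n for n in REQUIRED_CODESETS if not sets.get(n)]
    if missing:
        raise ConfigError(f"required codesets absent or empty: {', '.join(missing)}")
    for combo in combos:
        for set_name in combo:
            if not sets.get(set_name):
                raise ConfigError(f"oral combination references absent codeset {set_name!r}")
    for regimen in regimens:
        if regimen.requires_dx is not None and not sets.get(regimen.requires_dx):
            raise ConfigError(
                f"regimen {regimen.name!r} requires absent codeset {regimen.requires_dx!r}"
            )
    if not regimens:
        raise ConfigError("at least one chemotherapy regimen must be configured")

    return CodeSets(
        sets=sets,
        regimens=regimens,
        oral_antibiotic_combinations=combos,
        cci_conditions=cci,
        unknown_names=unknown,
    )


def load_cpi_table(path: str | Path | None = None) -> dict[int, float]:
    """Load the medical-CPI index table (year -> index value)."""
    if path is None:
        ref = importlib.resources.files("fnepisodes.resources") / "default_cpi.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    table = {int(year): float(value) for year, value in (raw.get("medical_cpi") or raw).items()}
    if not table:
        raise ConfigError("CPI table is empty")
    for year, value in table.items():
        if value <= 0:
            raise ConfigError(f"CPI index for {year} must be positive")
    return table


# ---------------------------------------------------------------------------
# dataset container and loading


@dataclass
class RowError:
    table: str
    row: int
    claim_id: str | None
    message: str


class _MemberClaims:
    """Per-member date indexes the episode builder consults repeatedly."""

    __slots__ = ("medical_by_date", "pharmacy_by_date", "chemo_dates", "fn_dx_dates")

    def __init__(self) -> None:
        self.medical_by_date: dict[Date, list[MedicalClaim]] = {}
        self.pharmacy_by_date: dict[Date, list[PharmacyClaim]] = {}
        self.chemo_dates: list[Date] = []
        self.fn_dx_dates: list[Date] = []


@dataclass
class ClaimsDataset:
    members: dict[str, Member]
    enrollment: list[EnrollmentSpan]
    medical: list[MedicalClaim]
    pharmacy: list[PharmacyClaim]
    errors: list[RowError] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_member: dict[str, _MemberClaims] | None = None
        self._enrollment_merged: dict[str, list[tuple[Date, Date]]] | None = None

    # -- indexes ----------------------------------------------------------
    def member_claims(self, member_id: str) -> _MemberClaims:
        if self._by_member is None:
            index: dict[str, _MemberClaims] = {}
            for claim in self.medical:
                mc = index.setdefault(claim.member_id, _MemberClaims())
                mc.medical_by_date.setdefault(claim.service_date, []).append(claim)
            for claim in self.pharmacy:
                mc = index.setdefault(claim.member_id, _MemberClaims())
                mc.pharmacy_by_date.setdefault(claim.fill_date, []).append(claim)
            self._by_member = index
        return self._by_member.get(member_id, _MemberClaims())

    def member_ids_with_claims(self) -> list[str]:
        self.member_claims("")  # force the index
        assert self._by_member is not None
        return sorted(self._by_member)

    def merged_enrollment(self, member_id: str) -> list[tuple[Date, Date]]:
        """Enrollment spans with overlapping/adjacent (gap <= 1 day) merged."""
        if self._enrollment_merged is None:
            by_member: dict[str, list[tuple[Date, Date]]] = {}
            for span in self.enrollment:
                by_member.setdefault(span.member_id, []).append((span.start_date, span.end_date))
            merged: dict[str, list[tuple[Date, Date]]] = {}
            for mid, spans in by_member.items():
                spans.sort()
                out = [spans[0]]
                for start, end in spans[1:]:
                    last_start, last_end = out[-1]
                    if start <= last_end + dt.timedelta(days=1):
                        out[-1] = (last_start, max(last_end, end))
                    else:
                        out.append((start, end))
                merged[mid] = out
            self._enrollment_merged = merged
        return self._enrollment_merged.get(member_id, [])

    def is_enrolled(self, member_id: str, start: Date, end: Date) -> bool:
        """True iff one merged span covers [start, end] with no gap."""
        return any(s <= start and end <= e for s, e in self.merged_enrollment(member_id))


def _parse_date(value, *, required: bool) -> Date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        if required:
            raise ValueError("missing date")
        return None
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    if isinstance(value, dt.datetime):
        return value.date()
    return dt.date.fromisoformat(str(value).strip())


def _split_codes(value) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ()
    parts = str(value).replace(",", ";").split(";")
    return tuple(_normalize_code(p) for p in parts if p.strip())


def _require_columns(df: pd.DataFrame, table: str, columns: Sequence[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing required column(s): {', '.join(missing)}")


def load_claims(
    medical_path: str | Path,
    pharmacy_path: str | Path,
    enrollment_path: str | Path,
    members_path: str | Path,
) -> ClaimsDataset:
    """Read and validate the four claim tables from CSV.

    Rows violating record invariants (bad dates, negative paid amounts,
    inpatient claims without a discharge date, ...) are rejected with
    row-level diagnostics collected on ``dataset.errors``; a missing
    required column raises :class:`SchemaError` immediately.
    """
    med = pd.read_csv(medical_path, dtype=str, keep_default_na=False)
    rx = pd.read_csv(pharmacy_path, dtype=str, keep_default_na=False)
    enr = pd.read_csv(enrollment_path, dtype=str, keep_default_na=False)
    mem = pd.read_csv(members_path, dtype=str, keep_default_na=False)

    _require_columns(
        med, "medical",
        ["claim_id", "member_id", "service_date", "discharge_date", "setting",
         "dx_codes", "proc_codes", "paid_amount"],
    )
    _require_columns(rx, "pharmacy", ["claim_id", "member_id", "fill_date", "drug_code", "paid_amount"])
    _require_columns(enr, "enrollment", ["member_id", "start_date", "end_date"])
    _require_columns(mem, "members", ["member_id", "birth_year", "sex", "payer", "region"])

    errors: list[RowError] = []

    members: dict[str, Member] = {}
    for i, row in enumerate(mem.itertuples(index=False)):
        try:
            mid = str(row.member_id)
            if mid in members:
                raise ValueError(f"duplicate member_id {mid}")
            sex = str(row.sex).strip().lower()
            payer = str(row.payer).strip().lower()
            region = str(row.region).strip().lower()
            if sex not in SEXES:
                raise ValueError(f"unknown sex {row.sex!r}")
            if payer not in PAYERS:
                raise ValueError(f"unknown payer {row.payer!r}")
            if region not in REGIONS:
                raise ValueError(f"unknown region {row.region!r}")
            members[mid] = Member(mid, int(row.birth_year), sex, payer, region)
        except (ValueError, TypeError) as exc:
            errors.append(RowError("members", i, None, str(exc)))

    enrollment: list[EnrollmentSpan] = []
    for i, row in enumerate(enr.itertuples(index=False)):
        try:
            start = _parse_date(row.start_date, required=True)
            end = _parse_date(row.end_date, required=True)
            if end < start:
                raise ValueError("end_date precedes start_date")
            enrollment.append(EnrollmentSpan(str(row.member_id), start, end))
        except (ValueError, TypeError) as exc:
            errors.append(RowError("enrollment", i, None, str(exc)))

    medical: list[MedicalClaim] = []
    for i, row in enumerate(med.itertuples(index=False)):
        cid = str(row.claim_id)
        try:
            setting = str(row.setting).strip().lower()
            if setting not in SETTINGS:
                raise ValueError(f"unknown setting {row.setting!r}")
            service = _parse_date(row.service_date, required=True)
            discharge = _parse_date(row.discharge_date, required=False)
            if setting == "inpatient":
                if discharge is None:
                    raise ValueError("inpatient claim lacks discharge_date")
                if discharge < service:
                    raise ValueError("discharge_date precedes service_date")
            elif discharge is not None:
                raise ValueError("discharge_date present on non-inpatient claim")
            paid = float(row.paid_amount)
            if paid < 0:
                raise ValueError("negative paid_amount")
            medical.append(
                MedicalClaim(cid, str(row.member_id), service, discharge, setting,
                             _split_codes(row.dx_codes), _split_codes(row.proc_codes), paid)
            )
        except (ValueError, TypeError) as exc:
            errors.append(RowError("medical", i, cid, str(exc)))

    pharmacy: list[PharmacyClaim] = []
    for i, row in enumerate(rx.itertuples(index=False)):
        cid = str(row.claim_id)
        try:
            fill = _parse_date(row.fill_date, required=True)
            paid = float(row.paid_amount)
            if paid < 0:
                raise ValueError("negative paid_amount")
            pharmacy.append(
                PharmacyClaim(cid, str(row.member_id), fill, _normalize_code(row.drug_code), paid)
            )
        except (ValueError, TypeError) as exc:
            errors.append(RowError("pharmacy", i, cid, str(exc)))

    return ClaimsDataset(members=members, enrollment=enrollment, medical=medical,
                         pharmacy=pharmacy, errors=errors)


def write_claims(dataset: ClaimsDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four tables back to CSV (inverse of :func:`load_claims`)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    members_df = pd.DataFrame(
        [
            {"member_id": m.member_id, "birth_year": m.birth_year, "sex": m.sex,
             "payer": m.payer, "region": m.region}
            for m in dataset.members.values()
        ],
        columns=["member_id", "birth_year", "sex", "payer", "region"],
    )
    enrollment_df = pd.DataFrame(
        [
            {"member_id": s.member_id, "start_date": s.start_date.isoformat(),
             "end_date": s.end_date.isoformat()}
            for s in dataset.enrollment
        ],
        columns=["member_id", "start_date", "end_date"],
    )
    medical_df = pd.DataFrame(
        [
            {
                "claim_id": c.claim_id,
                "member_id": c.member_id,
                "service_date": c.service_date.isoformat(),
                "discharge_date": c.discharge_date.isoformat() if c.discharge_date else "",
                "setting": c.setting,
                "dx_codes": ";".join(c.dx_codes),
                "proc_codes": ";".join(c.proc_codes),
                "paid_amount": f"{c.paid_amount:.2f}",
            }
            for c in dataset.medical
        ],
        columns=["claim_id", "member_id", "service_date", "discharge_date", "setting",
                 "dx_codes", "proc_codes", "paid_amount"],
    )
    pharmacy_df = pd.DataFrame(
        [
            {"claim_id": c.claim_id, "member_id": c.member_id,
             "fill_date": c.fill_date.isoformat(), "drug_code": c.drug_code,
             "paid_amount": f"{c.paid_amount:.2f}"}
            for c in dataset.pharmacy
        ],
        columns=["claim_id", "member_id", "fill_date", "drug_code", "paid_amount"],
    )

    for name, df in [("members", members_df), ("enrollment", enrollment_df),
                     ("medical", medical_df), ("pharmacy", pharmacy_df)]:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths
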