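"""Loading, validation and filtering of JADER-schema spontaneous-report tables.

A JADER-style database consists of four relational tables keyed by an opaque
report identifier: patient demographics (``demo``), drug records with role
codes (``drug``), adverse reactions coded as MedDRA preferred terms (``reac``)
and primary illness (``hist``).  This module reads those tables from delimited
text files, derives per-report case flags from a preferred-term case
definition, maps 10-year age bands onto the five analysis strata, and applies
the complete-case filter (reports lacking sex or age are removed before any
modelling).  No record linkage or deduplication is attempted: spontaneous
reporting databases carry no reliable case-identification key, so reports are
taken at face value.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

log = logging.getLogger(__name__)

TABLES = ("demo", "drug", "reac", "hist")

#: Canonical (English) column names required per table.
REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("report_id", "sex", "age_band", "reporting_year"),
    "drug": ("report_id", "drug_name", "role_code", "start_date"),
    "reac": ("report_id", "pt_code", "onset_date"),
    "hist": ("report_id",),
}

ROLE_SUSPECTED = "suspected"
ROLE_INTERACTING = "interacting"
ROLE_CONCOMITANT = "concomitant"

#: Accepted spellings for the three drug role codes (after NFKC + casefold).
ROLE_ALIASES: dict[str, str] = {
    "suspected": ROLE_SUSPECTED,
    "higiyaku": ROLE_SUSPECTED,
    "被疑薬": ROLE_SUSPECTED,
    "interacting": ROLE_INTERACTING,
    "sougosayou": ROLE_INTERACTING,
    "相互作用": ROLE_INTERACTING,
    "concomitant": ROLE_CONCOMITANT,
    "heiyouyaku": ROLE_CONCOMITANT,
    "併用薬": ROLE_CONCOMITANT,
}

SEX_ALIASES: dict[str, str] = {
    "male": "male",
    "m": "male",
    "男性": "male",
    "female": "female",
    "f": "female",
    "女性": "female",
}


class AgeStratum(str, Enum):
    """Five analysable age strata (10-year bands merged) plus unknown."""

    LE19 = "<=19"
    Y20_39 = "20-39"
    Y40_59 = "40-59"
    Y60_79 = "60-79"
    GE80 = ">=80"
    UNKNOWN = "unknown"


#: The strata that enter analyses, in reporting order.
ANALYSIS_STRATA: tuple[AgeStratum, ...] = (
    AgeStratum.LE19,
    AgeStratum.Y20_39,
    AgeStratum.Y40_59,
    AgeStratum.Y60_79,
    AgeStratum.GE80,
)


@dataclass(frozen=True)
class CaseDefinition:
    """A set of MedDRA preferred-term codes defining the adverse event.

    PT codes are opaque strings; no MedDRA hierarchy traversal is performed.
    """

    pt_codes: frozenset[str]
    label: str = "case"

    def __post_init__(self) -> None:
        if not self.pt_codes:
            raise ValueError("CaseDefinition requires at least one PT code")
        object.__setattr__(self, "pt_codes", frozenset(str(c) for c in self.pt_codes))


#: Default case definition: Stevens-Johnson syndrome, oculomucocutaneous
#: syndrome, and toxic epidermal necrolysis.
SJS_TEN = CaseDefinition(frozenset({"10042033", "10030081", "10044223"}), "SJS/TEN")


@dataclass
class ReportDatabase:
    """The four JADER-schema tables plus load bookkeeping."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    hist: pd.DataFrame
    malformed: dict[str, int] = field(default_factory=dict)

    @property
    def n_reports(self) -> int:
        return int(self.demo["report_id"].nunique())

    def table(self, name: str) -> pd.DataFrame:
        if name not in TABLES:
            raise KeyError(name)
        return getattr(self, name)


def normalize_drug_name(name: str) -> str:
    """Exact-match normalization: Unicode NFKC then casefold then strip.

    Brand/generic synonym mapping is deliberately not built in; callers supply
    pre-mapped names if they need it.
    """
    return unicodedata.normalize("NFKC", str(name)).casefold().strip()


def normalize_drug_names(names: Iterable[str]) -> frozenset[str]:
    return frozenset(normalize_drug_name(n) for n in names)


_BAND_RE = re.compile(r"(\d{1,3})\s*s?$")


def map_age_band(age_band: str) -> AgeStratum:
    """Map a 10-year age-band label (``"20s"``, ``"30s"`` ...) to a stratum.

    Total function: anything unparsable maps to UNKNOWN.  Decades below 20
    merge into <=19 and decades of 80 or more into >=80, so edge labels such
    as ``"0s"`` or ``"100s"`` are handled.
    """
    if age_band is None:
        return AgeStratum.UNKNOWN
    s = unicodedata.normalize("NFKC", str(age_band)).strip().casefold()
    m = _BAND_RE.fullmatch(s)
    if not m:
        return AgeStratum.UNKNOWN
    decade = int(m.group(1))
    if decade % 10 != 0:
        return AgeStratum.UNKNOWN
    if decade < 20:
        return AgeStratum.LE19
    if decade < 40:
        return AgeStratum.Y20_39
    if decade < 60:
        return AgeStratum.Y40_59
    if decade < 80:
        return AgeStratum.Y60_79
    return AgeStratum.GE80


DATE_DAY_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")
DATE_MONTH_RE = re.compile(r"^\d{4}-\d{2}$")
DATE_YEAR_RE = re.compile(r"^\d{4}$")


def date_precision(value: str) -> str:
    """Classify an ISO-8601-ish date string as day/month/year/missing."""
    s = str(value).strip()
    if DATE_DAY_RE.match(s):
        return "day"
    if DATE_MONTH_RE.match(s):
        return "month"
    if DATE_YEAR_RE.match(s):
        return "year"
    return "missing"


def _read_schema_config(schema_config) -> dict:
    if schema_config is None:
        return {}
    if isinstance(schema_config, (str, Path)):
        with open(schema_config, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh) or {}
    return dict(schema_config)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def load_database(
    paths: Mapping[str, str | Path],
    schema_config: Mapping | str | Path | None = None,
) -> ReportDatabase:
    """Load the four tables from delimited text files.

    Parameters
    ----------
    paths
        Mapping from table name (demo/drug/reac/hist) to a CSV or TSV file.
        Delimiter is auto-detected from the extension (.tsv/.tab/.txt → tab).
    schema_config
        Optional YAML path or mapping ``{table: {canonical_name: file_column}}``
        so that files with non-canonical headers (e.g. raw Japanese headers)
        can be loaded without rewriting them.

    Malformed rows (empty report_id, unrecognized role codes) are counted and
    logged but never dropped; no deduplication is performed.
    """
    cfg = _read_schema_config(schema_config)
    frames: dict[str, pd.DataFrame] = {}
    malformed: dict[str, int] = {}
    for name in TABLES:
        if name not in paths:
            raise FileNotFoundError(f"no path given for required table '{name}'")
        path = Path(paths[name])
        if not path.exists():
            raise FileNotFoundError(f"table '{name}': file not found: {path}")
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
        colmap = cfg.get(name, {})
        if colmap:
            df = df.rename(columns={v: k for k, v in colmap.items()})
        for col in REQUIRED_COLUMNS[name]:
            if col not in df.columns:
                raise KeyError(f"table '{name}' is missing required column '{col}'")
        n_bad = int((df["report_id"].str.strip() == "").sum())
        if n_bad:
            log.warning("table %s: %d rows with empty report_id (kept)", name, n_bad)
        malformed[name] = n_bad
        if name == "drug":
            raw = df["role_code"].map(
                lambda s: unicodedata.normalize("NFKC", str(s)).strip().casefold()
            )
            df["role_code"] = raw.map(lambda s: ROLE_ALIASES.get(s, s))
            unknown = ~df["role_code"].isin(
                {ROLE_SUSPECTED, ROLE_INTERACTING, ROLE_CONCOMITANT}
            )
            if unknown.any():
                log.warning(
                    "table drug: %d rows with unrecognized role code (kept verbatim)",
                    int(unknown.sum()),
                )
                malformed["drug_role"] = int(unknown.sum())
        frames[name] = df
        log.info("loaded table %s: %d rows from %s", name, len(df), path)
    return ReportDatabase(
        demo=frames["demo"],
        drug=frames["drug"],
        reac=frames["reac"],
        hist=frames["hist"],
        malformed=malformed,
    )


def write_database(db: ReportDatabase, outdir: str | Path) -> dict[str, Path]:
    """Write the four tables as canonical-header CSV files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in TABLES:
        path = outdir / f"{name}.csv"
        db.table(name).to_csv(path, index=False)
        paths[name] = path
    return paths


def build_analysis_dataset(
    db: ReportDatabase,
    case_def: CaseDefinition = SJS_TEN,
    year_range: tuple[int, int] = (2004, 2015),
    drop_incomplete: bool = True,
) -> pd.DataFrame:
    """Derive the one-row-per-report analysis dataset.

    Columns: report_id, sex, age_stratum, reporting_year (nullable),
    is_case, suspected_drugs (frozenset of normalized names).  ``is_case`` is
    true iff at least one reaction record of the report carries a PT code in
    ``case_def``.  With ``drop_incomplete`` (the default), reports with
    unknown sex or age stratum are removed — the complete-case filter applied
    before any modelling; the removed count is logged and recorded in
    ``.attrs``.  Reporting years outside ``year_range`` are treated as
    missing (such reports stay in the dataset but are excluded later from
    models that use the year term).
    """
    demo = db.demo
    n_dup = int(demo["report_id"].duplicated().sum())
    if n_dup:
        log.warning("demo: %d duplicated report_ids; keeping first occurrence", n_dup)
        demo = demo.drop_duplicates("report_id", keep="first")
    n_raw = len(demo)

    def _map_unique(series: pd.Series, func) -> pd.Series:
        # age bands / sex labels take few distinct values; map via lookup
        return series.map({v: func(v) for v in series.unique()})

    sex = _map_unique(
        demo["sex"],
        lambda s: SEX_ALIASES.get(
            unicodedata.normalize("NFKC", str(s)).strip().casefold(), "unknown"
        ),
    )
    stratum = _map_unique(demo["age_band"], lambda b: map_age_band(b).value)
    year = pd.to_numeric(demo["reporting_year"], errors="coerce")
    lo, hi = year_range
    out_of_range = year.notna() & ((year < lo) | (year > hi))
    if out_of_range.any():
        log.warning(
            "%d reports with reporting_year outside [%d, %d]; year treated as missing",
            int(out_of_range.sum()), lo, hi,
        )
    year = year.mask(out_of_range).astype("Int64")

    case_ids = set(
        db.reac.loc[db.reac["pt_code"].isin(case_def.pt_codes), "report_id"]
    )
    susp = db.drug.loc[db.drug["role_code"] == ROLE_SUSPECTED]
    name_lut = {v: normalize_drug_name(v) for v in susp["drug_name"].unique()}
    susp_map = (
        susp.assign(name=susp["drug_name"].map(name_lut))
        .groupby("report_id")["name"]
        .agg(frozenset)
    )

    ds = pd.DataFrame(
        {
            "report_id": demo["report_id"].to_numpy(),
            "sex": sex.to_numpy(),
            "age_stratum": stratum.to_numpy(),
            "reporting_year": year.to_numpy(dtype=object),
        }
    )
    ds["reporting_year"] = pd.array(ds["reporting_year"], dtype="Int64")
    ds["is_case"] = ds["report_id"].isin(case_ids)
    ds["suspected_drugs"] = ds["report_id"].map(susp_map)
    ds["suspected_drugs"] = ds["suspected_drugs"].where(
        ds["suspected_drugs"].notna(), frozenset()
    )

    n_complete = n_raw
    if drop_incomplete:
        complete = (ds["sex"] != "unknown") & (
            ds["age_stratum"] != AgeStratum.UNKNOWN.value
        )
        removed = int((~complete).sum())
        log.info(
            "complete-case filter: %d of %d reports removed (missing age or sex)",
            removed, n_raw,
        )
        ds = ds.loc[complete].reset_index(drop=True)
        n_complete = len(ds)
        if ds.empty:
            raise ValueError("no reports remain after the complete-case filter")
    if ds.empty:
        raise ValueError("empty analysis dataset: nothing to analyse")

    ds.attrs.update(
        n_raw=n_raw,
        n_complete=n_complete,
        n_missing_year=int(ds["reporting_year"].isna().sum()),
        case_definition=case_def.label,
        n_cases=int(ds["is_case"].sum()),
    )
    return ds


def write_analysis_dataset(ds: pd.DataFrame, path: str | Path) -> Path:
    """Write the analysis dataset as CSV with a fixed column order."""
    out = ds.copy()
    out["suspected_drugs"] = out["suspected_drugs"].map(
        lambda s: ";".join(sorted(s))
    )
    cols = ["report_id", "sex", "age_stratum", "reporting_year", "is_case",
            "suspected_drugs"]
    path = Path(path)
    out[cols].to_csv(path, index=False)
    return path


def subset_by_drug(ds: pd.DataFrame, drug_names: Iterable[str]) -> pd.DataFrame:
    """Reports whose suspected drugs intersect ``drug_names``.

    Used both for per-drug subset analyses and for drug groups (a report
    suspected of two drugs in the group is counted once).  Raises if the
    subset is empty.
    """
    names = normalize_drug_names(drug_names)
    if not names:
        raise ValueError("drug_names must be non-empty")
    mask = ds["suspected_drugs"].map(lambda s: not names.isdisjoint(s))
    sub = ds.loc[mask].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no reports list any of {sorted(names)} as suspected drug")
    sub.attrs.update(ds.attrs)
    sub.attrs["subset_drugs"] = sorted(names)
    return sub
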