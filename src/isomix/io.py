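"""Domain types and CSV ingestion for stable-isotope food-web data.

Everything downstream (preprocessing, mixing models, residency analysis)
consumes the types defined here: individual consumer tissue records, raw
basal-source samples, per-source summary statistics, and trophic enrichment
factors.  All isotope values are per-mil (permil) deviations from the
international reference scale (delta notation); lengths are millimetres.

CSV conventions: comma-separated, UTF-8, "." decimal, blank cell = absent
value, one row per tissue sample.  No unit auto-detection is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TRACERS",
    "HABITATS",
    "GUILDS",
    "IsotopeValue",
    "ConsumerRecord",
    "SourceSample",
    "SourceSummary",
    "TEFSpec",
    "SchemaError",
    "ValidationError",
    "delta_from_ratios",
    "load_consumers",
    "write_consumers",
    "load_sources",
    "write_sources",
    "load_tef",
]

#: Closed set of tracers the package understands.
TRACERS = ("d13C", "d15N", "d34S")

#: Closed set of habitat codes.
HABITATS = ("main_channel", "floodplain", "estuary")

#: Closed set of trophic guilds; each guild selects a trophic enrichment factor.
GUILDS = ("herbivore", "omnivore", "carnivore")


class SchemaError(ValueError):
    """A file-level problem: missing columns, mixed layouts, empty input."""


class ValidationError(ValueError):
    """Row-level problems, aggregated with row numbers."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class IsotopeValue:
    """A single delta-notation measurement on the international scale."""

    tracer: str
    value: float  # permil

    def __post_init__(self) -> None:
        if self.tracer not in TRACERS:
            raise ValueError(f"unknown tracer {self.tracer!r}; expected one of {TRACERS}")
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite isotope value for {self.tracer}")


@dataclass(frozen=True)
class ConsumerRecord:
    """One fish or prawn muscle-tissue measurement.

    d34S and cn_ratio may be absent (None): sulphur is only measured on a
    subsample, and the C:N ratio is only needed to evaluate lipid correction.
    """

    record_id: str
    species_code: str
    site_id: str
    habitat: str
    guild: str
    standard_length: float  # mm
    d13C: float
    d15N: float
    d34S: float | None = None
    cn_ratio: float | None = None
    lipid_corrected: bool = False

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValueError(f"habitat {self.habitat!r} not in {HABITATS}")
        if self.guild not in GUILDS:
            raise ValueError(f"guild {self.guild!r} not in {GUILDS}")
        if not (self.standard_length > 0):
            raise ValueError("standard_length must be > 0 mm")
        for name in ("d13C", "d15N"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.cn_ratio is not None and not (self.cn_ratio > 0):
            raise ValueError("cn_ratio must be > 0 when present")


@dataclass(frozen=True)
class SourceSample:
    """One raw basal-source measurement (algal biofilm, CPOM, seston...)."""

    source_name: str
    habitat: str
    d13C: float | None = None
    d15N: float | None = None

    def __post_init__(self) -> None:
        if self.d13C is None and self.d15N is None:
            raise ValueError("a source sample needs at least one tracer")

    @property
    def tracers(self) -> tuple[str, ...]:
        return tuple(t for t in ("d13C", "d15N") if getattr(self, t) is not None)


@dataclass(frozen=True)
class SourceSummary:
    """Per-source mean/SD/n for each tracer, the parametrization the mixing
    model consumes (source means and SDs enter the likelihood directly)."""

    source_name: str
    means: dict[str, float] = field(default_factory=dict)  # tracer -> permil
    sds: dict[str, float] = field(default_factory=dict)  # tracer -> permil
    n: int = 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if set(self.means) != set(self.sds):
            raise ValueError("means and sds must cover the same tracers")
        for t, sd in self.sds.items():
            if t not in TRACERS:
                raise ValueError(f"unknown tracer {t!r}")
            if sd < 0:
                raise ValueError(f"sd for {t} must be >= 0")

    @property
    def tracers(self) -> tuple[str, ...]:
        return tuple(t for t in TRACERS if t in self.means)


@dataclass(frozen=True)
class TEFSpec:
    """Trophic enrichment factor for one guild: per-tracer mean/SD shift
    added to source values inside the mixing likelihood."""

    guild: str
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise ValueError(f"guild {self.guild!r} not in {GUILDS}")
        if set(self.means) != set(self.sds):
            raise ValueError("means and sds must cover the same tracers")
        for t, sd in self.sds.items():
            if sd < 0:
                raise ValueError(f"sd for {t} must be >= 0")


# ---------------------------------------------------------------------------
# delta notation
# ---------------------------------------------------------------------------

def delta_from_ratios(r_sample: float, r_standard: float) -> float:
    """Convert heavy:light isotope abundance ratios to a delta value (permil).

    delta = (r_sample / r_standard - 1) * 1e3.  Both ratios must be > 0.
    """
    if not (r_sample > 0 and r_standard > 0):
        raise ValueError("isotope abundance ratios must be > 0")
    return (r_sample / r_standard - 1.0) * 1e3


# ---------------------------------------------------------------------------
# consumer CSV I/O
# ---------------------------------------------------------------------------

CONSUMER_COLUMNS = (
    "record_id",
    "species_code",
    "site_id",
    "habitat",
    "guild",
    "standard_length_mm",
    "d13C",
    "d15N",
    "d34S",
    "cn_ratio",
)

_REQUIRED_CONSUMER_COLUMNS = CONSUMER_COLUMNS[:8]


def _norm_token(value: str) -> str:
    return str(value).strip().lower().replace(" ", "_").replace("-", "_")


def load_consumers(path: str | Path) -> list[ConsumerRecord]:
    """Read a consumers CSV into validated records.

    Habitat and guild strings are normalized case-insensitively against the
    closed sets.  Rows failing validation are collected and reported together
    with their row numbers (2-based, counting the header as row 1).
    """
    df = _read_csv(path)
    missing = [c for c in _REQUIRED_CONSUMER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"consumers file missing required columns: {missing}")

    records: list[ConsumerRecord] = []
    errors: list[str] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            records.append(
                ConsumerRecord(
                    record_id=str(row["record_id"]),
                    species_code=str(row["species_code"]),
                    site_id=str(row["site_id"]),
                    habitat=_norm_token(row["habitat"]),
                    guild=_norm_token(row["guild"]),
                    standard_length=_num(row["standard_length_mm"], "standard_length_mm"),
                    d13C=_num(row["d13C"], "d13C"),
                    d15N=_num(row["d15N"], "d15N"),
                    d34S=_opt_num(row.get("d34S"), "d34S"),
                    cn_ratio=_opt_num(row.get("cn_ratio"), "cn_ratio"),
                )
            )
        except ValueError as exc:
            errors.append(f"row {pos}: {exc}")
    if errors:
        raise ValidationError(errors)
    return records


def write_consumers(records: Iterable[ConsumerRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id,
                "species_code": r.species_code,
                "site_id": r.site_id,
                "habitat": r.habitat,
                "guild": r.guild,
                "standard_length_mm": r.standard_length,
                "d13C": r.d13C,
                "d15N": r.d15N,
                "d34S": r.d34S,
                "cn_ratio": r.cn_ratio,
            }
        )
    pd.DataFrame(rows, columns=CONSUMER_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# source CSV I/O (raw-sample layout or summary layout, auto-detected)
# ---------------------------------------------------------------------------

_RAW_SOURCE_COLUMNS = ("source_name", "habitat")
_SUMMARY_SOURCE_COLUMNS = ("source_name", "tracer", "mean", "sd", "n")


def load_sources(path: str | Path) -> list[SourceSample] | list[SourceSummary]:
    """Read a sources CSV, auto-detecting the layout by its columns.

    Raw layout: source_name, habitat, d13C, d15N (one row per sample).
    Summary layout: source_name, tracer, mean, sd, n (one row per
    source x tracer — the format of a published source-estimates table).
    """
    df = _read_csv(path)
    cols = set(df.columns)
    is_summary = set(_SUMMARY_SOURCE_COLUMNS) <= cols
    is_raw = set(_RAW_SOURCE_COLUMNS) <= cols and (
        "d13C" in cols or "d15N" in cols
    )
    if is_summary and ("d13C" in cols or "d15N" in cols):
        raise SchemaError("sources file mixes raw and summary layouts")
    if is_summary:
        return _load_source_summaries(df)
    if is_raw:
        return _load_source_samples(df)
    raise SchemaError(
        "sources file matches neither the raw layout "
        f"{_RAW_SOURCE_COLUMNS + ('d13C', 'd15N')} nor the summary layout "
        f"{_SUMMARY_SOURCE_COLUMNS}"
    )


def _load_source_samples(df: pd.DataFrame) -> list[SourceSample]:
    samples: list[SourceSample] = []
    errors: list[str] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            samples.append(
                SourceSample(
                    source_name=str(row["source_name"]),
                    habitat=_norm_token(row["habitat"]),
                    d13C=_opt_num(row.get("d13C"), "d13C"),
                    d15N=_opt_num(row.get("d15N"), "d15N"),
                )
            )
        except ValueError as exc:
            errors.append(f"row {pos}: {exc}")
    if errors:
        raise ValidationError(errors)
    return samples


def _load_source_summaries(df: pd.DataFrame) -> list[SourceSummary]:
    summaries: list[SourceSummary] = []
    errors: list[str] = []
    for name, group in df.groupby("source_name", sort=False):
        means: dict[str, float] = {}
        sds: dict[str, float] = {}
        ns: set[int] = set()
        for pos, row in group.iterrows():
            tracer = str(row["tracer"]).strip()
            if tracer not in TRACERS:
                errors.append(f"source {name!r}: unknown tracer {tracer!r}")
                continue
            try:
                means[tracer] = _num(row["mean"], "mean")
                sds[tracer] = _num(row["sd"], "sd")
                ns.add(int(_num(row["n"], "n")))
            except ValueError as exc:
                errors.append(f"source {name!r}, tracer {tracer}: {exc}")
        if len(ns) > 1:
            errors.append(f"source {name!r}: inconsistent n across tracers: {sorted(ns)}")
        if not errors:
            summaries.append(
                SourceSummary(source_name=str(name), means=means, sds=sds, n=ns.pop())
            )
    if errors:
        raise ValidationError(errors)
    return summaries


def write_sources(
    sources: Sequence[SourceSample] | Sequence[SourceSummary], path: str | Path
) -> None:
    if not sources:
        raise ValueError("nothing to write")
    if isinstance(sources[0], SourceSummary):
        rows = [
            {"source_name": s.source_name, "tracer": t, "mean": s.means[t], "sd": s.sds[t], "n": s.n}
            for s in sources
            for t in s.tracers
        ]
        pd.DataFrame(rows, columns=_SUMMARY_SOURCE_COLUMNS).to_csv(path, index=False)
    else:
        rows = [
            {"source_name": s.source_name, "habitat": s.habitat, "d13C": s.d13C, "d15N": s.d15N}
            for s in sources
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def load_tef(path: str | Path) -> list[TEFSpec]:
    """Read a TEF CSV (guild, tracer, mean, sd) into one TEFSpec per guild."""
    df = _read_csv(path)
    missing = [c for c in ("guild", "tracer", "mean", "sd") if c not in df.columns]
    if missing:
        raise SchemaError(f"tef file missing required columns: {missing}")
    specs: list[TEFSpec] = []
    for guild, group in df.groupby("guild", sort=False):
        means = {}
        sds = {}
        for _, row in group.iterrows():
            tracer = str(row["tracer"]).strip()
            means[tracer] = _num(row["mean"], "mean")
            sds[tracer] = _num(row["sd"], "sd")
        specs.append(TEFSpec(guild=_norm_token(guild), means=means, sds=sds))
    return specs


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path} is empty") from None
    if df.empty:
        raise SchemaError(f"{path} has a header but no data rows")
    df.columns = [c.strip() for c in df.columns]
    return df


def _num(value, name: str) -> float:
    s = str(value).strip().replace("−", "-")  # tolerate unicode minus
    if s == "":
        raise ValueError(f"{name} is required but blank")
    try:
        out = float(s)
    except ValueError:
        raise ValueError(f"{name}={value!r} is not numeric") from None
    if not math.isfinite(out):
        raise ValueError(f"{name} must be finite")
    return out


def _opt_num(value, name: str) -> float | None:
    if value is None or str(value).strip() == "":
        return None
    return _num(value, name)
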