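"""Parameter model for the four-state epilepsy adherence cost-effectiveness model.

Domain types for every model input — age-band rate tables, disability
weights, per-state costs, the intervention budget and economic constants —
plus readers/writers for the delimited parameter files and the closed-form
derivations (disability weight → utility, budget total, currency
conversion).

The four health states describe a person already diagnosed with epilepsy:

* ``NONADHERENT`` ("A") — diagnosed, not taking anti-seizure medication;
* ``ADHERENT`` ("B") — diagnosed, on treatment;
* ``REMISSION`` ("C") — off medication and seizure-free for a year;
* ``DEATH`` ("D") — absorbing.

Transition rates are annual probabilities tabulated on age bands, separately
by sex where the source statistics differ by sex.  Two band systems coexist
(a coarse one for epilepsy mortality/remission, a fine demographic one for
background mortality/relapse); they are kept verbatim and resolved per
lookup rather than re-binned.
"""

from __future__ import annotations

import enum
import hashlib
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HealthState",
    "Sex",
    "AgeBand",
    "BandTable",
    "RateTables",
    "DisabilityWeights",
    "UtilitySet",
    "CostBand",
    "CostModel",
    "Thresholds",
    "ParameterSet",
    "ParameterError",
    "STATES",
    "STATE_INDEX",
    "load_parameters",
    "write_parameters",
    "lookup_rate",
    "derive_utilities",
    "total_budget",
    "convert_currency",
    "convert_to_zar",
    "fixture_dir",
    "fixture_checksums",
]


class ParameterError(ValueError):
    """A parameter file or value violates the model's contracts."""


class HealthState(enum.Enum):
    """The four Markov health states."""

    NONADHERENT = "A"
    ADHERENT = "B"
    REMISSION = "C"
    DEATH = "D"


#: Canonical state ordering used by every occupancy vector and matrix.
STATES: tuple[HealthState, ...] = (
    HealthState.NONADHERENT,
    HealthState.ADHERENT,
    HealthState.REMISSION,
    HealthState.DEATH,
)
STATE_INDEX: dict[HealthState, int] = {s: i for i, s in enumerate(STATES)}


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def coerce(cls, value: "Sex | str") -> "Sex":
        if isinstance(value, Sex):
            return value
        return cls(str(value).strip().lower())


@dataclass(frozen=True, order=True)
class AgeBand:
    """Inclusive age band; ``upper is None`` marks an open-ended top band."""

    lower: int
    upper: int | None

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ParameterError(f"age band lower bound must be >= 0, got {self.lower}")
        if self.upper is not None and self.upper < self.lower:
            raise ParameterError(f"age band {self} has upper < lower")

    def contains(self, age: int) -> bool:
        return age >= self.lower and (self.upper is None or age <= self.upper)

    @classmethod
    def parse(cls, text: str) -> "AgeBand":
        text = str(text).strip().replace("‐", "-").replace("–", "-")
        if text.endswith("+"):
            return cls(int(text[:-1]), None)
        m = re.fullmatch(r"(\d+)\s*-\s*(\d+)", text)
        if m:
            return cls(int(m.group(1)), int(m.group(2)))
        if text.isdigit():
            age = int(text)
            return cls(age, age)
        raise ParameterError(f"cannot parse age band {text!r}")

    def __str__(self) -> str:
        if self.upper is None:
            return f"{self.lower}+"
        if self.upper == self.lower:
            return str(self.lower)
        return f"{self.lower}-{self.upper}"


@dataclass(frozen=True)
class BandTable:
    """An age-band → annual-probability map with contiguity validation.

    Lookups above the top band reuse the top band's value (the source
    tables are open-ended at the top).
    """

    name: str
    entries: tuple[tuple[AgeBand, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "entries", tuple(sorted(self.entries, key=lambda e: e[0].lower))
        )

    def validate(self, cover_from: int = 0, cover_to: int = 120) -> None:
        if not self.entries:
            raise ParameterError(f"{self.name}: empty rate table")
        bands = [b for b, _ in self.entries]
        if bands[0].lower > cover_from:
            raise ParameterError(
                f"{self.name}: gap in age bands before {bands[0]} (coverage must start at {cover_from})"
            )
        for prev, nxt in zip(bands, bands[1:]):
            if prev.upper is None:
                raise ParameterError(f"{self.name}: open-ended band {prev} is not last")
            if nxt.lower != prev.upper + 1:
                raise ParameterError(
                    f"{self.name}: gap in age bands between {prev} and {nxt}"
                )
        top = bands[-1]
        if top.upper is not None and top.upper < cover_to:
            raise ParameterError(
                f"{self.name}: gap in age bands above {top} (coverage must reach {cover_to})"
            )
        for band, value in self.entries:
            if not (0.0 <= value <= 1.0):
                raise ParameterError(
                    f"{self.name}: probability {value} for band {band} outside [0, 1]"
                )

    def value_at(self, age: int) -> float:
        if age < 0:
            raise ParameterError(f"{self.name}: negative age {age}")
        for band, value in self.entries:
            if band.contains(age):
                return value
        # above the top band: reuse the top band
        return self.entries[-1][1]

    def bands(self) -> tuple[AgeBand, ...]:
        return tuple(b for b, _ in self.entries)


@dataclass(frozen=True)
class RateTables:
    """All annual transition probabilities of the model.

    ``mortality_nonadherent`` / ``mortality_adherent`` are epilepsy
    mortality by age (2.5× resp. 0.5× the published cohort rate);
    ``remission`` is the annual probability of entering remission from
    either epilepsy state (identical from A and B by assumption), by age
    and sex; ``background_mortality`` applies in remission;  ``relapse``
    is the annual probability of leaving remission back to epilepsy, of
    which ``relapse_split_to_adherent`` returns to the adherent state.
    """

    mortality_nonadherent: BandTable
    mortality_adherent: BandTable
    remission: Mapping[Sex, BandTable]
    background_mortality: Mapping[Sex, BandTable]
    relapse: BandTable
    relapse_split_to_adherent: float = 0.5

    def validate(self) -> None:
        self.mortality_nonadherent.validate()
        self.mortality_adherent.validate()
        self.relapse.validate()
        for sex in Sex:
            if sex not in self.remission or sex not in self.background_mortality:
                raise ParameterError(f"missing {sex.value} column in rate tables")
            self.remission[sex].validate()
            self.background_mortality[sex].validate()
        if not (0.0 <= self.relapse_split_to_adherent <= 1.0):
            raise ParameterError(
                f"relapse_split_to_adherent {self.relapse_split_to_adherent} outside [0, 1]"
            )
        for (band, m_non), (_, m_adh) in zip(
            self.mortality_nonadherent.entries, self.mortality_adherent.entries
        ):
            if m_non < m_adh:
                raise ParameterError(
                    f"band {band}: nonadherent mortality {m_non} < adherent mortality {m_adh}"
                )


_RATE_QUANTITIES = (
    "mortality_nonadherent",
    "mortality_adherent",
    "remission",
    "background_mortality",
    "relapse",
)


def lookup_rate(
    tables: RateTables,
    quantity: str,
    age: int,
    sex: Sex | str | None = None,
) -> float:
    """Annual probability of *quantity* for a person of *age* (and *sex*).

    Ages above the top tabulated band reuse the top band's value.
    """
    if age < 0:
        raise ParameterError(f"negative age {age}")
    if quantity not in _RATE_QUANTITIES:
        raise ParameterError(
            f"unknown rate quantity {quantity!r}; expected one of {_RATE_QUANTITIES}"
        )
    table = getattr(tables, quantity)
    if isinstance(table, Mapping):
        if sex is None:
            raise ParameterError(f"{quantity} is sex-specific; a sex is required")
        table = table[Sex.coerce(sex)]
    return table.value_at(age)


@dataclass(frozen=True)
class DisabilityWeights:
    """GBD disability weights feeding the utility derivation.

    ``adherent_seizure_free_share`` is the fraction of adherent patients
    assumed seizure-free (the rest have reduced seizures), which mixes the
    two treated weights into the adherent-state utility.
    """

    untreated: float = 0.42
    treated_seizure_free: float = 0.072
    treated_with_seizures: float = 0.319
    adherent_seizure_free_share: float = 0.60

    def validate(self) -> None:
        for name in ("untreated", "treated_seizure_free", "treated_with_seizures"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"disability weight {name}={v} outside [0, 1]")
        if not (0.0 <= self.adherent_seizure_free_share <= 1.0):
            raise ParameterError("adherent_seizure_free_share outside [0, 1]")


@dataclass(frozen=True)
class UtilitySet:
    """Per-state health-state utilities on the 0 (dead) – 1 (full health) scale."""

    nonadherent: float
    adherent: float
    remission: float
    death: float = 0.0

    def of(self, state: HealthState) -> float:
        return {
            HealthState.NONADHERENT: self.nonadherent,
            HealthState.ADHERENT: self.adherent,
            HealthState.REMISSION: self.remission,
            HealthState.DEATH: self.death,
        }[state]

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.nonadherent, self.adherent, self.remission, self.death], dtype=float
        )

    def validate(self) -> None:
        for state in STATES:
            u = self.of(state)
            if not (0.0 <= u <= 1.0):
                raise ParameterError(f"utility for {state.name} = {u} outside [0, 1]")
        if self.death != 0.0:
            raise ParameterError("DEATH utility must be 0")


def derive_utilities(dw: DisabilityWeights) -> UtilitySet:
    """Convert disability weights to utilities as ``1 − DW``.

    The adherent state blends the treated-seizure-free and
    treated-with-seizures weights by the assumed seizure-freedom share.
    """
    dw.validate()
    share = dw.adherent_seizure_free_share
    adherent_dw = share * dw.treated_seizure_free + (1.0 - share) * dw.treated_with_seizures
    return UtilitySet(
        nonadherent=1.0 - dw.untreated,
        adherent=1.0 - adherent_dw,
        remission=1.0 - dw.treated_seizure_free,
        death=0.0,
    )


@dataclass(frozen=True)
class CostBand:
    """Annual ZAR cost with its low/high bounds (±15% in the shipped fixture)."""

    central: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.central <= self.high):
            raise ParameterError(
                f"central cost {self.central} outside [{self.low}, {self.high}]"
            )
        if self.low < 0:
            raise ParameterError("costs must be nonnegative")

    def at(self, level: str) -> float:
        try:
            return {"central": self.central, "low": self.low, "high": self.high}[level]
        except KeyError:
            raise ParameterError(f"unknown cost level {level!r}") from None


@dataclass(frozen=True)
class CostModel:
    """Per-state annual costs, the itemized program budget and economic constants."""

    state_cost: Mapping[HealthState, CostBand]
    budget_items: tuple[tuple[str, float], ...]
    exchange_rate_zar_per_intl_dollar: float = 5.39
    gdp_per_capita_intl_dollar: float = 13215.0
    working_days_per_year_for_daily_gdp: int = 365
    # provenance of the epilepsy-mortality tables: multipliers applied to the
    # published cohort mortality for nonadherent and adherent patients
    mortality_multiplier_nonadherent: float = 2.5
    mortality_multiplier_adherent: float = 0.5

    def state_cost_vector(self, level: str = "central") -> np.ndarray:
        return np.array([self.state_cost[s].at(level) for s in STATES], dtype=float)

    def validate(self) -> None:
        for state in STATES:
            if state not in self.state_cost:
                raise ParameterError(f"missing state cost for {state.name}")
        for state in (HealthState.REMISSION, HealthState.DEATH):
            if self.state_cost[state].central != 0.0:
                raise ParameterError(f"{state.name} cost must be 0")
        if self.exchange_rate_zar_per_intl_dollar <= 0:
            raise ParameterError("exchange rate must be positive")
        if self.gdp_per_capita_intl_dollar <= 0:
            raise ParameterError("GDP per capita must be positive")
        if self.working_days_per_year_for_daily_gdp <= 0:
            raise ParameterError("days per year must be a positive integer")

    @property
    def gdp_per_capita_zar(self) -> float:
        return convert_to_zar(self.gdp_per_capita_intl_dollar, self)

    @property
    def gdp_per_capita_zar_per_day(self) -> float:
        return self.gdp_per_capita_zar / self.working_days_per_year_for_daily_gdp


def total_budget(cost: CostModel) -> float:
    """Annual program budget in ZAR — the sum of the itemized budget lines."""
    total = 0.0
    for label, amount in cost.budget_items:
        if amount < 0:
            raise ParameterError(f"budget item {label!r} has negative amount {amount}")
        total += amount
    return total


def convert_currency(amount_zar: float, cost: CostModel) -> float:
    """ZAR → purchasing-power-parity international dollars (full precision)."""
    if cost.exchange_rate_zar_per_intl_dollar <= 0:
        raise ParameterError("exchange rate must be positive")
    return amount_zar / cost.exchange_rate_zar_per_intl_dollar


def convert_to_zar(amount_intl_dollar: float, cost: CostModel) -> float:
    """International dollars → ZAR (full precision)."""
    if cost.exchange_rate_zar_per_intl_dollar <= 0:
        raise ParameterError("exchange rate must be positive")
    return amount_intl_dollar * cost.exchange_rate_zar_per_intl_dollar


@dataclass(frozen=True)
class Thresholds:
    """Cost-effectiveness thresholds in international dollars per QALY."""

    wtp_intl_dollar: float = 2154.0
    gdp_threshold_intl_dollar: float = 13215.0

    def validate(self) -> None:
        if self.wtp_intl_dollar <= 0 or self.gdp_threshold_intl_dollar <= 0:
            raise ParameterError("thresholds must be positive")


@dataclass(frozen=True)
class ParameterSet:
    """The full parameter bundle consumed by the model pipeline."""

    rates: RateTables
    disability_weights: DisabilityWeights
    costs: CostModel
    thresholds: Thresholds

    @property
    def utilities(self) -> UtilitySet:
        return derive_utilities(self.disability_weights)

    def validate(self) -> None:
        self.rates.validate()
        self.disability_weights.validate()
        self.costs.validate()
        self.thresholds.validate()
        self.utilities.validate()


# ---------------------------------------------------------------------------
# file I/O

_EPI_RATES = "epilepsy_rates.tsv"
_BG_RATES = "background_rates.tsv"
_STATE_COSTS = "state_costs.tsv"
_CONFIG = "economics.yaml"


def fixture_dir() -> Path:
    """Directory of the packaged parameter fixture (the published tables)."""
    return Path(str(resources.files("chwcea").joinpath("fixtures")))


def _read_tsv(path: Path, columns: Iterable[str]) -> pd.DataFrame:
    if not path.exists():
        raise ParameterError(f"parameter file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParameterError(f"cannot parse {path.name}: {exc}") from exc
    missing = set(columns) - set(df.columns)
    if missing:
        raise ParameterError(f"{path.name}: missing columns {sorted(missing)}")
    return df


def _to_float(raw: str, path_name: str, row: int, column: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ParameterError(
            f"{path_name}, line {row + 2}, column {column!r}: "
            f"cannot parse {raw!r} as a number"
        ) from None


def _band_table(df: pd.DataFrame, path_name: str, column: str, name: str) -> BandTable:
    entries = []
    for row, (band_text, raw) in enumerate(zip(df["band"], df[column])):
        band = AgeBand.parse(band_text)
        entries.append((band, _to_float(raw, path_name, row, column)))
    return BandTable(name=name, entries=tuple(entries))


def _require(config: Mapping, key: str, where: str):
    if key not in config:
        raise ParameterError(f"{where}: missing required key {key!r}")
    return config[key]


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load and validate a parameter set from a directory of parameter files.

    With no argument, the packaged fixture transcribing the published
    tables is loaded.  The directory must contain ``epilepsy_rates.tsv``
    (band, epilepsy mortality by adherence, remission by sex),
    ``background_rates.tsv`` (band, background mortality by sex, relapse),
    ``state_costs.tsv`` (state, central/low/high annual cost) and
    ``economics.yaml`` (disability weights, budget items, economic
    constants, thresholds); see ``fixtures/config_schema.json`` for the
    config layout.
    """
    directory = fixture_dir() if path is None else Path(path)
    if not directory.is_dir():
        raise ParameterError(f"parameter directory not found: {directory}")

    epi = _read_tsv(
        directory / _EPI_RATES,
        ["band", "mortality_nonadherent", "mortality_adherent", "remission_male", "remission_female"],
    )
    bg = _read_tsv(
        directory / _BG_RATES, ["band", "mortality_male", "mortality_female", "relapse"]
    )
    costs_df = _read_tsv(directory / _STATE_COSTS, ["state", "central", "low", "high"])

    config_path = directory / _CONFIG
    if not config_path.exists():
        raise ParameterError(f"parameter file not found: {config_path}")
    with open(config_path) as fh:
        try:
            config = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ParameterError(f"cannot parse {config_path.name}: {exc}") from exc
    if not isinstance(config, Mapping):
        raise ParameterError(f"{config_path.name}: top level must be a mapping")

    rates = RateTables(
        mortality_nonadherent=_band_table(
            epi, _EPI_RATES, "mortality_nonadherent", "mortality_nonadherent"
        ),
        mortality_adherent=_band_table(
            epi, _EPI_RATES, "mortality_adherent", "mortality_adherent"
        ),
        remission={
            Sex.MALE: _band_table(epi, _EPI_RATES, "remission_male", "remission[male]"),
            Sex.FEMALE: _band_table(epi, _EPI_RATES, "remission_female", "remission[female]"),
        },
        background_mortality={
            Sex.MALE: _band_table(bg, _BG_RATES, "mortality_male", "background_mortality[male]"),
            Sex.FEMALE: _band_table(bg, _BG_RATES, "mortality_female", "background_mortality[female]"),
        },
        relapse=_band_table(bg, _BG_RATES, "relapse", "relapse"),
        relapse_split_to_adherent=float(
            config.get("relapse_split_to_adherent", 0.5)
        ),
    )

    state_cost: dict[HealthState, CostBand] = {}
    for row, rec in costs_df.iterrows():
        try:
            state = HealthState(str(rec["state"]).strip())
        except ValueError:
            raise ParameterError(
                f"{_STATE_COSTS}, line {row + 2}: unknown state {rec['state']!r}"
            ) from None
        state_cost[state] = CostBand(
            central=_to_float(rec["central"], _STATE_COSTS, row, "central"),
            low=_to_float(rec["low"], _STATE_COSTS, row, "low"),
            high=_to_float(rec["high"], _STATE_COSTS, row, "high"),
        )

    dw_cfg = _require(config, "disability_weights", _CONFIG)
    dw = DisabilityWeights(
        untreated=float(_require(dw_cfg, "untreated", "disability_weights")),
        treated_seizure_free=float(_require(dw_cfg, "treated_seizure_free", "disability_weights")),
        treated_with_seizures=float(_require(dw_cfg, "treated_with_seizures", "disability_weights")),
        adherent_seizure_free_share=float(
            _require(dw_cfg, "adherent_seizure_free_share", "disability_weights")
        ),
    )

    econ = _require(config, "economy", _CONFIG)
    budget_cfg = _require(config, "budget_items", _CONFIG)
    if not isinstance(budget_cfg, list):
        raise ParameterError("budget_items must be a list of [label, amount] pairs")
    budget_items = tuple((str(label), float(amount)) for label, amount in budget_cfg)
    cost_model = CostModel(
        state_cost=state_cost,
        budget_items=budget_items,
        exchange_rate_zar_per_intl_dollar=float(
            _require(econ, "exchange_rate_zar_per_intl_dollar", "economy")
        ),
        gdp_per_capita_intl_dollar=float(
            _require(econ, "gdp_per_capita_intl_dollar", "economy")
        ),
        working_days_per_year_for_daily_gdp=int(
            econ.get("working_days_per_year_for_daily_gdp", 365)
        ),
        mortality_multiplier_nonadherent=float(
            econ.get("mortality_multiplier_nonadherent", 2.5)
        ),
        mortality_multiplier_adherent=float(
            econ.get("mortality_multiplier_adherent", 0.5)
        ),
    )

    thr_cfg = _require(config, "thresholds", _CONFIG)
    thresholds = Thresholds(
        wtp_intl_dollar=float(_require(thr_cfg, "wtp_intl_dollar", "thresholds")),
        gdp_threshold_intl_dollar=float(
            _require(thr_cfg, "gdp_threshold_intl_dollar", "thresholds")
        ),
    )

    params = ParameterSet(
        rates=rates, disability_weights=dw, costs=cost_model, thresholds=thresholds
    )
    params.validate()
    return params


def write_parameters(params: ParameterSet, directory: str | Path) -> None:
    """Write a parameter set as the delimited files ``load_parameters`` reads.

    Values round-trip bit-exactly (floats are serialized with ``repr``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rates = params.rates

    epi_rows = []
    for (band, m_non), (_, m_adh), (_, rem_m), (_, rem_f) in zip(
        rates.mortality_nonadherent.entries,
        rates.mortality_adherent.entries,
        rates.remission[Sex.MALE].entries,
        rates.remission[Sex.FEMALE].entries,
    ):
        epi_rows.append((str(band), repr(m_non), repr(m_adh), repr(rem_m), repr(rem_f)))
    _write_tsv(
        directory / _EPI_RATES,
        ["band", "mortality_nonadherent", "mortality_adherent", "remission_male", "remission_female"],
        epi_rows,
    )

    bg_rows = []
    for (band, mm), (_, mf), (_, rel) in zip(
        rates.background_mortality[Sex.MALE].entries,
        rates.background_mortality[Sex.FEMALE].entries,
        rates.relapse.entries,
    ):
        bg_rows.append((str(band), repr(mm), repr(mf), repr(rel)))
    _write_tsv(directory / _BG_RATES, ["band", "mortality_male", "mortality_female", "relapse"], bg_rows)

    cost_rows = [
        (s.value, repr(params.costs.state_cost[s].central), repr(params.costs.state_cost[s].low), repr(params.costs.state_cost[s].high))
        for s in STATES
    ]
    _write_tsv(directory / _STATE_COSTS, ["state", "central", "low", "high"], cost_rows)

    config = {
        "relapse_split_to_adherent": rates.relapse_split_to_adherent,
        "disability_weights": {
            "untreated": params.disability_weights.untreated,
            "treated_seizure_free": params.disability_weights.treated_seizure_free,
            "treated_with_seizures": params.disability_weights.treated_with_seizures,
            "adherent_seizure_free_share": params.disability_weights.adherent_seizure_free_share,
        },
        "budget_items": [[label, amount] for label, amount in params.costs.budget_items],
        "economy": {
            "exchange_rate_zar_per_intl_dollar": params.costs.exchange_rate_zar_per_intl_dollar,
            "gdp_per_capita_intl_dollar": params.costs.gdp_per_capita_intl_dollar,
            "working_days_per_year_for_daily_gdp": params.costs.working_days_per_year_for_daily_gdp,
            "mortality_multiplier_nonadherent": params.costs.mortality_multiplier_nonadherent,
            "mortality_multiplier_adherent": params.costs.mortality_multiplier_adherent,
        },
        "thresholds": {
            "wtp_intl_dollar": params.thresholds.wtp_intl_dollar,
            "gdp_threshold_intl_dollar": params.thresholds.gdp_threshold_intl_dollar,
        },
    }
    with open(directory / _CONFIG, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def _write_tsv(path: Path, header: list[str], rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def fixture_checksums(directory: str | Path | None = None) -> dict[str, str]:
    """SHA-256 of each parameter file, for run logs and reproducibility."""
    directory = fixture_dir() if directory is None else Path(directory)
    sums = {}
    for name in sorted((_EPI_RATES, _BG_RATES, _STATE_COSTS, _CONFIG)):
        p = directory / name
        if p.exists():
            sums[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return sums
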