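"""Capture-mark-recapture data model, readers/writers, and descriptive summaries.

The central container is :class:`EncounterHistorySet`: one row per marked
animal, one 0/1 detection column per annual sampling occasion, plus
per-occasion metadata (calendar year, survey effort in hours, hurricane
flag).  Occasion years may be non-consecutive; the interval structure is
carried explicitly so downstream survival models can exponentiate annual
rates over multi-year gaps.

Also provided here: a MARK-style ``.inp`` writer/reader for interoperability
with classical capture-recapture software, per-year capture summaries
(captures, recaptures, recapture rate, sex composition), and the
body-condition ANCOVA (``log(mass) ~ plastron_length + period``) used to
test whether the length-mass relationship shifted between study periods.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "Occasion",
    "Individual",
    "EncounterHistorySet",
    "CaptureSummary",
    "BodyConditionResult",
    "read_encounter_csv",
    "write_encounter_csv",
    "read_occasions_csv",
    "write_occasions_csv",
    "write_mark_inp",
    "read_mark_inp",
    "summarize",
    "body_condition",
]

FEMALE = "female"
MALE = "male"
_SEXES = (FEMALE, MALE)


class EncounterValidationError(ValueError):
    """Raised when an encounter-history dataset violates its invariants."""


@dataclass(frozen=True)
class Occasion:
    """One annual sampling occasion.

    ``hurricane`` marks occasions at the end of an interval during which a
    hurricane crossed the study site, so the flag is attached to the
    *interval ending* at this occasion when building survival covariates.
    """

    year: int
    effort_hours: float = 0.0
    hurricane: bool = False

    def __post_init__(self) -> None:
        if self.effort_hours < 0:
            raise EncounterValidationError(
                f"effort_hours must be >= 0, got {self.effort_hours} for {self.year}"
            )


@dataclass
class Morphometric:
    """A single morphometric record tied to an occasion index."""

    occasion_index: int
    plastron_length_cm: float
    mass_g: float


@dataclass
class Individual:
    """One marked animal: id, sex, per-occasion 0/1 detections."""

    id: str
    sex: str
    detections: tuple[int, ...]
    morphometrics: list[Morphometric] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise EncounterValidationError(
                f"individual {self.id!r}: unknown sex {self.sex!r}"
            )
        dets = tuple(int(d) for d in self.detections)
        if any(d not in (0, 1) for d in dets):
            raise EncounterValidationError(
                f"individual {self.id!r}: detections must be 0/1"
            )
        if not any(dets):
            raise EncounterValidationError(
                f"individual {self.id!r}: all-zero history (never detected); "
                "conditional-on-first-capture models cannot use it"
            )
        object.__setattr__(self, "detections", dets)

    @property
    def first_detection(self) -> int:
        return self.detections.index(1)

    @property
    def last_detection(self) -> int:
        return len(self.detections) - 1 - self.detections[::-1].index(1)


@dataclass
class EncounterHistorySet:
    """All individuals and occasions of a mark-recapture study."""

    occasions: list[Occasion]
    individuals: list[Individual]

    def __post_init__(self) -> None:
        years = [o.year for o in self.occasions]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise EncounterValidationError(
                f"occasion years must be strictly increasing, got {years}"
            )
        seen: set[str] = set()
        for ind in self.individuals:
            if ind.id in seen:
                raise EncounterValidationError(f"duplicate individual id {ind.id!r}")
            seen.add(ind.id)
            if len(ind.detections) != len(self.occasions):
                raise EncounterValidationError(
                    f"individual {ind.id!r}: {len(ind.detections)} detections "
                    f"for {len(self.occasions)} occasions"
                )

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    @property
    def years(self) -> list[int]:
        return [o.year for o in self.occasions]

    @property
    def interval_lengths(self) -> np.ndarray:
        """Years elapsed between adjacent occasions (>= 1 each)."""
        y = np.asarray(self.years)
        return np.diff(y)

    def detection_matrix(self) -> np.ndarray:
        return np.array([ind.detections for ind in self.individuals], dtype=int)

    def sex_codes(self) -> np.ndarray:
        """0 = female, 1 = male."""
        return np.array([0 if i.sex == FEMALE else 1 for i in self.individuals])


@dataclass
class CaptureSummary:
    """Per-occasion capture tallies (one row per occasion year)."""

    table: pd.DataFrame  # year, captures, new, recaptures, recapture_rate,
    #                      prop_female, effort_hours


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_YEARCOL = re.compile(r"^y(\d{4})$")


def read_occasions_csv(path) -> list[Occasion]:
    """Read occasion metadata CSV with columns ``year,effort_hours,hurricane``."""
    df = pd.read_csv(path)
    required = {"year", "effort_hours", "hurricane"}
    missing = required - set(df.columns)
    if missing:
        raise EncounterValidationError(f"occasion CSV missing columns {sorted(missing)}")
    return [
        Occasion(int(r.year), float(r.effort_hours), bool(int(r.hurricane)))
        for r in df.itertuples()
    ]


def write_occasions_csv(occasions: list[Occasion], path) -> None:
    pd.DataFrame(
        {
            "year": [o.year for o in occasions],
            "effort_hours": [o.effort_hours for o in occasions],
            "hurricane": [int(o.hurricane) for o in occasions],
        }
    ).to_csv(path, index=False)


def read_encounter_csv(path, occasions: list[Occasion] | None = None) -> EncounterHistorySet:
    """Read an encounter-history CSV.

    Layout: ``id,sex,y<year>,...[,pl_cm,mass_g,measure_year]`` with one
    ``y<year>`` detection column per occasion.  When ``occasions`` is not
    supplied, occasions are reconstructed from the year columns with zero
    effort and no hurricane flags (suitable for toy data; pass the metadata
    side-car for real studies).

    Morphometric columns, when present, attach one record per row; repeated
    ids with identical detection histories may be used to carry several
    measurements, but ids must otherwise be unique.
    """
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise EncounterValidationError(f"{path}: empty CSV")
    header = list(rows[0].keys())
    year_cols = [c for c in header if _YEARCOL.match(c)]
    if not year_cols:
        raise EncounterValidationError(f"{path}: no y<year> detection columns found")
    years = [int(_YEARCOL.match(c).group(1)) for c in year_cols]
    if occasions is None:
        occasions = [Occasion(y) for y in years]
    else:
        if [o.year for o in occasions] != years:
            raise EncounterValidationError(
                "occasion metadata years do not match detection columns"
            )
    has_morpho = {"pl_cm", "mass_g", "measure_year"}.issubset(header)

    individuals: dict[str, Individual] = {}
    for i, row in enumerate(rows):
        rid = row["id"]
        dets = []
        for c in year_cols:
            v = (row[c] or "").strip()
            if v not in ("0", "1"):
                raise EncounterValidationError(
                    f"{path}: row {i + 2}, column {c}: bad detection symbol {v!r}"
                )
            dets.append(int(v))
        morpho = []
        if has_morpho and (row["pl_cm"] or "").strip():
            my = int(row["measure_year"])
            if my not in years:
                raise EncounterValidationError(
                    f"{path}: row {i + 2}: measure_year {my} is not an occasion year"
                )
            morpho.append(
                Morphometric(years.index(my), float(row["pl_cm"]), float(row["mass_g"]))
            )
        if rid in individuals:
            prev = individuals[rid]
            if prev.detections != tuple(dets) or prev.sex != row["sex"]:
                raise EncounterValidationError(f"{path}: duplicate id {rid!r}")
            prev.morphometrics.extend(morpho)
        else:
            individuals[rid] = Individual(rid, row["sex"], tuple(dets), morpho)
    return EncounterHistorySet(occasions, list(individuals.values()))


def write_encounter_csv(ehs: EncounterHistorySet, path) -> None:
    """Write the CSV layout accepted by :func:`read_encounter_csv`."""
    year_cols = [f"y{y}" for y in ehs.years]
    fieldnames = ["id", "sex", *year_cols, "pl_cm", "mass_g", "measure_year"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fieldnames)
        w.writeheader()
        for ind in ehs.individuals:
            base = {"id": ind.id, "sex": ind.sex}
            base.update({c: d for c, d in zip(year_cols, ind.detections)})
            if not ind.morphometrics:
                w.writerow({**base, "pl_cm": "", "mass_g": "", "measure_year": ""})
            else:
                for m in ind.morphometrics:
                    w.writerow(
                        {
                            **base,
                            "pl_cm": repr(m.plastron_length_cm),
                            "mass_g": repr(m.mass_g),
                            "measure_year": ehs.years[m.occasion_index],
                        }
                    )


# ---------------------------------------------------------------------------
# MARK INP dialect
# ---------------------------------------------------------------------------


def write_mark_inp(ehs: EncounterHistorySet, path) -> None:
    """Write a MARK-style ``.inp`` file.

    One line per individual: the contiguous 0/1 history then two
    group-frequency columns (females first): ``101 1 0;``.  Occasion years
    and effort are preserved in ``/* */`` header comments so the file round
    trips through :func:`read_mark_inp`.
    """
    with open(path, "w") as fh:
        fh.write("/* terrapop encounter histories */\n")
        fh.write(f"/* years: {' '.join(str(y) for y in ehs.years)} */\n")
        fh.write(
            "/* effort_hours: "
            + " ".join(repr(o.effort_hours) for o in ehs.occasions)
            + " */\n"
        )
        fh.write(
            "/* hurricane: "
            + " ".join(str(int(o.hurricane)) for o in ehs.occasions)
            + " */\n"
        )
        fh.write("/* groups: female male */\n")
        for ind in ehs.individuals:
            hist = "".join(str(d) for d in ind.detections)
            freq = "1 0" if ind.sex == FEMALE else "0 1"
            fh.write(f"/* {ind.id} */ {hist} {freq};\n")


def read_mark_inp(path) -> EncounterHistorySet:
    """Read the dialect produced by :func:`write_mark_inp`."""
    years: list[int] = []
    effort: list[float] = []
    hurr: list[int] = []
    individuals: list[Individual] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            m = re.match(r"^/\* years: (.*) \*/$", line)
            if m:
                years = [int(t) for t in m.group(1).split()]
                continue
            m = re.match(r"^/\* effort_hours: (.*) \*/$", line)
            if m:
                effort = [float(t) for t in m.group(1).split()]
                continue
            m = re.match(r"^/\* hurricane: (.*) \*/$", line)
            if m:
                hurr = [int(t) for t in m.group(1).split()]
                continue
            m = re.match(r"^(?:/\*\s*(?P<id>\S+)\s*\*/\s*)?(?P<hist>[01]+)\s+(?P<f>\d+)\s+(?P<m>\d+);$", line)
            if m:
                sex = FEMALE if int(m.group("f")) > 0 else MALE
                count = int(m.group("f")) + int(m.group("m"))
                rid = m.group("id") or f"ind{len(individuals) + 1}"
                for k in range(count):
                    individuals.append(
                        Individual(
                            rid if count == 1 else f"{rid}.{k + 1}",
                            sex,
                            tuple(int(c) for c in m.group("hist")),
                        )
                    )
    if not years:
        raise EncounterValidationError(f"{path}: missing years header comment")
    if not effort:
        effort = [0.0] * len(years)
    if not hurr:
        hurr = [0] * len(years)
    occ = [Occasion(y, e, bool(h)) for y, e, h in zip(years, effort, hurr)]
    return EncounterHistorySet(occ, individuals)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize(ehs: EncounterHistorySet) -> CaptureSummary:
    """Per-occasion captures, new marks, recaptures and sex composition.

    A capture at occasion *t* is a recapture when the animal has at least
    one earlier detection; otherwise it is a new individual.
    """
    det = ehs.detection_matrix()
    sex = ehs.sex_codes()
    prior = np.zeros_like(det)
    prior[:, 1:] = np.cumsum(det[:, :-1], axis=1)
    cap = det == 1
    recap = cap & (prior > 0)
    captures = cap.sum(axis=0)
    recaptures = recap.sum(axis=0)
    new = captures - recaptures
    females = (cap & (sex[:, None] == 0)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        rate = np.where(captures > 0, recaptures / np.maximum(captures, 1), 0.0)
        propf = np.where(captures > 0, females / np.maximum(captures, 1), np.nan)
    table = pd.DataFrame(
        {
            "year": ehs.years,
            "captures": captures,
            "new": new,
            "recaptures": recaptures,
            "recapture_rate": rate,
            "prop_female": propf,
            "effort_hours": [o.effort_hours for o in ehs.occasions],
        }
    )
    return CaptureSummary(table)


# ---------------------------------------------------------------------------
# Body-condition ANCOVA
# ---------------------------------------------------------------------------


@dataclass
class BodyConditionResult:
    """OLS fits of log(mass) on plastron length with a study-period term.

    ``additive`` is the model log(mass) ~ length + period, ``interaction``
    adds length x period.  ``period_pvalue`` and ``interaction_pvalue`` are
    the two-sided tests of no period shift / no slope change.
    """

    additive: sm.regression.linear_model.RegressionResultsWrapper
    interaction: sm.regression.linear_model.RegressionResultsWrapper
    period_coef: float
    period_se: float
    period_pvalue: float
    interaction_coef: float
    interaction_se: float
    interaction_pvalue: float
    n_before: int
    n_after: int


def body_condition(
    records: pd.DataFrame,
    split_year: int = 2014,
    outlier_abs_resid: float | None = None,
) -> BodyConditionResult:
    """Body-condition ANCOVA: does mass-at-length differ between periods?

    Parameters
    ----------
    records
        DataFrame with columns ``year``, ``pl_cm`` (plastron length, cm),
        ``mass_g`` (mass, g); one row per measurement.
    split_year
        Records with ``year <= split_year`` form the early period.
    outlier_abs_resid
        Optional absolute-residual cutoff (on log-mass scale) for dropping
        gross measurement errors before the final fit; off by default.
    """
    rec = records.copy()
    if (rec["mass_g"] <= 0).any() or (rec["pl_cm"] <= 0).any():
        raise EncounterValidationError("masses and lengths must be positive")
    rec["logmass"] = np.log(rec["mass_g"].astype(float))
    rec["period"] = (rec["year"] > split_year).astype(float)
    n_before = int((rec["period"] == 0).sum())
    n_after = int((rec["period"] == 1).sum())
    if n_before < 3 or n_after < 3:
        raise EncounterValidationError(
            f"need >= 3 records per period, got {n_before} before and "
            f"{n_after} after {split_year}"
        )

    def _fit(df: pd.DataFrame):
        x_add = sm.add_constant(df[["pl_cm", "period"]].to_numpy())
        add = sm.OLS(df["logmass"].to_numpy(), x_add).fit()
        x_int = np.column_stack(
            [x_add, df["pl_cm"].to_numpy() * df["period"].to_numpy()]
        )
        inter = sm.OLS(df["logmass"].to_numpy(), x_int).fit()
        return add, inter

    add, inter = _fit(rec)
    if outlier_abs_resid is not None:
        keep = np.abs(add.resid) <= outlier_abs_resid
        rec = rec.loc[np.asarray(keep)]
        add, inter = _fit(rec)

    return BodyConditionResult(
        additive=add,
        interaction=inter,
        period_coef=float(add.params[2]),
        period_se=float(add.bse[2]),
        period_pvalue=float(add.pvalues[2]),
        interaction_coef=float(inter.params[3]),
        interaction_se=float(inter.bse[3]),
        interaction_pvalue=float(inter.pvalues[3]),
        n_before=n_before,
        n_after=n_after,
    )
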