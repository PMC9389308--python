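"""LMS growth-reference tables: data model, I/O and age interpolation.

A growth reference tabulates, per sex and measure, the distribution of an
anthropometric measurement by age as (L, M, S) triplets.  This module reads
and writes such tables as delimited text, interpolates them at arbitrary
ages (piecewise-linear, knot-exact, no extrapolation), and derives centile
curves from them.  A reduced representation holding only centile curves
(e.g. P3/P50) is supported for references published without L/M/S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lms

__all__ = [
    "MEASURES",
    "SEXES",
    "LMSReference",
    "CentileCurveReference",
    "ReferenceSet",
    "ReferenceValidationError",
    "AgeOutOfRangeError",
    "read_lms_reference",
    "write_lms_reference",
    "centile_curve_from_lms",
]

MEASURES = ("weight", "height", "bmi")  # kg, cm, kg/m^2
SEXES = ("female", "male")

#: accepted spellings in reference files, lower-cased
_SEX_CODES = {
    "f": "female", "female": "female", "2": "female",
    "m": "male", "male": "male", "1": "male",
}


class ReferenceValidationError(ValueError):
    """A reference table violates the LMS invariants (names row/column)."""


class AgeOutOfRangeError(ValueError):
    """Requested age lies outside the tabulated span; no extrapolation."""


def _canonical_sex(value) -> str:
    key = str(value).strip().lower()
    try:
        return _SEX_CODES[key]
    except KeyError:
        raise ReferenceValidationError(f"unrecognized sex code {value!r}") from None


@dataclass(frozen=True)
class LMSReference:
    """One sex's LMS table for one measure.

    ``ages`` must be strictly increasing with at least 2 rows; every M and S
    must be positive.  Interpolation at a tabulated age reproduces the
    tabulated triplet exactly.
    """

    measure: str
    sex: str
    ages: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray
    label: str = "reference"

    def __post_init__(self):
        if self.measure not in MEASURES:
            raise ReferenceValidationError(f"unknown measure {self.measure!r}")
        if self.sex not in SEXES:
            raise ReferenceValidationError(f"unknown sex {self.sex!r}")
        for name in ("ages", "L", "M", "S"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        n = len(self.ages)
        if n < 2:
            raise ReferenceValidationError("reference needs at least 2 rows")
        if any(len(getattr(self, name)) != n for name in ("L", "M", "S")):
            raise ReferenceValidationError("column lengths differ")
        for name in ("ages", "L", "M", "S"):
            col = getattr(self, name)
            bad = np.flatnonzero(~np.isfinite(col))
            if bad.size:
                raise ReferenceValidationError(
                    f"non-finite value in column {name!r} at row {bad[0]}")
        if np.any(np.diff(self.ages) <= 0):
            row = int(np.flatnonzero(np.diff(self.ages) <= 0)[0]) + 1
            raise ReferenceValidationError(f"non-increasing age at row {row}")
        for name in ("M", "S"):
            bad = np.flatnonzero(getattr(self, name) <= 0)
            if bad.size:
                raise ReferenceValidationError(
                    f"non-positive {name} at row {int(bad[0])}")

    @property
    def age_span(self) -> tuple[float, float]:
        return float(self.ages[0]), float(self.ages[-1])

    def contains_age(self, age) -> np.ndarray | bool:
        age = np.asarray(age, dtype=float)
        ok = (age >= self.ages[0]) & (age <= self.ages[-1])
        return ok if ok.ndim else bool(ok)

    def interpolate(self, age):
        """Piecewise-linear (L, M, S) at ``age`` (scalar or array).

        Raises :class:`AgeOutOfRangeError` outside the tabulated span.
        """
        age = np.asarray(age, dtype=float)
        ok = (age >= self.ages[0]) & (age <= self.ages[-1])
        if not np.all(ok):
            lo, hi = self.age_span
            raise AgeOutOfRangeError(
                f"age outside tabulated span [{lo:g}, {hi:g}] "
                f"for {self.label}/{self.measure}/{self.sex}")
        out = tuple(np.interp(age, self.ages, col) for col in (self.L, self.M, self.S))
        if age.ndim == 0:
            return tuple(float(v) for v in out)
        return out

    def to_frame(self) -> pd.DataFrame:
        sex_code = "M" if self.sex == "male" else "F"
        return pd.DataFrame(
            {"sex": sex_code, "age": self.ages, "L": self.L, "M": self.M, "S": self.S}
        )


@dataclass(frozen=True)
class CentileCurveReference:
    """Reduced reference holding only the 3rd and 50th centile curves."""

    measure: str
    sex: str
    ages: np.ndarray
    P3: np.ndarray
    P50: np.ndarray
    label: str = "reference"

    def __post_init__(self):
        for name in ("ages", "P3", "P50"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.ages) < 2:
            raise ReferenceValidationError("centile-curve reference needs at least 2 rows")
        if np.any(np.diff(self.ages) <= 0):
            raise ReferenceValidationError("non-increasing age")
        if np.any(self.P3 >= self.P50):
            row = int(np.flatnonzero(self.P3 >= self.P50)[0])
            raise ReferenceValidationError(f"P3 >= P50 at row {row}")

    def interpolate(self, age):
        age = np.asarray(age, dtype=float)
        if np.any((age < self.ages[0]) | (age > self.ages[-1])):
            raise AgeOutOfRangeError("age outside tabulated span")
        p3 = np.interp(age, self.ages, self.P3)
        p50 = np.interp(age, self.ages, self.P50)
        if age.ndim == 0:
            return float(p3), float(p50)
        return p3, p50


class ReferenceSet:
    """A labelled collection of LMS references keyed by (measure, sex).

    The unit a chart user thinks of as "the growth chart": one reference per
    measure and sex, all from the same source population.
    """

    def __init__(self, references, label: str | None = None):
        self._refs: dict[tuple[str, str], LMSReference] = {}
        labels = set()
        for ref in references:
            key = (ref.measure, ref.sex)
            if key in self._refs:
                raise ReferenceValidationError(f"duplicate reference for {key}")
            self._refs[key] = ref
            labels.add(ref.label)
        if label is None:
            if len(labels) != 1:
                raise ReferenceValidationError(
                    "references carry mixed labels; pass label= explicitly")
            label = labels.pop()
        self.label = label

    def get(self, measure: str, sex: str) -> LMSReference:
        try:
            return self._refs[(measure, sex)]
        except KeyError:
            raise KeyError(
                f"no {measure}/{sex} reference in chart {self.label!r}") from None

    def __contains__(self, key) -> bool:
        return tuple(key) in self._refs

    def __iter__(self):
        return iter(self._refs.values())

    def measures(self):
        return sorted({m for m, _ in self._refs})


def _read_table(path) -> pd.DataFrame:
    # sep=None sniffs comma vs tab
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     skipinitialspace=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def read_lms_reference(path, measure: str, sex: str | None = None,
                       label: str = "reference",
                       column_map: dict[str, str] | None = None,
                       age_in_months: bool = False) -> list[LMSReference]:
    """Read an LMS reference table from delimited text.

    The file needs header columns sex, age, l, m, s (case-insensitive;
    remap via ``column_map``, e.g. ``{"age": "agemos"}``).  A file may hold
    both sexes; pass ``sex`` to keep one.  ``age_in_months`` divides the age
    column by 12.  Returns one :class:`LMSReference` per sex present.
    """
    df = _read_table(path)
    colnames = {k: k for k in ("sex", "age", "l", "m", "s")}
    if column_map:
        colnames.update({k.lower(): v.lower() for k, v in column_map.items()})
    missing = [v for v in colnames.values() if v not in df.columns]
    if missing:
        raise ReferenceValidationError(
            f"missing column(s) {missing} in {path} (have {list(df.columns)})")

    out = []
    df = df.assign(_sex=[_canonical_sex(v) for v in df[colnames["sex"]]])
    wanted = [ _canonical_sex(sex) ] if sex is not None else \
        [s for s in SEXES if s in set(df["_sex"])]
    for sx in wanted:
        sub = df[df["_sex"] == sx]
        if sub.empty:
            raise ReferenceValidationError(f"no rows for sex {sx!r} in {path}")
        cols = {}
        for std, actual in colnames.items():
            if std == "sex":
                continue
            try:
                cols[std] = sub[actual].astype(float).to_numpy()
            except ValueError as exc:
                raise ReferenceValidationError(
                    f"non-numeric cell in column {actual!r}: {exc}") from None
        age = cols["age"] / 12.0 if age_in_months else cols["age"]
        order = np.argsort(age, kind="stable")
        out.append(LMSReference(measure=measure, sex=sx, ages=age[order],
                                L=cols["l"][order], M=cols["m"][order],
                                S=cols["s"][order], label=label))
    return out


def write_lms_reference(path, references) -> None:
    """Write one or more LMSReference objects as a CSV with columns
    sex, age, L, M, S (sex coded F/M)."""
    frames = [ref.to_frame() for ref in references]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def centile_curve_from_lms(ref: LMSReference, p: float) -> pd.DataFrame:
    """Evaluate the reference's ``p``-th centile curve at every tabulated age.

    Returns a frame with columns age and value, where value at each knot is
    ``lms_value(z_p, L, M, S)`` with ``z_p`` the standard-normal quantile of
    ``p/100``.  ``p=50`` reproduces the M column exactly.
    """
    z_p = lms.centile_to_z(p)
    values = lms.lms_value(np.full_like(ref.ages, z_p), ref.L, ref.M, ref.S)
    return pd.DataFrame({"age": ref.ages, "value": values})


def centile_curve_reference_from_lms(ref: LMSReference) -> CentileCurveReference:
    """Build a P3/P50 reduced reference from a full LMS reference."""
    p3 = centile_curve_from_lms(ref, 3.0)["value"].to_numpy()
    p50 = centile_curve_from_lms(ref, 50.0)["value"].to_numpy()
    return CentileCurveReference(measure=ref.measure, sex=ref.sex,
                                 ages=ref.ages.copy(), P3=p3, P50=p50,
                                 label=ref.label)
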