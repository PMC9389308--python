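"""End-to-end dual-chart cohort analysis.

Reads a cohort of measured children, excludes adults, standardizes each
child's weight, height and BMI against two growth charts (a general
population reference and a condition-specific one), classifies every score
into the three screening bands (< 3rd centile, 3rd–97th, > 97th), tabulates
a band x chart x measure contingency table, and compares the two charts
band-by-band with percentage-point differences and chi-squared tests.

Statistical tests (chi-squared, Spearman, Mann-Whitney) are thin,
contract-enforcing wrappers over scipy.stats.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import lms
from .bands import THREE_BAND_ORDER, classify_three, three_band_scheme
from .references import ReferenceSet, _canonical_sex

logger = logging.getLogger(__name__)

__all__ = [
    "ADULT_AGE_CUTOFF",
    "CohortValidationError",
    "load_cohort",
    "exclude_adults",
    "standardize_cohort",
    "band_table",
    "BandTable",
    "ComparisonResult",
    "compare_references",
    "chi_square_test",
    "mcnemar_test",
    "spearman_corr",
    "mann_whitney",
    "lthyroxine_subgroup",
    "report",
    "round_half_up",
]

ADULT_AGE_CUTOFF = 18.0  # pediatric references end at 18; retain age < 18

_MEASURES = ("weight", "height", "bmi")

_OPTIONAL_NUMERIC = ("birth_weight_g", "gestational_age_wk", "breastfed_months",
                     "mother_bmi", "father_bmi")
_OPTIONAL_FLAGS = ("breastfed", "l_thyroxine")


class CohortValidationError(ValueError):
    pass


def round_half_up(x):
    """Round to nearest integer with ties going away from zero.

    Display convention for percentages (so 26.5 -> 27), as opposed to
    numpy's round-half-even.
    """
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return out if out.ndim else float(out)


def _parse_flag(value):
    s = str(value).strip().lower()
    if s in {"1", "true", "yes", "y"}:
        return True
    if s in {"0", "false", "no", "n"}:
        return False
    raise ValueError(f"not a yes/no flag: {value!r}")


def load_cohort(path) -> tuple[pd.DataFrame, list[str]]:
    """Read a cohort table; return (valid records, row error messages).

    Expected delimited-text columns: ``id``, ``sex`` and either
    ``age_years`` or ``birth_date`` + ``exam_date`` (ISO 8601; decimal age
    is the date difference over 365.25), plus ``weight_kg`` and
    ``height_cm``; optional covariates ``birth_weight_g``,
    ``gestational_age_wk``, ``breastfed``, ``breastfed_months``,
    ``l_thyroxine``, ``mother_bmi``, ``father_bmi``.

    Malformed rows are collected (with line numbers) rather than fatal;
    raises :class:`CohortValidationError` only when no row is valid.
    BMI is derived as weight / (height in m)^2.
    """
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str,
                      skipinitialspace=True)
    raw.columns = [c.strip().lower() for c in raw.columns]
    has_age = "age_years" in raw.columns
    has_dates = {"birth_date", "exam_date"} <= set(raw.columns)
    required = {"id", "sex", "weight_kg", "height_cm"}
    missing = required - set(raw.columns)
    if missing or not (has_age or has_dates):
        raise CohortValidationError(
            f"cohort file needs columns {sorted(required)} plus age_years or "
            f"birth_date+exam_date; missing {sorted(missing)}")

    records, errors = [], []
    for i, row in raw.iterrows():
        line = i + 2  # header is line 1
        try:
            rec = {"id": str(row["id"]), "sex": _canonical_sex(row["sex"])}
            if has_age and not pd.isna(row["age_years"]):
                rec["age_years"] = float(row["age_years"])
            else:
                birth = pd.Timestamp(row["birth_date"])
                exam = pd.Timestamp(row["exam_date"])
                rec["age_years"] = (exam - birth).days / 365.25
            if rec["age_years"] < 0:
                raise ValueError("negative age")
            weight = float(row["weight_kg"])
            height = float(row["height_cm"])
            if weight <= 0 or height <= 0:
                raise ValueError("non-positive weight or height")
            rec["weight_kg"] = weight
            rec["height_cm"] = height
            rec["bmi"] = lms.bmi(weight, height / 100.0)
            for col in _OPTIONAL_NUMERIC:
                if col in raw.columns and not pd.isna(row[col]):
                    rec[col] = float(row[col])
            for col in _OPTIONAL_FLAGS:
                if col in raw.columns and not pd.isna(row[col]):
                    rec[col] = _parse_flag(row[col])
            records.append(rec)
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if not records:
        raise CohortValidationError(
            f"no valid rows in {path}: " + "; ".join(errors[:5]))
    cohort = pd.DataFrame.from_records(records)
    for col in _OPTIONAL_FLAGS:
        if col in cohort.columns:
            cohort[col] = cohort[col].astype("boolean")
    if errors:
        logger.warning("%d malformed row(s) in %s", len(errors), path)
    return cohort, errors


def exclude_adults(cohort: pd.DataFrame, cutoff: float = ADULT_AGE_CUTOFF
                   ) -> pd.DataFrame:
    """Retain children below the adult cutoff (age < 18 by default)."""
    keep = cohort["age_years"] < cutoff
    n_excluded = int((~keep).sum())
    if n_excluded:
        frac = n_excluded / len(cohort)
        logger.info("excluded %d adult record(s) (%.1f%%)", n_excluded, 100 * frac)
    return cohort[keep].reset_index(drop=True)


def standardize_cohort(cohort: pd.DataFrame, chart_standard: ReferenceSet,
                       chart_specialized: ReferenceSet) -> pd.DataFrame:
    """Standardize every child against both charts for all three measures.

    Returns a long table with one row per child x measure x chart:
    columns id, sex, age_years, measure, reference, value, z, centile,
    in_range.  Children whose age falls outside a reference's tabulated
    span are flagged ``in_range=False`` (z/centile NaN) for that chart,
    never silently dropped.
    """
    rows = []
    for chart in (chart_standard, chart_specialized):
        for measure in _MEASURES:
            values = {"weight": cohort["weight_kg"],
                      "height": cohort["height_cm"],
                      "bmi": cohort["bmi"]}[measure].to_numpy(dtype=float)
            for sex in ("female", "male"):
                mask = (cohort["sex"] == sex).to_numpy()
                if not mask.any():
                    continue
                ref = chart.get(measure, sex)
                ages = cohort.loc[mask, "age_years"].to_numpy(dtype=float)
                in_range = ref.contains_age(ages)
                z = np.full(ages.shape, np.nan)
                if in_range.any():
                    L, M, S = ref.interpolate(ages[in_range])
                    z[in_range] = lms.lms_z(values[mask][in_range], L, M, S)
                centile = np.where(np.isfinite(z), 100.0 * sps.norm.cdf(z), np.nan)
                sub = pd.DataFrame({
                    "id": cohort.loc[mask, "id"].to_numpy(),
                    "sex": sex,
                    "age_years": ages,
                    "measure": measure,
                    "reference": chart.label,
                    "value": values[mask],
                    "z": z,
                    "centile": centile,
                    "in_range": in_range,
                })
                rows.append(sub)
    out = pd.concat(rows, ignore_index=True)
    n_flagged = int((~out["in_range"]).sum())
    if n_flagged:
        logger.warning("%d child-measure score(s) outside reference span", n_flagged)
    return out.sort_values(["measure", "reference", "id"], kind="stable",
                           ignore_index=True)


@dataclass
class BandTable:
    """Three-band x chart x measure contingency of a standardized cohort.

    ``counts`` is indexed by band (under/norm/over) with one column per
    (measure, reference); ``percentages`` holds 100*count/column-total at
    full precision, ``display`` the same rounded half-up to integers.
    """

    counts: pd.DataFrame
    totals: pd.Series
    reference_labels: tuple[str, str]

    @property
    def percentages(self) -> pd.DataFrame:
        return 100.0 * self.counts / self.totals

    @property
    def display(self) -> pd.DataFrame:
        return self.percentages.apply(round_half_up).astype(int)

    def column(self, measure: str, reference: str) -> tuple[np.ndarray, int]:
        col = self.counts[(measure, reference)]
        return col.to_numpy(), int(self.totals[(measure, reference)])


def band_table(standardized: pd.DataFrame,
               scheme=None,
               reference_labels: tuple[str, str] | None = None) -> BandTable:
    """Tabulate three-band counts per measure and chart.

    Out-of-range scores are excluded from the tallies (they carry no band).
    """
    scheme = scheme or three_band_scheme()
    ok = standardized[standardized["in_range"]].copy()
    ok["band"] = classify_three(ok["z"].to_numpy(), scheme=scheme)
    if reference_labels is None:
        labs = tuple(pd.unique(standardized["reference"]))
        if len(labs) != 2:
            raise ValueError("expected exactly two reference labels, got "
                             f"{labs}; pass reference_labels=")
        reference_labels = labs
    measures = [m for m in _MEASURES if m in set(ok["measure"])]
    cols = {}
    for measure in measures:
        for ref in reference_labels:
            sub = ok[(ok["measure"] == measure) & (ok["reference"] == ref)]
            counts = sub["band"].value_counts()
            cols[(measure, ref)] = [int(counts.get(b, 0)) for b in THREE_BAND_ORDER]
    counts = pd.DataFrame(cols, index=list(THREE_BAND_ORDER))
    counts.columns = pd.MultiIndex.from_tuples(counts.columns,
                                               names=["measure", "reference"])
    return BandTable(counts=counts, totals=counts.sum(axis=0),
                     reference_labels=reference_labels)


def band_table_from_counts(counts_by_measure: dict[str, dict[str, list[int]]],
                           reference_labels: tuple[str, str]) -> BandTable:
    """Build a :class:`BandTable` directly from published band counts.

    ``counts_by_measure[measure][reference]`` is the (under, norm, over)
    count triple.  Used to re-analyze printed contingency tables.
    """
    cols = {}
    for measure, by_ref in counts_by_measure.items():
        for ref in reference_labels:
            triple = by_ref[ref]
            if len(triple) != len(THREE_BAND_ORDER):
                raise ValueError("need one count per band")
            cols[(measure, ref)] = [int(c) for c in triple]
    counts = pd.DataFrame(cols, index=list(THREE_BAND_ORDER))
    counts.columns = pd.MultiIndex.from_tuples(counts.columns,
                                               names=["measure", "reference"])
    return BandTable(counts=counts, totals=counts.sum(axis=0),
                     reference_labels=reference_labels)


def chi_square_test(contingency) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r x c count table.

    No continuity correction (pass the 2x2 through
    :func:`scipy.stats.chi2_contingency` with ``correction=False``).
    Raises on zero row/column margins — collapse categories first.
    """
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or np.any(table < 0) or table.sum() <= 0:
        raise ValueError("need a non-negative 2-D count table with positive total")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row/column margin; collapse categories "
                         "before testing")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def mcnemar_test(n01: int, n10: int) -> tuple[float, int, float]:
    """McNemar test on discordant pair counts (paired alternative to the
    independence chi-squared when the same children are classified under
    both charts).  Without continuity correction."""
    if n01 + n10 == 0:
        raise ValueError("no discordant pairs")
    stat = (n01 - n10) ** 2 / (n01 + n10)
    return float(stat), 1, float(sps.chi2.sf(stat, 1))


@dataclass
class ComparisonResult:
    """Band membership compared between the two charts for one measure."""

    measure: str
    band: str
    count_standard: int
    total_standard: int
    count_specialized: int
    total_specialized: int
    statistic: float | None = None
    df: int | None = None
    p_value: float | None = None
    test: str = "chi2"
    warning: str | None = None

    @property
    def pct_standard(self) -> float:
        return 100.0 * self.count_standard / self.total_standard

    @property
    def pct_specialized(self) -> float:
        return 100.0 * self.count_specialized / self.total_specialized

    @property
    def pp_difference(self) -> float:
        """Percentage-point difference, standard minus specialized."""
        return self.pct_standard - self.pct_specialized

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(pct_standard=self.pct_standard,
                 pct_specialized=self.pct_specialized,
                 pp_difference=self.pp_difference)
        return d


def compare_references(table: BandTable, measure: str, band: str
                       ) -> ComparisonResult:
    """Compare one band's share between the two charts.

    The chi-squared test is run on the 2x2 table (in band / out of band) x
    (standard / specialized chart); degenerate margins skip the test with a
    warning but still report the percentage-point difference.
    """
    if band not in THREE_BAND_ORDER:
        raise ValueError(f"unknown band {band!r}")
    ref_std, ref_spec = table.reference_labels
    counts_std, total_std = table.column(measure, ref_std)
    counts_spec, total_spec = table.column(measure, ref_spec)
    if total_std == 0 or total_spec == 0:
        raise ValueError("empty chart column")
    i = THREE_BAND_ORDER.index(band)
    in_std, in_spec = int(counts_std[i]), int(counts_spec[i])
    result = ComparisonResult(measure=measure, band=band,
                              count_standard=in_std, total_standard=total_std,
                              count_specialized=in_spec,
                              total_specialized=total_spec)
    contingency = [[in_std, total_std - in_std],
                   [in_spec, total_spec - in_spec]]
    try:
        result.statistic, result.df, result.p_value = chi_square_test(contingency)
    except ValueError as exc:
        result.warning = f"test skipped: {exc}"
        logger.warning("%s/%s: %s", measure, band, result.warning)
    return result


def spearman_corr(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Returns NaN (with a warning) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("spearman_corr undefined for a constant vector")
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Returns ``U = min(U_a, U_b)`` with mid-rank ties.  Exact enumeration
    for small tie-free samples (both n <= 20), the tie-corrected normal
    approximation otherwise (scipy's default policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "asymptotic" if (a.size > 20 or b.size > 20 or has_ties) else "exact"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    u = min(u_a, a.size * b.size - u_a)
    return u, float(res.pvalue)


def lthyroxine_subgroup(standardized: pd.DataFrame, cohort: pd.DataFrame,
                        reference: str, measure: str = "height"
                        ) -> ComparisonResult | None:
    """Norm-band share of height scores, L-thyroxine treated vs untreated.

    Children on thyroid hormone replacement cluster more tightly around the
    reference median, so a larger share lands inside the wide 3rd–97th
    centile norm band.  Returns None (with a warning) when either subgroup
    is empty after pairwise deletion of missing flags.
    """
    if "l_thyroxine" not in cohort.columns:
        logger.warning("cohort carries no l_thyroxine flag; subgroup skipped")
        return None
    flags = cohort[["id", "l_thyroxine"]].dropna()
    sub = standardized[(standardized["measure"] == measure)
                       & (standardized["reference"] == reference)
                       & standardized["in_range"]]
    merged = sub.merge(flags, on="id", how="inner")
    treated = merged[merged["l_thyroxine"].astype(bool)]
    untreated = merged[~merged["l_thyroxine"].astype(bool)]
    if treated.empty or untreated.empty:
        logger.warning("empty L-thyroxine subgroup; comparison skipped")
        return None
    in_norm = lambda df: int((classify_three(df["z"].to_numpy()) == "norm").sum())
    result = ComparisonResult(
        measure=measure, band="norm",
        count_standard=in_norm(treated), total_standard=len(treated),
        count_specialized=in_norm(untreated), total_specialized=len(untreated),
        test="chi2_lthyroxine_subgroup")
    contingency = [
        [result.count_standard, result.total_standard - result.count_standard],
        [result.count_specialized,
         result.total_specialized - result.count_specialized]]
    try:
        result.statistic, result.df, result.p_value = chi_square_test(contingency)
    except ValueError as exc:
        result.warning = f"test skipped: {exc}"
    return result


def report(table: BandTable | None, comparisons: list[ComparisonResult],
           n_loaded: int = 0, n_excluded_adults: int = 0,
           seed: int | None = None, config: dict | None = None) -> dict:
    """Assemble the machine-readable run summary.

    Deterministic (sorted keys, plain types) so identical runs serialize
    byte-identically.  An empty analysis yields zero counts and an explicit
    no-data flag.
    """
    summary: dict = {
        "n_loaded": int(n_loaded),
        "n_excluded_adults": int(n_excluded_adults),
        "seed": seed,
        "config": config or {},
        "no_data": table is None or bool((table.totals == 0).all()),
    }
    if table is not None:
        summary["reference_labels"] = list(table.reference_labels)
        summary["band_counts"] = {
            f"{m}:{r}": [int(c) for c in table.counts[(m, r)]]
            for m, r in table.counts.columns
        }
        summary["band_display_pct"] = {
            f"{m}:{r}": [int(c) for c in table.display[(m, r)]]
            for m, r in table.counts.columns
        }
        summary["totals"] = {f"{m}:{r}": int(t)
                             for (m, r), t in table.totals.items()}
    else:
        summary["band_counts"] = {}
    summary["comparisons"] = [c.to_dict() for c in comparisons]
    return summary


def write_report(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_band_table(table: BandTable, path) -> None:
    """Write the contingency as delimited text mirroring the published
    layout: one row per band, 'count (pct)' per measure x chart column."""
    display = table.display
    out = pd.DataFrame(index=table.counts.index)
    for col in table.counts.columns:
        out["_".join(col)] = [f"{c} ({p})" for c, p in
                              zip(table.counts[col], display[col])]
    out.index.name = "band"
    out.to_csv(path, sep="\t")
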