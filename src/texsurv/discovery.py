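"""Optimised-cutoff survival discovery with false-discovery-rate control.

For each candidate marker the cohort is dichotomised at every admissible
threshold (midpoints between consecutive sorted unique marker values,
subject to a group-size floor) and the split with the most significant
log-rank p is kept — an intentionally aggressive search whose type-I
inflation is then handled by Benjamini-Hochberg control at FDR q and by
cutoff-transfer cross-validation (:mod:`texsurv.crossval`).

The module also implements the marker-selection rules used on the ranked
table (balance between the prognostic groups breaking p-value ties, a
median-split robustness check) and the combined two-marker stratum
(subjects adverse on both markers).

`MarkerDiscovery` wraps the whole engine as a model object built from a
cohort DataFrame; its `fit()` returns `DiscoveryResults` carrying the
ranked table, shortlist, cross-validation outcomes, the multivariate Cox
fit and a `summary()` view.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .survival import (
    BinaryGroupHR,
    CoxPH,
    CoxPHResults,
    binary_group_hr,
    logrank_scan,
    logrank_test,
)

__all__ = [
    "CutoffResult",
    "BHTable",
    "CombinedStratum",
    "optimize_cutoff",
    "median_cutoff_check",
    "benjamini_hochberg",
    "select_best_markers",
    "combine_markers",
    "adverse_mask",
    "MarkerDiscovery",
    "DiscoveryResults",
    "detect_marker_columns",
    "format_p",
]

TIME_COL = "time_months"
EVENT_COL = "event"

#: prefixes recognised as marker columns in a cohort table
MARKER_PREFIXES = ("marker_", "ctta_", "pta_", "pet_")


def detect_marker_columns(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if c.startswith(MARKER_PREFIXES)]


def format_p(p: float, floor: float = 1e-4) -> str:
    """Display convention: p-values below 1e-4 print as ``<0.0001``."""
    return "<0.0001" if p < floor else f"{p:.4f}"


@dataclass(frozen=True)
class CutoffResult:
    """One marker's optimised dichotomisation.

    ``direction`` gives the poor-prognosis side in reporting style: the
    poor group is ``marker < cutoff`` when direction is ``"<"``, else
    ``marker >= cutoff``.
    """

    marker: str
    cutoff: float
    direction: str  # "<" or ">="
    n_poor: int
    n_good: int
    chi2: float
    p: float
    median_p: float | None = None

    @property
    def cutoff_display(self) -> str:
        return f"{self.direction} {self.cutoff:.3f}"

    @property
    def balance(self) -> int:
        return abs(self.n_poor - self.n_good)


def adverse_mask(values: np.ndarray, result: CutoffResult) -> np.ndarray:
    """Boolean mask of subjects on the poor-prognosis side of a cutoff."""
    values = np.asarray(values, dtype=float)
    if result.direction == "<":
        return values < result.cutoff
    return values >= result.cutoff


def _analysable(cohort: pd.DataFrame, marker: str):
    """Drop subjects with a missing value for this marker."""
    sub = cohort.loc[cohort[marker].notna(), [TIME_COL, EVENT_COL, marker]]
    return (
        sub[TIME_COL].to_numpy(float),
        sub[EVENT_COL].to_numpy(int),
        sub[marker].to_numpy(float),
    )


def optimize_cutoff(
    cohort: pd.DataFrame, marker: str, min_group_size: int = 2
) -> CutoffResult:
    """Exhaustive optimal-cutpoint search for one marker.

    Candidates are the midpoints between consecutive sorted unique marker
    values whose induced split leaves at least ``min_group_size`` subjects
    on each side.  Both directions are implicit in the two-sided log-rank;
    the poor side is the one with more deaths than expected.  Ties in p
    break toward the most balanced split, then the lower cutoff.
    """
    time, event, values = _analysable(cohort, marker)
    if time.size < 2 * min_group_size:
        raise ValueError(
            f"{marker}: fewer than {2 * min_group_size} subjects with non-missing values"
        )
    if event.sum() < 1:
        raise ValueError(f"{marker}: no events among analysable subjects")
    uniq = np.unique(values)
    if uniq.size < 2:
        raise ValueError(f"{marker}: marker constant, no admissible cutoff")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    below = values[None, :] < candidates[:, None]  # (C, n) "<" side membership
    n_below = below.sum(axis=1)
    ok = (n_below >= min_group_size) & (time.size - n_below >= min_group_size)
    if not ok.any():
        raise ValueError(
            f"{marker}: no cutoff satisfies the group-size floor {min_group_size}"
        )
    candidates, below, n_below = candidates[ok], below[ok], n_below[ok]
    chi2, o_minus_e = logrank_scan(time, event, below)
    # rank: max chi2 (min p), then balanced split, then lower cutoff
    balance = np.abs(2 * n_below - time.size)
    order = np.lexsort((candidates, balance, -np.round(chi2, 10)))
    best = order[0]
    poor_below = o_minus_e[best] > 0  # "<" side saw more deaths than expected
    direction = "<" if poor_below else ">="
    n_b = int(n_below[best])
    n_poor = n_b if poor_below else time.size - n_b
    c = float(chi2[best])
    return CutoffResult(
        marker=marker,
        cutoff=float(candidates[best]),
        direction=direction,
        n_poor=n_poor,
        n_good=time.size - n_poor,
        chi2=c,
        p=float(sps.chi2.sf(c, df=1)) if c > 0 else 1.0,
    )


def median_cutoff_check(cohort: pd.DataFrame, marker: str) -> CutoffResult:
    """Log-rank at the unoptimised median split — the robustness check.

    The split is ``value < median`` versus ``value >= median`` (a subject
    exactly at the median lands on the ``>=`` side); the poor side is
    whichever shows worse survival.  Raises when the marker is constant.
    """
    time, event, values = _analysable(cohort, marker)
    med = float(np.median(values))
    below = values < med
    if not below.any() or below.all():
        raise ValueError(f"{marker}: degenerate median split (constant marker?)")
    lr = logrank_test(time, event, below)
    poor_below = (lr.observed - lr.expected) > 0
    n_b = int(below.sum())
    n_poor = n_b if poor_below else time.size - n_b
    return CutoffResult(
        marker=marker,
        cutoff=med,
        direction="<" if poor_below else ">=",
        n_poor=n_poor,
        n_good=time.size - n_poor,
        chi2=lr.chi2,
        p=lr.p,
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BHTable:
    """Step-up FDR table: markers ranked by raw p with critical values i*q/m."""

    table: pd.DataFrame  # columns: marker, p, rank, critical, significant
    q: float
    m: int

    @property
    def significant(self) -> list[str]:
        return self.table.loc[self.table["significant"], "marker"].tolist()

    def is_significant(self, marker: str) -> bool:
        row = self.table.loc[self.table["marker"] == marker]
        return bool(row["significant"].iloc[0]) if len(row) else False


def benjamini_hochberg(
    raw_p: Sequence[float], q: float = 0.2, markers: Sequence[str] | None = None
) -> BHTable:
    """Benjamini-Hochberg step-up procedure at FDR level q.

    Sorts p ascending (stable for ties), sets critical value i*q/m for
    rank i of m, and flags ranks 1..k where k is the largest rank with
    p <= critical (no rank when none qualifies).
    """
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    names = list(markers) if markers is not None else [f"m{i}" for i in range(p.size)]
    order = np.argsort(p, kind="stable")
    m = p.size
    ranks = np.arange(1, m + 1)
    crit = ranks * q / m
    sorted_p = p[order]
    passing = np.nonzero(sorted_p <= crit)[0]
    k = passing[-1] + 1 if passing.size else 0
    table = pd.DataFrame(
        {
            "marker": [names[i] for i in order],
            "p": sorted_p,
            "rank": ranks,
            "critical": crit,
            "significant": ranks <= k,
        }
    )
    return BHTable(table=table, q=q, m=m)


# ---------------------------------------------------------------------------
# Marker selection and combination
# ---------------------------------------------------------------------------

def select_best_markers(
    cutoff_results: Iterable[CutoffResult],
    bh: BHTable,
    require_median_significant: bool = False,
    median_alpha: float = 0.05,
    tie_decimals: int = 4,
) -> list[tuple[CutoffResult, str]]:
    """Rank BH-significant markers, breaking p ties by group balance.

    Markers whose raw p agree to ``tie_decimals`` decimal places are
    ordered by the balance of their prognostic groups (|n_poor - n_good|
    ascending — a marker splitting 27/39 beats one splitting 6/60 at the
    same p).  When ``require_median_significant`` is set, markers must
    also be significant at the median split (``median_p < median_alpha``)
    to stay on the shortlist.  Returns (result, rationale) pairs; an
    empty input yields an empty shortlist.
    """
    results = [r for r in cutoff_results if bh.is_significant(r.marker)]
    if require_median_significant:
        results = [
            r
            for r in results
            if r.median_p is not None and r.median_p < median_alpha
        ]
    keyed = sorted(
        results,
        key=lambda r: (round(r.p, tie_decimals), r.balance, r.marker),
    )
    shortlist = []
    for r in keyed:
        rationale = (
            f"BH-significant (p={format_p(r.p)}); split {r.n_poor}/{r.n_good} "
            f"(balance {r.balance})"
        )
        if r.median_p is not None:
            rationale += f"; median-split p={format_p(r.median_p)}"
        shortlist.append((r, rationale))
    return shortlist


@dataclass(frozen=True)
class CombinedStratum:
    """Two-marker combination: poor stratum = adverse on BOTH markers."""

    marker_a: str
    marker_b: str
    n_poor: int
    n_good: int
    hr: BinaryGroupHR | None  # None when the poor stratum is empty
    flagged_empty: bool


def combine_markers(
    cohort: pd.DataFrame, result_a: CutoffResult, result_b: CutoffResult
) -> CombinedStratum:
    """Stratify by joint adversity on two discovered cutoffs.

    Subjects adverse on both markers form the poor stratum; everyone else
    (including subjects missing either marker value being treated as
    non-adverse is *not* assumed — rows missing either marker are
    dropped) is good.  An empty poor stratum is flagged, with no HR.
    """
    cols = [TIME_COL, EVENT_COL, result_a.marker, result_b.marker]
    sub = cohort.loc[
        cohort[result_a.marker].notna() & cohort[result_b.marker].notna(), cols
    ]
    poor = adverse_mask(sub[result_a.marker].to_numpy(float), result_a) & adverse_mask(
        sub[result_b.marker].to_numpy(float), result_b
    )
    n_poor = int(poor.sum())
    if n_poor == 0 or n_poor == len(sub):
        return CombinedStratum(
            result_a.marker, result_b.marker, n_poor, len(sub) - n_poor, None, True
        )
    hr = binary_group_hr(
        sub[TIME_COL].to_numpy(float), sub[EVENT_COL].to_numpy(int), poor
    )
    return CombinedStratum(
        result_a.marker, result_b.marker, n_poor, len(sub) - n_poor, hr, False
    )


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class MarkerDiscovery:
    """Optimised-cutoff biomarker discovery on a cohort table.

    Parameters
    ----------
    cohort : DataFrame
        Must contain ``time_months`` (positive), ``event`` (0/1) and one
        column per marker.
    markers : list of str, optional
        Columns to test; defaults to every column starting with one of
        ``marker_``, ``ctta_``, ``pta_``, ``pet_``.
    min_group_size : int
        Group-size floor for admissible cutoffs (default 2 — observed
        discovery tables contain splits as extreme as 2/64).
    fdr_q : float
        Benjamini-Hochberg FDR level (default 0.2).

    Examples
    --------
    >>> from texsurv.synthetic import CohortSpec, gen_cohort
    >>> cohort = gen_cohort(CohortSpec(seed=7), n_null_markers=5)
    >>> res = MarkerDiscovery(cohort).fit(seed=7)
    >>> res.summary()  # doctest: +SKIP
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        markers: Sequence[str] | None = None,
        min_group_size: int = 2,
        fdr_q: float = 0.2,
    ):
        for col in (TIME_COL, EVENT_COL):
            if col not in cohort.columns:
                raise ValueError(f"cohort missing required column {col!r}")
        self.cohort = cohort.reset_index(drop=True)
        self.markers = list(markers) if markers is not None else detect_marker_columns(
            cohort
        )
        if not self.markers:
            raise ValueError("no marker columns found")
        self.min_group_size = min_group_size
        self.fdr_q = fdr_q

    @classmethod
    def from_csv(cls, path, **kwargs) -> "MarkerDiscovery":
        from .synthetic import read_cohort_csv

        return cls(read_cohort_csv(path), **kwargs)

    def fit(
        self,
        cross_validate: bool = True,
        k_folds: int = 3,
        seed: int = 0,
        require_median_significant: bool = False,
        max_multivariate: int = 5,
    ) -> "DiscoveryResults":
        """Run the full discovery cascade.

        Order: per-marker optimised Kaplan-Meier cutoffs -> BH control at
        ``fdr_q`` -> balance/median selection rules -> (optionally)
        k-fold cutoff-transfer cross-validation of the shortlist ->
        multivariate Cox on the CV survivors' dichotomised indicators ->
        combined stratum of the top two survivors.
        """
        from .crossval import CVResult, cv_cutoff_transfer, stratified_folds

        cutoff_results: dict[str, CutoffResult] = {}
        skipped: dict[str, str] = {}
        for marker in self.markers:
            try:
                res = optimize_cutoff(self.cohort, marker, self.min_group_size)
                try:
                    res = dataclasses.replace(
                        res, median_p=median_cutoff_check(self.cohort, marker).p
                    )
                except ValueError:
                    pass
                cutoff_results[marker] = res
            except ValueError as exc:
                skipped[marker] = str(exc)
        if not cutoff_results:
            raise ValueError("no marker admitted an optimised cutoff")

        names = list(cutoff_results)
        bh = benjamini_hochberg(
            [cutoff_results[m].p for m in names], q=self.fdr_q, markers=names
        )
        shortlist = select_best_markers(
            cutoff_results.values(), bh, require_median_significant
        )

        cv_results: dict[str, "CVResult"] = {}
        cv_survivors: list[str] = []
        if cross_validate and shortlist:
            events = self.cohort[EVENT_COL].to_numpy(int)
            folds = stratified_folds(events, k=k_folds, seed=seed)
            for res, _ in shortlist:
                try:
                    cv = cv_cutoff_transfer(
                        self.cohort, res.marker, folds, self.min_group_size
                    )
                except ValueError:
                    continue
                cv_results[res.marker] = cv
                if cv.recombined_p < 0.05:
                    cv_survivors.append(res.marker)
        elif shortlist:
            cv_survivors = [res.marker for res, _ in shortlist]

        cox: CoxPHResults | None = None
        cox_markers = cv_survivors[:max_multivariate]
        if cox_markers:
            X = np.column_stack(
                [
                    adverse_mask(
                        self.cohort[m].to_numpy(float), cutoff_results[m]
                    ).astype(float)
                    for m in cox_markers
                ]
            )
            keep = ~np.isnan(
                np.column_stack([self.cohort[m].to_numpy(float) for m in cox_markers])
            ).any(axis=1)
            try:
                cox = CoxPH(
                    self.cohort.loc[keep, TIME_COL],
                    self.cohort.loc[keep, EVENT_COL],
                    X[keep],
                    names=[f"{m} {cutoff_results[m].cutoff_display}" for m in cox_markers],
                ).fit()
            except ValueError:
                cox = None

        combined: CombinedStratum | None = None
        if len(cox_markers) >= 2:
            combined = combine_markers(
                self.cohort, cutoff_results[cox_markers[0]], cutoff_results[cox_markers[1]]
            )

        return DiscoveryResults(
            model=self,
            cutoff_results=cutoff_results,
            skipped=skipped,
            bh=bh,
            shortlist=shortlist,
            cv_results=cv_results,
            cv_survivors=cv_survivors,
            cox=cox,
            combined=combined,
            seed=seed,
        )


@dataclass
class DiscoveryResults:
    """Everything the discovery cascade produced, with a summary table."""

    model: MarkerDiscovery
    cutoff_results: dict[str, CutoffResult]
    skipped: dict[str, str]
    bh: BHTable
    shortlist: list[tuple[CutoffResult, str]]
    cv_results: dict
    cv_survivors: list[str]
    cox: CoxPHResults | None
    combined: CombinedStratum | None
    seed: int

    def summary(self) -> pd.DataFrame:
        """Ranked discovery table: one row per tested marker.

        Columns mirror the conventional reporting format: cutoff with the
        poor-prognosis direction, group sizes, raw p, BH critical value
        and significance flag.
        """
        rows = []
        for _, bh_row in self.bh.table.iterrows():
            r = self.cutoff_results[bh_row["marker"]]
            rows.append(
                {
                    "marker": r.marker,
                    "cutoff (poor)": r.cutoff_display,
                    "n_poor": r.n_poor,
                    "n_good": r.n_good,
                    "p": format_p(r.p),
                    "BH critical": round(bh_row["critical"], 4),
                    "significant": bool(bh_row["significant"]),
                }
            )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        lines = [
            f"MarkerDiscovery: {len(self.cutoff_results)} markers tested, "
            f"{len(self.bh.significant)} BH-significant at q={self.bh.q}",
            self.summary().to_string(index=False),
        ]
        if self.cv_results:
            lines.append("cross-validation (recombined log-rank p):")
            for m, cv in self.cv_results.items():
                lines.append(f"  {m}: p={format_p(cv.recombined_p)}")
        if self.cox is not None:
            lines.append("multivariate Cox:")
            lines.append(self.cox.summary().to_string())
        if self.combined is not None and self.combined.hr is not None:
            c = self.combined
            lines.append(
                f"combined stratum ({c.marker_a} & {c.marker_b}, "
                f"{c.n_poor}/{c.n_poor + c.n_good} poor): {c.hr}"
            )
        return "\n".join(lines)
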