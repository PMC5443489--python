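"""Windowed differential-methylation analysis around a target CpG.

Given per-donor single-base methylation calls (e.g. pancreatic-islet WGBS)
and donor metadata, this module compares donor groups site by site inside a
genomic window — typically +/-5 kb around a target coordinate.  Per site the
control and case methylation levels (percent) are compared with a
Mann-Whitney U test; the window summary tallies how many sites increased or
decreased (control mean minus case mean), counts significant sites (sDMPs,
nominal p < 0.05), and reports the mean change over the sDMPs with a
percentile-bootstrap confidence interval obtained by resampling donors.

The change convention throughout is **control mean minus case mean**: a
positive change means cases are hypo-methylated relative to controls.

Donor groupings supported: T2D status (non-T2D controls vs T2D cases), age
(young < 40 years vs old >= 40), sex (male vs female), and sex-matched T2D
(controls restricted to the sex of the cases).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "extract_window",
    "site_test",
    "summarize_window",
    "stratify",
    "WindowSummary",
    "parse_window",
]

logger = logging.getLogger(__name__)

#: Largest number of group-label assignments for which the exact
#: Mann-Whitney null distribution is used (no ties); beyond it, or with
#: ties, the normal approximation with tie correction applies.
EXACT_ENUMERATION_LIMIT = 20000


@dataclass
class WindowSummary:
    """Aggregate differential-methylation statistics for one window."""

    chrom: str
    start: int
    end: int
    n_controls: int
    n_cases: int
    n_sites: int
    increased_dmps: int
    decreased_dmps: int
    ties: int
    sdmp_count: int
    mean_change_sdmp: float      # percentage points, control minus case
    mean_change_all: float       # same convention, averaged over every site
    ci_low: float
    ci_high: float
    per_site: pd.DataFrame = None

    def to_row(self) -> dict:
        return {
            "window": f"{self.chrom}:{self.start}-{self.end}",
            "n_controls": self.n_controls,
            "n_cases": self.n_cases,
            "increased_dmps": self.increased_dmps,
            "decreased_dmps": self.decreased_dmps,
            "sdmp_count": self.sdmp_count,
            "mean_change_sdmp": self.mean_change_sdmp,
            "mean_change_all": self.mean_change_all,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def parse_window(spec: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` or ``chrom:center+-half`` window strings."""
    chrom, _, coords = spec.partition(":")
    if not chrom or not coords:
        raise ValueError(f"bad window spec {spec!r}; expected chrom:start-end")
    if "+-" in coords:
        center, half = coords.split("+-")
        c, h = int(center), int(half)
        return chrom, c - h, c + h
    start, end = coords.split("-")
    return chrom, int(start), int(end)


def extract_window(calls: dict[str, pd.DataFrame], chrom: str,
                   start: int, end: int, min_ct: int = 10) -> pd.DataFrame:
    """Site x donor matrix of reliable methylation levels on the percent scale.

    ``calls`` maps donor id -> methratio-style DataFrame.  Coordinates are
    1-based inclusive; both strands of a CpG stay separate rows (indexed by
    (pos, strand)).  Sites where a donor lacks a reliable call get NaN; a
    donor column missing every site is still kept.
    """
    if start > end:
        raise ValueError(f"window start {start} exceeds end {end}")
    columns = {}
    for donor, frame in calls.items():
        sel = frame[(frame["chrom"] == chrom)
                    & (frame["pos"] >= start) & (frame["pos"] <= end)
                    & (frame["eff_ct"] > min_ct)]
        columns[donor] = pd.Series(
            sel["ratio"].to_numpy(dtype=float) * 100.0,
            index=pd.MultiIndex.from_arrays(
                [sel["pos"].to_numpy(), sel["strand"].to_numpy()],
                names=["pos", "strand"]))
    matrix = pd.DataFrame(columns)
    if matrix.empty:
        raise ValueError(f"no reliable calls in {chrom}:{start}-{end}")
    return matrix.sort_index()


def site_test(values_control, values_case) -> tuple[float, bool]:
    """Two-sided Mann-Whitney U p-value for one site.

    Uses the exact permutation null when the data are tie-free and the
    number of distinct group labelings C(n1+n2, n2) is small enough to
    enumerate; otherwise the normal approximation with tie correction.
    Returns ``(p, tie_flag)``; if every value in both groups is identical
    the test is vacuous and p = 1 with the flag set.
    """
    a = np.asarray(values_control, dtype=float)
    b = np.asarray(values_case, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("site_test needs at least one value per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0, True
    has_ties = len(np.unique(pooled)) < pooled.size
    n_assignments = math.comb(a.size + b.size, min(a.size, b.size))
    if not has_ties and n_assignments <= EXACT_ENUMERATION_LIMIT:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0)), has_ties


def _group_columns(matrix: pd.DataFrame, groups) -> tuple[list, list]:
    if isinstance(groups, tuple) and len(groups) == 2:
        controls, cases = list(groups[0]), list(groups[1])
    else:  # mapping donor -> 'control' / 'case'
        controls = [d for d in matrix.columns if groups[d] == "control"]
        cases = [d for d in matrix.columns if groups[d] == "case"]
    if not controls or not cases:
        raise ValueError("both groups need at least one donor")
    missing = [d for d in controls + cases if d not in matrix.columns]
    if missing:
        raise ValueError(f"donor(s) {missing} not in matrix")
    return controls, cases


def summarize_window(matrix: pd.DataFrame, groups, alpha: float = 0.05,
                     n_boot: int = 1000, seed: int = 0,
                     chrom: str = "chr", start: int = None,
                     end: int = None) -> WindowSummary:
    """Tally per-site tests and direction of change over one window.

    Per site, donors with a missing (unreliable) value are dropped from
    that site's test; a site with no donor left in either group is excluded
    from all tallies (logged).  The confidence interval on the mean sDMP
    change is a seeded percentile bootstrap resampling *donors* within each
    group (the sDMP site set stays fixed).
    """
    if matrix.empty:
        raise ValueError("empty window matrix")
    controls, cases = _group_columns(matrix, groups)

    ctrl = matrix[controls].to_numpy(dtype=float)
    case = matrix[cases].to_numpy(dtype=float)

    rows = []
    kept_idx = []
    dropped = 0
    for i in range(matrix.shape[0]):
        a = ctrl[i][~np.isnan(ctrl[i])]
        b = case[i][~np.isnan(case[i])]
        if a.size == 0 or b.size == 0:
            dropped += 1
            continue
        p, tied = site_test(a, b)
        change = a.mean() - b.mean()          # control minus case
        rows.append({"control_mean": a.mean(), "case_mean": b.mean(),
                     "change": change, "p": p, "tie": tied})
        kept_idx.append(matrix.index[i])
    if dropped:
        logger.info("window summary: %d site(s) excluded (no donors in a group)",
                    dropped)
    if not rows:
        raise ValueError("no testable sites in window")
    per_site = pd.DataFrame(rows, index=pd.Index(kept_idx))
    per_site.index.names = matrix.index.names

    increased = int((per_site["change"] > 0).sum())
    decreased = int((per_site["change"] < 0).sum())
    ties = int((per_site["change"] == 0).sum())
    sdmp_mask = per_site["p"] < alpha
    sdmp_count = int(sdmp_mask.sum())

    if sdmp_count > 0:
        mean_change = float(per_site.loc[sdmp_mask, "change"].mean())
        ci_low, ci_high = _bootstrap_ci(
            matrix.loc[per_site.index[sdmp_mask]], controls, cases,
            n_boot=n_boot, seed=seed)
    else:
        mean_change = float("nan")
        ci_low = ci_high = float("nan")

    if start is None:
        positions = [ix[0] if isinstance(ix, tuple) else ix
                     for ix in matrix.index]
        start, end = int(min(positions)), int(max(positions))

    return WindowSummary(
        chrom=chrom, start=start, end=end,
        n_controls=len(controls), n_cases=len(cases),
        n_sites=len(per_site),
        increased_dmps=increased, decreased_dmps=decreased, ties=ties,
        sdmp_count=sdmp_count, mean_change_sdmp=mean_change,
        mean_change_all=float(per_site["change"].mean()),
        ci_low=ci_low, ci_high=ci_high, per_site=per_site)


def _bootstrap_ci(sdmp_matrix: pd.DataFrame, controls, cases,
                  n_boot: int, seed: int,
                  level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap over donors of the mean control-minus-case change."""
    rng = np.random.default_rng(seed)
    ctrl = sdmp_matrix[controls].to_numpy(dtype=float)
    case = sdmp_matrix[cases].to_numpy(dtype=float)
    n_c, n_t = ctrl.shape[1], case.shape[1]
    reps = np.empty(n_boot)
    for r in range(n_boot):
        ci = rng.integers(0, n_c, size=n_c)
        ti = rng.integers(0, n_t, size=n_t)
        with np.errstate(invalid="ignore"):
            change = (np.nanmean(ctrl[:, ci], axis=1)
                      - np.nanmean(case[:, ti], axis=1))
        reps[r] = np.nanmean(change)
    lo = (1.0 - level) / 2.0
    return (float(np.nanquantile(reps, lo)),
            float(np.nanquantile(reps, 1.0 - lo)))


def recount_site_table(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Recompute window tallies from a published per-site table.

    ``table`` needs columns ``control_mean``, ``case_mean`` (percent) and
    ``p``; useful for re-deriving summary counts from a supplementary
    per-site listing.  Change convention is control minus case.
    """
    change = (table["control_mean"] - table["case_mean"]).to_numpy(dtype=float)
    p = table["p"].to_numpy(dtype=float)
    sdmp = p < alpha
    hypo_sdmp = sdmp & (change > 0)
    return {
        "n_sites": int(len(table)),
        "increased_dmps": int((change > 0).sum()),
        "decreased_dmps": int((change < 0).sum()),
        "sdmp_count": int(sdmp.sum()),
        "hypo_sdmp_count": int(hypo_sdmp.sum()),
        "mean_change_sdmp": float(change[sdmp].mean()) if sdmp.any() else float("nan"),
        "mean_change_hypo_sdmp": (float(change[hypo_sdmp].mean())
                                  if hypo_sdmp.any() else float("nan")),
    }


def stratify(donors: pd.DataFrame, scheme: str) -> tuple[list, list]:
    """Split donors into (controls, cases) under a grouping scheme.

    ``donors`` needs columns ``donor_id``, ``age``, ``sex``, ``t2d``.
    Schemes: ``t2d`` (non-T2D vs T2D), ``age`` (young < 40 vs old >= 40),
    ``sex`` (male vs female), ``t2d_sex_matched`` (controls restricted to
    the cases' sex; requires all cases to share one sex).
    """
    d = donors
    if scheme == "t2d":
        return (d.loc[~d["t2d"].astype(bool), "donor_id"].tolist(),
                d.loc[d["t2d"].astype(bool), "donor_id"].tolist())
    if scheme == "age":
        if (d["age"] < 0).any():
            raise ValueError("negative age in donor metadata")
        return (d.loc[d["age"] < 40, "donor_id"].tolist(),
                d.loc[d["age"] >= 40, "donor_id"].tolist())
    if scheme == "sex":
        sex = d["sex"].astype(str).str.lower()
        return (d.loc[sex == "male", "donor_id"].tolist(),
                d.loc[sex == "female", "donor_id"].tolist())
    if scheme == "t2d_sex_matched":
        cases = d[d["t2d"].astype(bool)]
        case_sexes = set(cases["sex"].astype(str).str.lower())
        if len(case_sexes) != 1:
            raise ValueError("sex matching undefined: T2D cases have mixed sex")
        (case_sex,) = case_sexes
        matched = d[d["sex"].astype(str).str.lower() == case_sex]
        return (matched.loc[~matched["t2d"].astype(bool), "donor_id"].tolist(),
                matched.loc[matched["t2d"].astype(bool), "donor_id"].tolist())
    raise ValueError(f"unknown stratification scheme {scheme!r}")
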