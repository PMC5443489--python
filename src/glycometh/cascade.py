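"""Longitudinal DMP discovery cascade for a paired two-timepoint design.

The discovery design samples each subject's blood at two stages (stage 1,
baseline; stage 5, ten-year follow-up), in two case/control subgroups defined
by oral glucose tolerance testing.  Differentially methylated positions
(DMPs) are discovered in three steps per subgroup:

1. *Longitudinal gate* — within each (subgroup, arm), a per-probe two-sided
   paired t-test of stage-5 minus stage-1 beta values flags probes whose
   methylation moved over time (nominal p < alpha; no multiple-testing
   correction, though an FDR column is emitted for information).
2. *Ranking* — probes passing the gate are ranked by the absolute
   case-minus-control mean beta difference at stage 5 and truncated to the
   top k (default 250).
3. *Set algebra* — case-specific DMPs are the case-arm top-k minus the
   control-arm top-k; the subgroup-specific sets are then intersected across
   subgroups to find shared candidates.

Sample sheets are CSVs with columns ``sample_id, subject_id, stage, arm,
subgroup``; ``sample_id`` keys the beta-matrix columns and each subject in a
group must appear at exactly stages 1 and 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "paired_stage_test",
    "select_stage5_dmps",
    "case_specific_dmps",
    "overlap_dmps",
    "annotate_direction",
    "case_control_delta",
    "run_cascade",
    "DmpSet",
    "CascadeResult",
]

SAMPLE_SHEET_COLUMNS = ("sample_id", "subject_id", "stage", "arm", "subgroup")


@dataclass
class DmpSet:
    """Top-k selection for one (subgroup, arm) group."""

    group: tuple[str, str]            # (subgroup, arm)
    table: pd.DataFrame               # selected probes with rank column
    k: int
    alpha: float

    @property
    def probes(self) -> set[str]:
        return set(self.table.index)


@dataclass
class CascadeResult:
    """Full cascade output: per-group tests, selections, set algebra."""

    tests: dict[tuple[str, str], pd.DataFrame]
    selections: dict[tuple[str, str], DmpSet]
    case_specific: dict[str, set[str]]
    overlap: list[str]
    summary: pd.DataFrame = field(default=None)


def _check_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample sheet missing required column(s): {missing}")
    out = samples.copy()
    out["stage"] = out["stage"].astype(int)
    return out


def paired_stage_test(beta: pd.DataFrame, samples: pd.DataFrame,
                      subgroup: str, arm: str) -> pd.DataFrame:
    """Per-probe paired t-test of stage-5 vs stage-1 beta within one group.

    Returns a DataFrame indexed by probe with columns ``p_value``,
    ``delta_stage`` (mean stage-5 minus stage-1 beta) and ``degenerate``
    (True where the per-subject differences have zero variance, in which
    case ``p_value`` is NaN).

    Raises if any subject in the group lacks one of the two stages.
    """
    samples = _check_sample_sheet(samples)
    grp = samples[(samples["subgroup"] == subgroup) & (samples["arm"] == arm)]
    if grp.empty:
        raise ValueError(f"no samples for subgroup={subgroup!r} arm={arm!r}")

    by_subject = grp.pivot_table(index="subject_id", columns="stage",
                                 values="sample_id", aggfunc="first")
    for stage in (1, 5):
        if stage not in by_subject.columns or by_subject[stage].isna().any():
            bad = (by_subject.index.tolist() if stage not in by_subject.columns
                   else by_subject.index[by_subject[stage].isna()].tolist())
            raise ValueError(
                f"subject(s) {bad} in ({subgroup}, {arm}) lack a stage-{stage} sample")

    s1 = beta[by_subject[1].tolist()].to_numpy(dtype=float)
    s5 = beta[by_subject[5].tolist()].to_numpy(dtype=float)
    diffs = s5 - s1                                   # probes x subjects
    n = diffs.shape[1]
    if n < 2:
        raise ValueError("paired test needs at least two subjects")

    dbar = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = dbar / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(degenerate, np.nan, p)

    return pd.DataFrame(
        {"p_value": p, "delta_stage": dbar, "t": t, "degenerate": degenerate},
        index=beta.index)


def case_control_delta(beta: pd.DataFrame, samples: pd.DataFrame,
                       subgroup: str, stage: int = 5) -> pd.Series:
    """Per-probe case-minus-control mean beta at the given stage."""
    samples = _check_sample_sheet(samples)
    sel = samples[(samples["subgroup"] == subgroup) & (samples["stage"] == stage)]
    case_cols = sel.loc[sel["arm"] == "case", "sample_id"].tolist()
    ctrl_cols = sel.loc[sel["arm"] == "control", "sample_id"].tolist()
    if not case_cols or not ctrl_cols:
        raise ValueError(f"subgroup {subgroup!r} lacks case or control samples "
                         f"at stage {stage}")
    delta = beta[case_cols].mean(axis=1) - beta[ctrl_cols].mean(axis=1)
    delta.name = "delta_case_control"
    return delta


def select_stage5_dmps(results: pd.DataFrame, delta_cc: pd.Series,
                       group: tuple[str, str], k: int = 250,
                       alpha: float = 0.05) -> DmpSet:
    """Gate on paired-test p < alpha, rank by \\|case-control delta\\|, keep top k.

    Tie-break is deterministic: absolute delta descending, then p ascending,
    then probe id lexicographic.  Degenerate probes (NaN p) never pass the
    gate.  An FDR (Benjamini-Hochberg) column is attached for information;
    selection uses nominal p only.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if results.empty:
        raise ValueError("empty test results")
    tab = results.join(delta_cc)
    ok = tab["p_value"].notna()
    tab = tab.loc[ok].copy()
    tab["fdr"] = multipletests(tab["p_value"].to_numpy(), method="fdr_bh")[1]
    passed = tab[tab["p_value"] < alpha].copy()
    passed["abs_delta"] = passed["delta_case_control"].abs()
    passed = passed.sort_values(
        by=["abs_delta", "p_value"],
        ascending=[False, True],
        kind="mergesort",
    )
    # final lexicographic tie-break on probe id
    passed["_pid"] = passed.index
    passed = passed.sort_values(
        by=["abs_delta", "p_value", "_pid"],
        ascending=[False, True, True],
        kind="mergesort").drop(columns="_pid")
    selected = passed.head(k).copy()
    selected["rank"] = np.arange(1, len(selected) + 1)
    selected["direction"] = [annotate_direction(d)
                             for d in selected["delta_case_control"]]
    return DmpSet(group=group, table=selected, k=k, alpha=alpha)


def case_specific_dmps(case_set: DmpSet, control_set: DmpSet) -> set[str]:
    """Probes selected in the case arm but not in the control arm.

    Removing probes that also moved in controls strips age/time effects
    shared by both arms, leaving candidates specific to the case condition.
    """
    if case_set.group[0] != control_set.group[0]:
        raise ValueError("case and control sets must come from the same subgroup")
    return case_set.probes - control_set.probes


def overlap_dmps(set_a, set_b) -> list[str]:
    """Sorted intersection of two probe sets."""
    return sorted(set(set_a) & set(set_b))


def annotate_direction(delta_case_control: float) -> str:
    """``hypo`` if cases are less methylated than controls, ``hyper`` if more,
    ``tie`` at exactly zero."""
    if delta_case_control < 0:
        return "hypo"
    if delta_case_control > 0:
        return "hyper"
    return "tie"


def run_cascade(beta: pd.DataFrame, samples: pd.DataFrame,
                subgroups=None, k: int = 250,
                alpha: float = 0.05) -> CascadeResult:
    """Run the full discovery cascade over every subgroup in the sample sheet.

    Probes with any missing beta in a group's samples are dropped for that
    group (no imputation).  Returns per-group test tables, top-k selections,
    per-subgroup case-specific sets, the cross-subgroup overlap, and a
    summary table of counts per stage.
    """
    samples = _check_sample_sheet(samples)
    if subgroups is None:
        subgroups = sorted(samples["subgroup"].unique())

    tests: dict[tuple[str, str], pd.DataFrame] = {}
    selections: dict[tuple[str, str], DmpSet] = {}
    case_specific: dict[str, set[str]] = {}
    rows = []
    for sg in subgroups:
        delta_cc = case_control_delta(beta, samples, sg, stage=5)
        for arm in ("control", "case"):
            cols = samples.loc[(samples["subgroup"] == sg) &
                               (samples["arm"] == arm), "sample_id"]
            complete = beta[cols].notna().all(axis=1)
            sub_beta = beta.loc[complete]
            res = paired_stage_test(sub_beta, samples, sg, arm)
            tests[(sg, arm)] = res
            selections[(sg, arm)] = select_stage5_dmps(
                res, delta_cc, group=(sg, arm), k=k, alpha=alpha)
        specific = case_specific_dmps(selections[(sg, "case")],
                                      selections[(sg, "control")])
        case_specific[sg] = specific
        rows.append({
            "subgroup": sg,
            "control_stage5_dmps": len(selections[(sg, "control")].table),
            "case_stage5_dmps": len(selections[(sg, "case")].table),
            "case_specific_dmps": len(specific),
        })

    if len(subgroups) >= 2:
        overlap = sorted(set.intersection(*[case_specific[sg] for sg in subgroups]))
    else:
        overlap = sorted(case_specific[subgroups[0]])

    summary = pd.DataFrame(rows).set_index("subgroup")
    summary["overlap_dmps"] = len(overlap)
    return CascadeResult(tests=tests, selections=selections,
                         case_specific=case_specific, overlap=overlap,
                         summary=summary)
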