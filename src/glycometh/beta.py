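"""Infinium-style beta values from methylated/unmethylated fluorescent intensities.

A methylation array probe reports two fluorescent signals per CpG: M from the
methylated allele and U from the unmethylated allele.  After subtracting a
background estimate derived from negative-control probes, the methylation
level is summarised as the beta value

    beta = max(M, 0) / (|U| + |M| + 100)

which lies in [0, 1) for any real intensities; the +100 offset regularises
low-intensity probes.  Values near 0 mean unmethylated, near 1 fully
methylated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "beta_value",
    "subtract_background",
    "beta_matrix_from_intensities",
    "read_beta_matrix",
    "write_beta_matrix",
]

#: Regularising offset in the beta-value denominator (fixed by convention).
BETA_OFFSET = 100.0


def beta_value(M, U):
    """Beta value ``max(M, 0) / (|U| + |M| + 100)``.

    Accepts scalars or array-likes; broadcasting follows numpy rules.  The
    result is always in ``[0, 1)``: a negative M (possible after background
    subtraction) contributes 0 to the numerator but its magnitude still
    appears in the denominator.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    out = np.maximum(M, 0.0) / (np.abs(U) + np.abs(M) + BETA_OFFSET)
    if out.ndim == 0:
        return float(out)
    return out


def subtract_background(intensities: pd.DataFrame, negative_controls,
                        statistic: str = "mean") -> pd.DataFrame:
    """Subtract a background estimate from M and U intensity columns.

    Parameters
    ----------
    intensities
        DataFrame with at least columns ``M`` and ``U`` (one row per probe).
    negative_controls
        Intensities of negative-control probes; the background estimate is
        their mean (or median, per ``statistic``).
    statistic
        ``"mean"`` (default) or ``"median"``.

    Returns a copy with the background removed; corrected intensities may be
    negative, which the beta-value formula tolerates.
    """
    controls = np.asarray(list(negative_controls), dtype=float)
    if controls.size == 0:
        raise ValueError("negative_controls must contain at least one intensity")
    if statistic == "mean":
        bg = float(np.mean(controls))
    elif statistic == "median":
        bg = float(np.median(controls))
    else:
        raise ValueError(f"unknown background statistic: {statistic!r}")
    out = intensities.copy()
    out["M"] = out["M"].astype(float) - bg
    out["U"] = out["U"].astype(float) - bg
    return out


def beta_matrix_from_intensities(per_sample: dict[str, pd.DataFrame],
                                 negative_controls=None,
                                 statistic: str = "mean") -> pd.DataFrame:
    """Build a probe x sample beta matrix from per-sample intensity tables.

    ``per_sample`` maps sample id -> DataFrame with columns ``probe_id``,
    ``M``, ``U``.  If ``negative_controls`` is given (mapping sample id ->
    control intensities, or a single iterable applied to all samples),
    background subtraction is applied first.
    """
    columns = {}
    for sample, table in per_sample.items():
        tab = table
        if negative_controls is not None:
            controls = (negative_controls[sample]
                        if isinstance(negative_controls, dict)
                        else negative_controls)
            tab = subtract_background(tab, controls, statistic=statistic)
        betas = beta_value(tab["M"].to_numpy(), tab["U"].to_numpy())
        columns[sample] = pd.Series(betas, index=tab["probe_id"].to_numpy())
    matrix = pd.DataFrame(columns)
    matrix.index.name = "probe_id"
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated probe ids: {dupes[:5]}")
    return matrix


def write_beta_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a probe x sample beta matrix as TSV (probes as rows)."""
    matrix.to_csv(path, sep="\t", index=True)


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a beta matrix TSV written by :func:`write_beta_matrix`."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    bad = matrix.to_numpy(dtype=float)
    if np.nanmin(bad) < 0 or np.nanmax(bad) > 1:
        raise ValueError(f"beta values outside [0, 1] in {path}")
    return matrix
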