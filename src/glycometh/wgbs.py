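"""Per-cytosine methylation calling from whole-genome bisulfite sequencing.

After bisulfite conversion, an unmethylated cytosine reads as T and a
methylated one as C, so at each reference cytosine the methylation ratio is

    ratio = (# reads showing C) / (effective CT count)

where the effective CT count is the number of reads showing C or T (other
bases are ignored).  A call is *reliable* when the effective CT count is
strictly greater than 10.  Where both mates of a read pair cover the same
position only one mate contributes (mate 1 by default), so a pair is never
double-counted.  Cytosines are classified by sequence context — CG, CHG or
CHH (H = A, C or T) — reading the reference on the strand of the cytosine.

The module starts from per-cytosine count tables (methratio-style TSV) or
from minimal aligned-read records used to exercise the counting rules; it
does not align reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CytosineCall",
    "AlignedReadRecord",
    "classify_context",
    "count_calls",
    "filter_reliable",
    "calls_to_frame",
    "read_methratio",
    "write_methratio",
    "write_bedgraph",
    "RELIABLE_MIN_CT",
]

logger = logging.getLogger(__name__)

#: Minimum effective CT count (exclusive) for a reliable call.
RELIABLE_MIN_CT = 10

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

METHRATIO_COLUMNS = ["chrom", "pos", "strand", "context", "ratio",
                     "eff_ct", "c_count"]


@dataclass(frozen=True)
class CytosineCall:
    """One cytosine's methylation call (1-based coordinate, strand-specific)."""

    chrom: str
    pos: int
    strand: str
    context: str
    c_count: int
    effective_ct_count: int

    def __post_init__(self):
        if self.c_count > self.effective_ct_count:
            raise ValueError(
                f"c_count {self.c_count} exceeds effective CT count "
                f"{self.effective_ct_count} at {self.chrom}:{self.pos}")

    @property
    def ratio(self) -> float:
        if self.effective_ct_count == 0:
            return float("nan")
        return self.c_count / self.effective_ct_count

    @property
    def reliable(self) -> bool:
        return self.effective_ct_count > RELIABLE_MIN_CT


@dataclass
class AlignedReadRecord:
    """Minimal aligned bisulfite read: observed base (C or T) per cytosine site.

    ``bases`` maps 1-based reference position -> observed base.  Mates of a
    pair share ``read_id`` and differ in ``mate`` (1 or 2).
    """

    read_id: str
    mate: int
    chrom: str
    strand: str
    bases: dict[int, str] = field(default_factory=dict)


def classify_context(reference: str, pos: int, strand: str) -> str:
    """Sequence context (CG / CHG / CHH) of the cytosine at 1-based ``pos``.

    On the minus strand the context is read on the reverse complement, i.e.
    moving leftward along the plus-strand sequence with complemented bases.
    Returns ``"undetermined"`` when fewer than two downstream bases exist.
    Raises if the addressed base is not a cytosine on the given strand.
    """
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    i = pos - 1
    if i < 0 or i >= len(reference):
        raise ValueError(f"position {pos} outside reference of length {len(reference)}")

    if strand == "+":
        if reference[i].upper() != "C":
            raise ValueError(f"base at {pos} on + strand is {reference[i]!r}, not C")
        down = [reference[j].upper() for j in (i + 1, i + 2) if j < len(reference)]
    else:
        if reference[i].upper() != "G":  # a G on + is a C on -
            raise ValueError(f"base at {pos} on - strand is "
                             f"{_COMPLEMENT.get(reference[i].upper())!r}, not C")
        down = [_COMPLEMENT[reference[j].upper()] for j in (i - 1, i - 2) if j >= 0]

    if len(down) < 2 and not (down and down[0] == "G"):
        return "undetermined"
    if down[0] == "G":
        return "CG"
    if down[1] == "G":
        return "CHG"
    return "CHH"


def count_calls(reads, reference: str, chrom: str = "chr",
                primary_mate: int = 1) -> list[CytosineCall]:
    """Tally per-cytosine C / effective CT counts from aligned-read records.

    Where both mates of a pair observe the same position, only the
    ``primary_mate`` contributes (single-counting of overlapping mate
    pairs).  Observed bases other than C and T are excluded from the
    effective count.  Pairs whose mates map to different chromosomes are
    skipped with a log entry.

    Each reference cytosine is a strand-specific record: a C on the plus
    strand and the G of the same CpG (a C on the minus strand) are distinct
    calls.
    """
    by_pair: dict[str, list[AlignedReadRecord]] = {}
    for read in reads:
        by_pair.setdefault(read.read_id, []).append(read)

    counts: dict[tuple[int, str], list[int]] = {}   # (pos, strand) -> [c, ct]
    for read_id, mates in by_pair.items():
        chroms = {r.chrom for r in mates}
        if len(chroms) > 1:
            logger.warning("pair %s has mates on different chromosomes %s; skipped",
                           read_id, sorted(chroms))
            continue
        primary = [r for r in mates if r.mate == primary_mate]
        other = [r for r in mates if r.mate != primary_mate]
        primary_positions = {p for r in primary for p in r.bases}
        contributions: list[tuple[int, str, str]] = []
        for r in primary:
            for p, base in r.bases.items():
                contributions.append((p, r.strand, base))
        for r in other:
            for p, base in r.bases.items():
                if p in primary_positions:
                    continue        # overlap: primary mate already counted
                contributions.append((p, r.strand, base))
        for p, strand, base in contributions:
            base = base.upper()
            if base not in ("C", "T"):
                continue
            key = (p, strand)
            cell = counts.setdefault(key, [0, 0])
            cell[1] += 1
            if base == "C":
                cell[0] += 1

    calls = []
    for (p, strand), (c, ct) in sorted(counts.items()):
        context = classify_context(reference, p, strand)
        calls.append(CytosineCall(chrom=chrom, pos=p, strand=strand,
                                  context=context, c_count=c,
                                  effective_ct_count=ct))
    return calls


def filter_reliable(calls, min_ct: int = RELIABLE_MIN_CT):
    """Keep calls with effective CT count strictly greater than ``min_ct``.

    Order-preserving and idempotent.  Works on a list of
    :class:`CytosineCall` or a methratio-style DataFrame.
    """
    if isinstance(calls, pd.DataFrame):
        return calls[calls["eff_ct"] > min_ct].copy()
    return [c for c in calls if c.effective_ct_count > min_ct]


def calls_to_frame(calls) -> pd.DataFrame:
    """Convert CytosineCall records to a methratio-style DataFrame."""
    rows = [{"chrom": c.chrom, "pos": c.pos, "strand": c.strand,
             "context": c.context, "ratio": c.ratio,
             "eff_ct": c.effective_ct_count, "c_count": c.c_count}
            for c in calls]
    return pd.DataFrame(rows, columns=METHRATIO_COLUMNS)


def write_methratio(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, columns=METHRATIO_COLUMNS)


def read_methratio(path) -> pd.DataFrame:
    """Read a per-cytosine TSV (chrom, pos, strand, context, ratio, eff_ct, c_count)."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in METHRATIO_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if (frame["c_count"] > frame["eff_ct"]).any():
        raise ValueError(f"{path}: c_count exceeds eff_ct")
    return frame


def write_bedgraph(frame: pd.DataFrame, path, value_col: str = "ratio") -> None:
    """Export per-cytosine values as bedGraph (0-based half-open intervals)."""
    bed = pd.DataFrame({
        "chrom": frame["chrom"],
        "start": frame["pos"].astype(int) - 1,
        "end": frame["pos"].astype(int),
        "value": frame[value_col],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)
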