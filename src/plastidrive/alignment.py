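"""Aligned plastome handling and window-wise divergence counting.

Chloroplast genomes of seed plants do not measurably recombine, so an
aligned set of plastomes can be scanned with sliding windows and each
window's total sequence divergence from a designated reference treated as
a single linked marker.  This module reads aligned FASTA plus BED
annotations, removes the redundant inverted repeat (IR_A) so that the
duplicated region is not counted twice, segments the ungapped reference
into overlapping windows (default 1 kb windows, 10 bp step), and counts
per-window nucleotide changes (SNPs, insertions and deletions) of every
sample versus the reference.

Conventions
-----------
* All coordinates are 1-based inclusive on the ungapped reference.
  BED input/output converts to/from 0-based half-open at the I/O boundary.
* Changes are counted per alignment column, not per mutational event:
  an n-bp indel contributes n.
* Insertion columns (gap in the reference) are assigned to the reference
  position immediately 5' of the insertion run; insertions before the
  first reference base are assigned position 0 and fall in no window.
* An IUPAC ambiguity code counts as a change only when its base set
  shares no base with the reference column's base set.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "PlastomeAlignment",
    "WindowGrid",
    "DivergenceMatrix",
    "strip_inverted_repeat",
    "segment_reference",
    "count_changes",
    "build_matrix",
    "collapse_windows",
    "intersect_annotations",
    "read_bed",
    "write_bed",
]

GAP = "-"

# IUPAC nucleotide codes -> base sets (N matches everything, so never a change)
_IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


class CoordinateError(ValueError):
    """A genomic interval lies outside the sequence it refers to."""


def _validate_interval(start: int, end: int, length: int, what: str = "interval") -> None:
    if start < 1 or end > length or start > end:
        raise CoordinateError(
            f"{what} [{start}, {end}] out of bounds for length {length}"
        )


@dataclass
class PlastomeAlignment:
    """An equal-length alignment of complete plastomes with one reference.

    Parameters
    ----------
    sample_ids
        Unique identifiers, one per row.
    rows
        Aligned sequences over ``{A, C, G, T, IUPAC ambiguity, -}``, all of
        identical length.
    reference_id
        The sample whose ungapped coordinates define windows and
        annotations.
    annotations
        ``(feature_name, start, end, strand)`` tuples in 1-based inclusive
        ungapped reference coordinates.
    """

    sample_ids: list[str]
    rows: list[str]
    reference_id: str
    annotations: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.rows):
            raise ValueError("sample_ids and rows differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if self.reference_id not in self.sample_ids:
            raise ValueError(f"reference {self.reference_id!r} not among samples")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"aligned rows have unequal lengths: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]
        arr = self._char_matrix()
        if arr.shape[1] and (arr == GAP).all(axis=0).any():
            raise ValueError("alignment contains an all-gap column")
        L = self.reference_length
        for name, start, end, _strand in self.annotations:
            _validate_interval(start, end, L, f"annotation {name!r}")

    def _char_matrix(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows], dtype="U1")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def reference_row(self) -> str:
        return self.rows[self.sample_ids.index(self.reference_id)]

    @property
    def reference_length(self) -> int:
        """Ungapped length of the reference sequence."""
        return len(self.reference_row) - self.reference_row.count(GAP)

    @property
    def non_reference_ids(self) -> list[str]:
        return [s for s in self.sample_ids if s != self.reference_id]

    def row(self, sample_id: str) -> str:
        try:
            return self.rows[self.sample_ids.index(sample_id)]
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    @classmethod
    def from_fasta(
        cls,
        path,
        reference_id: str,
        annotations: list[tuple[str, int, int, str]] | None = None,
    ) -> "PlastomeAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return cls(
            sample_ids=[r.id for r in records],
            rows=[str(r.seq) for r in records],
            reference_id=reference_id,
            annotations=annotations or [],
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.sample_ids, self.rows):
                fh.write(f">{sid}\n")
                for i in range(0, len(row), 70):
                    fh.write(row[i : i + 70] + "\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read BED (0-based half-open) into 1-based inclusive tuples."""
    out: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            chrom_start, chrom_end = int(parts[1]), int(parts[2])
            if chrom_end <= chrom_start:
                raise ValueError(f"empty or inverted BED interval: {line!r}")
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{chrom_start}-{chrom_end}"
            strand = parts[5] if len(parts) > 5 else "+"
            out.append((name, chrom_start + 1, chrom_end, strand))
    return out


def write_bed(path, intervals: list[tuple[str, int, int, str]], chrom: str = "plastome") -> None:
    """Write 1-based inclusive tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for name, start, end, strand in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\t0\t{strand}\n")


def strip_inverted_repeat(sequence: str, ir_interval: tuple[int, int]) -> str:
    """Excise one inverted-repeat copy from an ungapped plastome.

    The plastome carries its large inverted repeat twice; one copy (IR_A)
    is removed before window counting so the duplicated sequence is not
    counted twice.

    Parameters
    ----------
    sequence
        Ungapped plastome sequence.
    ir_interval
        1-based inclusive ``(start, end)`` of the repeat copy to remove.
    """
    start, end = ir_interval
    _validate_interval(start, end, len(sequence), "IR interval")
    return sequence[: start - 1] + sequence[end:]


@dataclass(frozen=True)
class WindowGrid:
    """Sliding windows over the ungapped reference, full windows only.

    Starts are ``1, 1+step, 1+2*step, ...``; the last window is the last
    one that fits entirely, so the window count is
    ``floor((L - w) / s) + 1``.
    """

    window_size: int
    step: int
    reference_length: int
    starts: np.ndarray  # 1-based inclusive window starts

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.window_size - 1

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def windows(self) -> list[tuple[int, int]]:
        return list(zip(self.starts.tolist(), self.ends.tolist()))


def segment_reference(reference_length: int, window_size: int = 1000, step: int = 10) -> WindowGrid:
    """Build the overlapping window grid over the reference.

    Only windows that fit entirely within the reference are emitted (no
    truncated terminal window), so ``n_windows = floor((L - w)/s) + 1``.
    """
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    if window_size > reference_length:
        raise ValueError(
            f"window_size {window_size} exceeds reference length {reference_length}"
        )
    n = (reference_length - window_size) // step + 1
    starts = 1 + step * np.arange(n, dtype=np.int64)
    return WindowGrid(window_size=window_size, step=step,
                      reference_length=reference_length, starts=starts)


def _column_reference_positions(reference_row: str) -> np.ndarray:
    """Map each alignment column to a 1-based ungapped reference position.

    Columns where the reference has a base get that base's position;
    insertion columns (reference gap) get the position of the nearest
    reference base 5' of them (0 before the first base).
    """
    is_base = np.frombuffer(reference_row.encode(), dtype="S1") != GAP.encode()
    return np.cumsum(is_base).astype(np.int64)


def _difference_columns(reference_row: str, sample_row: str) -> np.ndarray:
    """Boolean per-column: does the sample differ from the reference?

    Substitution, deletion (gap in sample) and insertion (gap in
    reference) columns each count; a shared gap does not.  Ambiguity
    codes differ only when the two base sets are disjoint.
    """
    ref = np.array(list(reference_row), dtype="U1")
    smp = np.array(list(sample_row), dtype="U1")
    both_gap = (ref == GAP) & (smp == GAP)
    plain = (ref != smp) & ~both_gap
    # ambiguity rescue: equal-set or overlapping-set codes are not changes
    amb = plain & np.isin(smp, list("RYSWKMBDHVNU")) | plain & np.isin(ref, list("RYSWKMBDHVNU"))
    if amb.any():
        for i in np.nonzero(amb)[0]:
            r, s = ref[i], smp[i]
            if r == GAP or s == GAP:
                continue
            if _IUPAC.get(r, frozenset()) & _IUPAC.get(s, frozenset()):
                plain[i] = False
    return plain


def _per_position_change_counts(alignment: PlastomeAlignment, sample_id: str) -> np.ndarray:
    """Number of differing alignment columns assigned to each reference
    position; index 0 holds insertions 5' of the first reference base."""
    if sample_id == alignment.reference_id:
        raise ValueError("sample must differ from the reference")
    ref_row = alignment.reference_row
    pos = _column_reference_positions(ref_row)
    diff = _difference_columns(ref_row, alignment.row(sample_id))
    L = alignment.reference_length
    return np.bincount(pos[diff], minlength=L + 1)


def count_changes(alignment: PlastomeAlignment, sample_id: str, window: tuple[int, int]) -> int:
    """Count alignment columns in ``window`` where ``sample_id`` differs
    from the reference (SNPs, insertions and deletions, one per column)."""
    start, end = window
    _validate_interval(start, end, alignment.reference_length, "window")
    per_pos = _per_position_change_counts(alignment, sample_id)
    return int(per_pos[start : end + 1].sum())


@dataclass
class DivergenceMatrix:
    """Windows x samples matrix of per-window change counts.

    The reference sample is excluded.  ``collapse_map`` records, after
    :func:`collapse_windows`, which original windows each collapsed row
    merges (keyed by collapsed window id).
    """

    counts: np.ndarray  # (n_windows, n_samples) non-negative ints
    window_ids: list[str]
    starts: np.ndarray
    ends: np.ndarray
    sample_ids: list[str]
    collapsed: bool = False
    collapse_map: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (windows x samples)")
        if (self.counts < 0).any():
            raise ValueError("negative change counts")
        if self.counts.shape != (len(self.window_ids), len(self.sample_ids)):
            raise ValueError("counts shape inconsistent with ids")

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df.insert(0, "window_id", self.window_ids)
        df.insert(1, "start", self.starts)
        df.insert(2, "end", self.ends)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DivergenceMatrix":
        df = pd.read_csv(path, sep="\t")
        meta = ["window_id", "start", "end"]
        samples = [c for c in df.columns if c not in meta]
        return cls(
            counts=df[samples].to_numpy(),
            window_ids=df["window_id"].astype(str).tolist(),
            starts=df["start"].to_numpy(),
            ends=df["end"].to_numpy(),
            sample_ids=samples,
        )


def build_matrix(alignment: PlastomeAlignment, grid: WindowGrid) -> DivergenceMatrix:
    """Count changes of every non-reference sample in every grid window."""
    if grid.reference_length != alignment.reference_length:
        raise ValueError(
            "window grid was built for a different reference length "
            f"({grid.reference_length} != {alignment.reference_length})"
        )
    samples = alignment.non_reference_ids
    n_w = grid.n_windows
    counts = np.zeros((n_w, len(samples)), dtype=np.int64)
    starts, ends = grid.starts, grid.ends
    for j, sid in enumerate(samples):
        per_pos = _per_position_change_counts(alignment, sid)
        cs = np.concatenate([[0], np.cumsum(per_pos[1:])])  # cs[p] = sum positions 1..p
        counts[:, j] = cs[ends] - cs[starts - 1]
    window_ids = [f"w{s}" for s in starts.tolist()]
    return DivergenceMatrix(
        counts=counts, window_ids=window_ids, starts=starts.copy(),
        ends=ends.copy(), sample_ids=list(samples),
    )


def collapse_windows(matrix: DivergenceMatrix) -> DivergenceMatrix:
    """Merge runs of adjacent windows with identical count vectors.

    Adjacent windows sharing an identical count vector carry no extra
    information and would inflate the multiple-testing family, so each
    maximal run becomes a single row spanning the run.
    """
    if matrix.collapsed:
        raise ValueError("matrix is already collapsed")
    if matrix.n_windows == 0:
        return replace(matrix, collapsed=True, collapse_map={})
    change = np.any(matrix.counts[1:] != matrix.counts[:-1], axis=1)
    run_starts = np.concatenate([[0], np.nonzero(change)[0] + 1])
    run_ends = np.concatenate([run_starts[1:] - 1, [matrix.n_windows - 1]])
    collapse_map: dict[str, list[str]] = {}
    ids, starts, ends = [], [], []
    for a, b in zip(run_starts, run_ends):
        cid = matrix.window_ids[a]
        ids.append(cid)
        starts.append(matrix.starts[a])
        ends.append(matrix.ends[b])
        collapse_map[cid] = matrix.window_ids[a : b + 1]
    return DivergenceMatrix(
        counts=matrix.counts[run_starts],
        window_ids=ids,
        starts=np.asarray(starts),
        ends=np.asarray(ends),
        sample_ids=list(matrix.sample_ids),
        collapsed=True,
        collapse_map=collapse_map,
    )


def expand_collapsed(collapsed: DivergenceMatrix, original_grid_ids: list[str]) -> np.ndarray:
    """Reconstruct the original (uncollapsed) count matrix from a collapsed
    one using its collapse map; order follows ``original_grid_ids``."""
    if not collapsed.collapsed or collapsed.collapse_map is None:
        raise ValueError("matrix is not collapsed")
    row_of: dict[str, np.ndarray] = {}
    for i, cid in enumerate(collapsed.window_ids):
        for wid in collapsed.collapse_map[cid]:
            row_of[wid] = collapsed.counts[i]
    return np.vstack([row_of[w] for w in original_grid_ids])


def intersect_annotations(
    windows, annotations: list[tuple[str, int, int, str]]
) -> list[list[str]]:
    """Label each window with the features overlapping it by >= 1 bp.

    ``windows`` is a :class:`WindowGrid`, a :class:`DivergenceMatrix`, or a
    list of ``(start, end)`` intervals.  Windows overlapping no feature are
    labelled ``["intergenic"]``.
    """
    if isinstance(windows, WindowGrid):
        pairs = windows.windows()
    elif isinstance(windows, DivergenceMatrix):
        pairs = list(zip(windows.starts.tolist(), windows.ends.tolist()))
    else:
        pairs = list(windows)
    for name, start, end, _ in annotations:
        if start > end or start < 1:
            raise ValueError(f"malformed annotation interval {name!r}: [{start}, {end}]")
    labels: list[list[str]] = []
    for ws, we in pairs:
        if ws > we:
            raise ValueError(f"malformed window interval [{ws}, {we}]")
        hits = [name for name, fs, fe, _ in annotations if fs <= we and fe >= ws]
        labels.append(hits if hits else ["intergenic"])
    return labels
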