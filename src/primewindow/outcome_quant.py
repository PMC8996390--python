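"""Editing-outcome quantification from amplicon reads, and run-off nick calling.

Read classification (precise / wt / indel / ambiguous) is rule-based:

* *precise*: gap-free alignment to the edited amplicon with at most
  ``max_mismatch`` mismatches AND an exact match over the edit locus
  +- ``flank`` nt;
* *wt*: the symmetric condition against the WT amplicon;
* *indel*: the optimal alignment to either reference contains a gap within
  the edit locus +- flank;
* *ambiguous*: everything else, including empty reads and reads too short
  to cover the edit locus.

These rules are artifact-defined conventions of this package (common
amplicon pipelines differ in detail); they depend on thresholds, not
alignment scores, so labels are stable under aligner substitutions.
Alignment is global with affine gaps (match 2, mismatch -3, open -5,
extend -1) and free reference end gaps so partial-coverage reads align as
an infix.  Reads are tested in both orientations.

Run-off nick calling: each read is anchored in the reference by its first
15 nt, extended as the longest reference-consistent prefix (<= 1 mismatch),
and up to ``max_trim_a`` untemplated terminal A's (an A not matching the
reference at the run-off end, the polymerase A-tailing artifact) are
trimmed; the prefix end gap index is histogrammed and modal offsets are
reported as bp upstream of the PAM start.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import Align, SeqIO

from ._seq import revcomp
from .errors import ConfigError
from .pegrna_design import EditSpec, apply_edit

__all__ = [
    "EfficiencyReport",
    "NickCallResult",
    "AmpliconRefs",
    "classify_read",
    "quantify_amplicon",
    "call_nicks",
    "iter_reads",
]

LABELS = ("precise", "wt", "indel", "ambiguous")


@dataclass(frozen=True)
class EfficiencyReport:
    """Read counts and percentages for one amplicon experiment.

    Percentages are computed over classified (non-ambiguous) reads and sum
    to 100 up to floating-point rounding.
    """

    n_total: int
    n_precise: int
    n_indel: int
    n_wt: int
    n_ambiguous: int

    def __post_init__(self) -> None:
        if self.n_total != self.n_precise + self.n_indel + self.n_wt + self.n_ambiguous:
            raise ValueError("read counts do not sum to n_total")

    @property
    def n_classified(self) -> int:
        return self.n_total - self.n_ambiguous

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.n_classified if self.n_classified else 0.0

    @property
    def precise_pct(self) -> float:
        return self._pct(self.n_precise)

    @property
    def indel_pct(self) -> float:
        return self._pct(self.n_indel)

    @property
    def wt_pct(self) -> float:
        return self._pct(self.n_wt)

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_precise": self.n_precise,
            "n_indel": self.n_indel,
            "n_wt": self.n_wt,
            "n_ambiguous": self.n_ambiguous,
            "precise_pct": self.precise_pct,
            "indel_pct": self.indel_pct,
            "wt_pct": self.wt_pct,
        }


@dataclass(frozen=True)
class NickCallResult:
    """Cut-position histogram from run-off reads.

    ``histogram`` maps cut gap index -> read count; ``modal_offsets`` are the
    most frequent cut positions expressed as bp upstream of the PAM start.
    """

    histogram: dict[int, int]
    modal_offsets: tuple[int, ...]
    n_reads_used: int
    n_unmapped: int

    def offsets_histogram(self, pam_start: int) -> dict[int, int]:
        return {pam_start - gap: n for gap, n in sorted(self.histogram.items())}


# ---------------------------------------------------------------------------
# Read input
# ---------------------------------------------------------------------------

def iter_reads(source) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTA/FASTQ path (gzip ok) or an iterable
    of strings / (id, seq[, qual]) tuples / SeqRecords."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        name = path.name.lower()
        fmt = "fastq" if name.rstrip(".gz").endswith((".fq", ".fastq")) or name.endswith(
            (".fq.gz", ".fastq.gz")
        ) else "fasta"
        opener = gzip.open if name.endswith(".gz") else open
        with opener(path, "rt") as handle:
            for rec in SeqIO.parse(handle, fmt):
                yield rec.id, str(rec.seq)
        return
    for i, item in enumerate(source):
        if isinstance(item, str):
            yield f"read_{i}", item
        elif hasattr(item, "seq") and hasattr(item, "id"):
            yield item.id, str(item.seq)
        else:
            yield str(item[0]), str(item[1])


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    # Reads may cover only part of the amplicon; end overhangs are free.
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # older Biopython naming
        aligner.query_end_gap_score = 0
        aligner.target_end_gap_score = 0
    return aligner


def _infer_edit_spans(wt: str, edited: str) -> tuple[tuple[int, int], tuple[int, int]]:
    """Edit locus as half-open spans in WT and edited coordinates, from the
    longest common prefix/suffix of the two amplicons."""
    lcp = 0
    while lcp < min(len(wt), len(edited)) and wt[lcp] == edited[lcp]:
        lcp += 1
    lcs = 0
    while (
        lcs < min(len(wt), len(edited)) - lcp
        and wt[len(wt) - 1 - lcs] == edited[len(edited) - 1 - lcs]
    ):
        lcs += 1
    return (lcp, len(wt) - lcs), (lcp, len(edited) - lcs)


class AmpliconRefs:
    """Pre-computed reference pair for fast repeated classification."""

    def __init__(
        self,
        wt_amplicon: str,
        edited_amplicon: str,
        edit_span_wt: tuple[int, int] | None = None,
        edit_span_ed: tuple[int, int] | None = None,
    ):
        self.wt = wt_amplicon.upper()
        self.edited = edited_amplicon.upper()
        if edit_span_wt is None or edit_span_ed is None:
            edit_span_wt, edit_span_ed = _infer_edit_spans(self.wt, self.edited)
        self.span_wt = edit_span_wt
        self.span_ed = edit_span_ed
        self._arr = {
            "wt": np.frombuffer(self.wt.encode(), dtype="S1"),
            "edited": np.frombuffer(self.edited.encode(), dtype="S1"),
        }
        self._aligner = _make_aligner()

    def ref(self, kind: str) -> str:
        return self.wt if kind == "wt" else self.edited

    def span(self, kind: str) -> tuple[int, int]:
        return self.span_wt if kind == "wt" else self.span_ed

    def window(self, kind: str, flank: int) -> tuple[int, int]:
        s, e = self.span(kind)
        ref = self.ref(kind)
        return max(0, s - flank), min(len(ref), e + flank)


def _gap_free_label(
    read: str, refs: AmpliconRefs, max_mismatch: int, flank: int
) -> str | None:
    """Equal-length Hamming shortcut: with these affine penalties the optimal
    global alignment of equal-length sequences is gap-free, so a direct
    mismatch count is exact."""
    arr = np.frombuffer(read.encode(), dtype="S1")
    for kind, label in (("edited", "precise"), ("wt", "wt")):
        ref_arr = refs._arr[kind]
        if len(arr) != len(ref_arr):
            continue
        if int((arr != ref_arr).sum()) > max_mismatch:
            continue
        ws, we = refs.window(kind, flank)
        if read[ws:we] == refs.ref(kind)[ws:we]:
            return label
    return None


def _analyze_alignment(aln) -> tuple[list[tuple[int, int]], int, tuple[int, int]]:
    """Internal gaps (as ref-coordinate intervals, zero-length for query
    insertions), mismatch count, and the aligned reference span."""
    t_blocks, q_blocks = aln.aligned
    target, query = str(aln.target), str(aln.query)
    gaps: list[tuple[int, int]] = []
    mismatches = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        seg_t = target[ts:te]
        seg_q = query[qs:qe]
        mismatches += sum(a != b for a, b in zip(seg_t, seg_q))
    for i in range(1, len(t_blocks)):
        t_prev_end, t_next_start = t_blocks[i - 1][1], t_blocks[i][0]
        q_prev_end, q_next_start = q_blocks[i - 1][1], q_blocks[i][0]
        if t_next_start > t_prev_end:  # deletion in read
            gaps.append((t_prev_end, t_next_start))
        if q_next_start > q_prev_end:  # insertion in read, at ref gap position
            gaps.append((t_prev_end, t_prev_end))
    if len(t_blocks) == 0:
        return gaps, mismatches, (0, 0)
    return gaps, mismatches, (t_blocks[0][0], t_blocks[-1][1])


def _classify_by_alignment(
    read: str, refs: AmpliconRefs, max_mismatch: int, flank: int
) -> str:
    analyses = []
    for kind, label in (("edited", "precise"), ("wt", "wt")):
        aln = refs._aligner.align(refs.ref(kind), read)[0]
        gaps, mismatches, (cov_s, cov_e) = _analyze_alignment(aln)
        ws, we = refs.window(kind, flank)
        window_covered = cov_s <= ws and cov_e >= we
        if (
            not gaps
            and mismatches <= max_mismatch
            and window_covered
            and read_window_matches(aln, ws, we)
        ):
            return label
        analyses.append((gaps, ws, we))
    for gaps, ws, we in analyses:
        for gs, ge in gaps:
            if gs <= we and ge >= ws:  # gap interval intersects the edit window
                return "indel"
    return "ambiguous"


def read_window_matches(aln, ws: int, we: int) -> bool:
    """True iff the read matches the reference exactly over ref window [ws, we)."""
    t_blocks, q_blocks = aln.aligned
    target, query = str(aln.target), str(aln.query)
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        lo, hi = max(ts, ws), min(te, we)
        if lo >= hi:
            continue
        if target[lo:hi] != query[qs + (lo - ts) : qs + (hi - ts)]:
            return False
    return True


def classify_read(
    read: str,
    wt_amplicon: str | AmpliconRefs,
    edited_amplicon: str | None = None,
    max_mismatch: int = 5,
    flank: int = 5,
) -> str:
    """Classify one read as precise / wt / indel / ambiguous.

    Deterministic and orientation-invariant: the read and its reverse
    complement receive the same label.  An empty read is 'ambiguous'.
    """
    if isinstance(wt_amplicon, AmpliconRefs):
        refs = wt_amplicon
    else:
        if edited_amplicon is None:
            raise ConfigError("classify_read needs an edited amplicon")
        refs = AmpliconRefs(wt_amplicon, edited_amplicon)
    if flank < 1:
        raise ConfigError(f"flank must be >= 1, got {flank}")
    read = read.upper()
    if not read:
        return "ambiguous"
    # Fast path: gap-free equal-length comparison, both orientations.
    labels = set()
    oriented = (read, revcomp(read))
    for r in oriented:
        lab = _gap_free_label(r, refs, max_mismatch, flank)
        if lab:
            labels.add(lab)
    if labels:
        return "precise" if "precise" in labels else "wt"
    for r in oriented:
        label = _classify_by_alignment(r, refs, max_mismatch, flank)
        if label != "ambiguous":
            return label
    return "ambiguous"


def quantify_amplicon(
    reads,
    wt_amplicon: str,
    edit: EditSpec,
    max_mismatch: int = 5,
    flank: int = 5,
    return_labels: bool = False,
):
    """Classify every read of an amplicon experiment against WT and edited
    references and report precise/indel/WT fractions.

    ``reads`` is a FASTQ/FASTA path or an iterable (see :func:`iter_reads`);
    ``edit`` coordinates are in the amplicon frame.  Returns an
    :class:`EfficiencyReport`, plus per-read ``[(id, label), ...]`` when
    ``return_labels`` is true.
    """
    wt_amplicon = wt_amplicon.upper()
    edited = apply_edit(wt_amplicon, edit)
    span_wt, span_ed = _infer_edit_spans(wt_amplicon, edited)
    if len(wt_amplicon) < (span_wt[1] - span_wt[0]) + 2 * flank:
        raise ConfigError(
            "reference amplicon shorter than the edit locus plus flanks"
        )
    refs = AmpliconRefs(wt_amplicon, edited, span_wt, span_ed)
    counts = {label: 0 for label in LABELS}
    labels: list[tuple[str, str]] = []
    n = 0
    for read_id, seq in iter_reads(reads):
        n += 1
        label = classify_read(seq, refs, max_mismatch=max_mismatch, flank=flank)
        counts[label] += 1
        if return_labels:
            labels.append((read_id, label))
    if n == 0:
        raise ConfigError("no reads supplied")
    report = EfficiencyReport(
        n_total=n,
        n_precise=counts["precise"],
        n_indel=counts["indel"],
        n_wt=counts["wt"],
        n_ambiguous=counts["ambiguous"],
    )
    return (report, labels) if return_labels else report


# ---------------------------------------------------------------------------
# Run-off nick calling
# ---------------------------------------------------------------------------

def call_nicks(
    runoff_reads,
    reference: str,
    pam_start: int,
    max_trim_a: int = 1,
    max_mismatch: int = 1,
    min_anchor: int = 15,
) -> NickCallResult:
    """Histogram run-off read end positions (cut gap indices) on a reference.

    Each read is anchored by exact match of its first ``min_anchor`` nt,
    extended as the longest reference-consistent prefix (``max_mismatch``
    tolerated), then up to ``max_trim_a`` terminal untemplated A's are
    trimmed.  Reads that fail to anchor are counted in ``n_unmapped``.
    ``modal_offsets`` are the histogram maxima as bp upstream of ``pam_start``.
    """
    reference = reference.upper()
    if not (0 <= pam_start <= len(reference)):
        raise ConfigError(f"pam_start {pam_start} outside reference")
    histogram: dict[int, int] = {}
    n_used = 0
    n_unmapped = 0
    for _, seq in iter_reads(runoff_reads):
        seq = seq.upper()
        if len(seq) < min_anchor:
            n_unmapped += 1
            continue
        p0 = reference.find(seq[:min_anchor])
        if p0 < 0:
            n_unmapped += 1
            continue
        mismatches = 0
        i = 0
        while i < len(seq) and p0 + i < len(reference):
            if seq[i] != reference[p0 + i]:
                mismatches += 1
                if mismatches > max_mismatch:
                    break
            i += 1
        prefix_len = i
        trimmed = 0
        while (
            trimmed < max_trim_a
            and prefix_len > 0
            and seq[prefix_len - 1] == "A"
            and reference[p0 + prefix_len - 1] != "A"
        ):
            prefix_len -= 1
            trimmed += 1
        gap = p0 + prefix_len
        histogram[gap] = histogram.get(gap, 0) + 1
        n_used += 1
    if histogram:
        peak = max(histogram.values())
        modal = tuple(
            sorted(pam_start - gap for gap, n in histogram.items() if n == peak)
        )
    else:
        modal = ()
    return NickCallResult(
        histogram=dict(sorted(histogram.items())),
        modal_offsets=modal,
        n_reads_used=n_used,
        n_unmapped=n_unmapped,
    )
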