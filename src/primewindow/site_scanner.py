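"""Genome-wide enumeration of prime-editing target sites.

A *target site* is one PAM occurrence (on either strand) together with its
protospacer, the canonical non-target-strand nick position and the editable
window.  Minus-strand PAMs are found as plus-strand occurrences of the
reverse-complement pattern (e.g. CCN for NGG), so both strands are scanned
in a single pass over the forward sequence.

Sites whose protospacer, PAM or window falls off the contig, or overlaps an
ambiguous base (N), are not reported.  Soft-masked (lowercase) sequence is
treated as uppercase.  Overlapping PAM occurrences are all reported (a GGG
run yields an NGG match at each offset).
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from ._seq import IUPAC_SETS, revcomp_pattern
from .editor_model import (
    EditorProfile,
    nick_gap,
    protospacer_interval,
    window_interval,
)
from .errors import PrimewindowError

__all__ = [
    "TargetSite",
    "scan_contig",
    "scan_genome",
    "sites_to_bed",
    "sites_to_table",
    "read_fasta",
    "normalize_contig_name",
    "DEFAULT_EXCLUDE_ALIASES",
]


@dataclass(frozen=True)
class TargetSite:
    """One PAM occurrence with its derived prime-editing geometry.

    All coordinates are 0-based; intervals half-open; ``nick_gap`` is a gap
    index (between base ``nick_gap - 1`` and ``nick_gap``).
    """

    contig: str
    strand: str
    pam_start: int
    pam_end: int
    protospacer_start: int
    protospacer_end: int
    nick_gap: int
    editable_positions: tuple[int, ...]
    editor: str

    def protospacer_seq(self, contig_seq: str) -> str:
        """Protospacer in guide (strand) orientation."""
        from ._seq import revcomp

        sub = contig_seq[self.protospacer_start : self.protospacer_end].upper()
        return sub if self.strand == "+" else revcomp(sub)


def _pattern_regex(pattern: str) -> re.Pattern:
    # Lookahead so overlapping occurrences are all found.
    body = "".join(
        f"[{IUPAC_SETS[c]}]" if len(IUPAC_SETS[c]) > 1 else IUPAC_SETS[c]
        for c in pattern
    )
    return re.compile(f"(?=({body}))")


def _make_site(
    seq: str, contig: str, profile: EditorProfile, pam_start: int, strand: str
) -> TargetSite | None:
    """Build a TargetSite, or None if it does not fit or overlaps an N."""
    plen = profile.pam.length
    ps_start, ps_end = protospacer_interval(profile, pam_start, strand)
    if ps_start < 0 or ps_end > len(seq):
        return None
    w_start, w_end = window_interval(profile, pam_start, strand)
    if w_start < 0 or w_end > len(seq):  # windows sit inside the protospacer,
        return None                       # but keep the guard for custom profiles
    span_start = min(ps_start, pam_start, w_start)
    span_end = max(ps_end, pam_start + plen, w_end)
    if "N" in seq[span_start:span_end]:
        return None
    return TargetSite(
        contig=contig,
        strand=strand,
        pam_start=pam_start,
        pam_end=pam_start + plen,
        protospacer_start=ps_start,
        protospacer_end=ps_end,
        nick_gap=nick_gap(profile, pam_start, strand),
        editable_positions=tuple(range(w_start, w_end)),
        editor=profile.name,
    )


def scan_contig(
    seq: str, contig_name: str, profile: EditorProfile
) -> Iterator[TargetSite]:
    """Yield every target site of ``profile`` on both strands of one contig.

    Ordering is by ``pam_start``, then strand ('+' before '-').  Empty or
    too-short sequences yield an empty stream (never an error).
    """
    seq_u = str(seq).upper()
    plus_re = _pattern_regex(profile.pam.pattern)
    minus_re = _pattern_regex(revcomp_pattern(profile.pam.pattern))
    sites: list[TargetSite] = []
    for m in plus_re.finditer(seq_u):
        site = _make_site(seq_u, contig_name, profile, m.start(), "+")
        if site is not None:
            sites.append(site)
    for m in minus_re.finditer(seq_u):
        site = _make_site(seq_u, contig_name, profile, m.start(), "-")
        if site is not None:
            sites.append(site)
    sites.sort(key=lambda s: (s.pam_start, s.strand))  # '+' < '-' in ASCII
    yield from sites


# ---------------------------------------------------------------------------
# Genome-level scanning
# ---------------------------------------------------------------------------

# Contig-name dialects treated as the same chromosome for exclusion purposes.
DEFAULT_EXCLUDE_ALIASES: dict[str, str] = {"M": "MT", "CHRM": "MT"}


def normalize_contig_name(name: str) -> str:
    """Normalise a contig name for exclusion matching: chr-prefix and case
    insensitive, with 'M' aliased to 'MT' (so Y/chrY and MT/chrM/chrMT match)."""
    n = name.strip().upper()
    if n.startswith("CHR"):
        n = n[3:]
    return DEFAULT_EXCLUDE_ALIASES.get(n, "MT" if n == "M" else n)


def read_fasta(source: str | Path | Mapping[str, str]) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into {contig: sequence}.

    A mapping passes through unchanged, so in-memory genomes and files are
    interchangeable everywhere in the package.
    """
    if isinstance(source, Mapping):
        return dict(source)
    path = Path(source)
    if not path.exists():
        raise PrimewindowError(f"FASTA not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    try:
        with opener(path, "rt") as handle:
            genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}
    except OSError as exc:
        raise PrimewindowError(f"could not read FASTA {path}: {exc}") from exc
    if len(genome) == 0:
        raise PrimewindowError(f"no FASTA records in {path}")
    return genome


def scan_genome(
    fasta: str | Path | Mapping[str, str],
    profiles: Sequence[EditorProfile] | EditorProfile,
    exclude_contigs: Iterable[str] = (),
) -> tuple[dict[str, list[TargetSite]], pd.DataFrame]:
    """Scan all non-excluded contigs with each profile.

    Returns ``(sites_by_editor, summary)`` where ``summary`` is a tidy
    DataFrame with columns contig, editor, n_sites.  An excluded name absent
    from the FASTA triggers a warning, not an error.
    """
    genome = read_fasta(fasta)
    if isinstance(profiles, EditorProfile):
        profiles = [profiles]
    excluded_norm = {normalize_contig_name(e) for e in exclude_contigs}
    present_norm = {normalize_contig_name(c) for c in genome}
    for name in exclude_contigs:
        if normalize_contig_name(name) not in present_norm:
            warnings.warn(f"excluded contig {name!r} not present in FASTA", stacklevel=2)

    sites_by_editor: dict[str, list[TargetSite]] = {p.name: [] for p in profiles}
    rows = []
    for contig, seq in genome.items():
        skip = normalize_contig_name(contig) in excluded_norm
        for profile in profiles:
            found = [] if skip else list(scan_contig(seq, contig, profile))
            sites_by_editor[profile.name].extend(found)
            rows.append({"contig": contig, "editor": profile.name, "n_sites": len(found)})
    summary = pd.DataFrame(rows, columns=["contig", "editor", "n_sites"])
    return sites_by_editor, summary


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def sites_to_bed(sites: Iterable[TargetSite], what: str = "protospacer") -> list[str]:
    """Render sites as BED6 lines (0-based half-open).

    ``what`` selects the feature: 'protospacer', 'window' (the contiguous
    editable interval) or 'nick' (a zero-length feature at the gap index).
    Name field is ``editor|strand|pam_start``.
    """
    if what not in {"protospacer", "window", "nick"}:
        raise ValueError(f"what must be protospacer/window/nick, got {what!r}")
    lines = []
    for s in sites:
        if what == "protospacer":
            start, end = s.protospacer_start, s.protospacer_end
        elif what == "window":
            start = min(s.editable_positions)
            end = max(s.editable_positions) + 1
        else:
            start = end = s.nick_gap
        name = f"{s.editor}|{s.strand}|{s.pam_start}"
        lines.append(f"{s.contig}\t{start}\t{end}\t{name}\t0\t{s.strand}")
    return lines


def sites_to_table(sites: Iterable[TargetSite]) -> pd.DataFrame:
    """One row per site, with 1-based inclusive display coordinates."""
    rows = []
    for s in sites:
        rows.append(
            {
                "editor": s.editor,
                "contig": s.contig,
                "strand": s.strand,
                "pam_start_1": s.pam_start + 1,
                "pam_end_1": s.pam_end,
                "protospacer_start_1": s.protospacer_start + 1,
                "protospacer_end_1": s.protospacer_end,
                "nick_gap_0": s.nick_gap,
                "window_start_1": min(s.editable_positions) + 1,
                "window_end_1": max(s.editable_positions) + 1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "editor", "contig", "strand", "pam_start_1", "pam_end_1",
            "protospacer_start_1", "protospacer_end_1", "nick_gap_0",
            "window_start_1", "window_end_1",
        ],
    )
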