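"""pegRNA design (spacer/PBS/RTT), PE3 nicking-guide selection and PE4 assembly.

Design follows the nick on the non-target strand (the protospacer-bearing
strand).  Reverse transcription extends the 3' end created by the nick, so
the RTT-encoded replacement always starts at the nick and runs toward (and,
for long RTTs, past) the PAM:

* PBS  = reverse complement of the L_pbs bases immediately 5' of the nick on
  the nicked strand (equivalently, a substring of the protospacer ending at
  the nick, reverse-complemented),
* RTT  = reverse complement of the *edited* sequence spanning L_rtt nt 3' of
  the nick.

Edits strictly 5' of the nick cannot be encoded this way and raise
:class:`~primewindow.errors.EditUpstreamOfNickError` (they remain *covered*
positions for the coverage statistic — reachable in cells via the nickase's
distal cleavage heterogeneity — but no canonical-nick design exists).

All emitted sequences are DNA (oligo-ready); pass ``rna=True`` where offered
to transliterate T->U.  PE4 constructs link pegRNA and ngRNA through a Csy4
recognition site on one transcript.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import gc_percent, revcomp
from .editor_model import EditorProfile
from .errors import (
    DesignError,
    EditOutsideWindowError,
    EditUpstreamOfNickError,
    RttTooShortError,
)
from .site_scanner import TargetSite, scan_contig

__all__ = [
    "EditSpec",
    "PegRNADesign",
    "NgRNAPick",
    "Pe4Construct",
    "CandidateSearch",
    "apply_edit",
    "candidate_sites_for_edit",
    "design_pegrna",
    "sweep_designs",
    "pick_ngrna",
    "assemble_pe4_construct",
    "DEFAULT_SCAFFOLD",
    "DEFAULT_CSY4_SITE",
    "DEFAULT_PBS_RANGE",
    "DEFAULT_RTT_RANGE",
]

# Generic single-guide scaffold used as a configurable placeholder between
# spacer and RTT; any scaffold (including linker-modified variants) may be
# substituted.
DEFAULT_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)
# Canonical 28-nt Csy4 recognition hairpin (DNA sense), overridable.
DEFAULT_CSY4_SITE = "GTTCACTGCCGTATAGGCAGCTAAGAAA"

DEFAULT_PBS_RANGE = (8, 17)
DEFAULT_RTT_RANGE = (10, 34)
DEFAULT_PBS_LEN = 13
DEFAULT_RTT_HOMOLOGY = 7  # nt of downstream homology beyond the edit end


@dataclass(frozen=True)
class EditSpec:
    """A requested insertion (at a 0-based gap index) or substitution (0-based pos)."""

    contig: str
    edit_type: str  # {"insertion", "substitution"}
    seq: str  # inserted sequence, or the single alternative base
    gap: int | None = None
    pos: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        if self.edit_type == "insertion":
            if self.gap is None or self.gap < 0:
                raise DesignError("insertion requires a non-negative 0-based gap index")
            if not seq or set(seq) - set("ACGT"):
                raise DesignError(f"inserted_seq must be non-empty ACGT, got {seq!r}")
        elif self.edit_type == "substitution":
            if self.pos is None or self.pos < 0:
                raise DesignError("substitution requires a non-negative 0-based pos")
            if len(seq) != 1 or seq not in "ACGT":
                raise DesignError(f"alt_base must be a single base, got {seq!r}")
        else:
            raise DesignError(f"edit_type must be insertion/substitution, got {self.edit_type!r}")

    @property
    def start(self) -> int:
        """Leftmost 0-based coordinate touched by the edit (gap for insertions)."""
        return self.gap if self.edit_type == "insertion" else self.pos  # type: ignore[return-value]

    @property
    def inserted_len(self) -> int:
        """Net length gained by applying the edit."""
        return len(self.seq) if self.edit_type == "insertion" else 0


def apply_edit(seq: str, edit: EditSpec, offset: int = 0) -> str:
    """Apply an edit to a sequence; ``offset`` shifts edit coordinates into
    the sequence's local frame (local = genomic - offset)."""
    if edit.edit_type == "insertion":
        g = edit.gap - offset  # type: ignore[operator]
        if not (0 <= g <= len(seq)):
            raise DesignError(f"insertion gap {edit.gap} outside sequence")
        return seq[:g] + edit.seq + seq[g:]
    p = edit.pos - offset  # type: ignore[operator]
    if not (0 <= p < len(seq)):
        raise DesignError(f"substitution pos {edit.pos} outside sequence")
    if seq[p].upper() == edit.seq:
        raise DesignError(
            f"substitution alt base {edit.seq!r} equals the reference base at pos {edit.pos}"
        )
    return seq[:p] + edit.seq + seq[p + 1 :]


@dataclass(frozen=True)
class PegRNADesign:
    """A designed pegRNA: spacer, PBS and RTT, with an edited-allele preview.

    Sequences are DNA in pegRNA (guide) orientation.  ``spacer_u6`` prepends
    a G when the spacer does not already start with one (U6 expression);
    the unaltered spacer is always kept.
    """

    editor: str
    site: TargetSite
    spacer: str
    pbs: str
    rtt: str
    edited_allele_preview: str
    relative_edit_position: int  # nick-relative; 0 = insertion at the nick
    l_pbs: int
    l_rtt: int

    @property
    def spacer_u6(self) -> str:
        return self.spacer if self.spacer.startswith("G") else "G" + self.spacer

    @property
    def pbs_gc(self) -> float:
        return gc_percent(self.pbs)

    @property
    def rtt_gc(self) -> float:
        return gc_percent(self.rtt)

    def extension(self) -> str:
        """3' extension appended after the scaffold: RTT then PBS (5'->3')."""
        return self.rtt + self.pbs


@dataclass(frozen=True)
class NgRNAPick:
    """A PE3 nicking-guide candidate on the strand opposite the pegRNA site."""

    protospacer: str
    pam_start: int
    strand: str
    nick_distance: int  # signed bp between ngRNA nick gap and pegRNA nick gap
    site: TargetSite


@dataclass(frozen=True)
class Pe4Construct:
    """Single-transcript pegRNA | Csy4 site | ngRNA assembly."""

    sequence: str
    annotations: tuple[tuple[str, int, int], ...]  # (name, start, end) half-open

    def segments(self) -> dict[str, str]:
        return {name: self.sequence[s:e] for name, s, e in self.annotations}


@dataclass
class CandidateSearch:
    """Ranked candidate sites for an edit; carries a reason when empty."""

    sites: list[tuple[TargetSite, int]] = field(default_factory=list)
    no_candidate_reason: dict | None = None

    def __iter__(self):
        return iter(self.sites)

    def __len__(self):
        return len(self.sites)


# ---------------------------------------------------------------------------
# Local (strand-oriented) frame helpers
# ---------------------------------------------------------------------------

def _to_local(contig_seq: str, site: TargetSite, edit: EditSpec):
    """Map contig + site + edit into a frame where the site is on '+'.

    Returns (local_seq, local_site_coords, local_edit).  For '-' sites the
    frame is the reverse complement of the contig with p -> L-1-p (bases)
    and g -> L-g (gaps); inserted sequence / alt base are complemented.
    """
    L = len(contig_seq)
    if site.strand == "+":
        return (
            contig_seq.upper(),
            dict(
                pam_start=site.pam_start,
                ps_start=site.protospacer_start,
                ps_end=site.protospacer_end,
                g=site.nick_gap,
            ),
            edit,
        )
    local_seq = revcomp(contig_seq.upper())
    coords = dict(
        pam_start=L - site.pam_end,
        ps_start=L - site.protospacer_end,
        ps_end=L - site.protospacer_start,
        g=L - site.nick_gap,
    )
    if edit.edit_type == "insertion":
        local_edit = EditSpec(
            contig=edit.contig, edit_type="insertion",
            seq=revcomp(edit.seq), gap=L - edit.gap, label=edit.label,
        )
    else:
        local_edit = EditSpec(
            contig=edit.contig, edit_type="substitution",
            seq=revcomp(edit.seq), pos=L - 1 - edit.pos, label=edit.label,
        )
    return local_seq, coords, local_edit


def relative_edit_position(site: TargetSite, edit: EditSpec) -> int:
    """Nick-relative position of an edit at a site (editor sign convention).

    Substitutions: +k / -k as for bases.  Insertions: 0 means at the nick;
    +k (-k) means the insertion gap sits k gaps toward (away from) the PAM.
    """
    g = site.nick_gap
    sign = 1 if site.strand == "+" else -1
    if edit.edit_type == "insertion":
        return sign * (edit.gap - g)  # type: ignore[operator]
    p = edit.pos  # type: ignore[assignment]
    if site.strand == "+":
        return p - g + 1 if p >= g else p - g
    return g - p if p < g else -(p - g + 1)


def _edit_in_window(site: TargetSite, edit: EditSpec) -> bool:
    positions = set(site.editable_positions)
    if edit.edit_type == "substitution":
        return edit.pos in positions
    # insertion: the gap lies between two window positions, or at the nick
    eg = edit.gap
    return eg == site.nick_gap or (eg - 1 in positions and eg in positions)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def candidate_sites_for_edit(
    contig_seq: str,
    edit: EditSpec,
    profile: EditorProfile,
) -> CandidateSearch:
    """All sites of ``profile`` whose editable window contains the edit,
    ranked nick-proximal first (ascending |relative position|).

    When no site qualifies, ``no_candidate_reason`` reports the nearest PAM
    occurrence and its distance from the edit.
    """
    all_sites = list(scan_contig(contig_seq, edit.contig, profile))
    hits: list[tuple[TargetSite, int]] = []
    for site in all_sites:
        if _edit_in_window(site, edit):
            hits.append((site, relative_edit_position(site, edit)))
    hits.sort(key=lambda sr: (abs(sr[1]), sr[0].pam_start, sr[0].strand))
    if hits:
        return CandidateSearch(sites=hits)
    reason: dict = {"message": "no site's editable window contains the edit"}
    if all_sites:
        edit_point = edit.start
        nearest = min(all_sites, key=lambda s: abs(s.nick_gap - edit_point))
        reason.update(
            nearest_pam_start=nearest.pam_start,
            nearest_strand=nearest.strand,
            nearest_nick_distance_bp=abs(nearest.nick_gap - edit_point),
        )
    else:
        reason["nearest_pam_start"] = None
    return CandidateSearch(sites=[], no_candidate_reason=reason)


def design_pegrna(
    site: TargetSite,
    edit: EditSpec,
    contig_seq: str,
    l_pbs: int = DEFAULT_PBS_LEN,
    l_rtt: int | None = None,
) -> PegRNADesign:
    """Design spacer/PBS/RTT for one edit at one site.

    ``l_rtt=None`` uses (distance from nick to edit end) + 7 nt of downstream
    homology.  Raises :class:`RttTooShortError` when the RTT cannot cover the
    edit plus >= 1 nt of homology, :class:`EditOutsideWindowError` when the
    edit is not in the site's window, and :class:`EditUpstreamOfNickError`
    for edits 5' of the nick (not encodable from the canonical nick).
    """
    if not _edit_in_window(site, edit):
        raise EditOutsideWindowError(
            f"edit at {edit.contig}:{edit.start} is outside the editable window "
            f"of site pam_start={site.pam_start} ({site.strand}, {site.editor})"
        )
    rel = relative_edit_position(site, edit)
    if rel < 0:
        raise EditUpstreamOfNickError(
            f"edit at relative position {rel} lies 5' of the nick; the RTT is "
            "copied 3' of the nick and cannot encode it"
        )
    local_seq, c, local_edit = _to_local(contig_seq, site, edit)
    g = c["g"]
    if l_pbs < 1:
        raise DesignError(f"l_pbs must be >= 1, got {l_pbs}")
    if g - l_pbs < c["ps_start"]:
        raise DesignError(
            f"l_pbs={l_pbs} reaches past the PAM-distal protospacer end "
            f"(max {g - c['ps_start']} for this profile)"
        )

    edited_local = apply_edit(local_seq, local_edit)
    # End of the edit in *edited* coordinates (edits are at/3' of the nick,
    # so coordinates up to g are unchanged).
    if local_edit.edit_type == "insertion":
        edit_end = local_edit.gap + len(local_edit.seq)  # type: ignore[operator]
    else:
        edit_end = local_edit.pos + 1  # type: ignore[operator]
    min_rtt = (edit_end - g) + 1
    if l_rtt is None:
        l_rtt = (edit_end - g) + DEFAULT_RTT_HOMOLOGY
    if l_rtt < min_rtt:
        raise RttTooShortError(
            f"l_rtt={l_rtt} cannot cover the edit plus 1 nt of downstream "
            f"homology; minimum feasible is {min_rtt}",
            min_feasible=min_rtt,
        )
    if g + l_rtt > len(edited_local):
        raise DesignError(
            f"l_rtt={l_rtt} runs past the contig end; at most "
            f"{len(edited_local) - g} available"
        )

    spacer = local_seq[c["ps_start"] : c["ps_end"]]
    pbs = revcomp(local_seq[g - l_pbs : g])
    rtt = revcomp(edited_local[g : g + l_rtt])
    if len(set(pbs)) == 1:
        warnings.warn(
            f"PBS {pbs!r} is a homopolymer; consider a different l_pbs",
            stacklevel=2,
        )
    preview = edited_local[c["ps_start"] : g + l_rtt]
    return PegRNADesign(
        editor=site.editor,
        site=site,
        spacer=spacer,
        pbs=pbs,
        rtt=rtt,
        edited_allele_preview=preview,
        relative_edit_position=rel,
        l_pbs=l_pbs,
        l_rtt=l_rtt,
    )


def sweep_designs(
    site: TargetSite,
    edit: EditSpec,
    contig_seq: str,
    pbs_range: tuple[int, int] = DEFAULT_PBS_RANGE,
    rtt_range: tuple[int, int] = DEFAULT_RTT_RANGE,
) -> pd.DataFrame:
    """One row per (L_pbs, L_rtt) combination; invalid combos are flagged,
    never silently dropped.  Includes GC% of PBS and RTT."""
    if pbs_range[0] > pbs_range[1] or rtt_range[0] > rtt_range[1]:
        raise DesignError("pbs_range and rtt_range must be non-empty")
    rows = []
    for l_pbs in range(pbs_range[0], pbs_range[1] + 1):
        for l_rtt in range(rtt_range[0], rtt_range[1] + 1):
            row: dict = {"l_pbs": l_pbs, "l_rtt": l_rtt}
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    d = design_pegrna(site, edit, contig_seq, l_pbs=l_pbs, l_rtt=l_rtt)
            except DesignError as exc:
                row.update(ok=False, reason=type(exc).__name__, spacer="", pbs="",
                           rtt="", pbs_gc_pct=float("nan"), rtt_gc_pct=float("nan"))
            else:
                row.update(
                    ok=True, reason="", spacer=d.spacer, pbs=d.pbs, rtt=d.rtt,
                    pbs_gc_pct=round(d.pbs_gc, 2), rtt_gc_pct=round(d.rtt_gc, 2),
                )
            rows.append(row)
    return pd.DataFrame(rows)


def pick_ngrna(
    contig_seq: str,
    peg_site: TargetSite,
    profile: EditorProfile,
    distance_range: tuple[int, int] = (40, 100),
) -> list[NgRNAPick]:
    """PE3 nicking-guide candidates on the strand opposite the pegRNA site.

    Candidates are sites of ``profile`` whose nick-to-nick distance (signed,
    ngRNA nick gap minus pegRNA nick gap in plus-strand coordinates) has
    absolute value within ``distance_range``; sorted by |distance|.
    """
    dmin, dmax = distance_range
    if dmin > dmax or dmax < 0:
        raise DesignError(f"distance_range must be a non-empty range, got {distance_range}")
    want_strand = "-" if peg_site.strand == "+" else "+"
    picks = []
    for site in scan_contig(contig_seq, peg_site.contig, profile):
        if site.strand != want_strand:
            continue
        d = site.nick_gap - peg_site.nick_gap
        if dmin <= abs(d) <= dmax:
            picks.append(
                NgRNAPick(
                    protospacer=site.protospacer_seq(contig_seq),
                    pam_start=site.pam_start,
                    strand=site.strand,
                    nick_distance=d,
                    site=site,
                )
            )
    picks.sort(key=lambda p: (abs(p.nick_distance), p.pam_start))
    return picks


def assemble_pe4_construct(
    peg: PegRNADesign,
    ng: NgRNAPick,
    scaffold: str = DEFAULT_SCAFFOLD,
    csy4_site: str = DEFAULT_CSY4_SITE,
    rna: bool = False,
) -> Pe4Construct:
    """Assemble the single transcript  spacer+scaffold+RTT+PBS | Csy4 | ng_spacer+scaffold.

    In-cell Csy4 cleavage at the recognition site releases the two guide
    units; the annotation intervals tile the sequence without overlap.
    """
    for name, s in (("scaffold", scaffold), ("csy4_site", csy4_site)):
        if not s or set(s.upper()) - set("ACGTU"):
            raise DesignError(f"{name} must be a non-empty nucleotide string")
    segments = [
        ("peg_spacer", peg.spacer),
        ("scaffold", scaffold),
        ("rtt", peg.rtt),
        ("pbs", peg.pbs),
        ("csy4_site", csy4_site),
        ("ng_spacer", ng.protospacer),
        ("ng_scaffold", scaffold),
    ]
    seq_parts: list[str] = []
    annotations: list[tuple[str, int, int]] = []
    pos = 0
    for name, part in segments:
        seq_parts.append(part)
        annotations.append((name, pos, pos + len(part)))
        pos += len(part)
    sequence = "".join(seq_parts)
    if rna:
        sequence = sequence.replace("T", "U").replace("t", "u")
    return Pe4Construct(sequence=sequence, annotations=tuple(annotations))
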