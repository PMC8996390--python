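"""Editor profiles and nick/window coordinate arithmetic.

A prime editor built on a Cas9 nickase is characterised, for targetability
purposes, by three things:

* its PAM (an IUPAC pattern 3' of the protospacer, e.g. ``NGG``, or ``YG``
  for the relaxed-PAM RHA-FnCas9 variant),
* its canonical nick offset N — the nick on the non-target strand sits N
  protospacer nucleotides upstream (5') of the PAM, and
* its editable window — positions relative to the nick where an edit can be
  installed with useful efficiency.

Coordinates are 0-based, half-open internally.  A nick is represented as a
*gap index* g meaning "between base g-1 and base g" on the plus strand.
Relative positions use the convention: +k is the k-th base on the PAM side
of the nick, -k the k-th base on the PAM-distal side; position 0 does not
exist (the nick itself is the 0 boundary).

Built-in profiles::

    SpPE      NGG, nick 3 bp upstream of PAM, window (-1, +3)
    FnPE      NGG, nick 6 bp upstream of PAM, window (-6, +3)
    RHA-FnPE  YG,  nick 6 bp upstream of PAM, window (-6, +3)

The observed nick ranges (3-4 bp for SpCas9, 6-8 bp for FnCas9 on the
non-target strand) are collapsed to the canonical design offsets 3 and 6;
the full ranges remain expressible through custom profiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._seq import IUPAC_SETS
from .errors import BoundaryError, ProfileError

__all__ = [
    "PamSpec",
    "EditorProfile",
    "BUILTIN_PROFILE_NAMES",
    "builtin_profile",
    "load_profiles",
    "nick_gap",
    "protospacer_interval",
    "window_positions",
    "window_interval",
]


@dataclass(frozen=True)
class PamSpec:
    """An IUPAC PAM pattern located 3' of the protospacer (Cas9 geometry)."""

    pattern: str
    side: str = "three_prime_of_protospacer"

    def __post_init__(self) -> None:
        pattern = self.pattern.upper()
        object.__setattr__(self, "pattern", pattern)
        if len(pattern) < 1:
            raise ProfileError("PamSpec.pattern must be at least 1 nt")
        bad = sorted(set(pattern) - set(IUPAC_SETS))
        if bad:
            raise ProfileError(
                f"PamSpec.pattern contains non-IUPAC characters {bad!r} in {pattern!r}"
            )
        if self.side != "three_prime_of_protospacer":
            raise ProfileError(
                f"PamSpec.side must be 'three_prime_of_protospacer', got {self.side!r}"
            )

    @property
    def length(self) -> int:
        return len(self.pattern)

    def matches(self, seq: str, start: int = 0) -> bool:
        """Case-insensitive IUPAC match of the pattern at ``seq[start:]``.

        Ambiguous genome bases (N) never match.
        """
        if start < 0 or start + self.length > len(seq):
            return False
        for code, base in zip(self.pattern, seq[start : start + self.length].upper()):
            if base not in IUPAC_SETS[code] or code == "N" and base == "N":
                return False
        return True


@dataclass(frozen=True)
class EditorProfile:
    """PAM spec, nick geometry and editable window of one prime editor."""

    name: str
    pam: PamSpec
    nick_offset: int
    window: tuple[int, int]
    protospacer_len: int = 20

    def __post_init__(self) -> None:
        if isinstance(self.pam, str):  # convenience: accept a raw pattern
            object.__setattr__(self, "pam", PamSpec(self.pam))
        if not self.name:
            raise ProfileError("EditorProfile.name must be non-empty")
        if self.protospacer_len < 1:
            raise ProfileError("protospacer_len must be >= 1")
        if not (1 <= self.nick_offset <= self.protospacer_len):
            raise ProfileError(
                f"nick_offset must be in [1, protospacer_len]; "
                f"got {self.nick_offset} for {self.name!r}"
            )
        lo, hi = self.window
        if lo == 0 or hi == 0:
            raise ProfileError(
                f"window must not contain 0 (the nick is the 0 boundary); got {self.window}"
            )
        if not (lo <= -1 < 1 <= hi):
            raise ProfileError(
                f"window must satisfy lo <= -1 < +1 <= hi; got {self.window}"
            )
        # Window positions mapped into the protospacer must stay inside it:
        # +hi reaches nick_offset - hi bases short of the PAM (no editing in
        # the PAM), -|lo| reaches nick_offset + |lo| bases from the PAM.
        if hi > self.nick_offset:
            raise ProfileError(
                f"window hi={hi} extends into the PAM (nick_offset {self.nick_offset})"
            )
        if self.nick_offset - lo > self.protospacer_len:
            raise ProfileError(
                f"window lo={lo} extends past the PAM-distal protospacer end "
                f"(nick_offset {self.nick_offset}, protospacer {self.protospacer_len} nt)"
            )

    @property
    def window_size(self) -> int:
        """Number of editable positions: (hi - lo + 1) minus the excluded 0."""
        lo, hi = self.window
        return hi - lo


_BUILTINS: dict[str, EditorProfile] = {
    "SpPE": EditorProfile("SpPE", PamSpec("NGG"), nick_offset=3, window=(-1, 3)),
    "FnPE": EditorProfile("FnPE", PamSpec("NGG"), nick_offset=6, window=(-6, 3)),
    "RHA-FnPE": EditorProfile("RHA-FnPE", PamSpec("YG"), nick_offset=6, window=(-6, 3)),
}

BUILTIN_PROFILE_NAMES: tuple[str, ...] = tuple(_BUILTINS)


def builtin_profile(name: str) -> EditorProfile:
    """Return a built-in profile by name ({SpPE, FnPE, RHA-FnPE})."""
    try:
        return _BUILTINS[name]
    except KeyError:
        raise ProfileError(
            f"unknown builtin profile {name!r}; choose from {sorted(_BUILTINS)}"
        ) from None


def _profile_from_record(rec: dict) -> EditorProfile:
    try:
        window = (int(rec["window_lo"]), int(rec["window_hi"]))
        return EditorProfile(
            name=str(rec["name"]),
            pam=PamSpec(str(rec["pam"])),
            nick_offset=int(rec["nick_offset"]),
            window=window,
            protospacer_len=int(rec.get("protospacer_len", 20) or 20),
        )
    except KeyError as exc:
        raise ProfileError(f"profile record missing field {exc}") from None


def load_profiles(source: str | Path | Sequence | dict) -> list[EditorProfile]:
    """Resolve editor profiles from builtin names, a config file, or records.

    ``source`` may be

    * a builtin name ("FnPE") or comma-separated names ("SpPE,FnPE"),
    * a list of names and/or :class:`EditorProfile` objects,
    * a path to a TSV with columns name, pam, protospacer_len, nick_offset,
      window_lo, window_hi, or a JSON file containing a list of such records,
    * a dict or list of dicts with the same fields.
    """
    if isinstance(source, EditorProfile):
        return [source]
    if isinstance(source, dict):
        return [_profile_from_record(source)]
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix.lower() in {".tsv", ".txt", ".json"} or path.is_file():
            return _load_profile_file(path)
        names = [n.strip() for n in str(source).split(",") if n.strip()]
        return [builtin_profile(n) for n in names]
    profiles: list[EditorProfile] = []
    for item in source:
        if isinstance(item, EditorProfile):
            profiles.append(item)
        elif isinstance(item, dict):
            profiles.append(_profile_from_record(item))
        else:
            profiles.append(builtin_profile(str(item)))
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ProfileError(f"duplicate profile names in config: {names}")
    return profiles


def _load_profile_file(path: Path) -> list[EditorProfile]:
    if not path.is_file():
        raise ProfileError(f"profile config not found: {path}")
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if isinstance(records, dict):
            records = [records]
    else:
        records = pd.read_csv(path, sep="\t").to_dict("records")
    profiles = [_profile_from_record(r) for r in records]
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ProfileError(f"duplicate profile names in {path}: {names}")
    return profiles


# ---------------------------------------------------------------------------
# Coordinate arithmetic
# ---------------------------------------------------------------------------

def _check_strand(strand: str) -> None:
    if strand not in {"+", "-"}:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def protospacer_interval(
    profile: EditorProfile, pam_start: int, strand: str
) -> tuple[int, int]:
    """0-based half-open genomic interval of the protospacer for a PAM occurrence.

    On '+' the protospacer ends where the PAM starts; on '-' it starts where
    the PAM (seen as its reverse complement on the plus strand) ends.
    """
    _check_strand(strand)
    plen = profile.pam.length
    if strand == "+":
        return pam_start - profile.protospacer_len, pam_start
    return pam_start + plen, pam_start + plen + profile.protospacer_len


def nick_gap(profile: EditorProfile, pam_start: int, strand: str) -> int:
    """Gap index of the non-target-strand nick for a PAM occurrence.

    The nick sits ``nick_offset`` protospacer nucleotides from the
    PAM-proximal protospacer end.  A gap index g means "between base g-1 and
    base g" in plus-strand coordinates, for either strand.
    """
    _check_strand(strand)
    if strand == "+":
        return pam_start - profile.nick_offset
    return pam_start + profile.pam.length + profile.nick_offset


def window_interval(profile: EditorProfile, pam_start: int, strand: str) -> tuple[int, int]:
    """Half-open genomic interval spanned by the editable window (contiguous)."""
    _check_strand(strand)
    lo, hi = profile.window
    g = nick_gap(profile, pam_start, strand)
    if strand == "+":
        return g + lo, g + hi
    return g - hi, g - lo


def window_positions(
    profile: EditorProfile,
    pam_start: int,
    strand: str,
    contig_len: int,
) -> tuple[int, ...]:
    """Genomic 0-based positions of the editable bases for one PAM occurrence.

    Relative position +k (k >= 1) is the k-th base on the PAM side of the
    nick, -k the k-th base on the PAM-distal side; all arithmetic is mirrored
    on '-'.  Windows are never clipped: a window (or protospacer/PAM) that
    falls off the contig raises :class:`BoundaryError`.
    """
    _check_strand(strand)
    ps_start, ps_end = protospacer_interval(profile, pam_start, strand)
    pam_end = pam_start + profile.pam.length
    if min(ps_start, pam_start) < 0 or max(ps_end, pam_end) > contig_len:
        raise BoundaryError(
            f"site at pam_start={pam_start} ({strand}) does not fit in a "
            f"{contig_len}-nt contig (protospacer {ps_start}..{ps_end})"
        )
    w_start, w_end = window_interval(profile, pam_start, strand)
    if w_start < 0 or w_end > contig_len:
        raise BoundaryError(
            f"editable window {w_start}..{w_end} of site at pam_start={pam_start} "
            f"({strand}) extends past the contig boundary (len {contig_len})"
        )
    return tuple(range(w_start, w_end))


def relative_position(
    profile: EditorProfile, pam_start: int, strand: str, pos: int
) -> int:
    """Nick-relative position of genomic base ``pos`` (sign convention above).

    Returns +k for the k-th base on the PAM side of the nick, -k on the
    PAM-distal side.  Defined for any genomic position, in-window or not.
    """
    g = nick_gap(profile, pam_start, strand)
    if strand == "+":
        return pos - g + 1 if pos >= g else pos - g
    return g - pos if pos < g else -(pos - g + 1)
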