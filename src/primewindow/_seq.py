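"""Small sequence helpers shared across modules."""

from __future__ import annotations

from Bio.Seq import reverse_complement as _bio_rc

# IUPAC nucleotide codes -> set of concrete bases matched.  An 'N' *in the
# genome* matches nothing (ambiguous template bases cannot be designed
# against); 'N' in a PAM pattern matches any concrete base.
IUPAC_SETS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# Complement of each IUPAC code (for deriving the reverse-complement PAM
# pattern, e.g. NGG -> CCN).
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware, case preserved by Biopython)."""
    return str(_bio_rc(seq))


def revcomp_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern, e.g. ``NGG -> CCN``, ``YG -> CR``."""
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(pattern.upper()))


def gc_percent(seq: str) -> float:
    """GC content in percent; 0.0 for an empty string."""
    if not seq:
        return 0.0
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def base_matches(base: str, code: str) -> bool:
    """True iff a concrete genome base matches an IUPAC pattern code."""
    return base in IUPAC_SETS.get(code, "")
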