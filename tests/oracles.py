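"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's scanning/arithmetic code paths:
window positions are enumerated by literal base-counting, PAM matching is a
position-by-position set-membership loop, and coverage is an all-pairs
membership test.
"""

from __future__ import annotations

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq.upper()))


def iupac_match(seq: str, pos: int, pattern: str) -> bool:
    """Literal sliding-window IUPAC match (genome N never matches)."""
    if pos < 0 or pos + len(pattern) > len(seq):
        return False
    for k, code in enumerate(pattern):
        if seq[pos + k] not in IUPAC[code]:
            return False
    return True


def oracle_window_positions(pam_start, strand, nick_offset, lo, hi, pam_len=2,
                            protospacer_len=20):
    """Editable genomic positions, enumerated by counting bases one at a time.

    Walk from the PAM-proximal protospacer base, step ``nick_offset`` bases
    to find the nick gap, then collect +1..hi toward the PAM and -1..lo away
    from it.
    """
    positions = []
    if strand == "+":
        # protospacer bases adjacent to PAM: pam_start-1, pam_start-2, ...
        walk = pam_start
        for _ in range(nick_offset):
            walk -= 1  # step over one protospacer base toward the PAM-distal end
        gap = walk  # nick between walk-1 and walk
        p = gap
        for _ in range(hi):  # +1..+hi: toward the PAM
            positions.append(p)
            p += 1
        p = gap - 1
        for _ in range(-lo):  # -1..lo: away from the PAM
            positions.append(p)
            p -= 1
    else:
        walk = pam_start + pam_len
        for _ in range(nick_offset):
            walk += 1
        gap = walk
        p = gap - 1
        for _ in range(hi):
            positions.append(p)
            p -= 1
        p = gap
        for _ in range(-lo):
            positions.append(p)
            p += 1
    return sorted(positions), gap


def oracle_scan(seq, pattern, nick_offset, lo, hi, protospacer_len=20):
    """All (strand, pam_start) target sites via naive matching on the
    sequence and its reverse complement, with in-bounds and no-N filters."""
    seq = seq.upper()
    L = len(seq)
    plen = len(pattern)
    out = []
    for strand, pat in (("+", pattern), ("-", rc_pattern(pattern))):
        for i in range(L - plen + 1):
            if not iupac_match(seq, i, pat):
                continue
            if strand == "+":
                ps = (i - protospacer_len, i)
            else:
                ps = (i + plen, i + plen + protospacer_len)
            if ps[0] < 0 or ps[1] > L:
                continue
            w, _gap = oracle_window_positions(i, strand, nick_offset, lo, hi, plen,
                                              protospacer_len)
            if w[0] < 0 or w[-1] >= L:
                continue
            region = seq[min(ps[0], i): max(ps[1], i + plen)]
            if "N" in region:
                continue
            out.append((strand, i))
    return sorted(out, key=lambda t: (t[1], t[0]))


def rc_pattern(pattern: str) -> str:
    comp = {
        "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
        "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
        "N": "N",
    }
    return "".join(comp[c] for c in reversed(pattern))


def oracle_coverage(variants, sites):
    """All-pairs membership: a variant is targetable iff any site's window
    contains its 0-based position on the same contig."""
    n_targetable = 0
    for v in variants:
        hit = any(
            s.contig == v.contig and (v.pos - 1) in s.editable_positions
            for s in sites
        )
        n_targetable += hit
    return n_targetable


def oracle_splice(wt_contig: str, rtt: str, nick_gap: int, net_insertion: int) -> str:
    """Reconstruct the edited allele by splicing the RTT-encoded flap onto
    the nicked plus strand: the reverse complement of the RTT replaces the
    WT bases from the nick over (len(rtt) - net_insertion) nt."""
    flap = rc(rtt)
    return wt_contig[:nick_gap] + flap + wt_contig[nick_gap + len(rtt) - net_insertion:]
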